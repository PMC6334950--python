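"""Synthetic post-partum dairy cohort with a known 7-cluster structure.

The generator emulates the structure of a 145-cow transition-period cohort:
seven physiological states (sizes 19/37/27/44/5/10/3) ranging from a
metabolically unremarkable reference cluster to small, deviant groups
(ketoacidotic cows; fresh cows with massive lipomobilization). Each cluster
is a :class:`ClusterPrototype` of *primitive measured* quantities (blood gas
panel, serum chemistry, urine panel, clinical covariates) obtained by
inverting the acid-base formulas from per-cluster targets on the derived
variables: the reference cluster sits at the midpoints of the within-study
reference intervals, and the other clusters are displaced along the
qualitative deviation pattern of the source tabulation (single arrow: one
interval width beyond the bound; double arrow: two widths; parenthesized
arrow: half a width from the center, still inside).

Gaussian noise is applied to the primitive quantities only (sd = ``noise_sd``
x the between-prototype spread of that variable, with a documented floor for
variables whose prototypes agree), truncated to physiologic bounds; every
derived variable is then recomputed forward through the blood and urine
modules, so each synthetic record is internally consistent — its bicarbonate
always matches its pH and pCO2, its XA its electroneutrality balance. The
generating cluster is retained as a simulation-only ground-truth column.

This is an emulation of the study design, not a reconstruction of the real
animals: within-cluster dispersions and farm effects are modeled, not
reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blood_acidbase import DEFAULT_CONSTANTS, derive_blood_frame
from .urine_acidbase import derive_urine_frame
from .reference_intervals import study_reference_intervals

__all__ = [
    "ClusterPrototype", "SyntheticConfig", "default_prototypes",
    "generate_cohort", "write_cohort", "read_cohort",
    "PRIMITIVE_VARIABLES", "PRIMITIVE_BOUNDS", "COHORT_COLUMNS",
]

#: Primitive measured quantities that carry sampling noise. Total protein is
#: recomputed as albumin + globulin after noise so the protein fractions stay
#: coherent; all acid-base variables are derived forward.
PRIMITIVE_VARIABLES = [
    "pH_v", "pCO2_v", "ctHb", "body_temp",
    "cNa", "cK", "cCa_ion", "cCl", "cGlucose", "cLactate", "cPi", "cMg_total",
    "cAlbumin", "cGlobulin",
    "cNEFA", "cBHB", "cUrea", "cBilirubin", "cCholesterol", "aGLDH",
    "cNa_u", "cK_u", "cCa_u", "cMg_u", "cCl_u", "pH_u",
    "cBE_u", "cAE_u", "cAmm_u", "bcs",
]

#: Physiologic truncation bounds applied after noise (units as elsewhere).
PRIMITIVE_BOUNDS = {
    "pH_v": (6.8, 7.8), "pCO2_v": (20.0, 90.0), "ctHb": (4.0, 18.0),
    "body_temp": (37.0, 40.0),
    "cNa": (125.0, 160.0), "cK": (2.5, 7.0), "cCa_ion": (0.5, 1.8),
    "cCl": (80.0, 125.0), "cGlucose": (0.5, 8.0), "cLactate": (0.05, 8.0),
    "cPi": (0.3, 3.5), "cMg_total": (0.4, 1.8),
    "cAlbumin": (15.0, 50.0), "cGlobulin": (15.0, 70.0),
    "cNEFA": (0.02, 3.0), "cBHB": (100.0, 6000.0), "cUrea": (1.0, 12.0),
    "cBilirubin": (0.5, 40.0), "cCholesterol": (0.5, 8.0), "aGLDH": (2.0, 150.0),
    "cNa_u": (1.0, 250.0), "cK_u": (30.0, 400.0), "cCa_u": (0.2, 15.0),
    "cMg_u": (0.5, 25.0), "cCl_u": (5.0, 250.0), "pH_u": (5.0, 9.6),
    "cBE_u": (0.0, 600.0), "cAE_u": (1.0, 400.0), "cAmm_u": (0.5, 250.0),
    "bcs": (1.5, 5.0),
}

#: Floor on the between-prototype spread used for the noise scale, so that
#: variables whose prototypes coincide still carry assay precision plus
#: within-state biological variation (floor ~ 5x the desired within-cluster
#: SD at the default noise_sd of 0.2).
SPREAD_FLOOR = {
    "pH_v": 0.02, "pCO2_v": 4.0, "ctHb": 1.0, "body_temp": 0.4,
    "cNa": 4.0, "cK": 0.8, "cCa_ion": 0.12, "cCl": 3.0, "cGlucose": 1.2,
    "cLactate": 0.6, "cPi": 0.6, "cMg_total": 0.2,
    "cAlbumin": 12.0, "cGlobulin": 13.0,
    "cNEFA": 1.3, "cBHB": 500.0, "cUrea": 2.0, "cBilirubin": 2.5,
    "cCholesterol": 1.0, "aGLDH": 15.0,
    "cNa_u": 12.0, "cK_u": 60.0, "cCa_u": 1.5, "cMg_u": 4.0, "cCl_u": 15.0,
    "pH_u": 0.2, "cBE_u": 30.0, "cAE_u": 20.0, "cAmm_u": 10.0, "bcs": 0.5,
}

_CLUSTER_SIZES = (19, 37, 27, 44, 5, 10, 3)
_N_FARMS_TOTAL = 13


@dataclass(frozen=True)
class ClusterPrototype:
    """Central primitive values and metadata for one physiological state."""

    name: int
    size: int
    targets: dict[str, float]
    shift_pattern: dict[str, float] = field(default_factory=dict)
    dim_median: float = 5.0
    n_farms: int = 4
    rumen_fill_probs: tuple[float, float, float] = (0.4, 0.5, 0.1)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        for var, (lo, hi) in PRIMITIVE_BOUNDS.items():
            t = self.targets.get(var)
            if t is not None and not (lo <= t <= hi):
                raise ValueError(
                    f"cluster {self.name}: target {var}={t} outside "
                    f"physiologic bounds ({lo}, {hi})")


@dataclass(frozen=True)
class SyntheticConfig:
    prototypes: tuple[ClusterPrototype, ...]
    noise_sd: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(p.size for p in self.prototypes)


def _shifted(low: float, high: float, arrows: float) -> float:
    """Target on a derived variable from its reference interval and an arrow
    code: 0 center; +-n -> n interval widths beyond the bound; fractional
    |code| < 1 -> parenthesized arrow, still inside the interval."""
    mid, w = 0.5 * (low + high), high - low
    if arrows == 0:
        return mid
    if abs(arrows) < 1:
        return mid + arrows * w
    return high + arrows * w if arrows > 0 else low + arrows * w


def default_prototypes() -> list[ClusterPrototype]:
    """The seven study-condition prototypes, built by formula inversion.

    Per-cluster targets are set on the derived control variables (AG, SID_m5,
    Atot_alb, Atot_prt, urinary BAR and pH, plus the metabolism markers) and
    inverted to primitives: albumin and total protein from the buffer totals,
    chloride from the SID target, bicarbonate from SID_m3 - AG and hence pCO2
    from the Henderson-Hasselbalch relation, and the urine titration
    components from the BAR target and a chosen total acid excretion.
    """
    ref = study_reference_intervals()
    c = DEFAULT_CONSTANTS

    # arrow codes per cluster 1..7 (cluster 2 is the reference, code 0)
    ag_arrows = [0, 0, -1, -1, 1, 0, -2]
    sid_arrows = [-1, 0, -1, -1, 0, 0, -2]
    atot_alb_arrows = [0, 0, -1, 0.5, -1, 1, 2]
    atot_prt_arrows = [-0.75, 0, 0, 0, 0, 2, 0]  # cluster 1: mild deficit (colostrum)
    ph_u_arrows = [0, 0, -1, -1, -1, 0, 1]

    # direct primitive/metabolism targets per cluster
    na = [148.0, 143.0, 143.0, 143.0, 143.0, 145.0, 143.0]
    k = [4.3] * 7
    ca = [1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 0.9]
    lact = [0.7, 0.7, 0.4, 0.7, 0.4, 0.7, 0.7]
    mg = [0.95, 0.95, 0.8, 0.95, 0.95, 1.15, 0.95]
    glu = [3.5, 3.5, 3.5, 3.5, 2.2, 3.5, 3.5]
    pi = [1.8] * 7
    cthb = [10.0, 10.0, 10.0, 10.0, 10.0, 9.0, 11.0]
    temp = [38.7, 38.6, 38.9, 38.7, 39.1, 38.3, 38.7]
    nefa = [0.92, 0.30, 0.92, 0.92, 0.92, 0.15, 1.52]
    bhb = [700.0, 700.0, 700.0, 700.0, 2000.0, 500.0, 900.0]
    chol = [2.1, 2.5, 2.1, 2.5, 2.1, 2.9, 2.5]
    bili = [3.0, 3.0, 3.0, 3.0, 5.0, 3.0, 15.0]
    urea = [4.0] * 7
    gldh = [15.0] * 7
    # urine: cluster 1 fed a salt surplus (Na+Cl excretion up), cluster 3
    # anorectic (low Cl intake, low excretion), cluster 4 excreting its acid
    # load with chloride, cluster 6 on sodium-bicarbonate rumen buffer
    na_u = [55.0, 15.0, 15.0, 15.0, 15.0, 40.0, 15.0]
    k_u = [200.0] * 7
    ca_u = [2.0] * 7
    mg_u = [8.0] * 7
    cl_u = [170.0, 90.0, 60.0, 130.0, 90.0, 80.0, 90.0]
    bar_t = [1.7, 2.95, 0.4, 1.02, 0.4, 4.9, 4.9]
    acid_denom = [110.0, 81.0, 170.0, 100.0, 170.0, 80.5, 40.5]
    amm_frac = [0.25, 0.25, 0.25, 0.25, 0.6, 0.25, 0.25]
    bcs = [3.5, 3.25, 3.25, 3.25, 3.25, 2.5, 4.5]
    dim = [3.0, 5.0, 6.0, 4.0, 8.0, 54.0, 1.0]
    n_farms = [4, 11, 11, 12, 4, 3, 1]
    rumen = [(0.521, 0.479, 0.0), (0.297, 0.541, 0.162), (0.48, 0.48, 0.04),
             (0.409, 0.523, 0.068), (0.8, 0.2, 0.0), (0.2, 0.5, 0.3),
             (1.0, 0.0, 0.0)]
    # venous pH: all states within the normal band, acid-loaded states at
    # its lower edge, the alkali-loaded lactating group at the upper edge
    ph_v = [7.385, 7.392, 7.390, 7.382, 7.384, 7.396, 7.390]

    protos: list[ClusterPrototype] = []
    for i in range(7):
        sid5 = _shifted(ref["SID_m5"].low, ref["SID_m5"].high, sid_arrows[i])
        ag = _shifted(ref["AG"].low, ref["AG"].high, ag_arrows[i])
        a_alb = _shifted(ref["Atot_alb"].low, ref["Atot_alb"].high, atot_alb_arrows[i])
        a_prt = _shifted(ref["Atot_prt"].low, ref["Atot_prt"].high, atot_prt_arrows[i])
        ph_u = _shifted(ref["pH_u"].low, ref["pH_u"].high, ph_u_arrows[i])

        albumin = a_alb / c.atot_alb_coeff
        total_protein = a_prt / c.atot_prt_coeff
        globulin = total_protein - albumin
        if globulin <= 0:
            raise ValueError(f"cluster {i + 1}: Atot targets imply non-positive globulin")
        cl = na[i] + k[i] + 2.0 * ca[i] - lact[i] - sid5
        hco3 = na[i] + k[i] - cl - ag
        pco2 = hco3 / (c.S * 10.0 ** (ph_v[i] - c.pK1))
        amm = amm_frac[i] * acid_denom[i]
        ae = acid_denom[i] - amm
        be = bar_t[i] * acid_denom[i]

        targets = {
            "pH_v": ph_v[i], "pCO2_v": pco2, "ctHb": cthb[i], "body_temp": temp[i],
            "cNa": na[i], "cK": k[i], "cCa_ion": ca[i], "cCl": cl,
            "cGlucose": glu[i], "cLactate": lact[i], "cPi": pi[i],
            "cMg_total": mg[i], "cAlbumin": albumin, "cGlobulin": globulin,
            "cNEFA": nefa[i], "cBHB": bhb[i], "cUrea": urea[i],
            "cBilirubin": bili[i], "cCholesterol": chol[i], "aGLDH": gldh[i],
            "cNa_u": na_u[i], "cK_u": k_u[i], "cCa_u": ca_u[i],
            "cMg_u": mg_u[i], "cCl_u": cl_u[i], "pH_u": ph_u,
            "cBE_u": be, "cAE_u": ae, "cAmm_u": amm, "bcs": bcs[i],
        }
        pattern = {"AG": ag_arrows[i], "SID_m5": sid_arrows[i],
                   "Atot_alb": atot_alb_arrows[i], "Atot_prt": atot_prt_arrows[i],
                   "pH_u": ph_u_arrows[i]}
        protos.append(ClusterPrototype(
            name=i + 1, size=_CLUSTER_SIZES[i], targets=targets,
            shift_pattern=pattern, dim_median=dim[i], n_farms=n_farms[i],
            rumen_fill_probs=rumen[i]))
    return protos


def _noise_scales(prototypes, noise_sd: float) -> dict[str, float]:
    """Per-variable noise SD: noise_sd x the between-prototype spread
    (standard deviation of the prototype targets, floored per variable)."""
    scales = {}
    for var in PRIMITIVE_VARIABLES:
        targets = np.array([p.targets[var] for p in prototypes], dtype=float)
        spread = max(float(np.std(targets)), SPREAD_FLOOR.get(var, 0.0))
        scales[var] = noise_sd * spread
    return scales


#: Column order of the cohort CSV schema (primitives, clinical covariates,
#: then derived variables appended by generate_cohort).
COHORT_COLUMNS = (["animal_id", "farm", "true_cluster", "dim", "rumen_fill"]
                  + PRIMITIVE_VARIABLES + ["cTotalProtein"])


def generate_cohort(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Draw the synthetic cohort and compute all derived variables forward.

    Returns one row per animal with primitives, clinical covariates, derived
    blood acid-base variables, urinary NABE/BAR, the albumin/globulin ratio
    AGR, and the simulation-only ``true_cluster`` ground-truth label.
    """
    if config is None:
        config = SyntheticConfig(prototypes=tuple(default_prototypes()))
    rng = np.random.default_rng(config.seed)
    scales = _noise_scales(config.prototypes, config.noise_sd)
    farm_pool = [f"F{j:02d}" for j in range(1, _N_FARMS_TOTAL + 1)]

    frames = []
    for proto in config.prototypes:
        n = proto.size
        cols: dict[str, np.ndarray] = {}
        for var in PRIMITIVE_VARIABLES:
            lo, hi = PRIMITIVE_BOUNDS[var]
            draw = rng.normal(proto.targets[var], scales[var], size=n)
            cols[var] = np.clip(draw, lo, hi)
        # days in milk: fresh cows 1-15, high-lactating 43-76
        dim_lo, dim_hi = (43, 76) if proto.dim_median > 20 else (1, 15)
        dim = np.clip(np.rint(rng.normal(proto.dim_median, 3.0, size=n)), dim_lo, dim_hi)
        farms = rng.choice(farm_pool, size=proto.n_farms, replace=False)
        df = pd.DataFrame(cols)
        df.insert(0, "rumen_fill", rng.choice(
            [1, 2, 3], size=n, p=np.asarray(proto.rumen_fill_probs)
            / sum(proto.rumen_fill_probs)))
        df.insert(0, "dim", dim.astype(int))
        df.insert(0, "true_cluster", proto.name)
        df.insert(0, "farm", rng.choice(farms, size=n))
        frames.append(df)

    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "animal_id", [f"cow{i + 1:03d}" for i in range(len(cohort))])
    cohort["cTotalProtein"] = cohort["cAlbumin"] + cohort["cGlobulin"]
    cohort = cohort[COHORT_COLUMNS]

    derived = derive_blood_frame(cohort)
    urine = derive_urine_frame(cohort)
    agr = cohort["cAlbumin"] / cohort["cGlobulin"]
    out = pd.concat([cohort, derived, urine], axis=1)
    out["AGR"] = agr
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write the cohort CSV (full float precision, round-trip safe)."""
    try:
        table.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"could not write cohort to {path}: {exc}") from exc


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    try:
        return pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"could not read cohort from {path}: {exc}") from exc
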