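"""Venous blood acid-base calculus for cattle.

Computes the traditional bicarbonate-centred variables (actual and standard
bicarbonate by Henderson-Hasselbalch, actual and extracellular base excess by
the Siggaard-Andersen Van Slyke equation, temperature-corrected pH/pCO2) and
the strong-ion variables of the Stewart/Constable framework (measured strong
ion difference with 3, 4 or 5 ion terms, non-volatile buffer totals from
albumin or total protein, strong ion gap, weak-acid charges and the
unmeasured-anion electroneutrality residual XA) from a single venous panel.

All formula-level functions accept scalars or numpy arrays and broadcast.
Concentrations are mmol/L unless stated otherwise; albumin and total protein
are g/L; hemoglobin is g/dL at the interface. Charge concentrations (mEq/L)
weight ionized calcium x2 and total magnesium x1.38 (69% dissociation of the
divalent cation). pH entering the dissociation and charge formulas is always
the analyzer pH at 37 degC; temperature-corrected values are reported
alongside but never fed back into those formulas, whose constants are defined
at 37 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "AcidBaseConstants",
    "DEFAULT_CONSTANTS",
    "BloodPanel",
    "DerivedAcidBase",
    "temperature_correct",
    "actual_bicarbonate",
    "base_excess_actual",
    "base_excess_ecf",
    "standard_bicarbonate",
    "anion_gap",
    "sid_measured",
    "atot",
    "strong_ion_gap",
    "weak_acid_charges",
    "magnesium_effective_charge",
    "unmeasured_anions",
    "derive_blood",
    "derive_blood_frame",
    "DERIVED_COLUMNS",
]


@dataclass(frozen=True)
class AcidBaseConstants:
    """Physico-chemical constants of the acid-base calculus (37 degC plasma).

    S is the CO2 solubility coefficient, pK1 the apparent first dissociation
    constant of carbonic acid, pKa the lumped dissociation constant of the
    non-volatile plasma weak acids. The Van Slyke block parameterizes
    BE = (1 - 0.0143*Hb) * (cHCO3 - 24.4 + (1.63*Hb + 9.5)*(pH - 7.40))
    with Hb in g/dL; the extracellular variant attenuates hemoglobin by
    ``ecf_hb_divisor``. Temperature correction uses the analyzer convention
    dpH/dT = -0.0147 /degC and pCO2 * 10^(0.019*dT).
    """

    S: float = 0.0307            # mmol/L/mmHg
    pK1: float = 6.12
    pKa: float = 7.06
    atot_alb_coeff: float = 0.76  # mEq/L per g/L albumin
    atot_prt_coeff: float = 0.36  # mEq/L per g/L total protein
    mg_net_charge: float = 1.38   # 2 * 0.69 dissociated fraction
    albumin_charge_slope: float = 0.141
    albumin_charge_pivot: float = 5.42
    globulin_charge_slope: float = 0.04
    globulin_charge_pivot: float = 5.58
    phosphate_charge_slope: float = 0.309
    phosphate_charge_intercept: float = 0.469
    # Van Slyke / reference point
    vs_hb_coeff: float = 0.0143
    vs_buffer_slope: float = 1.63
    vs_buffer_intercept: float = 9.5
    ref_hco3: float = 24.4        # mmol/L at the BE zero point
    ref_ph: float = 7.40
    ref_pco2: float = 40.0        # mmHg, equilibration target for std HCO3
    ecf_hb_divisor: float = 3.0
    # temperature correction
    dph_per_degc: float = -0.0147
    pco2_log10_per_degc: float = 0.019
    mchc: float = 33.0            # g/dL, Hct = ctHb / MCHC fallback

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "dph_per_degc" and v <= 0:
                raise ValueError(f"constant {f.name} must be positive, got {v}")
        if self.dph_per_degc >= 0:
            raise ValueError("dph_per_degc must be negative")


DEFAULT_CONSTANTS = AcidBaseConstants()

_LN10 = math.log(10.0)


def _check(cond, msg: str) -> None:
    if not np.all(cond):
        raise ValueError(msg)


def _ret(x, *like):
    """Return a python float when every input was scalar, else an ndarray."""
    if all(np.ndim(v) == 0 for v in like):
        return float(x)
    return np.asarray(x, dtype=float)


def temperature_correct(pH_v, pCO2_v, body_temp, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Correct analyzer pH and pCO2 (37 degC) to rectal body temperature.

    Returns ``(pH_BT, pCO2_BT)``. Identity at 37 degC; above it pH falls and
    pCO2 rises, per the published analyzer coefficients.
    """
    t = np.asarray(body_temp, dtype=float)
    _check((t > 30.0) & (t < 43.0), "body_temp outside plausible range (30, 43) degC")
    dt = t - 37.0
    ph_bt = np.asarray(pH_v, dtype=float) + constants.dph_per_degc * dt
    pco2_bt = np.asarray(pCO2_v, dtype=float) * 10.0 ** (constants.pco2_log10_per_degc * dt)
    return _ret(ph_bt, pH_v, body_temp), _ret(pco2_bt, pCO2_v, body_temp)


def actual_bicarbonate(pH, pCO2, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Actual plasma bicarbonate, S * pCO2 * 10^(pH - pK1) (mmol/L)."""
    p = np.asarray(pCO2, dtype=float)
    _check(p >= 0, "pCO2 must be non-negative")
    out = constants.S * p * 10.0 ** (np.asarray(pH, dtype=float) - constants.pK1)
    return _ret(out, pH, pCO2)


def _van_slyke(pH, pCO2, hb, constants: AcidBaseConstants):
    hco3 = actual_bicarbonate(pH, pCO2, constants)
    hb = np.asarray(hb, dtype=float)
    beta = constants.vs_buffer_slope * hb + constants.vs_buffer_intercept
    return (1.0 - constants.vs_hb_coeff * hb) * (
        np.asarray(hco3) - constants.ref_hco3
        + beta * (np.asarray(pH, dtype=float) - constants.ref_ph)
    )


def base_excess_actual(pH, pCO2, ctHb, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Actual base excess of whole blood (Van Slyke equation, mmol/L)."""
    _check(np.asarray(ctHb, dtype=float) >= 0, "ctHb must be non-negative")
    return _ret(_van_slyke(pH, pCO2, ctHb, constants), pH, pCO2, ctHb)


def base_excess_ecf(pH, pCO2, ctHb, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Standard base excess of extracellular fluid: hemoglobin diluted to
    model the whole extracellular compartment (ctHb / 3)."""
    _check(np.asarray(ctHb, dtype=float) >= 0, "ctHb must be non-negative")
    hb = np.asarray(ctHb, dtype=float) / constants.ecf_hb_divisor
    return _ret(_van_slyke(pH, pCO2, hb, constants), pH, pCO2, ctHb)


def standard_bicarbonate(pH, pCO2, ctHb, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Bicarbonate after CO2 equilibration of the sample to pCO2 = 40 mmHg.

    The sample is moved along its in-vitro buffer line (base excess held
    constant; slope from the Van Slyke buffer term beta = 1.63*Hb + 9.5)
    until pCO2 = 40 mmHg, and the Henderson-Hasselbalch bicarbonate at the
    equilibrated pH is returned. When the sample is already at 40 mmHg this
    is exactly the actual bicarbonate. Solved by damped Newton iteration on
    the equilibrated pH (the residual is smooth and strictly increasing).
    """
    c = constants
    hb = np.asarray(ctHb, dtype=float)
    _check(hb >= 0, "ctHb must be non-negative")
    hco3 = np.asarray(actual_bicarbonate(pH, pCO2, c))
    beta = c.vs_buffer_slope * hb + c.vs_buffer_intercept
    # invariant along the buffer line: cHCO3 - 24.4 + beta*(pH - 7.40)
    target = hco3 - c.ref_hco3 + beta * (np.asarray(pH, dtype=float) - c.ref_ph)
    amp = c.S * c.ref_pco2
    x = np.full(np.broadcast(hco3, beta, target).shape, c.ref_ph)
    for _ in range(60):
        e = amp * 10.0 ** (x - c.pK1)
        f = e - c.ref_hco3 + beta * (x - c.ref_ph) - target
        x = x - f / (_LN10 * e + beta)
    out = amp * 10.0 ** (x - c.pK1)
    return _ret(out, pH, pCO2, ctHb)


def anion_gap(cNa, cK, cCl, cHCO3):
    """Classic anion gap (cNa + cK) - (cCl + cHCO3), mEq/L."""
    for v, name in ((cNa, "cNa"), (cK, "cK"), (cCl, "cCl"), (cHCO3, "cHCO3")):
        _check(np.asarray(v, dtype=float) >= 0, f"{name} must be non-negative")
    out = (np.asarray(cNa, dtype=float) + np.asarray(cK, dtype=float)
           - np.asarray(cCl, dtype=float) - np.asarray(cHCO3, dtype=float))
    return _ret(out, cNa, cK, cCl, cHCO3)


def sid_measured(cNa, cK, cCl, cLactate=0.0, cCa_ion=0.0, variant: str = "m5"):
    """Measured strong ion difference (mEq/L).

    variant ``m3``: (Na + K) - Cl; ``m4``: m3 - lactate; ``m5``: m4 plus the
    charge contribution of ionized calcium (2 * cCa_ion).
    """
    for v, name in ((cNa, "cNa"), (cK, "cK"), (cCl, "cCl"),
                    (cLactate, "cLactate"), (cCa_ion, "cCa_ion")):
        _check(np.asarray(v, dtype=float) >= 0, f"{name} must be non-negative")
    m3 = (np.asarray(cNa, dtype=float) + np.asarray(cK, dtype=float)
          - np.asarray(cCl, dtype=float))
    if variant == "m3":
        out = m3
    elif variant == "m4":
        out = m3 - np.asarray(cLactate, dtype=float)
    elif variant == "m5":
        out = m3 - np.asarray(cLactate, dtype=float) + 2.0 * np.asarray(cCa_ion, dtype=float)
    else:
        raise ValueError(f"unknown SID variant {variant!r}; expected m3, m4 or m5")
    return _ret(out, cNa, cK, cCl, cLactate, cCa_ion)


def atot(concentration, basis: str = "albumin", constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Non-volatile weak buffer total (mEq/L) from albumin or total protein (g/L)."""
    c = np.asarray(concentration, dtype=float)
    _check(c >= 0, "protein concentration must be non-negative")
    if basis == "albumin":
        out = c * constants.atot_alb_coeff
    elif basis == "protein":
        out = c * constants.atot_prt_coeff
    else:
        raise ValueError(f"unknown Atot basis {basis!r}; expected 'albumin' or 'protein'")
    return _ret(out, concentration)


def strong_ion_gap(atot_value, pH, AG, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Strong ion gap: dissociated buffer charge minus anion gap.

    SIG = Atot / (1 + 10^(pKa - pH)) - AG. Positive SIG indicates fewer
    unmeasured strong anions than the anion gap alone suggests.
    """
    a = np.asarray(atot_value, dtype=float)
    _check(a >= 0, "Atot must be non-negative")
    out = a / (1.0 + 10.0 ** (constants.pKa - np.asarray(pH, dtype=float))) - np.asarray(AG, dtype=float)
    return _ret(out, atot_value, pH, AG)


def weak_acid_charges(cAlbumin, cTotalProtein, cPi, pH,
                      constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Charges carried by albumin, globulin and phosphate at the given pH.

    Returns ``(charge_albumin, charge_globulin, charge_phosphate)`` in mEq/L.
    Globulin is total protein minus albumin. Albumin and globulin charges are
    linear in pH around their isoelectric pivots; the phosphate term is the
    published linear fit of its mean valence.
    """
    alb = np.asarray(cAlbumin, dtype=float)
    tp = np.asarray(cTotalProtein, dtype=float)
    pi = np.asarray(cPi, dtype=float)
    _check(alb >= 0, "cAlbumin must be non-negative")
    _check(pi >= 0, "cPi must be non-negative")
    _check(tp - alb >= -1e-12, "cAlbumin must not exceed cTotalProtein")
    p = np.asarray(pH, dtype=float)
    c = constants
    ch_alb = c.albumin_charge_slope * alb * (p - c.albumin_charge_pivot)
    ch_glob = c.globulin_charge_slope * (tp - alb) * (p - c.globulin_charge_pivot)
    ch_pi = pi * (c.phosphate_charge_slope * p - c.phosphate_charge_intercept)
    args = (cAlbumin, cTotalProtein, cPi, pH)
    return _ret(ch_alb, *args), _ret(ch_glob, *args), _ret(ch_pi, *args)


def magnesium_effective_charge(cMg_total, constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Effective charge of total magnesium: 1.38 * cMg (69% dissociation)."""
    m = np.asarray(cMg_total, dtype=float)
    _check(m >= 0, "cMg_total must be non-negative")
    return _ret(constants.mg_net_charge * m, cMg_total)


def unmeasured_anions(cNa, cK, cCa_ion, cMg_total, cCl, cHCO3,
                      charge_albumin, charge_globulin, charge_phosphate,
                      constants: AcidBaseConstants = DEFAULT_CONSTANTS):
    """Unmeasured-anion residual XA (mEq/L).

    Electroneutrality bookkeeping: measured cation charge (Na + K + 2*Ca +
    1.38*Mg) minus chloride, bicarbonate and the three weak-acid charges.
    The result is the net charge that must be balanced by anions that were
    not measured; under this sign convention a *higher* XA means *more*
    unmeasured anions.
    """
    out = (np.asarray(cNa, dtype=float) + np.asarray(cK, dtype=float)
           + 2.0 * np.asarray(cCa_ion, dtype=float)
           + np.asarray(magnesium_effective_charge(cMg_total, constants))
           - np.asarray(cCl, dtype=float) - np.asarray(cHCO3, dtype=float)
           - np.asarray(charge_albumin, dtype=float)
           - np.asarray(charge_globulin, dtype=float)
           - np.asarray(charge_phosphate, dtype=float))
    return _ret(out, cNa, cK, cCa_ion, cMg_total, cCl, cHCO3,
                charge_albumin, charge_globulin, charge_phosphate)


class BloodPanel(BaseModel, frozen=True):
    """One animal's venous blood gas + chemistry panel (analyzer units).

    ``Hct`` is optional; when absent the derived hematocrit falls back to
    ctHb / MCHC with MCHC = 33 g/dL.
    """

    pH_v: float
    pCO2_v: float           # mmHg
    ctHb: float             # g/dL
    body_temp: float = 38.5  # degC rectal
    cNa: float
    cK: float
    cCa_ion: float
    cCl: float
    cGlucose: float = 0.0
    cLactate: float = 0.0
    cPi: float = 0.0
    cMg_total: float = 0.0
    cAlbumin: float = 0.0   # g/L
    cTotalProtein: float = 0.0  # g/L
    Hct: Optional[float] = None  # fraction

    @model_validator(mode="after")
    def _physiology(self) -> "BloodPanel":
        if not (6.5 < self.pH_v < 8.0):
            raise ValueError(f"pH_v {self.pH_v} outside (6.5, 8.0)")
        if self.pCO2_v <= 0:
            raise ValueError("pCO2_v must be positive")
        for name in ("ctHb", "cNa", "cK", "cCa_ion", "cCl", "cGlucose",
                     "cLactate", "cPi", "cMg_total", "cAlbumin", "cTotalProtein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cAlbumin > self.cTotalProtein + 1e-12:
            raise ValueError("cAlbumin must not exceed cTotalProtein")
        return self


@dataclass(frozen=True)
class DerivedAcidBase:
    """All derived blood acid-base variables for one panel."""

    pH_BT: float
    pCO2_BT: float
    cHCO3_act: float
    cHCO3_std: float
    BE_act: float
    BE_ecf: float
    Hct: float
    AG: float
    SID_m3: float
    SID_m4: float
    SID_m5: float
    Atot_alb: float
    Atot_prt: float
    SIG_alb: float
    SIG_prt: float
    charge_albumin: float
    charge_globulin: float
    charge_phosphate: float
    XA: float


DERIVED_COLUMNS = [f.name for f in fields(DerivedAcidBase)]


def _derive(p: dict, hct, constants: AcidBaseConstants):
    """Shared scalar/vector derivation from a mapping of panel columns."""
    c = constants
    ph, pco2 = p["pH_v"], p["pCO2_v"]
    ph_bt, pco2_bt = temperature_correct(ph, pco2, p["body_temp"], c)
    hco3 = actual_bicarbonate(ph, pco2, c)
    ag = anion_gap(p["cNa"], p["cK"], p["cCl"], hco3)
    a_alb = atot(p["cAlbumin"], "albumin", c)
    a_prt = atot(p["cTotalProtein"], "protein", c)
    ch_alb, ch_glob, ch_pi = weak_acid_charges(
        p["cAlbumin"], p["cTotalProtein"], p["cPi"], ph, c)
    return dict(
        pH_BT=ph_bt,
        pCO2_BT=pco2_bt,
        cHCO3_act=hco3,
        cHCO3_std=standard_bicarbonate(ph, pco2, p["ctHb"], c),
        BE_act=base_excess_actual(ph, pco2, p["ctHb"], c),
        BE_ecf=base_excess_ecf(ph, pco2, p["ctHb"], c),
        Hct=hct,
        AG=ag,
        SID_m3=sid_measured(p["cNa"], p["cK"], p["cCl"], variant="m3"),
        SID_m4=sid_measured(p["cNa"], p["cK"], p["cCl"], p["cLactate"], variant="m4"),
        SID_m5=sid_measured(p["cNa"], p["cK"], p["cCl"], p["cLactate"], p["cCa_ion"], variant="m5"),
        Atot_alb=a_alb,
        Atot_prt=a_prt,
        SIG_alb=strong_ion_gap(a_alb, ph, ag, c),
        SIG_prt=strong_ion_gap(a_prt, ph, ag, c),
        charge_albumin=ch_alb,
        charge_globulin=ch_glob,
        charge_phosphate=ch_pi,
        XA=unmeasured_anions(p["cNa"], p["cK"], p["cCa_ion"], p["cMg_total"],
                             p["cCl"], hco3, ch_alb, ch_glob, ch_pi, c),
    )


def derive_blood(panel: BloodPanel, constants: AcidBaseConstants = DEFAULT_CONSTANTS) -> DerivedAcidBase:
    """Compute every derived acid-base variable from a validated panel."""
    hct = panel.Hct if panel.Hct is not None else panel.ctHb / constants.mchc
    vals = _derive(panel.model_dump(), float(hct), constants)
    return DerivedAcidBase(**{k: float(v) for k, v in vals.items()})


def derive_blood_frame(df: pd.DataFrame, constants: AcidBaseConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Vectorized :func:`derive_blood` over a cohort table.

    Requires the BloodPanel columns; an optional ``Hct`` column overrides the
    ctHb/MCHC fallback row-wise. Returns a new DataFrame of derived columns
    aligned on the input index.
    """
    needed = ["pH_v", "pCO2_v", "ctHb", "body_temp", "cNa", "cK", "cCa_ion",
              "cCl", "cLactate", "cPi", "cMg_total", "cAlbumin", "cTotalProtein"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"blood panel columns missing: {missing}")
    p = {c: df[c].to_numpy(dtype=float) for c in needed}
    fallback = p["ctHb"] / constants.mchc
    if "Hct" in df.columns:
        given = df["Hct"].to_numpy(dtype=float)
        hct = np.where(np.isnan(given), fallback, given)
    else:
        hct = fallback
    vals = _derive(p, hct, constants)
    out = pd.DataFrame(vals, index=df.index)
    return out[DERIVED_COLUMNS]
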