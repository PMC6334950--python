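"""Within-study reference intervals and qualitative classification.

The study design designates one metabolically unremarkable cluster as the
internal reference sample and takes each variable's 25th-75th percentile
range in that cluster as the "within-study" reference interval. Cluster (or
animal) values are then summarized qualitatively: within the interval, below
or above it, or *markedly* below/above when the excess exceeds a configurable
fraction of the interval width (the double-arrow calls of the source
discipline's tabulations).

On top of the per-variable calls, :func:`interpret_strong_ion` applies the
strong-ion reading: a fall in strong ion difference (SID) or a rise in
non-volatile buffer ions (Atot) marks a metabolic acidosis; the opposite
shifts mark a metabolic alkalosis; deviations of the unmeasured-anion
residual XA or of the strong ion gap flag unmeasured ions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceInterval", "ReferenceIntervalSet", "Call", "QualitativeCall",
    "internal_intervals", "classify", "interpret_strong_ion",
    "study_reference_intervals",
]


@dataclass(frozen=True)
class ReferenceInterval:
    """Low/high bounds for one variable; one-sided bounds use +-inf."""

    variable: str
    low: float
    high: float
    source: str = "internal_IQR"  # or "literature"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.variable}: low {self.low} > high {self.high}")

    @property
    def width(self) -> float:
        w = self.high - self.low
        return w if math.isfinite(w) else float("nan")


class ReferenceIntervalSet(dict):
    """Mapping variable -> ReferenceInterval with CSV/JSON round-trip."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(iv) for iv in self.values()])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {k: asdict(v) for k, v in self.items()}, indent=2))

    @classmethod
    def from_json(cls, path) -> "ReferenceIntervalSet":
        raw = json.loads(Path(path).read_text())
        return cls({k: ReferenceInterval(**v) for k, v in raw.items()})


class Call(str, Enum):
    """Qualitative position of a value relative to a reference interval,
    ordered marked_below < below < within < above < marked_above."""

    marked_below = "marked_below"
    below = "below"
    within = "within"
    above = "above"
    marked_above = "marked_above"

    @property
    def rank(self) -> int:
        return ["marked_below", "below", "within", "above", "marked_above"].index(self.value)

    @property
    def direction(self) -> int:
        """-1 below, 0 within, +1 above (marked calls collapse onto +-1)."""
        return (0 if self is Call.within
                else -1 if self in (Call.below, Call.marked_below) else 1)


@dataclass(frozen=True)
class QualitativeCall:
    variable: str
    call: Call


def internal_intervals(values_by_variable: Mapping[str, Sequence[float]] | pd.DataFrame,
                       min_n: int = 4,
                       source: str = "internal_IQR") -> ReferenceIntervalSet:
    """Derive per-variable IQR reference intervals from the reference sample.

    ``low``/``high`` are the 25th and 75th percentiles under numpy's linear
    interpolation between order statistics. Variables with fewer than
    ``min_n`` non-missing values raise, naming the variable.
    """
    if isinstance(values_by_variable, pd.DataFrame):
        items = {c: values_by_variable[c].to_numpy(dtype=float)
                 for c in values_by_variable.columns}
    else:
        items = {k: np.asarray(v, dtype=float) for k, v in values_by_variable.items()}
    out = ReferenceIntervalSet()
    for name, vals in items.items():
        vals = vals[~np.isnan(vals)]
        if vals.size < min_n:
            raise ValueError(
                f"variable {name!r} has only {vals.size} non-missing values "
                f"(need >= {min_n}) for an internal reference interval")
        lo, hi = np.percentile(vals, [25.0, 75.0])
        out[name] = ReferenceInterval(name, float(lo), float(hi), source)
    return out


def classify(value: float, interval: ReferenceInterval,
             marked_margin: float = 0.5) -> QualitativeCall:
    """Qualitative call for one value against one interval.

    Bounds are inclusive. Beyond a bound by more than
    ``marked_margin * (high - low)`` the call is marked (double arrow). For
    one-sided (infinite-width) intervals a deviation is never marked.
    """
    if marked_margin < 0:
        raise ValueError("marked_margin must be non-negative")
    iv = interval
    if np.isnan(value):
        raise ValueError(f"cannot classify missing value for {iv.variable!r}")
    w = iv.high - iv.low
    cut = marked_margin * w if math.isfinite(w) else float("inf")
    if value < iv.low:
        call = Call.marked_below if iv.low - value > cut else Call.below
    elif value > iv.high:
        call = Call.marked_above if value - iv.high > cut else Call.above
    else:
        call = Call.within
    return QualitativeCall(iv.variable, call)


# label vocabulary of the strong-ion interpretation
SID_ACIDOSIS = "SID-acidosis"
SID_ALKALOSIS = "SID-alkalosis"
ATOT_ACIDOSIS = "Atot-acidosis"
ATOT_ALKALOSIS = "Atot-alkalosis"
UNMEASURED_ANIONS = "increased-unmeasured-anions"
UNMEASURED_CATIONS = "increased-unmeasured-cations"
NONE = "none"


def interpret_strong_ion(calls: Mapping[str, Call] | Iterable[QualitativeCall]) -> set[str]:
    """Strong-ion interpretation from qualitative calls.

    Expects calls keyed by variable name for ``SID_m5`` and at least one of
    ``Atot_alb``/``Atot_prt``; ``SIG_alb``, ``SIG_prt`` and ``XA`` are used
    when present. Mixed disorders yield multiple labels; an unremarkable
    profile yields ``{"none"}``.
    """
    if not isinstance(calls, Mapping):
        calls = {c.variable: c.call for c in calls}
    if "SID_m5" not in calls:
        raise ValueError("interpretation requires a call for SID_m5")
    if not ({"Atot_alb", "Atot_prt"} & calls.keys()):
        raise ValueError("interpretation requires a call for Atot_alb or Atot_prt")

    labels: set[str] = set()
    sid = calls["SID_m5"].direction
    if sid < 0:
        labels.add(SID_ACIDOSIS)
    elif sid > 0:
        labels.add(SID_ALKALOSIS)
    atot_dirs = {calls[k].direction for k in ("Atot_alb", "Atot_prt") if k in calls}
    if 1 in atot_dirs:
        labels.add(ATOT_ACIDOSIS)
    if -1 in atot_dirs:
        labels.add(ATOT_ALKALOSIS)
    sig_dirs = {calls[k].direction for k in ("SIG_alb", "SIG_prt") if k in calls}
    xa = calls["XA"].direction if "XA" in calls else 0
    if xa > 0 or -1 in sig_dirs:
        labels.add(UNMEASURED_ANIONS)
    if xa < 0 or 1 in sig_dirs:
        labels.add(UNMEASURED_CATIONS)
    return labels or {NONE}


def study_reference_intervals() -> ReferenceIntervalSet:
    """The study's printed reference column, shipped as a versioned fixture.

    Acid-base rows are the internal cluster-derived IQR intervals of the
    source cohort; metabolism rows are the literature bounds it interpreted
    against (one-sided bounds as +-inf). Units: NABE mmol/L, NEFA mmol/L,
    BHB umol/L, cholesterol mmol/L, albumin g/L, gamma-globulins g/L.
    """
    inf = float("inf")
    internal = {
        "pH_u": (8.17, 8.35), "NABE": (106.0, 210.0), "BAR": (2.3, 3.6),
        "pH_v": (7.38, 7.40), "cHCO3_std": (27.0, 28.8), "BE_ecf": (4.3, 6.5),
        "AG": (13.5, 15.3), "SID_m5": (42.6, 45.5),
        "Atot_alb": (21.4, 25.5), "Atot_prt": (24.5, 27.2),
        "SIG_alb": (0.5, 3.4), "SIG_prt": (2.4, 4.7), "XA": (7.4, 8.8),
    }
    literature = {
        "cNEFA": (-inf, 0.62), "cBHB": (-inf, 1200.0),
        "cCholesterol": (1.5, inf), "cAlbumin": (30.0, 39.0),
        "gamma_globulin": (16.4, 30.4),
    }
    out = ReferenceIntervalSet()
    for name, (lo, hi) in internal.items():
        out[name] = ReferenceInterval(name, lo, hi, "internal_IQR")
    for name, (lo, hi) in literature.items():
        out[name] = ReferenceInterval(name, lo, hi, "literature")
    return out
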