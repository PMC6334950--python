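"""Urinary net acid-base excretion from titration components.

Bovine urine is titrated to pH 4.0 (acid consumed = base excess cBE), back
to pH 7.0 (lye consumed = acid excess cAE) and, after formaldehyde
precipitation, to pH 7.0 again (ammonium cAmm). This module models only the
numeric outputs of that protocol:

    NABE = cBE - (cAE + cAmm)        net acid-base excretion, mmol/L
    BAR  = cBE / (cAE + cAmm)        base-acid ratio, unitless

NABE > 0 (equivalently BAR > 1) marks net base excretion, the physiological
state of a well-fed herbivore; negative NABE flags an acid load being cleared
renally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = ["UrinePanel", "UrineAcidBase", "nabe", "bar", "derive_urine",
           "derive_urine_frame", "UndefinedRatioError"]


class UndefinedRatioError(ValueError):
    """Raised when cAE + cAmm = 0; the titration protocol guarantees a
    nonzero acid excess, so a zero denominator signals bad data."""


def _nonneg(*pairs):
    for v, name in pairs:
        if not np.all(np.asarray(v, dtype=float) >= 0):
            raise ValueError(f"{name} must be non-negative")


def nabe(cBE, cAE, cAmm):
    """Net acid-base excretion cBE - (cAE + cAmm), mmol/L."""
    _nonneg((cBE, "cBE"), (cAE, "cAE"), (cAmm, "cAmm"))
    out = (np.asarray(cBE, dtype=float) - np.asarray(cAE, dtype=float)
           - np.asarray(cAmm, dtype=float))
    if all(np.ndim(v) == 0 for v in (cBE, cAE, cAmm)):
        return float(out)
    return out


def bar(cBE, cAE, cAmm):
    """Base-acid ratio cBE / (cAE + cAmm), unitless."""
    _nonneg((cBE, "cBE"), (cAE, "cAE"), (cAmm, "cAmm"))
    denom = np.asarray(cAE, dtype=float) + np.asarray(cAmm, dtype=float)
    if np.any(denom == 0):
        raise UndefinedRatioError("cAE + cAmm is zero; base-acid ratio undefined")
    out = np.asarray(cBE, dtype=float) / denom
    if all(np.ndim(v) == 0 for v in (cBE, cAE, cAmm)):
        return float(out)
    return out


class UrinePanel(BaseModel, frozen=True):
    """One animal's urine panel (mmol/L except pH)."""

    cNa_u: float = 0.0
    cK_u: float = 0.0
    cCa_u: float = 0.0
    cMg_u: float = 0.0
    cCl_u: float = 0.0
    pH_u: float
    cBE_u: float
    cAE_u: float
    cAmm_u: float

    @model_validator(mode="after")
    def _physiology(self) -> "UrinePanel":
        if not (4.0 < self.pH_u < 10.0):
            raise ValueError(f"pH_u {self.pH_u} outside (4.0, 10.0)")
        for name in ("cNa_u", "cK_u", "cCa_u", "cMg_u", "cCl_u",
                     "cBE_u", "cAE_u", "cAmm_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        return self


@dataclass(frozen=True)
class UrineAcidBase:
    NABE: float  # mmol/L
    BAR: float   # unitless


def derive_urine(panel: UrinePanel) -> UrineAcidBase:
    return UrineAcidBase(
        NABE=nabe(panel.cBE_u, panel.cAE_u, panel.cAmm_u),
        BAR=bar(panel.cBE_u, panel.cAE_u, panel.cAmm_u),
    )


def derive_urine_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized NABE/BAR over a cohort table with cBE_u/cAE_u/cAmm_u columns."""
    missing = [c for c in ("cBE_u", "cAE_u", "cAmm_u") if c not in df.columns]
    if missing:
        raise ValueError(f"urine titration columns missing: {missing}")
    be = df["cBE_u"].to_numpy(dtype=float)
    ae = df["cAE_u"].to_numpy(dtype=float)
    amm = df["cAmm_u"].to_numpy(dtype=float)
    return pd.DataFrame(
        {"NABE": nabe(be, ae, amm) if len(df) else [],
         "BAR": bar(be, ae, amm) if len(df) else []},
        index=df.index, dtype=float)
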