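"""Derived lipid markers from the standard lipid panel.

The standard panel measures total cholesterol (TC), triglycerides (TG)
and HDL-cholesterol (HDL-C). From those three values this module
computes:

* nonHDL-C = TC - HDL-C
* LDL-C by the Sampson/NIH closed-form equation
* eLDL-TG, the estimated triglyceride content of LDL, by the published
  four-term equation

  ``eLDL-TG = TG/38.5 + nonHDL-C/5.75 + 9.75*TG/nonHDL-C + 244/HDL-C - 2.95``

* sdLDL-C, cholesterol on small dense LDL, via the published
  large-buoyant-LDL regression: lbLDL-C = 1.43*LDL-C -
  0.14*ln(TG)*LDL-C - 8.99, and sdLDL-C = LDL-C - lbLDL-C
* Rem-C, remnant cholesterol, nonHDL-C - LDL-C

All functions work on scalars or numpy arrays, in mg/dl. Out-of-range
inputs yield a value *plus* a flag rather than suppression, so cohort
row counts are preserved; only genuinely undefined terms (nonpositive
denominators, missing inputs) yield NaN.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import (
    NONHDL_LIMIT_MG_DL,
    SAMPSON_TG_LIMIT_MG_DL,
    TG_LIMIT_MG_DL,
    Reason,
    ValidityFlag,
    check_validity,
)


@dataclass(frozen=True)
class EquationCoefficients:
    """Coefficients of the four-term LDL-TG estimating equation.

    Defaults are the published values; they can be overridden for
    refitting experiments. Terms, in order: TG, nonHDL-C, TG/nonHDL-C,
    1/HDL-C, intercept.
    """

    tg: float = 1.0 / 38.5
    nonhdl: float = 1.0 / 5.75
    tg_over_nonhdl: float = 9.75
    inv_hdl: float = 244.0
    intercept: float = -2.95

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tg, self.nonhdl, self.tg_over_nonhdl, self.inv_hdl, self.intercept]
        )

    @classmethod
    def from_array(cls, arr) -> "EquationCoefficients":
        a = np.asarray(arr, dtype=float)
        if a.shape != (5,):
            raise ValueError("expected 5 coefficients")
        return cls(*a.tolist())


PUBLISHED_COEFFICIENTS = EquationCoefficients()

#: Required input columns for :func:`derive_all`.
PANEL_COLUMNS = ("tc", "tg", "hdl_c")


def nonhdl_c(tc, hdl_c):
    """nonHDL-C = TC - HDL-C (mg/dl). May be <= 0; flagged downstream."""
    value = np.asarray(tc, dtype=float) - np.asarray(hdl_c, dtype=float)
    return value.item() if value.ndim == 0 else value


def eldl_tg(tg, nonhdl, hdl_c, coef: EquationCoefficients | None = None):
    """Estimated LDL-TG (mg/dl) from TG, nonHDL-C and HDL-C.

    Returns NaN where HDL-C <= 0 or nonHDL-C <= 0 (the ratio and
    reciprocal terms are undefined); values beyond the applicability
    bounds (TG >= 1,000 or nonHDL-C >= 400 mg/dl) are still computed —
    callers should carry the accompanying validity flag.
    """
    c = coef or PUBLISHED_COEFFICIENTS
    tg = np.asarray(tg, dtype=float)
    nonhdl = np.asarray(nonhdl, dtype=float)
    hdl_c = np.asarray(hdl_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = (
            c.tg * tg
            + c.nonhdl * nonhdl
            + c.tg_over_nonhdl * tg / nonhdl
            + c.inv_hdl / hdl_c
            + c.intercept
        )
        value = np.where((hdl_c <= 0) | (nonhdl <= 0), np.nan, value)
    return value.item() if value.ndim == 0 else value


def eldl_tg_checked(
    tg: float, nonhdl: float, hdl_c: float, coef: EquationCoefficients | None = None
) -> tuple[float, ValidityFlag]:
    """Scalar eLDL-TG together with its applicability flag."""
    flag = check_validity(tg, nonhdl, hdl_c)
    if Reason.MISSING_INPUT in flag.reasons:
        return float("nan"), flag
    return eldl_tg(tg, nonhdl, hdl_c, coef), flag


def sampson_ldl_c(tc, tg, hdl_c):
    """LDL-C (mg/dl) by the Sampson/NIH equation.

    LDL-C = TC/0.948 - HDL-C/0.971
            - (TG/8.56 + TG*nonHDL-C/2140 - TG^2/16100) - 9.44

    The equation's published domain is TG < 800 mg/dl; values beyond it
    are computed and flagged by :func:`derive_all`.
    """
    tc = np.asarray(tc, dtype=float)
    tg = np.asarray(tg, dtype=float)
    hdl_c = np.asarray(hdl_c, dtype=float)
    nonhdl = tc - hdl_c
    value = (
        tc / 0.948
        - hdl_c / 0.971
        - (tg / 8.56 + tg * nonhdl / 2140.0 - tg**2 / 16100.0)
        - 9.44
    )
    return value.item() if value.ndim == 0 else value


def sdldl_c(ldl_c, tg):
    """Small dense LDL cholesterol (mg/dl).

    Large buoyant LDL-C is predicted as
    1.43*LDL-C - 0.14*ln(TG)*LDL-C - 8.99 and subtracted from LDL-C.
    Undefined (NaN) where TG <= 0 because of the log term.
    """
    ldl_c = np.asarray(ldl_c, dtype=float)
    tg = np.asarray(tg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lb = 1.43 * ldl_c - 0.14 * np.log(tg) * ldl_c - 8.99
        value = np.where(tg <= 0, np.nan, ldl_c - lb)
    return value.item() if value.ndim == 0 else value


def rem_c(nonhdl, ldl_c):
    """Remnant cholesterol = nonHDL-C - LDL-C (mg/dl). May be negative."""
    value = np.asarray(nonhdl, dtype=float) - np.asarray(ldl_c, dtype=float)
    return value.item() if value.ndim == 0 else value


def derive_all(
    panels: pd.DataFrame,
    coef: EquationCoefficients | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Compute every derived marker for a table of lipid panels.

    ``panels`` needs columns ``tc, tg, hdl_c`` (mg/dl); ``apob`` and
    ``id`` are carried through if present. Returns a copy with added
    columns ``nonhdl_c, ldl_c_sampson, eldl_tg, sdldl_c, rem_c, flags``.
    ``flags`` is a per-row ``;``-joined string of ``marker:REASON``
    tokens (empty string when everything is in range). Bad rows never
    abort the table; their markers are NaN and/or flagged.
    """
    df = panels.rename(columns=column_map or {}).copy()
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")

    tc = pd.to_numeric(df["tc"], errors="coerce").to_numpy(dtype=float)
    tg = pd.to_numeric(df["tg"], errors="coerce").to_numpy(dtype=float)
    hdl = pd.to_numeric(df["hdl_c"], errors="coerce").to_numpy(dtype=float)
    miss = np.isnan(tc) | np.isnan(tg) | np.isnan(hdl)

    nonhdl = tc - hdl
    ldl = sampson_ldl_c(tc, tg, hdl)
    etg = eldl_tg(tg, nonhdl, hdl, coef)
    sd = sdldl_c(ldl, tg)
    rc = rem_c(nonhdl, ldl)

    flag_specs = [
        # eLDL-TG applicability and definedness
        (~miss & (tg >= TG_LIMIT_MG_DL), "eldl_tg", Reason.TG_OVER_LIMIT),
        (~miss & (nonhdl >= NONHDL_LIMIT_MG_DL), "eldl_tg", Reason.NONHDL_OVER_LIMIT),
        (~miss & (hdl <= 0), "eldl_tg", Reason.NONPOSITIVE_HDL),
        (~miss & (nonhdl <= 0), "eldl_tg", Reason.NONPOSITIVE_NONHDL),
        # Sampson LDL-C published domain
        (~miss & (tg >= SAMPSON_TG_LIMIT_MG_DL), "ldl_c_sampson", Reason.TG_OVER_LIMIT),
        (~miss & np.less(ldl, 0, where=~miss, out=np.zeros_like(ldl, dtype=bool)),
         "ldl_c_sampson", Reason.IMPLAUSIBLE),
        # sdLDL-C needs a positive TG for the log term
        (~miss & (tg <= 0), "sdldl_c", Reason.NONPOSITIVE_TG),
        (~miss & np.less(sd, 0, where=~miss, out=np.zeros_like(sd, dtype=bool)),
         "sdldl_c", Reason.IMPLAUSIBLE),
        # negative remnant cholesterol is reported, not clipped
        (~miss & np.less(rc, 0, where=~miss, out=np.zeros_like(rc, dtype=bool)),
         "rem_c", Reason.IMPLAUSIBLE),
    ]

    tokens: list[list[str]] = [[] for _ in range(len(df))]
    for i in np.nonzero(miss)[0]:
        tokens[i].append(f"all:{Reason.MISSING_INPUT.value}")
    for mask, marker, reason in flag_specs:
        for i in np.nonzero(mask)[0]:
            tokens[i].append(f"{marker}:{reason.value}")

    df["nonhdl_c"] = nonhdl
    df["ldl_c_sampson"] = ldl
    df["eldl_tg"] = etg
    df["sdldl_c"] = sd
    df["rem_c"] = rc
    df["flags"] = [";".join(t) for t in tokens]
    return df
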