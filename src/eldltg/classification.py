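"""Subject grouping rules: discordance quadrants, risk-enhancer groups
and quantile strata.

Discordance quadrants cross-classify subjects by LDL-C and eLDL-TG at
their (by default median) cutpoints: Q1 = low/low, Q2 = high LDL-C
only, Q3 = high eLDL-TG only, Q4 = high/high. "High" means strictly
greater than the cutpoint, so a value exactly at the cut is "low".

Risk-enhancer groups extend the conventional LDL-C >= 160 mg/dl and
TG >= 175 mg/dl enhancer rules with an eLDL-TG >= 44.6 mg/dl rule
(its 80th percentile): A = no test positive, B = LDL-C only,
C = TG only, D = eLDL-TG only, E = eLDL-TG positive together with
LDL-C or TG (or both). The remaining positivity pattern — LDL-C and
TG positive but eLDL-TG negative — is reported as BC_RESIDUAL so the
six labels partition all eight patterns. Enhancer positivity uses
">=" (a value exactly at the cut is positive).
"""
from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

DEFAULT_QUADRANT_CUTS = (141.0, 41.0)  # LDL-C, eLDL-TG medians (mg/dl)
DEFAULT_ENHANCER_CUTS = (160.0, 175.0, 44.6)  # LDL-C, TG, eLDL-TG (mg/dl)


class Quadrant(str, Enum):
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"


class EnhancerGroup(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    BC_RESIDUAL = "BC_RESIDUAL"


def assign_quadrant(
    ldl_c,
    eldl_tg,
    cut_ldl: float = DEFAULT_QUADRANT_CUTS[0],
    cut_eldltg: float = DEFAULT_QUADRANT_CUTS[1],
):
    """Discordance quadrant per subject.

    Vectorized; returns a string array ("Q1".."Q4", or "" when a marker
    is missing). Scalars in, scalar :class:`Quadrant` out (None when
    missing).
    """
    ldl = np.asarray(ldl_c, dtype=float)
    etg = np.asarray(eldl_tg, dtype=float)
    scalar = ldl.ndim == 0
    ldl, etg = np.atleast_1d(ldl), np.atleast_1d(etg)
    high_ldl = ldl > cut_ldl
    high_etg = etg > cut_eldltg
    code = np.where(high_ldl & ~high_etg, "Q2",
                    np.where(~high_ldl & high_etg, "Q3",
                             np.where(high_ldl & high_etg, "Q4", "Q1")))
    code = np.where(np.isnan(ldl) | np.isnan(etg), "", code)
    if scalar:
        return Quadrant(code[0]) if code[0] else None
    return code


def assign_enhancer_group(
    ldl_c,
    tg,
    eldl_tg,
    cut_ldl: float = DEFAULT_ENHANCER_CUTS[0],
    cut_tg: float = DEFAULT_ENHANCER_CUTS[1],
    cut_eldltg: float = DEFAULT_ENHANCER_CUTS[2],
):
    """Risk-enhancer group per subject (see module docstring).

    Vectorized; "" where any marker is missing. Scalars in, scalar
    :class:`EnhancerGroup` out.
    """
    ldl = np.asarray(ldl_c, dtype=float)
    tgv = np.asarray(tg, dtype=float)
    etg = np.asarray(eldl_tg, dtype=float)
    scalar = ldl.ndim == 0
    ldl, tgv, etg = np.atleast_1d(ldl), np.atleast_1d(tgv), np.atleast_1d(etg)
    L = ldl >= cut_ldl
    T = tgv >= cut_tg
    E = etg >= cut_eldltg
    out = np.full(ldl.shape, "", dtype=object)
    out[~L & ~T & ~E] = EnhancerGroup.A.value
    out[L & ~T & ~E] = EnhancerGroup.B.value
    out[~L & T & ~E] = EnhancerGroup.C.value
    out[~L & ~T & E] = EnhancerGroup.D.value
    out[E & (L | T)] = EnhancerGroup.E.value
    out[L & T & ~E] = EnhancerGroup.BC_RESIDUAL.value
    out[np.isnan(ldl) | np.isnan(tgv) | np.isnan(etg)] = ""
    if scalar:
        return EnhancerGroup(out[0]) if out[0] else None
    return out.astype(str)


def quantile_strata(values, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Empirical k-quantile strata of ``values``.

    Cutpoints are the (1/k, ..., (k-1)/k) empirical quantiles (linear
    interpolation, the common "type 7" definition). Membership is by
    half-open intervals (lo, hi], the lowest closed at the minimum, so
    heavily tied values share a stratum and stratum sizes may then be
    unequal. Returns ``(labels, cutpoints)`` where labels run 0..k-1.
    NaNs get label -1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if np.unique(finite).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} strata")
    cuts = np.quantile(finite, np.arange(1, k) / k)
    labels = np.searchsorted(cuts, v, side="left").astype(int)
    labels[np.isnan(v)] = -1
    return labels, cuts


def classify(
    derived: pd.DataFrame,
    quadrant_cuts: tuple[float, float] | None = None,
    enhancer_cuts: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Add ``quadrant`` and ``enhancer_group`` columns to a derived table.

    ``quadrant_cuts=None`` uses the empirical medians of the table's own
    ``ldl_c_sampson`` and ``eldl_tg`` columns, mirroring the discordance
    design; enhancer cuts default to (160, 175, 44.6) mg/dl.
    """
    df = derived.copy()
    if quadrant_cuts is None:
        quadrant_cuts = (
            float(np.nanmedian(df["ldl_c_sampson"])),
            float(np.nanmedian(df["eldl_tg"])),
        )
    if enhancer_cuts is None:
        enhancer_cuts = DEFAULT_ENHANCER_CUTS
    df["quadrant"] = assign_quadrant(df["ldl_c_sampson"], df["eldl_tg"], *quadrant_cuts)
    df["enhancer_group"] = assign_enhancer_group(
        df["ldl_c_sampson"], df["tg"], df["eldl_tg"], *enhancer_cuts
    )
    df.attrs["quadrant_cuts"] = quadrant_cuts
    df.attrs["enhancer_cuts"] = enhancer_cuts
    return df
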