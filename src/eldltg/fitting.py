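"""Refitting the LDL-TG estimating equation by ordinary least squares.

The regression target is LDL-TG measured by the beta-quantification
reference method; the design has exactly the published functional
form's five columns, in order: TG, nonHDL-C, TG/nonHDL-C, 1/HDL-C and
an intercept column of ones. Development mirrors the original
procedure: a random train/validation split, OLS on the training half,
and R-squared reported on both halves.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .equations import EquationCoefficients

DESIGN_COLUMNS = ("tg", "nonhdl_c", "tg_over_nonhdl", "inv_hdl", "intercept")
MIN_USABLE_ROWS = 10


@dataclass
class FitResult:
    """OLS fit of the four-term functional form."""

    coefficients: EquationCoefficients
    standard_errors: np.ndarray
    r2_train: float
    r2_validation: float | None
    n_train: int
    n_validation: int
    residuals: np.ndarray
    excluded: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(DESIGN_COLUMNS, self.coefficients.as_array())),
            "standard_errors": dict(zip(DESIGN_COLUMNS, self.standard_errors)),
            "r2_train": self.r2_train,
            "r2_validation": self.r2_validation,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "excluded": self.excluded,
        }


def build_design(
    df: pd.DataFrame,
    target: str | None = "bq_ldl_tg",
    tg_max: float | None = 11950.0,
    nonhdl_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None, pd.Index, dict[str, int]]:
    """Design matrix and target vector for the equation fit.

    ``df`` needs ``tg`` and ``hdl_c`` plus either ``nonhdl_c`` or
    ``tc``. Rows with missing inputs, nonpositive HDL-C or nonHDL-C, or
    TG/nonHDL-C above the configured fitting bounds are excluded and
    counted (the default TG bound is the development data's maximum).
    Returns ``(X, y, kept_index, excluded_counts)``; raises if fewer
    than 10 usable rows remain.
    """
    work = df.copy()
    if "nonhdl_c" not in work.columns:
        if "tc" not in work.columns:
            raise ValueError("need nonhdl_c or tc column")
        work["nonhdl_c"] = pd.to_numeric(work["tc"], errors="coerce") - pd.to_numeric(
            work["hdl_c"], errors="coerce"
        )
    tg = pd.to_numeric(work["tg"], errors="coerce")
    nonhdl = pd.to_numeric(work["nonhdl_c"], errors="coerce")
    hdl = pd.to_numeric(work["hdl_c"], errors="coerce")
    y = pd.to_numeric(work[target], errors="coerce") if target is not None else None

    excluded: dict[str, int] = {}
    miss = tg.isna() | nonhdl.isna() | hdl.isna()
    if y is not None:
        miss |= y.isna()
    keep = ~miss
    excluded["missing"] = int(miss.sum())

    bad_hdl = keep & (hdl <= 0)
    excluded["nonpositive_hdl"] = int(bad_hdl.sum())
    keep &= ~bad_hdl
    bad_nonhdl = keep & (nonhdl <= 0)
    excluded["nonpositive_nonhdl"] = int(bad_nonhdl.sum())
    keep &= ~bad_nonhdl
    if tg_max is not None:
        over = keep & (tg > tg_max)
        excluded["tg_over_bound"] = int(over.sum())
        keep &= ~over
    if nonhdl_max is not None:
        over = keep & (nonhdl > nonhdl_max)
        excluded["nonhdl_over_bound"] = int(over.sum())
        keep &= ~over

    if int(keep.sum()) < MIN_USABLE_ROWS:
        raise ValueError(
            f"only {int(keep.sum())} usable rows after exclusions; need >= {MIN_USABLE_ROWS}"
        )

    idx = work.index[keep]
    tg_k = tg[keep].to_numpy()
    nonhdl_k = nonhdl[keep].to_numpy()
    hdl_k = hdl[keep].to_numpy()
    X = np.column_stack(
        [tg_k, nonhdl_k, tg_k / nonhdl_k, 1.0 / hdl_k, np.ones_like(tg_k)]
    )
    y_k = y[keep].to_numpy() if y is not None else None
    return X, y_k, idx, excluded


def fit_ols(X: np.ndarray, y: np.ndarray) -> FitResult:
    """OLS on a prebuilt design; raises on rank deficiency, naming the
    collinear columns; warns when the fit is saturated (n == p)."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # columns whose removal restores full rank are the culprits
        bad = [
            DESIGN_COLUMNS[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if n == p:
        warnings.warn("saturated fit (n == number of parameters); R^2 is degenerate 1")
    model = sm.OLS(y, X).fit()
    resid = y - model.predict(X)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    return FitResult(
        coefficients=EquationCoefficients.from_array(model.params),
        standard_errors=np.asarray(model.bse),
        r2_train=float(r2),
        r2_validation=None,
        n_train=n,
        n_validation=0,
        residuals=resid,
    )


def split_train_validation(
    df: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible random split; disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    n_train = int(round(fraction * len(df)))
    return df.iloc[perm[:n_train]], df.iloc[perm[n_train:]]


def fit_equation(
    df: pd.DataFrame,
    target: str = "bq_ldl_tg",
    fraction: float = 0.5,
    seed: int = 0,
    tg_max: float | None = 11950.0,
    nonhdl_max: float | None = None,
) -> FitResult:
    """Full development loop: split, fit on the training half, report
    R-squared on both halves."""
    train, val = split_train_validation(df, fraction, seed)
    Xt, yt, _, excl_t = build_design(train, target, tg_max, nonhdl_max)
    res = fit_ols(Xt, yt)
    Xv, yv, _, excl_v = build_design(val, target, tg_max, nonhdl_max)
    pred = Xv @ res.coefficients.as_array()
    sst = np.sum((yv - yv.mean()) ** 2)
    res.r2_validation = float(1.0 - np.sum((yv - pred) ** 2) / sst) if sst > 0 else 1.0
    res.n_validation = len(yv)
    res.excluded = {k: excl_t.get(k, 0) + excl_v.get(k, 0) for k in excl_t}
    return res


def residual_diagnostics(
    residuals: np.ndarray, by: np.ndarray, n_bands: int = 10, label: str = "band"
) -> pd.DataFrame:
    """Residual spread by bands of a conditioning variable.

    Bands are equal-count quantile bands of ``by``; empty bands are
    simply absent from the table. Used to justify applicability bounds
    from data (where the banded residual SD blows up, the equation
    should not be applied).
    """
    residuals = np.asarray(residuals, dtype=float)
    by = np.asarray(by, dtype=float)
    edges = np.unique(np.quantile(by, np.linspace(0, 1, n_bands + 1)))
    if edges.size < 2:  # degenerate conditioning variable: one band
        edges = np.array([edges[0], edges[0]])
    idx = np.clip(np.searchsorted(edges, by, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        rows.append(
            {
                label + "_lo": edges[b],
                label + "_hi": edges[b + 1],
                "n": int(m.sum()),
                "resid_mean": float(residuals[m].mean()),
                "resid_sd": float(residuals[m].std(ddof=1)) if m.sum() > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
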