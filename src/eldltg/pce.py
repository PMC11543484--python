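"""Pooled cohort equations (PCE) 10-year ASCVD risk.

The guideline-endorsed race/sex-specific Cox-model risk score:
risk = 1 - S10 ** exp(sum_of_terms - group_mean), where the terms are
log-transformed age, total cholesterol, HDL-C and systolic blood
pressure (treated/untreated), smoking and diabetes indicators, plus
the age interactions the published model includes. Coefficients live
in a versioned YAML config (``data/pce_coefficients.yaml``) so the
transcription is auditable.

Race handling follows the published convention: groups other than
White/Black are scored with the White coefficients and flagged. Ages
outside the validated 40-79 band are scored but flagged.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

VALID_AGE_RANGE = (40.0, 79.0)


@lru_cache(maxsize=1)
def load_coefficients() -> dict:
    path = resources.files("eldltg.data").joinpath("pce_coefficients.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def _terms(age, tc, hdl, sbp, bp_treated, smoker, diabetes) -> dict[str, np.ndarray]:
    ln_age, ln_tc, ln_hdl, ln_sbp = np.log(age), np.log(tc), np.log(hdl), np.log(sbp)
    treated = bp_treated.astype(float)
    untreated = 1.0 - treated
    return {
        "ln_age": ln_age,
        "ln_age_sq": ln_age**2,
        "ln_tc": ln_tc,
        "ln_age_ln_tc": ln_age * ln_tc,
        "ln_hdl": ln_hdl,
        "ln_age_ln_hdl": ln_age * ln_hdl,
        "ln_sbp_treated": ln_sbp * treated,
        "ln_age_ln_sbp_treated": ln_age * ln_sbp * treated,
        "ln_sbp_untreated": ln_sbp * untreated,
        "ln_age_ln_sbp_untreated": ln_age * ln_sbp * untreated,
        "smoker": smoker.astype(float),
        "ln_age_smoker": ln_age * smoker.astype(float),
        "diabetes": diabetes.astype(float),
    }


def pce_risk(
    age,
    sex,
    race,
    tc,
    hdl_c,
    sbp,
    bp_treated,
    diabetes,
    smoker,
    fixed_demographics: bool = False,
) -> np.ndarray:
    """10-year ASCVD risk in [0, 1], vectorized.

    ``sex`` takes "male"/"female" (or "M"/"F"); ``race`` takes
    "white"/"black", anything else is scored as White. With
    ``fixed_demographics=True`` every subject is scored as a
    55-year-old White male (lipids, blood pressure and the binary risk
    factors stay the subject's own), the design used to isolate the
    lipid contribution to the score.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    n = age.shape[0]
    tc = np.broadcast_to(np.asarray(tc, dtype=float), (n,))
    hdl_c = np.broadcast_to(np.asarray(hdl_c, dtype=float), (n,))
    sbp = np.broadcast_to(np.asarray(sbp, dtype=float), (n,))
    bp_treated = np.broadcast_to(np.asarray(bp_treated, dtype=bool), (n,))
    diabetes = np.broadcast_to(np.asarray(diabetes, dtype=bool), (n,))
    smoker = np.broadcast_to(np.asarray(smoker, dtype=bool), (n,))

    if fixed_demographics:
        age = np.full(n, 55.0)
        sex_norm = np.full(n, "male", dtype=object)
        race_norm = np.full(n, "white", dtype=object)
    else:
        sex_norm = _normalize(sex, n, {"m": "male", "male": "male",
                                       "f": "female", "female": "female"})
        race_norm = _normalize(race, n, {"white": "white", "black": "black"},
                               default="white")

    terms = _terms(age, tc, hdl_c, sbp, bp_treated, smoker, diabetes)
    cfg = load_coefficients()["groups"]
    risk = np.full(n, np.nan)
    for sx in ("male", "female"):
        for rc in ("white", "black"):
            mask = (sex_norm == sx) & (race_norm == rc)
            if not mask.any():
                continue
            g = cfg[f"{rc}_{sx}"]
            s = np.zeros(mask.sum())
            for name, coef in g["coefficients"].items():
                s += coef * terms[name][mask]
            risk[mask] = 1.0 - g["baseline_survival"] ** np.exp(s - g["mean_terms"])
    return risk


def pce_flags(age, race) -> np.ndarray:
    """Per-subject caveat strings: age outside 40-79, race fallback."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    n = age.shape[0]
    race_norm = _normalize(race, n, {"white": "white", "black": "black"}, default="")
    out = np.full(n, "", dtype=object)
    out[(age < VALID_AGE_RANGE[0]) | (age > VALID_AGE_RANGE[1])] = "AGE_OUT_OF_RANGE"
    fallback = race_norm == ""
    out[fallback] = np.where(
        out[fallback] == "", "RACE_FALLBACK_WHITE",
        out[fallback] + ";RACE_FALLBACK_WHITE",
    )
    return out.astype(str)


def _normalize(values, n: int, mapping: dict[str, str], default: str | None = None):
    arr = np.broadcast_to(np.atleast_1d(np.asarray(values, dtype=object)), (n,))
    out = np.empty(n, dtype=object)
    for i, v in enumerate(arr):
        key = str(v).strip().lower()
        if key in mapping:
            out[i] = mapping[key]
        elif default is not None:
            out[i] = default
        else:
            raise ValueError(f"unrecognized category: {v!r}")
    return out


def pce_risk_frame(df: pd.DataFrame, fixed_demographics: bool = False) -> pd.Series:
    """PCE risk for a cohort table with the standard column names
    (age, sex, race, tc, hdl_c, sbp, bp_treated, diabetes, smoker)."""
    return pd.Series(
        pce_risk(
            df["age"], df["sex"], df["race"], df["tc"], df["hdl_c"], df["sbp"],
            df["bp_treated"], df["diabetes"], df["smoker"],
            fixed_demographics=fixed_demographics,
        ),
        index=df.index,
        name="pce_risk",
    )
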