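"""Reproduce the equation-development procedure on synthetic data.

Simulates a reference-method cohort in which measured LDL-TG equals the
published equation's prediction plus noise calibrated to a 0.609
population R^2, splits it 50/50 into training and validation halves,
refits the four-term functional form by OLS, and compares the
recovered coefficients with the published ones.
"""
import numpy as np

from eldltg import CohortSpec, PUBLISHED_COEFFICIENTS, fit_equation, generate_panels
from eldltg.fitting import DESIGN_COLUMNS

panels = generate_panels(CohortSpec(n=20000, seed=42))
res = fit_equation(panels, target="bq_ldl_tg", fraction=0.5, seed=42)

print(f"{'term':>15} {'published':>10} {'refit':>10} {'SE':>8}")
for name, pub, est, se in zip(
    DESIGN_COLUMNS,
    PUBLISHED_COEFFICIENTS.as_array(),
    res.coefficients.as_array(),
    res.standard_errors,
):
    print(f"{name:>15} {pub:>10.4f} {est:>10.4f} {se:>8.4f}")

print(
    f"\nR^2 train {res.r2_train:.3f} / validation {res.r2_validation:.3f} "
    f"(n = {res.n_train} / {res.n_validation})"
)
print(
    "Train and validation R^2 agree closely (no overfitting) and sit "
    "near the 0.609 the noise was calibrated to. Each coefficient lands "
    "within a couple of standard errors of its published value; note the "
    "TG and TG/nonHDL-C terms are strongly collinear, so their individual "
    "estimates (and the small intercept) carry wide relative uncertainty "
    "even at n = 20,000."
)
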