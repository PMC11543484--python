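"""Derive every lipid marker from a few standard panels.

Builds three lipid panels (mg/dl), computes nonHDL-C, Sampson/NIH
LDL-C, eLDL-TG, sdLDL-C and remnant cholesterol, and prints the table.
The third panel has TG above the 1,000 mg/dl applicability bound: its
eLDL-TG is still computed but arrives flagged, so screens can count it
rather than silently lose the row.
"""
import pandas as pd

from eldltg import derive_all, si_display

panels = pd.DataFrame(
    {
        "id": ["normo", "mixed_dyslipidemia", "severe_htg"],
        "tc": [200.0, 265.0, 300.0],
        "tg": [150.0, 186.0, 1200.0],
        "hdl_c": [50.0, 54.5, 35.0],
    }
)

derived = derive_all(panels)
cols = ["id", "nonhdl_c", "ldl_c_sampson", "eldl_tg", "sdldl_c", "rem_c", "flags"]
print(derived[cols].round(1).to_string(index=False))

row = derived.iloc[0]
print(
    f"\nSubject '{row['id']}': eLDL-TG = {row['eldl_tg']:.1f} mg/dl "
    f"({si_display(row['eldl_tg'], 'triglyceride'):.2f} mmol/L). "
    "Values above ~44.6 mg/dl (the 80th percentile in a general "
    "population) would mark a risk-enhancer-positive subject."
)
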