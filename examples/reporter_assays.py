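"""Reporter-frequency normalization, clonogenic survival, and panel statistics.

Three replicate flow-cytometry measurements per condition are normalized to
the transfection efficiency of parallel GFP transfections; the two conditions
are then compared with an unpaired t-test inside a Holm-Sidak-corrected
family. A small clonogenic plate is normalized to the mean plating efficiency
of the DMSO / 0 Gy wells per cell line (control wells average to 1 exactly).
"""

import pandas as pd

from amplijoin.reporter import clonogenic_survival, normalize_flow_table
from amplijoin.stats import compare_groups

flow = pd.DataFrame(
    {
        "condition": ["control"] * 3 + ["inhibitor"] * 3,
        "pct_positive": [2.1, 1.9, 2.2, 0.9, 1.1, 1.0],
        "pct_transfection": [52.0, 48.0, 50.0, 51.0, 49.0, 50.0],
    }
)
flow = normalize_flow_table(flow)
print("transfection-normalized reporter frequencies:")
print(flow.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

stats = compare_groups(flow, "normalized_frequency", "condition", [("control", "inhibitor")])
row = stats.iloc[0]
print(
    f"\n{row.comparison}: {row.mean_a:.4f} vs {row.mean_b:.4f} "
    f"({row.fold:.1f}-fold {row.direction}), adjusted p = {row.p_adjusted:.4g}"
)

plate = pd.DataFrame(
    [
        ("KO", "DMSO", "0Gy", 96, 500), ("KO", "DMSO", "0Gy", 104, 500),
        ("KO", "M3814", "0Gy", 61, 500), ("KO", "M3814", "1Gy", 22, 500),
        ("KO", "DMSO", "1Gy", 58, 500),
    ],
    columns=["cell_line", "drug", "irradiation", "colonies", "seeded"],
)
surv = clonogenic_survival(plate)
print("\nclonogenic survival relative to DMSO / 0 Gy:")
print(
    surv[["cell_line", "drug", "irradiation", "plating_efficiency", "survival"]].to_string(
        index=False, float_format=lambda v: f"{v:.3f}"
    )
)
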