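"""Reporter-assay and clonogenic-survival normalizations.

Flow-cytometry reporter frequencies (e.g. GFP+ for a No Indel EJ reporter, or
mRuby2+ for an HDR reporter) are normalized to the transfection efficiency
measured in a parallel GFP transfection of the same sample. Clonogenic
survival is computed per well from the plating efficiency (colonies / cells
seeded) relative to the mean plating efficiency of the untreated control wells
of the same cell line, so wells seeded at different densities are comparable
and the control wells average to exactly 1.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["normalize_flow", "normalize_flow_table", "clonogenic_survival"]


def normalize_flow(pct_positive: float, pct_transfection: float) -> float:
    """Reporter frequency corrected for transfection efficiency.

    Both arguments are percentages in [0, 100]; the result is their ratio
    (e.g. 2.0% positive at 50% transfection -> 0.04, i.e. 4% of transfected
    cells).
    """
    for name, v in (("pct_positive", pct_positive), ("pct_transfection", pct_transfection)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} = {v} outside [0, 100]")
    if pct_transfection == 0:
        raise ValueError("transfection efficiency is zero; normalization undefined")
    return pct_positive / pct_transfection


def normalize_flow_table(
    data: pd.DataFrame,
    positive: str = "pct_positive",
    transfection: str = "pct_transfection",
) -> pd.DataFrame:
    """Add a ``normalized_frequency`` column to a tidy flow table."""
    out = data.copy()
    out["normalized_frequency"] = [
        normalize_flow(p, t) for p, t in zip(out[positive], out[transfection])
    ]
    return out


def clonogenic_survival(
    data: pd.DataFrame,
    control_key: tuple = ("DMSO", "0Gy"),
    line: str = "cell_line",
    treatment_cols: tuple = ("drug", "irradiation"),
    colonies: str = "colonies",
    seeded: str = "seeded",
) -> pd.DataFrame:
    """Per-well clonogenic survival relative to the untreated control wells.

    For each well, plating efficiency = colonies / cells seeded; survival =
    plating efficiency / mean plating efficiency of the control-condition
    wells of the same cell line. Raises if a line's control wells produced no
    colonies.
    """
    out = data.copy()
    if (out[seeded] <= 0).any():
        raise ValueError("cells seeded must be > 0 in every well")
    out["plating_efficiency"] = out[colonies] / out[seeded]
    is_control = pd.Series(True, index=out.index)
    for col, val in zip(treatment_cols, control_key):
        is_control &= out[col] == val
    control_means = {}
    for name, sub in out.groupby(line):
        ctrl = sub.loc[is_control.loc[sub.index], "plating_efficiency"]
        if len(ctrl) == 0:
            raise ValueError(f"cell line {name}: no control wells ({control_key})")
        if ctrl.mean() <= 0:
            raise ValueError(f"cell line {name}: control wells formed no colonies")
        control_means[name] = ctrl.mean()
    out["survival"] = [
        pe / control_means[ln] for pe, ln in zip(out["plating_efficiency"], out[line])
    ]
    return out
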