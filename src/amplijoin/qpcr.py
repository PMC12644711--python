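"""Relative quantification of the deletion rearrangement by qPCR (2^-ddCt).

For each sample, the cycle threshold of the rearrangement-specific reaction is
referenced to the control reaction within the same locus:
``dCt = mean(Ct_del) - mean(Ct_ctrl)``. Samples are then normalized to a
parental reference measured in the same run, ``ddCt = dCt_sample -
dCt_parental``, and the relative level reported as ``fold = 2**(-ddCt)``. This
orientation makes more rearrangement template (lower Ct_del) give a larger
fold, so the parental sample is exactly 1 against itself and a one-cycle drop
in Ct_del doubles the fold. No amplification-efficiency correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["QpcrRecord", "delta_ct", "ddct_fold", "quantify_table"]


@dataclass(frozen=True)
class QpcrRecord:
    """Ct replicates of one sample's rearrangement and control reactions."""

    sample: str
    ct_del: tuple  # rearrangement-specific reaction replicates
    ct_ctrl: tuple  # control reaction replicates (same locus)
    run: str = ""

    def __post_init__(self) -> None:
        if not self.ct_del or not self.ct_ctrl:
            raise ValueError(f"sample {self.sample}: both reactions need Ct values")
        for v in (*self.ct_del, *self.ct_ctrl):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"sample {self.sample}: Ct values must be finite and > 0")


def delta_ct(record: QpcrRecord) -> float:
    """dCt = mean(Ct_del) - mean(Ct_ctrl) of one sample."""
    return float(np.mean(record.ct_del) - np.mean(record.ct_ctrl))


def ddct_fold(record: QpcrRecord, parental: QpcrRecord) -> float:
    """Relative rearrangement level 2^-(dCt_sample - dCt_parental).

    Parental must be measured in the same run when run ids are given.
    """
    if record.run and parental.run and record.run != parental.run:
        raise ValueError(
            f"sample {record.sample} (run {record.run}) and parental "
            f"(run {parental.run}) were not measured in parallel"
        )
    return float(2.0 ** -(delta_ct(record) - delta_ct(parental)))


def quantify_table(data: pd.DataFrame, parental: str = "Parental") -> pd.DataFrame:
    """2^-ddCt for a long-format Ct table.

    Expected columns: ``sample``, ``reaction`` (``del`` or ``ctrl``), ``ct``,
    and optionally ``run``. Returns one row per sample with dCt, ddCt and fold
    relative to the parental sample.
    """
    records = {}
    for sample, sub in data.groupby("sample"):
        run = str(sub["run"].iloc[0]) if "run" in sub else ""
        dels = tuple(sub.loc[sub["reaction"] == "del", "ct"])
        ctrls = tuple(sub.loc[sub["reaction"] == "ctrl", "ct"])
        if not ctrls:
            raise ValueError(f"sample {sample}: missing control reaction")
        if not dels:
            raise ValueError(f"sample {sample}: missing rearrangement reaction")
        records[sample] = QpcrRecord(sample=str(sample), ct_del=dels, ct_ctrl=ctrls, run=run)
    if parental not in records:
        raise ValueError(f"parental sample {parental!r} not present")
    ref = records[parental]
    rows = [
        {
            "sample": name,
            "delta_ct": delta_ct(rec),
            "delta_delta_ct": delta_ct(rec) - delta_ct(ref),
            "fold": ddct_fold(rec, ref),
        }
        for name, rec in records.items()
    ]
    return pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)
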