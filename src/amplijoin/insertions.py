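"""Insertion-size profiling and Cas9 5'-overhang fill-in consistency scoring.

An insertion at the junction is *consistent with fill-in* when it equals the
sequence predicted to be duplicated by filling in an n-nt 5' overhang at the
left DSB, the right DSB, or a concatenation of overhangs from both
(``a + b = L`` with ``a, b >= 1``). Because staggered cleavage at either locus
can generate the same short insert, a 1-nt insertion is inherently ambiguous
between the two loci; all matching explanations are recorded and the primary
one follows the precedence left, right, both.

Scoring is by exact product reconstruction when the read is available
(``read == flank_left + prediction + flank_right``), which is independent of
how the aligner placed the insertion; without a read the insert string is
compared directly against the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .classify import INSERTION
from .locus import DEFAULT_MAX_OVERHANG, JunctionReference

__all__ = [
    "InsertionRecord",
    "score_insertion",
    "records_from_calls",
    "insertion_profile",
    "SIZE_BINS",
]

SIZE_BINS = ("1", "2", "3", "4", ">=5")

LEFT_FILLIN = "left_fillin"
RIGHT_FILLIN = "right_fillin"
BOTH_LOCI = "both_loci"
INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class InsertionRecord:
    """One insertion event and its fill-in explanation(s)."""

    read_id: str
    sequence: str
    length: int
    consistency: str  # left_fillin | right_fillin | both_loci | inconsistent
    overhang_left: int = 0
    overhang_right: int = 0
    explanations: tuple = ()  # all matching (label, a, b)
    flagged: bool = False  # non-ACGT insert
    read_count: int = 1


def size_bin(length: int) -> str:
    return str(length) if length < 5 else ">=5"


def score_insertion(
    insert: str,
    junction: JunctionReference,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
    read: str | None = None,
    read_id: str = "",
) -> InsertionRecord:
    """Score one insertion for consistency with 5'-overhang fill-in.

    If ``read`` is given, each candidate explanation is tested by rebuilding
    the full product at the junction coordinate; otherwise the insert string
    itself is compared. Inserts longer than ``2 * max_overhang`` can never be
    explained, and non-ACGT inserts are scored inconsistent and flagged.
    """
    L = len(insert)
    if L < 1:
        raise ValueError("empty insertion")
    if not set(insert) <= set("ACGT"):
        return InsertionRecord(read_id, insert, L, INCONSISTENT, flagged=True)

    seq, J = junction.sequence, junction.junction

    def matches(pred: str) -> bool:
        if read is not None:
            return read == seq[:J] + pred + seq[J:]
        return insert == pred

    explanations = []
    if L <= max_overhang:
        if matches(junction.fillin_left(L, max_overhang)):
            explanations.append((LEFT_FILLIN, L, 0))
        if matches(junction.fillin_right(L, max_overhang)):
            explanations.append((RIGHT_FILLIN, 0, L))
    if 2 <= L <= 2 * max_overhang:
        for a in range(max(1, L - max_overhang), min(max_overhang, L - 1) + 1):
            b = L - a
            pred = junction.fillin_left(a, max_overhang) + junction.fillin_right(b, max_overhang)
            if matches(pred):
                explanations.append((BOTH_LOCI, a, b))
    if not explanations:
        return InsertionRecord(read_id, insert, L, INCONSISTENT)
    label, a, b = explanations[0]
    return InsertionRecord(
        read_id,
        insert,
        L,
        label,
        overhang_left=a,
        overhang_right=b,
        explanations=tuple(explanations),
    )


def records_from_calls(
    calls: pd.DataFrame,
    junction: JunctionReference,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> list[InsertionRecord]:
    """Score every Insertion-category read of a call table.

    Only single-insertion reads are scored against the read product; the rare
    multi-insertion read is scored inconsistent (its inserts cannot all sit at
    the junction).
    """
    out = []
    sub = calls[calls["category"] == INSERTION]
    for row in sub.itertuples(index=False):
        inserts = [s for s in row.insertion_seq.split(";") if s]
        if len(inserts) == 1:
            out.append(
                score_insertion(
                    inserts[0], junction, max_overhang, read=row.sequence, read_id=row.read_id
                )
            )
        else:
            out.append(
                InsertionRecord(row.read_id, "".join(inserts), sum(map(len, inserts)), INCONSISTENT)
            )
    return out


def insertion_profile(records: Iterable[InsertionRecord]) -> pd.DataFrame:
    """Per-size insertion profile: frequency and percent fill-in consistent.

    Size bins are 1, 2, 3, 4 and >=5 nt. ``pct_consistent`` is the percentage
    of reads in the bin explained by fill-in from either or both loci. Empty
    input yields an empty frame with ``attrs["empty"] = True``.
    """
    counts: dict[str, list[int]] = {}
    expl: dict[str, dict[str, int]] = {}
    for rec in records:
        b = size_bin(rec.length)
        tot_con = counts.setdefault(b, [0, 0])
        tot_con[0] += rec.read_count
        if rec.consistency != INCONSISTENT:
            tot_con[1] += rec.read_count
        expl.setdefault(b, {}).setdefault(rec.consistency, 0)
        expl[b][rec.consistency] += rec.read_count
    if not counts:
        out = pd.DataFrame(
            columns=["size", "reads", "frequency", "pct_consistent", "explanations"]
        )
        out.attrs["empty"] = True
        return out
    total = sum(v[0] for v in counts.values())
    rows = []
    for b in SIZE_BINS:
        if b not in counts:
            continue
        n, con = counts[b]
        rows.append(
            {
                "size": b,
                "reads": n,
                "frequency": n / total,
                "pct_consistent": 100.0 * con / n,
                "explanations": ";".join(f"{k}={v}" for k, v in sorted(expl[b].items())),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["empty"] = False
    return out
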