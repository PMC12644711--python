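"""Per-read repair-outcome classification against the predicted No Indel EJ junction.

Category is a pure function of the indel content of the canonical alignment:

* no indels -> ``NoIndelEJ`` (base substitutions allowed),
* insertions only -> ``Insertion``,
* deletions only (continuous or discontinuous) -> ``Deletion``,
* both -> ``ComplexIndel``.

Reads whose best alignment falls below the identity floor are ``Unclassified``.
No read deduplication is performed: targeted amplicons begin and end at fixed
primer positions, so identical reads are expected and meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Iterator

import pandas as pd

from .align import DEFAULT_SCORING, Alignment, ScoringScheme, align_read
from .locus import JunctionReference

__all__ = [
    "CATEGORIES",
    "NO_INDEL_EJ",
    "INSERTION",
    "DELETION",
    "COMPLEX_INDEL",
    "UNCLASSIFIED",
    "JunctionCall",
    "classify_junction",
    "classify_all",
]

NO_INDEL_EJ = "NoIndelEJ"
INSERTION = "Insertion"
DELETION = "Deletion"
COMPLEX_INDEL = "ComplexIndel"
UNCLASSIFIED = "Unclassified"
CATEGORIES = (NO_INDEL_EJ, INSERTION, DELETION, COMPLEX_INDEL)


@dataclass(frozen=True)
class JunctionCall:
    """Classification of one read at the two-DSB junction."""

    read_id: str
    category: str
    sequence: str
    deletion_intervals: tuple  # of (start, end) on the junction reference
    total_deleted_nt: int
    insertions: tuple  # of (ref_position, inserted_sequence)
    n_base_changes: int
    score: float
    identity: float


def classify_junction(
    aln: Alignment,
    read_id: str = "",
    identity_floor: float = DEFAULT_SCORING.identity_floor,
) -> JunctionCall:
    """Assign the repair-outcome category to a canonical alignment."""
    if aln.identity < identity_floor:
        category = UNCLASSIFIED
    elif aln.insertions and aln.deletions:
        category = COMPLEX_INDEL
    elif aln.insertions:
        category = INSERTION
    elif aln.deletions:
        category = DELETION
    else:
        category = NO_INDEL_EJ
    return JunctionCall(
        read_id=read_id,
        category=category,
        sequence=aln.read,
        deletion_intervals=aln.deletions,
        total_deleted_nt=aln.total_deleted,
        insertions=aln.insertions,
        n_base_changes=aln.n_mismatches,
        score=aln.score,
        identity=aln.identity,
    )


_COLUMNS = [
    "read_id",
    "category",
    "n_insertions",
    "insertion_pos",
    "insertion_seq",
    "n_deletions",
    "deleted_nt",
    "deletion_intervals",
    "n_base_changes",
    "score",
    "identity",
    "sequence",
]


def _iter_reads(reads) -> Iterator[tuple[str, str]]:
    if isinstance(reads, (str, PathLike)):
        from .io import read_fastq

        yield from read_fastq(reads)
        return
    for item in reads:
        if hasattr(item, "seq"):  # Bio.SeqRecord
            yield item.id, str(item.seq)
        else:
            rid, seq = item
            yield rid, seq


def calls_to_frame(calls: Iterable[JunctionCall]) -> pd.DataFrame:
    rows = [
        {
            "read_id": c.read_id,
            "category": c.category,
            "n_insertions": len(c.insertions),
            "insertion_pos": ";".join(str(p) for p, _ in c.insertions),
            "insertion_seq": ";".join(s for _, s in c.insertions),
            "n_deletions": len(c.deletion_intervals),
            "deleted_nt": c.total_deleted_nt,
            "deletion_intervals": ";".join(f"{i}-{j}" for i, j in c.deletion_intervals),
            "n_base_changes": c.n_base_changes,
            "score": c.score,
            "identity": round(c.identity, 6),
            "sequence": c.sequence,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def classify_all(
    reads,
    junction: JunctionReference,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> pd.DataFrame:
    """Align and classify every read; returns one row per read.

    ``reads`` may be a FASTQ path, an iterable of ``(read_id, sequence)``
    pairs, or an iterable of Bio.SeqRecord objects. Read order does not affect
    summary counts; no deduplication is applied.
    """
    calls = [
        classify_junction(align_read(seq, junction, scoring), rid, scoring.identity_floor)
        for rid, seq in _iter_reads(reads)
    ]
    if not calls:
        warnings.warn("classify_all: no reads in input; returning empty table", stacklevel=2)
    return calls_to_frame(calls)
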