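"""Global affine-gap alignment of amplicon reads to a junction reference.

The aligner wraps :class:`Bio.Align.PairwiseAligner` (global mode, affine
gaps, BWA-like default scores) and converts its output into a compact,
canonicalized operation list on reference coordinates: insertions are
``(position, sequence)``, deletions are half-open ``[start, end)`` intervals,
and every indel is left-shifted to its leftmost score-equivalent placement so
that downstream microhomology arithmetic is placement-independent.

A gap of length L costs ``gap_open + gap_extend * L`` (subtracted from the
score). N bases match nothing and are counted as base changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .locus import JunctionReference

__all__ = ["ScoringScheme", "Alignment", "InputError", "align_read"]

_ALPHABET = "ACGTN"
_VALID = frozenset(_ALPHABET)


class InputError(ValueError):
    """A read contains symbols outside A/C/G/T/N."""


@dataclass(frozen=True)
class ScoringScheme:
    """Affine alignment scores; a length-L gap costs ``gap_open + gap_extend*L``.

    Defaults mirror BWA-style scoring (match +2, mismatch −4, gap open −6,
    gap extend −1). ``identity_floor`` is the minimum alignment identity
    (matches / alignment columns) below which a read is left Unclassified.
    """

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = 6.0
    gap_extend: float = 1.0
    identity_floor: float = 0.70

    def gap_score(self, length: int) -> float:
        return -(self.gap_open + self.gap_extend * length)


DEFAULT_SCORING = ScoringScheme()

_FORBID = -1e9


@lru_cache(maxsize=32)
def _aligner(scoring: ScoringScheme, forbid_insertions: bool, forbid_deletions: bool) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score thereafter; -(open+extend), -extend reproduces the
    # gap_open + gap_extend*L convention.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    if forbid_insertions:  # gaps in the reference (target)
        aligner.insertion_score = _FORBID
    if forbid_deletions:  # gaps in the read (query)
        aligner.deletion_score = _FORBID
    return aligner


def restricted_score(
    reference: str,
    read: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    forbid_insertions: bool = False,
    forbid_deletions: bool = False,
) -> float:
    """Optimal global score under the scheme, optionally forbidding one gap type."""
    return _aligner(scoring, forbid_insertions, forbid_deletions).score(reference, read)


@dataclass(frozen=True)
class Alignment:
    """Canonicalized global alignment of one read against the junction reference."""

    read: str
    score: float
    insertions: tuple  # of (ref_position, inserted_sequence)
    deletions: tuple  # of (start, end) half-open on the reference
    n_matches: int
    n_mismatches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.n_matches / self.columns if self.columns else 0.0

    @property
    def total_deleted(self) -> int:
        return sum(j - i for i, j in self.deletions)


def _segments(coordinates) -> list[tuple[int, int, int, int]]:
    """(t0, t1, q0, q1) runs from a biopython coordinate array."""
    t, q = coordinates
    return [
        (int(t[k]), int(t[k + 1]), int(q[k]), int(q[k + 1]))
        for k in range(len(t) - 1)
        if t[k + 1] != t[k] or q[k + 1] != q[k]
    ]


def _canonicalize(ref: str, ops: list) -> tuple[tuple, tuple]:
    """Left-shift each indel through equal bases to its leftmost placement.

    ``ops`` is a position-sorted list of ("ins", pos, seq) / ("del", i, j).
    Shifts stop at the previous operation's right edge so operations never
    reorder or overlap.
    """
    insertions, deletions = [], []
    floor = 0
    for op in ops:
        if op[0] == "del":
            _, i, j = op
            while i > floor and ref[i - 1] == ref[j - 1]:
                i -= 1
                j -= 1
            deletions.append((i, j))
            floor = j
        else:
            _, pos, seq = op
            while pos > floor and ref[pos - 1] == seq[-1]:
                seq = ref[pos - 1] + seq[:-1]
                pos -= 1
            insertions.append((pos, seq))
            floor = pos
    return tuple(insertions), tuple(deletions)


def align_read(
    read: str,
    junction: JunctionReference | str,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> Alignment:
    """Optimal global alignment of ``read`` to the junction reference.

    Returns a canonicalized :class:`Alignment`. Score ties between a gapped
    and an equal-length gapless (all-substitution) interpretation are resolved
    toward the gapless one (fewest gap openings). Raises :class:`InputError`
    for non-ACGTN symbols or an empty read.
    """
    ref = junction.sequence if isinstance(junction, JunctionReference) else junction
    if not read:
        raise InputError("empty read")
    if not set(read) <= _VALID:
        bad = sorted(set(read) - _VALID)
        raise InputError(f"read contains invalid symbols: {bad}")

    aligner = _aligner(scoring, False, False)
    alignments = aligner.align(ref, read)
    best = alignments[0]
    score = float(best.score)

    # prefer the all-substitution interpretation when it ties the optimum
    if len(read) == len(ref):
        mm = sum(1 for a, b in zip(ref, read) if a != b or a == "N")
        gapless = (len(ref) - mm) * scoring.match + mm * scoring.mismatch
        if gapless >= score:
            return Alignment(
                read=read,
                score=float(gapless),
                insertions=(),
                deletions=(),
                n_matches=len(ref) - mm,
                n_mismatches=mm,
                columns=len(ref),
            )

    ops: list = []
    n_match = n_mismatch = columns = 0
    for t0, t1, q0, q1 in _segments(best.coordinates):
        if t1 > t0 and q1 > q0:  # aligned block
            for a, b in zip(ref[t0:t1], read[q0:q1]):
                if a == b and a != "N":
                    n_match += 1
                else:
                    n_mismatch += 1
            columns += t1 - t0
        elif q1 > q0:  # gap in reference -> insertion in read
            ops.append(("ins", t0, read[q0:q1]))
            columns += q1 - q0
        else:  # gap in read -> deletion from reference
            ops.append(("del", t0, t1))
            columns += t1 - t0
    insertions, deletions = _canonicalize(ref, ops)
    return Alignment(
        read=read,
        score=score,
        insertions=insertions,
        deletions=deletions,
        n_matches=n_match,
        n_mismatches=n_mismatch,
        columns=columns,
    )
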