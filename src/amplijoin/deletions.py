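"""Deletion breakpoints, junction microhomology, and deletion profiles.

Microhomology (MH) here is the total flanking-identity length of a deletion:
the number of distinct equal-size placements producing the identical product,
minus one. Equivalently it is the longest common prefix of the two suffixes at
the deletion edges plus the longest common suffix of the two prefixes — a
placement-independent quantity, so left-aligned canonical intervals give the
same answer as any equivalent placement.

Some deletion products carry nucleotides consistent with staggered Cas9
cleavage: the retained end was extended by a 5'-overhang fill-in before the
deletion. Such reads surface either as a deletion plus an adjacent insertion
(ComplexIndel upstream) or as a deletion with junction-adjacent base changes.
:func:`assign_breakpoints` re-attributes them by exact product reconstruction
against each candidate fill-in, computes the deletion size net of the
duplicated bases, and measures MH in the fill-in-adjusted reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .classify import COMPLEX_INDEL, DELETION, JunctionCall
from .locus import DEFAULT_MAX_OVERHANG, JunctionReference, ParameterError

__all__ = [
    "DeletionRecord",
    "microhomology_length",
    "assign_breakpoints",
    "records_from_calls",
    "deletion_profile",
    "MH_BINS",
]

#: reported microhomology classes
MH_BINS = ("0", "1", "2", "3", "4+")


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def microhomology_length(junction: JunctionReference | str, interval: tuple[int, int]) -> int:
    """Total flanking-identity (microhomology) length of a deletion interval.

    ``interval`` is half-open ``[i, j)`` on the reference; the result equals
    the number of equal-size placements yielding the identical product, minus
    one.
    """
    seq = junction.sequence if isinstance(junction, JunctionReference) else junction
    i, j = interval
    if i >= j:
        raise ParameterError(f"empty or inverted deletion interval [{i}, {j})")
    if not (0 < i and j <= len(seq)):
        raise ParameterError(f"interval [{i}, {j}) outside 1..{len(seq)}")
    return _lcp(seq[i:], seq[j:]) + _lcp(seq[:i][::-1], seq[:j][::-1])


@dataclass(frozen=True)
class DeletionRecord:
    """One deletion event (possibly aggregating identical reads)."""

    read_id: str
    deletion_size: int  # net removed nt (> 0); reported as -size in output tables
    mh_length: int
    intervals: tuple  # canonical interval(s); in the adjusted frame if fillin_adjusted
    fillin_adjusted: bool = False
    fillin_face: str = ""  # 'left' | 'right' when adjusted
    overhang: int = 0
    discontinuous: bool = False
    ambiguous_fillin: bool = False
    read_count: int = 1


def _staggered_candidates(call: JunctionCall, junction: JunctionReference, max_overhang: int):
    """Yield (n, face, t) staggered products exactly matching the read."""
    seq, J, read = junction.sequence, junction.junction, call.sequence
    t = len(seq) - len(read)  # net removed nt before adding back the overhang
    for n in range(1, max_overhang + 1):
        span = t + n  # removed from the fill-in-adjusted reference
        if span - n < 1:
            continue
        fl = junction.fillin_left(n, max_overhang)
        if J + span <= len(seq) and read == seq[:J] + fl + seq[J + span :]:
            yield n, "left", span
        fr = junction.fillin_right(n, max_overhang)
        if J - span >= 0 and read == seq[: J - span] + fr + seq[J:]:
            yield n, "right", span


def assign_breakpoints(
    call: JunctionCall,
    junction: JunctionReference,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> DeletionRecord | None:
    """Deletion record for a call, reassigning staggered-cut breakpoints.

    Returns ``None`` for calls that do not enter the deletion pool: non-deletion
    categories, and ComplexIndel reads whose insertion is not explained by a
    fill-in product. Staggered reinterpretation is attempted only when the call
    carries an insertion or at least one base change, so plain deletions are
    never perturbed. When it applies, the reported size is net of the
    duplicated fill-in bases and MH is computed in the adjusted frame.
    """
    if call.category not in (DELETION, COMPLEX_INDEL) or not (
        call.deletion_intervals or len(call.sequence) < len(junction.sequence)
    ):
        return None

    if call.insertions or call.n_base_changes:
        matches = sorted(
            _staggered_candidates(call, junction, max_overhang),
            key=lambda m: (m[0], 0 if m[1] == "left" else 1),
        )
        if matches:
            n, face, span = matches[0]
            ambiguous = len(matches) > 1 and matches[1][0] == n
            seq, J = junction.sequence, junction.junction
            fill = junction.fillin_left(n) if face == "left" else junction.fillin_right(n)
            adjusted = seq[:J] + fill + seq[J:]
            iv = (J + n, J + n + span) if face == "left" else (J - span, J)
            d = span - n
            mh = min(microhomology_length(adjusted, iv), d)
            return DeletionRecord(
                read_id=call.read_id,
                deletion_size=d,
                mh_length=mh,
                intervals=(iv,),
                fillin_adjusted=True,
                fillin_face=face,
                overhang=n,
                ambiguous_fillin=ambiguous,
            )

    if call.category != DELETION:
        return None  # ComplexIndel without a fill-in explanation: excluded

    intervals = call.deletion_intervals
    J = junction.junction
    if len(intervals) == 1:
        iv = intervals[0]
        return DeletionRecord(
            read_id=call.read_id,
            deletion_size=iv[1] - iv[0],
            mh_length=microhomology_length(junction, iv),
            intervals=(iv,),
        )
    # discontinuous: size sums all segments, MH from the junction-spanning one
    total = sum(j - i for i, j in intervals)
    spanning = min(intervals, key=lambda iv: max(iv[0] - J, J - iv[1], 0))
    return DeletionRecord(
        read_id=call.read_id,
        deletion_size=total,
        mh_length=microhomology_length(junction, spanning),
        intervals=tuple(intervals),
        discontinuous=True,
    )


def records_from_calls(
    calls: pd.DataFrame | Iterable[JunctionCall],
    junction: JunctionReference,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> list[DeletionRecord]:
    """Deletion pool of a sample: every call that yields a DeletionRecord."""
    out = []
    for call in _iter_calls(calls):
        rec = assign_breakpoints(call, junction, max_overhang)
        if rec is not None:
            out.append(rec)
    return out


def _iter_calls(calls):
    if isinstance(calls, pd.DataFrame):
        for row in calls.itertuples(index=False):
            yield JunctionCall(
                read_id=row.read_id,
                category=row.category,
                sequence=row.sequence,
                deletion_intervals=tuple(
                    tuple(map(int, part.split("-")))
                    for part in row.deletion_intervals.split(";")
                    if part
                ),
                total_deleted_nt=int(row.deleted_nt),
                insertions=tuple(
                    (int(p), s)
                    for p, s in zip(
                        [x for x in str(row.insertion_pos).split(";") if x],
                        [x for x in row.insertion_seq.split(";") if x],
                    )
                ),
                n_base_changes=int(row.n_base_changes),
                score=float(row.score),
                identity=float(row.identity),
            )
    else:
        yield from calls


def mh_bin(k: int) -> str:
    return str(k) if k < 4 else "4+"


def deletion_profile(records: Iterable[DeletionRecord]) -> dict[str, pd.DataFrame]:
    """Aggregate deletion-size and microhomology tables for one sample.

    Returns ``{"size": ..., "size_mh": ..., "mh_usage": ...}``:

    * ``size`` — per-size frequency among deletion reads (sizes reported as
      negative integers, the field's sign convention);
    * ``size_mh`` — per-size MH composition (fraction of that size's reads at
      each MH class);
    * ``mh_usage`` — overall MH-usage distribution over classes 0,1,2,3,4+.

    With zero deletion reads all frames are empty and carry
    ``attrs["empty"] = True``.
    """
    counts: dict[tuple[int, str], int] = {}
    for rec in records:
        key = (rec.deletion_size, mh_bin(rec.mh_length))
        counts[key] = counts.get(key, 0) + rec.read_count
    if not counts:
        empty = {
            "size": pd.DataFrame(columns=["deletion_size", "reads", "frequency"]),
            "size_mh": pd.DataFrame(columns=["deletion_size", "mh", "reads", "fraction"]),
            "mh_usage": pd.DataFrame(columns=["mh", "reads", "fraction"]),
        }
        for frame in empty.values():
            frame.attrs["empty"] = True
        return empty

    df = pd.DataFrame(
        [(d, mh, n) for (d, mh), n in counts.items()], columns=["size_nt", "mh", "reads"]
    )
    total = df["reads"].sum()

    size = df.groupby("size_nt", as_index=False)["reads"].sum()
    size["frequency"] = size["reads"] / total
    size["deletion_size"] = -size["size_nt"]
    size = size.sort_values("size_nt")[["deletion_size", "reads", "frequency"]].reset_index(
        drop=True
    )

    size_mh = df.copy()
    size_mh["fraction"] = size_mh["reads"] / size_mh.groupby("size_nt")["reads"].transform("sum")
    size_mh["deletion_size"] = -size_mh["size_nt"]
    size_mh = size_mh.sort_values(["size_nt", "mh"])[
        ["deletion_size", "mh", "reads", "fraction"]
    ].reset_index(drop=True)

    usage = df.groupby("mh", as_index=False)["reads"].sum()
    usage["fraction"] = usage["reads"] / total
    usage["mh"] = pd.Categorical(usage["mh"], categories=list(MH_BINS), ordered=True)
    usage = usage.sort_values("mh").reset_index(drop=True)

    for frame in (size, size_mh, usage):
        frame.attrs["empty"] = False
    return {"size": size, "size_mh": size_mh, "mh_usage": usage}
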