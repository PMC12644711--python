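"""Synthetic dual-DSB junction amplicon reads with per-read ground truth.

The generator emulates the repair-outcome structure the classifier assumes:

* **NoIndelEJ** — the predicted junction restored exactly (plus sequencing
  substitutions);
* **Insertion** — with probability ``p_fillin`` a staggered-cut 5'-overhang
  fill-in product (1..max_overhang nt from the left DSB, the right DSB, or a
  concatenation from both), otherwise a uniformly random insert of comparable
  length, placed at the junction;
* **Deletion** — a mixture of microhomology-annealing deletions that remove
  the segment between one copy of a planted repeat pair (the product retains
  one copy) and blunt-processing deletions that trim both cut faces;
* **ComplexIndel** — one deletion plus one unrelated insertion at the
  junction.

Substitution errors are applied i.i.d. per base at rate ``substitution_error_rate``.
Everything is drawn from a single seeded ``numpy`` generator in a fixed order
(category, then category-specific draws, then errors, per read), so truth
tables are byte-stable across runs.

The synthetic junction places both PAMs on the retained side of each cut
(PAM-proximal retained ends), the geometry under which 5'-overhang fill-in
adds bases to the retained ends and staggered DSBs can produce insertions
from either locus. Consequently positions −6/−5 (CC) and +4/+5 (GG) relative
to the junction are fixed PAM bases; planted repeats must not conflict with
them.

ComplexIndel inserts are rejection-sampled so that the read's optimal
alignment strictly requires both an insertion and a deletion; without that
constraint short inserts can be absorbed as substitutions inside the deleted
segment, making the true category ill-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, ScoringScheme, restricted_score
from .classify import COMPLEX_INDEL, DELETION, INSERTION, NO_INDEL_EJ
from .locus import DEFAULT_MAX_OVERHANG, JunctionReference, LocusSpec

__all__ = [
    "SimConfig",
    "SimConfigError",
    "DEFAULT_REPEATS",
    "random_junction",
    "plant_repeats",
    "simulate_reads",
    "reconstruct_read",
]

_BASES = np.array(list("ACGT"))

#: default planted repeat pairs (sequence, left offset, right offset relative
#: to the junction); lengths 2/3/4 nt, placements clear of the PAM bases.
DEFAULT_REPEATS = (("CT", -9, 7), ("TGA", -15, 10), ("GATC", -20, 14))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def _check_dist(name: str, dist: dict) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise SimConfigError(f"{name} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in dist.values()):
        raise SimConfigError(f"{name} contains negative probabilities")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated amplicon library."""

    n_reads: int = 10_000
    seed: int = 0
    #: probabilities over (NoIndelEJ, Insertion, Deletion, ComplexIndel)
    category_mix: tuple = (0.40, 0.20, 0.35, 0.05)
    #: 5'-overhang size distribution (per locus); 1 nt overhangs dominate
    overhang_dist: dict = field(default_factory=lambda: {1: 0.55, 2: 0.20, 3: 0.15, 4: 0.10})
    fillin_source_mix: dict = field(
        default_factory=lambda: {"left": 0.45, "right": 0.45, "both": 0.10}
    )
    #: probability an Insertion read is a fill-in product rather than random
    p_fillin: float = 0.9
    #: weight of microhomology-annealing deletions (vs blunt-processing)
    w_mh: float = 0.6
    #: total-size distribution for blunt-processing deletions
    blunt_size_dist: dict = field(
        default_factory=lambda: {s: p / sum(0.78**k for k in range(1, 16)) for s, p in
                                 ((s, 0.78**s) for s in range(1, 16))}
    )
    #: inclusive bounds for ComplexIndel insert length
    complex_insert_range: tuple = (4, 8)
    #: probability a Deletion read is a staggered-cut product (fill-in + resection)
    p_staggered_deletion: float = 0.0
    substitution_error_rate: float = 0.001
    #: optional sequencing indel error rate; off by default so truth categories
    #: stay well defined
    indel_error_rate: float = 0.0
    max_overhang: int = DEFAULT_MAX_OVERHANG

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise SimConfigError("n_reads must be >= 0")
        if len(self.category_mix) != 4:
            raise SimConfigError("category_mix needs 4 probabilities")
        _check_dist("category_mix", dict(enumerate(self.category_mix)))
        _check_dist("overhang_dist", self.overhang_dist)
        if any(not 1 <= s <= self.max_overhang for s in self.overhang_dist):
            raise SimConfigError("overhang sizes must lie in 1..max_overhang")
        _check_dist("fillin_source_mix", self.fillin_source_mix)
        if set(self.fillin_source_mix) != {"left", "right", "both"}:
            raise SimConfigError("fillin_source_mix keys must be left/right/both")
        _check_dist("blunt_size_dist", self.blunt_size_dist)
        if not 0 <= self.p_fillin <= 1 or not 0 <= self.w_mh <= 1:
            raise SimConfigError("p_fillin and w_mh must lie in [0, 1]")
        if not 0 <= self.substitution_error_rate <= 0.1:
            raise SimConfigError("substitution_error_rate must lie in [0, 0.1]")
        if not 0 <= self.p_staggered_deletion <= 1:
            raise SimConfigError("p_staggered_deletion must lie in [0, 1]")

    def replace(self, **kw) -> "SimConfig":
        return dc_replace(self, **kw)


# ---------------------------------------------------------------------------
# synthetic junction construction


def _draw(rng: np.random.Generator, dist: dict):
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def random_junction(
    seed: int,
    flank: int = 60,
    repeats: tuple = (),
    margin: int = 25,
    name: str = "sim",
) -> JunctionReference:
    """Random two-locus junction reference with optional planted repeat pairs.

    The left locus carries its protospacer on the minus strand with the PAM
    (CC on the forward strand) at junction offsets −6/−5; the right locus is
    plus-strand with the PAM (GG) at +4/+5. Both retained ends are therefore
    PAM-proximal. ``repeats`` is a sequence of ``(repeat_seq, left_offset,
    right_offset)`` with each copy entirely on one side of the junction;
    flanking bases are adjusted so the microhomology of a deletion spanning a
    pair equals exactly the repeat length.
    """
    rng = np.random.default_rng(seed)
    return _build_junction(rng, flank, repeats, margin, name)


def plant_repeats(junction: JunctionReference, repeats, seed: int | None = None) -> JunctionReference:
    """Rebuild ``junction`` with fresh seeded-random flanks containing ``repeats``.

    Geometry (flank lengths, locus orientations) is preserved; every
    non-constrained position is redrawn from the seeded stream.
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    margin = max(len(junction.left.context) - junction.left.cut_index, 25)
    name = junction.left.name.removesuffix("_L")
    return _build_junction(rng, junction.flank_left, tuple(repeats), margin, name)


def _build_junction(rng, flank, repeats, margin, name) -> JunctionReference:
    from Bio.Seq import reverse_complement

    if margin < 25:
        raise SimConfigError("margin must be >= 25 to hold the protospacer")
    left_len = flank + margin
    right_len = flank + margin
    cut_l, cut_r = flank, margin
    left_ctx = rng.choice(_BASES, size=left_len).tolist()
    right_ctx = rng.choice(_BASES, size=right_len).tolist()

    def set_base(jpos: int, base: str, what: str, constrained: dict) -> None:
        prev = constrained.get(jpos)
        if prev is not None and prev != base:
            raise SimConfigError(f"{what}: position {jpos} already constrained to {prev!r}")
        constrained[jpos] = base
        if jpos < 0:
            left_ctx[cut_l + jpos] = base
        else:
            right_ctx[cut_r + jpos] = base

    def get_base(jpos: int) -> str:
        return left_ctx[cut_l + jpos] if jpos < 0 else right_ctx[cut_r + jpos]

    constrained: dict[int, str] = {}
    # PAMs: left locus minus strand -> CCN at junction offsets -6..-4;
    # right locus plus strand -> NGG at +3..+5
    set_base(-6, "C", "left PAM", constrained)
    set_base(-5, "C", "left PAM", constrained)
    set_base(4, "G", "right PAM", constrained)
    set_base(5, "G", "right PAM", constrained)

    placements = []
    for rep, lo, ro in repeats:
        rep = str(rep).upper()
        if not rep or not set(rep) <= set("ACGT"):
            raise SimConfigError(f"repeat {rep!r} must be non-empty A/C/G/T")
        if lo + len(rep) > 0 or ro < 0:
            raise SimConfigError(
                f"repeat {rep!r} at ({lo}, {ro}): each copy must lie entirely on one side"
            )
        if lo < -flank or ro + len(rep) > flank:
            raise SimConfigError(f"repeat {rep!r} at ({lo}, {ro}) outside the flanks")
        for start in (lo, ro):
            span = range(start, start + len(rep))
            if any(
                p in range(s, s + len(r)) for r, l2, r2 in placements for s in (l2, r2) for p in span
            ):
                raise SimConfigError(f"repeat {rep!r} at ({lo}, {ro}) overlaps another placement")
            for k, p in enumerate(span):
                set_base(p, rep[k], f"repeat {rep!r}", constrained)
        placements.append((rep, lo, ro))

    # break accidental microhomology extension around each planted pair so a
    # spanning deletion has MH exactly len(rep)
    for rep, lo, ro in placements:
        r = len(rep)
        for a, b in (((lo + r), (ro + r)), ((lo - 1), (ro - 1))):
            if a < -flank or b >= flank:
                continue
            if get_base(a) == get_base(b):
                target = a if a not in constrained else b
                if target in constrained:
                    raise SimConfigError(
                        f"cannot break microhomology extension around repeat {rep!r}"
                    )
                other = get_base(b if target == a else a)
                choices = [c for c in "ACGT" if c != other]
                set_base(target, choices[rng.integers(len(choices))], "MH break", constrained)

    left_context = "".join(left_ctx)
    right_context = "".join(right_ctx)
    left = LocusSpec(
        name=f"{name}_L",
        context=left_context,
        protospacer=reverse_complement(left_context[cut_l - 3 : cut_l + 17]),
        orientation="minus",
        retained_side="left",
    )
    right = LocusSpec(
        name=f"{name}_R",
        context=right_context,
        protospacer=right_context[cut_r - 17 : cut_r + 3],
        orientation="plus",
        retained_side="right",
    )
    sequence = left_context[cut_l - flank : cut_l] + right_context[cut_r : cut_r + flank]
    return JunctionReference(
        left=left,
        right=right,
        sequence=sequence,
        junction=flank,
        flank_left=flank,
        flank_right=flank,
        repeats=tuple((rep, flank + lo, flank + ro) for rep, lo, ro in placements),
    )


# ---------------------------------------------------------------------------
# read generation


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _mh_of_interval(seq: str, i: int, j: int) -> int:
    return _lcp(seq[i:], seq[j:]) + _lcp(seq[:i][::-1], seq[:j][::-1])


def _random_insert(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _complex_identifiable(ref: str, read: str, scoring: ScoringScheme) -> bool:
    full = restricted_score(ref, read, scoring)
    if restricted_score(ref, read, scoring, forbid_insertions=True) >= full:
        return False
    if restricted_score(ref, read, scoring, forbid_deletions=True) >= full:
        return False
    return True


def simulate_reads(
    junction: JunctionReference,
    config: SimConfig,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> tuple[list, pd.DataFrame]:
    """Generate reads and their ground-truth table.

    Returns ``(reads, truth)`` where ``reads`` is a list of ``(read_id,
    sequence)`` pairs (write with :func:`amplijoin.io.write_fastq`) and
    ``truth`` one row per read. Fully deterministic given ``config.seed``.
    """
    seq = junction.sequence
    J = junction.junction
    rng = np.random.default_rng(config.seed)
    cat_labels = (NO_INDEL_EJ, INSERTION, DELETION, COMPLEX_INDEL)
    mix = np.asarray(config.category_mix, dtype=float)

    if config.w_mh > 0 and config.category_mix[2] > 0 and not junction.repeats:
        raise SimConfigError(
            "microhomology-annealing deletions requested (w_mh > 0) but the "
            "junction has no planted repeats"
        )
    max_blunt = max(config.blunt_size_dist)
    if max_blunt >= min(J, len(seq) - J):
        raise SimConfigError("blunt deletion sizes must be smaller than the flanks")

    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    for k in range(config.n_reads):
        cat = cat_labels[rng.choice(4, p=mix / mix.sum())]
        row = {
            "read_id": f"read{k:06d}",
            "category": cat,
            "del_start": -1,
            "del_end": -1,
            "del_size": 0,
            "mh_length": -1,
            "insertion_seq": "",
            "insertion_source": "",
            "overhang_left": 0,
            "overhang_right": 0,
            "is_fillin": False,
            "is_staggered": False,
            "errors": "",
        }
        if cat == NO_INDEL_EJ:
            base = seq
        elif cat == INSERTION:
            fillin = rng.random() < config.p_fillin
            source = _draw(rng, config.fillin_source_mix)
            if source == "both":
                a = _draw(rng, config.overhang_dist)
                b = _draw(rng, config.overhang_dist)
                pred = junction.fillin_left(a, config.max_overhang) + junction.fillin_right(
                    b, config.max_overhang
                )
            else:
                a = _draw(rng, config.overhang_dist)
                b = 0
                pred = (
                    junction.fillin_left(a, config.max_overhang)
                    if source == "left"
                    else junction.fillin_right(a, config.max_overhang)
                )
            if fillin:
                ins = pred
                row.update(
                    insertion_source=source,
                    overhang_left=a if source in ("left", "both") else 0,
                    overhang_right=(b if source == "both" else (a if source == "right" else 0)),
                    is_fillin=True,
                )
            else:
                ins = _random_insert(rng, len(pred))
                row["insertion_source"] = "random"
            row["insertion_seq"] = ins
            base = seq[:J] + ins + seq[J:]
        elif cat == DELETION:
            if rng.random() < config.p_staggered_deletion:
                face = "left" if rng.random() < 0.5 else "right"
                n = _draw(rng, config.overhang_dist)
                s = _draw(rng, config.blunt_size_dist)
                t = s + n
                if face == "left":
                    fill = junction.fillin_left(n, config.max_overhang)
                    base = seq[:J] + fill + seq[J + t :]
                else:
                    fill = junction.fillin_right(n, config.max_overhang)
                    base = seq[: J - t] + fill + seq[J:]
                row.update(
                    del_start=(J if face == "left" else J - t),
                    del_end=(J + t if face == "left" else J),
                    del_size=s,
                    insertion_seq=fill,
                    insertion_source=face,
                    overhang_left=n if face == "left" else 0,
                    overhang_right=n if face == "right" else 0,
                    is_fillin=True,
                    is_staggered=True,
                )
                adjusted = seq[:J] + fill + seq[J:]
                iv = (J + n, J + n + t) if face == "left" else (J - t, J)
                row["mh_length"] = min(_mh_of_interval(adjusted, *iv), s)
            elif rng.random() < config.w_mh:
                rep, l0, r0 = junction.repeats[rng.integers(len(junction.repeats))]
                base = seq[:l0] + seq[r0:]
                row.update(
                    del_start=l0, del_end=r0, del_size=r0 - l0, mh_length=len(rep)
                )
            else:
                s = _draw(rng, config.blunt_size_dist)
                a = int(rng.integers(0, s + 1))
                i, j = J - a, J + (s - a)
                base = seq[:i] + seq[j:]
                row.update(
                    del_start=i, del_end=j, del_size=s, mh_length=_mh_of_interval(seq, i, j)
                )
        else:  # ComplexIndel
            lo, hi = config.complex_insert_range
            for _attempt in range(200):
                s = _draw(rng, config.blunt_size_dist)
                a = int(rng.integers(0, s + 1))
                i, j = J - a, J + (s - a)
                m = int(rng.integers(lo, hi + 1))
                ins = _random_insert(rng, m)
                base = seq[:i] + ins + seq[j:]
                if _complex_identifiable(seq, base, scoring):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise SimConfigError("could not draw an identifiable ComplexIndel read")
            row.update(
                del_start=i,
                del_end=j,
                del_size=s,
                insertion_seq=ins,
                insertion_source="random",
                mh_length=-1,
            )

        # substitution errors, i.i.d. per base
        eps = config.substitution_error_rate
        if eps > 0:
            hits = np.flatnonzero(rng.random(len(base)) < eps)
            if hits.size:
                chars = list(base)
                recs = []
                for p in hits:
                    alt = [c for c in "ACGT" if c != chars[p]]
                    chars[p] = alt[rng.integers(3)]
                    recs.append(f"{p}:{chars[p]}")
                base = "".join(chars)
                row["errors"] = ";".join(recs)
        rows.append(row)
        reads.append((row["read_id"], base))

    truth = pd.DataFrame(rows)
    return reads, truth


def reconstruct_read(junction: JunctionReference, row) -> str:
    """Rebuild a read from its truth-table row (reversing the error process)."""
    seq = junction.sequence
    J = junction.junction
    cat = row["category"]
    if cat == NO_INDEL_EJ:
        base = seq
    elif cat == INSERTION:
        base = seq[:J] + row["insertion_seq"] + seq[J:]
    elif cat == DELETION:
        i, j = int(row["del_start"]), int(row["del_end"])
        if row.get("is_staggered", False):
            fill = row["insertion_seq"]
            if row["insertion_source"] == "left":
                base = seq[:J] + fill + seq[j:]
            else:
                base = seq[:i] + fill + seq[J:]
        else:
            base = seq[:i] + seq[j:]
    elif cat == COMPLEX_INDEL:
        i, j = int(row["del_start"]), int(row["del_end"])
        base = seq[:i] + row["insertion_seq"] + seq[j:]
    else:
        raise ValueError(f"unknown truth category {cat!r}")
    if row.get("errors", ""):
        chars = list(base)
        for item in str(row["errors"]).split(";"):
            p, c = item.split(":")
            chars[int(p)] = c
        base = "".join(chars)
    return base
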