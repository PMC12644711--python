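"""Cas9 target loci, blunt-cut coordinates, staggered-cut fill-in, and junction references.

A :class:`LocusSpec` describes one SpCas9 target site inside a stretch of
genomic context: the 20-nt protospacer, the strand it sits on, and which side
of the blunt cut persists in the deletion-rearrangement product. SpCas9 with an
NGG PAM cleaves bluntly between protospacer positions 17 and 18 (1-based on the
protospacer strand), i.e. 3 nt 5' of the PAM. Cleavage can also be staggered:
the protospacer (non-target) strand is nicked further from the PAM, leaving a
short 5' overhang whose fill-in before blunt ligation duplicates the overhang
bases at the repair junction. Only the PAM-proximal fragment carries the
duplicated bases after fill-in, which is why the PAM orientation of a two-DSB
rearrangement determines whether such insertions are observable.

Two loci combine into a :class:`JunctionReference`: the predicted product of
joining the two blunt DSB ends without insertions or deletions ("No Indel EJ"),
against which amplicon reads are aligned and classified.

Coordinates are 0-based, half-open throughout; the cut is the boundary between
``cut_index - 1`` and ``cut_index`` on the context's forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import reverse_complement

__all__ = [
    "LocusSpec",
    "JunctionReference",
    "LocusDefinitionError",
    "ParameterError",
    "compute_blunt_cut",
    "predicted_fillin",
    "build_junction_reference",
]

PROTOSPACER_LEN = 20
#: blunt cut falls between protospacer positions 17|18 (1-based, protospacer strand)
CUT_OFFSET = 17
DEFAULT_MAX_OVERHANG = 4

_DNA = frozenset("ACGT")


class LocusDefinitionError(ValueError):
    """The locus violates a definition rule (protospacer placement or PAM)."""


class ParameterError(ValueError):
    """A numeric parameter is outside its allowed range."""


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def compute_blunt_cut(context: str, protospacer: str, orientation: str) -> int:
    """Return the 0-based forward-strand coordinate of the SpCas9 blunt cut.

    The cut sits between ``context[cut - 1]`` and ``context[cut]``, 3 nt 5' of
    the NGG PAM on the protospacer strand. Raises
    :class:`LocusDefinitionError` if the protospacer is absent or not unique on
    the stated strand, or if the adjacent trinucleotide is not NGG.
    """
    if orientation not in ("plus", "minus"):
        raise LocusDefinitionError(f"orientation must be 'plus' or 'minus', got {orientation!r}")
    if len(protospacer) != PROTOSPACER_LEN:
        raise LocusDefinitionError(
            f"protospacer must be {PROTOSPACER_LEN} nt, got {len(protospacer)}"
        )
    for label, seq in (("context", context), ("protospacer", protospacer)):
        if not set(seq) <= _DNA:
            raise LocusDefinitionError(f"{label} contains non-ACGT symbols")

    query = protospacer if orientation == "plus" else reverse_complement(protospacer)
    hits = _count_occurrences(context, query)
    if hits == 0:
        raise LocusDefinitionError("protospacer not found in context on the stated strand")
    if hits > 1:
        raise LocusDefinitionError(f"protospacer occurs {hits} times in context; must be unique")
    start = context.find(query)

    if orientation == "plus":
        pam = context[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + 3]
        if len(pam) < 3 or pam[1] != "G" or pam[2] != "G":
            raise LocusDefinitionError(f"PAM {pam!r} does not match NGG")
        cut = start + CUT_OFFSET
    else:
        # protospacer on the minus strand: PAM appears as CCN immediately 5'
        # of the reverse-complement occurrence on the forward strand
        pam = context[start - 3 : start]
        if len(pam) < 3 or pam[0] != "C" or pam[1] != "C":
            raise LocusDefinitionError(f"PAM {pam!r} (forward strand) does not match CCN")
        cut = start + (PROTOSPACER_LEN - CUT_OFFSET)
    if not 0 < cut < len(context):
        raise LocusDefinitionError("cut coordinate falls on the context boundary")
    return cut


@dataclass(frozen=True)
class LocusSpec:
    """One Cas9 target site.

    ``retained_side`` says which side of the cut (in forward-strand context
    coordinates) persists in the deletion-rearrangement product. ``cut_index``
    is derived at construction and validated against the protospacer/PAM rules.
    """

    name: str
    context: str
    protospacer: str
    orientation: str  # 'plus' | 'minus': strand of the protospacer within context
    retained_side: str  # 'left' | 'right' of cut_index in context coordinates
    cut_index: int = field(init=False)

    def __post_init__(self) -> None:
        if self.retained_side not in ("left", "right"):
            raise LocusDefinitionError(
                f"retained_side must be 'left' or 'right', got {self.retained_side!r}"
            )
        cut = compute_blunt_cut(self.context, self.protospacer, self.orientation)
        object.__setattr__(self, "cut_index", cut)

    def with_context(self, context: str) -> "LocusSpec":
        return replace(self, context=context)


def predicted_fillin(locus: LocusSpec, n: int, max_overhang: int = DEFAULT_MAX_OVERHANG) -> str:
    """Sequence duplicated at the junction by an n-nt 5'-overhang fill-in.

    Returns the n protospacer-strand bases immediately 5' of the blunt cut
    (protospacer positions ``18 - n .. 17``, 1-based), expressed on the
    *forward strand of the context*: for a plus-orientation locus this is
    ``context[cut - n : cut]``; for minus orientation it is
    ``context[cut : cut + n]`` (the reverse complement of the protospacer-strand
    bases). :meth:`JunctionReference.fillin_left` / ``fillin_right`` re-orient
    these onto the junction strand when a retained flank is flipped.
    """
    if not isinstance(n, int) or isinstance(n, bool):
        raise ParameterError(f"overhang size must be an integer, got {n!r}")
    if n < 1 or n > max_overhang:
        raise ParameterError(f"overhang size {n} outside 1..{max_overhang}")
    cut = locus.cut_index
    if locus.orientation == "plus":
        if cut - n < 0:
            raise ParameterError("context too short 5' of the cut for the requested overhang")
        return locus.context[cut - n : cut]
    if cut + n > len(locus.context):
        raise ParameterError("context too short 5' of the cut for the requested overhang")
    return locus.context[cut : cut + n]


@dataclass(frozen=True)
class JunctionReference:
    """Predicted No Indel EJ product of two DSBs.

    ``sequence[:junction]`` is the retained flank of the left locus (ending at
    its cut) and ``sequence[junction:]`` the retained flank of the right locus
    (starting at its cut), both expressed on the junction (amplicon) strand.
    ``left_flipped`` / ``right_flipped`` record whether a retained flank was
    reverse-complemented out of its context's forward strand when mapped onto
    the junction strand. ``repeats`` carries planted-repeat metadata
    ``(repeat_seq, left_start, right_start)`` in junction coordinates when the
    reference was built synthetically (see :mod:`amplijoin.simulate`).
    """

    left: LocusSpec
    right: LocusSpec
    sequence: str
    junction: int
    flank_left: int
    flank_right: int
    left_flipped: bool = False
    right_flipped: bool = False
    repeats: tuple = ()

    def __post_init__(self) -> None:
        if not (1 <= self.junction < len(self.sequence)):
            raise ValueError("junction coordinate must lie strictly inside the sequence")

    def fillin_left(self, n: int, max_overhang: int = DEFAULT_MAX_OVERHANG) -> str:
        """Fill-in insertion predicted from the left DSB, on the junction strand."""
        f = predicted_fillin(self.left, n, max_overhang)
        return reverse_complement(f) if self.left_flipped else f

    def fillin_right(self, n: int, max_overhang: int = DEFAULT_MAX_OVERHANG) -> str:
        """Fill-in insertion predicted from the right DSB, on the junction strand."""
        f = predicted_fillin(self.right, n, max_overhang)
        return reverse_complement(f) if self.right_flipped else f

    @property
    def name(self) -> str:
        return f"{self.left.name}+{self.right.name}"


def _retained_flank(locus: LocusSpec, flank: int, slot: str) -> tuple[str, bool]:
    """Retained flank on the junction strand and whether it was flipped.

    The left slot's flank must end at the cut; the right slot's must start at
    it. A retained fragment on the 'wrong' side for its slot is
    reverse-complemented onto the junction strand.
    """
    cut, ctx = locus.cut_index, locus.context
    if locus.retained_side == "left":
        if cut - flank < 0:
            raise ParameterError(
                f"locus {locus.name}: context too short; flank {flank} needs "
                f"{flank} nt left of the cut, only {cut} available"
            )
        seg = ctx[cut - flank : cut]
    else:
        if cut + flank > len(ctx):
            raise ParameterError(
                f"locus {locus.name}: context too short; flank {flank} needs "
                f"{flank} nt right of the cut, only {len(ctx) - cut} available"
            )
        seg = ctx[cut : cut + flank]
    if slot == locus.retained_side:
        return seg, False
    return reverse_complement(seg), True


def build_junction_reference(
    left: LocusSpec,
    right: LocusSpec,
    flank: int,
    flank_right: int | None = None,
) -> JunctionReference:
    """Concatenate the two retained flanks into the predicted No Indel EJ product.

    ``flank`` is the number of retained nucleotides taken from the left locus
    (which becomes the junction coordinate J); ``flank_right`` defaults to the
    same value.
    """
    if flank < 1:
        raise ParameterError("flank must be >= 1")
    fr = flank if flank_right is None else flank_right
    if fr < 1:
        raise ParameterError("flank_right must be >= 1")
    left_seg, left_flipped = _retained_flank(left, flank, "left")
    right_seg, right_flipped = _retained_flank(right, fr, "right")
    return JunctionReference(
        left=left,
        right=right,
        sequence=left_seg + right_seg,
        junction=len(left_seg),
        flank_left=flank,
        flank_right=fr,
        left_flipped=left_flipped,
        right_flipped=right_flipped,
    )
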