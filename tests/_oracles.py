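"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities from first principles — quadratic
dynamic programming, exhaustive placement enumeration, and an explicit
two-strand model of staggered cleavage — so they share no code path with the
package implementation they check.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_score(ref: str, read: str, match=2.0, mismatch=-4.0, gap_open=6.0, gap_extend=1.0):
    """Optimal global affine-gap score; a length-L gap costs gap_open + gap_extend*L."""
    n, m = len(ref), len(read)
    open_cost = -(gap_open + gap_extend)
    ext = -gap_extend
    # M: ends in substitution; X: ends in gap-in-read (deletion); Y: gap-in-ref (insertion)
    M = [NEG] * (m + 1)
    X = [NEG] * (m + 1)
    Y = [NEG] * (m + 1)
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = open_cost + ext * (j - 1)
    for i in range(1, n + 1):
        prevM, prevX, prevY = M, X, Y
        M = [NEG] * (m + 1)
        X = [NEG] * (m + 1)
        Y = [NEG] * (m + 1)
        X[0] = open_cost + ext * (i - 1)
        ri = ref[i - 1]
        for j in range(1, m + 1):
            sub = match if (ri == read[j - 1] and ri != "N") else mismatch
            best_prev = max(prevM[j - 1], prevX[j - 1], prevY[j - 1])
            M[j] = best_prev + sub if best_prev > NEG else NEG
            X[j] = max(
                (prevM[j] + open_cost) if prevM[j] > NEG else NEG,
                (prevX[j] + ext) if prevX[j] > NEG else NEG,
                (prevY[j] + open_cost) if prevY[j] > NEG else NEG,
            )
            Y[j] = max(
                (M[j - 1] + open_cost) if M[j - 1] > NEG else NEG,
                (Y[j - 1] + ext) if Y[j - 1] > NEG else NEG,
                (X[j - 1] + open_cost) if X[j - 1] > NEG else NEG,
            )
    return max(M[m], X[m], Y[m])


def mh_by_enumeration(seq: str, i: int, j: int) -> int:
    """Microhomology = (#equal-size placements giving the identical product) - 1."""
    d = j - i
    product = seq[:i] + seq[j:]
    count = 0
    for p in range(0, len(seq) - d + 1):
        if seq[:p] + seq[p + d :] == product:
            count += 1
    return count - 1


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def fillin_two_strand(context: str, cut: int, orientation: str, n: int) -> str:
    """Fill-in duplication from an explicit two-strand staggered-cut model.

    Builds both strands, nicks the protospacer strand n nt further from the
    PAM than the blunt position, fills the recessed 3' ends, and reads the
    bases the PAM-proximal fragment gains relative to the blunt product. The
    result is expressed on the forward strand of the context.
    """
    if orientation == "minus":
        # mirror through reverse complement, solve on the plus strand, map back
        res = fillin_two_strand(_revcomp(context), len(context) - cut, "plus", n)
        return _revcomp(res)
    # plus orientation: protospacer on top strand, PAM to the right of the cut.
    # Blunt cut boundary `cut` on both strands; staggered top-strand nick at
    # cut - n leaves a 5' overhang on the bottom strand of the left fragment
    # and on the top strand of the right (PAM-proximal) fragment.
    top = context
    right_top = top[cut - n :]  # 5' overhang: first n bases single-stranded
    right_bottom = _revcomp(top[cut:])  # recessed 3' end (at its right/3' side)
    # fill in: extend the bottom strand's 3' end across the overhang template
    right_bottom_filled = right_bottom + _revcomp(top[cut - n : cut])
    assert _revcomp(right_bottom_filled) == right_top  # now blunt
    blunt_right_top = top[cut:]
    gained = right_top[: len(right_top) - len(blunt_right_top)]
    return gained


def mirror_cut_index(context: str, cut_plus: int) -> int:
    """Map a forward-strand cut boundary through reverse complement."""
    return len(context) - cut_plus
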