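# Methods

## The measurement being modeled

Two Cas9/sgRNA ribonucleoproteins cut on either side of a genomic segment;
end joining of the two distal blunt ends produces a deletion rearrangement.
PCR primers anneal at fixed positions flanking the two cuts, so every
amplicon begins and ends with the same sequence and spans the new junction.
Reads are aligned to the *predicted No Indel EJ product* — the retained flank
of the left locus (ending at its blunt cut) concatenated with the retained
flank of the right locus (starting at its cut) — and categorized purely by
the indel content of the alignment: No Indel EJ (substitutions allowed),
Insertion, Deletion, or Complex Indel (both). Because amplicon ends are
primer-fixed, duplicate reads are informative and no deduplication is
applied.

## Locus model and coordinates

Coordinates are 0-based and half-open; a cut is the boundary between
`cut_index − 1` and `cut_index` on the context's forward strand. SpCas9 is
assumed: the protospacer must occur exactly once on its stated strand, the
PAM must match NGG (inputs violating either are rejected, not warned), and
the blunt cut falls between protospacer positions 17|18, 3 nt 5′ of the PAM.

**Staggered cleavage and fill-in.** The protospacer (non-target) strand may
be nicked 1–4 nt further from the PAM than the blunt position, leaving a 5′
overhang. Working through the two-strand geometry (the test suite carries an
explicit fragment/fill-in oracle): after polymerase fill-in, only the
**PAM-proximal** fragment gains bases — the n duplicated nucleotides are
protospacer positions 18−n…17. Hence insertions at a two-DSB junction are
observable when each locus retains its PAM-proximal side, the geometry used
for the synthetic junction here (PAM CC at junction offsets −6/−5, GG at
+4/+5). `max_overhang` defaults to 4; insertion sizes are binned 1, 2, 3, 4,
≥5.

`predicted_fillin` returns the duplicated bases on the context's forward
strand (`context[cut−n:cut]` for plus orientation, `context[cut:cut+n]` for
minus); `JunctionReference.fillin_left/right` re-orient them onto the
junction strand, applying a reverse complement exactly when the retained
flank itself was flipped. Flank lengths are configurable because real primer
windows vary by assay.

## Alignment and classification

Alignment is global with affine gaps: match +2, mismatch −4, a gap of length
L costs 6 + L ("open −6, extend −1"), N matches nothing. These BWA-like
defaults are conventions, not contracts — the category semantics are the
contract, and alignment scores are validated against an independent
quadratic Gotoh DP oracle. The engine is Biopython's `PairwiseAligner`;
indels are then left-shifted through equal bases to the leftmost
score-equivalent placement so microhomology arithmetic downstream is
placement-independent. When an equal-length all-substitution interpretation
ties the gapped optimum, the substitution reading wins (fewest gap
openings). Reads below 70% alignment identity are left Unclassified; the
floor is explicit because real pipelines must do *something* with unalignable
reads, and it is far below anything the simulator produces (the largest
default deletion keeps identity ≥ 0.71).

## Microhomology

MH of deletion `[i, j)` on `S` is the total flanking identity
`lcp(S[i:], S[j:]) + lcs(S[:i], S[:j])`, i.e. the number of equal-size
placements yielding the identical product minus one — the standard
junction-ambiguity definition, chosen because it is placement-independent
(whether one-sided or total identity was meant in the original assays is not
derivable; the total-identity convention is recorded in outputs). For
discontinuous deletions, size sums all segments and MH is computed for the
segment nearest the junction, flagged. Usage is reported over classes
0/1/2/3/4+.

**Staggered breakpoint assignment.** A deletion preceded by fill-in appears
either as deletion + adjacent insertion (Complex Indel upstream) or as a
deletion with junction-adjacent base changes, depending on which alignment
scores better. Both are handled read-level: candidate products
`S[:J] + fillin(n) + S[J+t:]` (left face; right face mirrored) are compared
to the read by exact string equality — placement-independent by
construction — trying n = 1…4 with smallest-n (smallest breakpoint shift)
precedence, left before right on ties, ambiguity flagged. On a match the
record reports size `d = t − n` (net of the duplicated bases) and MH in the
fill-in-adjusted frame, clamped at d. Reinterpretation is attempted only for
calls carrying an insertion or ≥1 base change, so plain deletions are never
perturbed. Complex Indel reads whose insertion is *not* explained by fill-in
stay out of deletion profiles. Because fill-in predictions are nested
(the (n−1)-mer is contained in the n-mer), distinct (face, n) hypotheses can
reconstruct the same read; the precedence rule makes the choice
deterministic, and the net size is invariant across hypotheses even when the
MH frame is not.

## Insertion scoring

An insertion of length L is fill-in consistent iff it equals the left
prediction, the right prediction, or `fillin_left(a) + fillin_right(b)` with
`a + b = L`, `1 ≤ a, b ≤ max_overhang`; all matching explanations are
recorded (precedence left, right, both) since e.g. any 1-nt insert matching
both loci is inherently ambiguous. Scoring uses exact product reconstruction
(`read == S[:J] + pred + S[J:]`) when the read is available, replacing a
fixed position-tolerance window: string equality is invariant to where the
aligner placed a slid insertion, and inserts genuinely away from the junction
can never reconstruct the read. For random L-mers the expected
false-consistency rate is at most `(2 + (L−1))·4^−L` (distinct predictions
may coincide, lowering it), verified by simulation.

## Filters and statistics

Variant sequences representing ≥ 0.1% of their pool — deletion reads, or
insertion + complex-indel reads — are retained for individual review; the
boundary is inclusive (10 of 10,000 stays, 9 goes) and removed mass is
reported. Category frequencies are computed over classified reads and summed
counts are conserved across filter stages.

Replicate comparisons use the unpaired two-sample t-test — Student
pooled-variance by default, Welch by flag, the choice recorded in every
output row since legend conventions rarely state it — with Holm–Šidák
step-down adjustment `p̃_(i) = 1 − (1 − p_(i))^(m−i+1)` within one explicit
family (one figure-panel-style set of comparisons). Under independent exact
nulls the procedure's family-wise error at m = 5 equals α = 0.05 exactly, so
the Monte-Carlo check asserts the empirical rate against α plus the 3σ
binomial margin of the estimator. Fold effects are reported as
max(a,b)/min(a,b) with a direction. Frequencies are compared on the raw
proportion scale (mean ± SD of replicate frequencies), with no transform.

## qPCR and reporter normalizations

ΔCt = mean(Ct_del) − mean(Ct_ctrl) within a sample; ΔΔCt references a
parental sample from the same run; fold = 2^−ΔΔCt. This orientation makes
more rearrangement template (earlier Ct_del) give a larger fold — parental
vs itself is exactly 1, one cycle doubles the fold, and a constant shift of
every Ct in a run cancels. The plausible opposite sign reading of
"subtracted from" phrasing in assay write-ups is rejected *because* it would
invert the direction of reported enrichments; no amplification-efficiency
correction is applied. Flow-reporter frequencies are `pct_positive /
pct_transfection` from parallel GFP transfections. Clonogenic survival
divides each well's plating efficiency (colonies/seeded) by the mean control
plating efficiency of the same cell line, making different seeding densities
comparable and the control mean exactly 1; normalizing per-well counts
without the density step would silently require equal seeding.

## Simulator

The generator's defaults define the study conditions used throughout the
tests: category mixture (0.40, 0.20, 0.35, 0.05) over (No Indel EJ,
Insertion, Deletion, Complex Indel); overhang sizes {1: 0.55, 2: 0.20,
3: 0.15, 4: 0.10} (1-nt overhangs dominate real insertion spectra); fill-in
source left/right/both = 0.45/0.45/0.10; 90% of insertions fill-in vs 10%
random; deletion mixture 60% microhomology-annealing over planted repeat
pairs of lengths 2/3/4 nt vs 40% blunt-processing with a truncated-geometric
total size (1–15 nt) split uniformly across the two faces; substitution
error 0.1% per base (typical high-quality short-read scale); no sequencing
indel errors by default so truth categories stay well defined. All draws
come from one seeded generator in a documented per-read order (category →
category-specific draws → errors), making FASTQ and truth tables
byte-stable. Qualities are constant Q37; the classifier is
quality-agnostic.

Planted repeat pairs are stamped into freshly drawn random flanks; the bases
immediately outside each pair are adjusted so a spanning deletion's MH is
exactly the repeat length, and placements conflicting with the fixed PAM
bases are rejected. Complex-indel inserts (4–8 nt) are rejection-sampled
until the optimal alignment score strictly exceeds the best insertion-free
and deletion-free restricted scores: short inserts adjacent to a deletion
can otherwise be absorbed as substitutions, making the true category
ill-defined rather than merely hard. The check uses score-only restricted
alignments, not the classifier's traceback.

What the simulator does **not** emulate: PCR chimeras and amplification
bias, paired-end structure and merging, quality-score error profiles,
sequencing indel errors (available but off by default), templated
insertions from distal sequence, and multi-cut re-cutting cycles. Passing
tests therefore demonstrate correctness of the classification and profiling
arithmetic under the stated generative assumptions, not robustness to every
artifact of real libraries.

## Problem sizes and numerical choices

Validation uses 10,000-read libraries for category recovery (error-free and
at 0.5% substitution rate), 500 random instances against the alignment DP
oracle, 1,000 against the microhomology enumeration oracle, 5,000 deletion
reads for planted-MH recovery, and 10,000 Monte-Carlo families for the FWER
check — sizes at which binomial 3σ bands are tight relative to the effects
asserted. Probability vectors must sum to 1 within 1e−9; the filter boundary
uses an 1e−12 tolerance against float division; identity ties in alignment
are broken toward substitutions; deletion sizes appear as negative integers
in output tables while internal arithmetic uses positive sizes.

## Known limitations

* Category equivalence with any specific vendor pipeline is defined at the
  category-semantics level, not bit-for-bit alignment output.
* Reads with sequencing errors inside a fill-in insertion are scored
  inconsistent (exact-match definition); at the default error rate this
  loses < 1% sensitivity.
* Staggered-cut reinterpretation requires an error-free read (exact product
  equality); noisy staggered reads fall back to their plain representation.
* The MH frame of a staggered deletion is reported under the smallest-shift
  hypothesis, which can differ from the generating overhang when predictions
  coincide; the net size does not.
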