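# Methods

## The classification model

A *degenerate motif* is an ordered list of allowed-residue sets over the
20-letter amino-acid alphabet, written `T[H/N]W[L/M]SP`: bare letters are
singletons, bracketed groups list alternatives. A *signature pair* couples
the TDC and TYDC variants of one conserved region; its *diagnostic
positions* are the offsets where the two variants' allowed sets are
disjoint, recomputed from the patterns whenever they are needed (the
packaged fixture stores the printed offsets only as hints, and a test
asserts that hints and recomputation agree). For the four packaged pairs
the diagnostic offsets are {4}, {3,4,5,7,9}, ∅ and {1,2}; the third pair's
variants intersect at every offset, which shapes the decision rule below.

Scanning is ungapped: every window of the query is compared to the motif,
with `X` (and the gap character) never satisfying an allowed set. Offsets
declared diagnostic must match exactly; the remaining offsets may mismatch
at up to `max_mismatch` positions (default 1). Matches are ordered by
(mismatch count, start).

Classification is by voting. For each pair both variants are scanned and
the class with the strictly better best match takes the pair's vote; equal
best matches or no match give none. A label is called when the winner has
at least `min_votes = 3` of 4 and leads by `margin = 1`; zero votes on both
sides is UNCLASSIFIED, everything else AMBIGUOUS. Three-of-four (rather
than all four) is deliberate: the third pair has no disjoint column, so its
vote can legitimately tie on a true family member, while the strongly
diagnostic SP/NA pair plus two others remain decisive. The thresholds are
exposed in `ClassificationConfig`; the defaults are this package's own
calibration of a qualitative rule.

## Motif discovery

Discovery formalises reading a two-class alignment by eye. Per column and
class, the summary is the smallest residue set covering at least `1 − ε`
of the class's non-gap residues, built greedily in descending frequency
order (ties alphabetical); `X` never enters a set but stays in the
denominator. A column is *conserved* in a class when that set has at most
`k_max = 3` residues and the gap fraction is at most `0.1`; *diagnostic*
when conserved in both classes with disjoint sets. Maximal runs of doubly
conserved columns (bridging at most `merge_gap = 1` non-conserved columns,
provided those columns still have renderable residues in both classes)
containing at least one diagnostic column and spanning at least
`min_length = 4` columns are reported as motif pairs, rendered in the same
bracket dialect the scanner parses — discovered signatures feed directly
back into classification.

Covering-set size was chosen over entropy as the conservation statistic
because the covering set *is* the degenerate pattern being reported; no
translation step sits between the test and its output.

`ε` defaults to 0: every class member must be covered, the strict reading
of "conserved in all members". On noisy inputs a single mutated residue
then breaks a column, so the documented noisy-input setting is `ε = 0.1`
(tolerate one outlier in ten, the same proportion as the gap tolerance).
At 5% per-site noise and study-scale families this raises planted-column
recall from ≈ 0.87 to ≈ 0.99 (mean over 20 seeds) at unchanged precision 1.0.

## Alignment

Pairwise global alignment is Gotoh's affine-gap dynamic programme
(gap of length k costs `open + (k−1)·extend`; defaults BLOSUM62, 10/1).
The three DP layers are filled row-wise with numpy; the within-row
recurrence of the horizontal-gap layer is linearised by adding `j·extend`
and taking a running maximum. Traceback re-maximises the recurrence at
each cell with a fixed preference (substitution, then gap in the first
sequence, then gap in the second), which keeps alignments deterministic
and avoids bit-exact float comparisons. The multiple aligner is
progressive: UPGMA guide tree on `1 − fractional identity` from all
pairwise alignments (ties merge the smallest index pair), then
profile–profile merges where a column pair scores the expectation of the
substitution score under the two columns' residue frequencies (gaps carry
zero mass). There is no iterative refinement; the target is conserved-column
fidelity on desk-scale families, not agreement with any external aligner.

## Distances, trees, bootstrap

The p-distance counts differing residues over columns where both rows are
non-gap; the Dayhoff-style correction `d = −ln(1 − p − 0.2 p²)` is defined
for `p < 0.8541`, beyond which the error message advises the uncorrected
model. Neighbor-joining is the standard agglomeration with the Q-criterion
(ties broken by smallest index pair), final three-way join by the
three-point formulas, and negative branch lengths clamped to zero (the
clamp is logged at debug level). NJ on corrected distances deliberately
stands in for full maximum-likelihood inference: the claims tested here —
two clusters, one per enzyme class — are topological, and NJ is exact on
additive matrices (a property the suite verifies against brute-force path
sums and scikit-bio's independent implementation).

Bootstrap resamples alignment columns with replacement, one `numpy`
generator seeded once per run; a replicate whose distances are incomputable
(for example a resampled pair sharing no non-gap column) is redrawn, up to
ten times the replicate count. Supports are percentages of replicates
containing the same leaf bipartition, attached to internal edges and
serialized as internal node labels in Newick; branch lengths are written to
six decimals (the round-trip tolerance).

## MRM arithmetic

Masses use monoisotopic constants (H 1.0078250319, D 2.0141017780, C 12,
N 14.0030740052, O 15.9949146221); a singly charged cation's m/z is the
atom-mass sum minus one electron (equivalently, protonation adds
1.00727646). The methylation series adds CH2 per methyl; the mono- and
di-methyl species ionize as [M+H]+ while the permanently charged
N,N,N-trimethyl quaternary ion is detected as the intact cation C13H19N2+
— compositionally M + 3 CH2 + H, which is the only model reproducing its
reported precursors. d5 labeling replaces the five indole-ring hydrogens
(shift 5 × 1.006277 ≈ 5.0314 Da). Products arise by neutral loss of the
amine (ammonia, methylamine, dimethylamine, trimethylamine by methyl
count), so every unlabeled member fragments to protonated vinylindole
(C10H10N+, m/z 144) and every labeled member to the d5 analogue (149);
protonated trimethylamine itself is the m/z 60 diagnostic ion.

Reported values are **truncated, not rounded**: precursors floored to one
decimal, products to the integer. This is required for internal
consistency — the exact trimethyl precursors 203.154 and 208.186 are
reported as 203.1 and 208.1, which rounding would miss. One reported
transition name (189.1→144 attributed to the *tri*methyl species) only
fits the dimethyl composition arithmetically; the table treats it as the
doubly methylated analyte and this note records the discrepancy rather
than silently renaming anything.

## Synthetic families

`generate_family` draws one uniform random backbone (default 500 residues,
the length of the reference TDC), writes each class's motif variants at
fixed anchors (TDC 92/103/167/318, TYDC 137/148/217/369 — the printed
per-protein positions), sampling every degenerate position per record
uniformly from its allowed set, and mutates non-motif sites independently
with probability `mu` (default 0.05, uniform over the other 19 residues).
Defaults mirror the study scale: 14 TDC + 28 TYDC sequences. Noise is
never applied inside motif windows — the class signal is exact by
construction, and within-class motif variability is exactly the
allowed-set variability the per-record sampling already provides (an
additional "within-allowed-set noise" switch would be statistically
indistinguishable and is therefore not offered). Ground truth records each
record's class and anchors plus the planted diagnostic columns: positions
where the two class ancestors' allowed sets (motif set, or backbone
singleton) are disjoint.

Because the printed anchors differ between classes, the two classes' motif
windows occupy different columns; planted diagnostic columns are therefore
motif-versus-backbone contrasts. For span-recovery experiments the layout
can place both classes' motifs at the same anchors — the biologically
faithful picture, since the paired motifs describe the same aligned region
and differ in printed position only through per-protein numbering.

`generate_citrus_like_pair` emulates the clementine/sweet-orange putative
TDC pair: two noise-free TDC-planted 500-mers made identical and then
substituted at position 463, giving 99.80% identity (499/500).

What passing these benchmarks does **not** show: real decarboxylases
diverge by indels and tree-structured evolution, not i.i.d. substitutions
on a shared backbone; alignment difficulty, gap handling in signatures,
and rate variation across sites are all absent from the generator. The
synthetic results validate the machinery (exact recovery, vote logic,
bootstrap behaviour), not field performance on database sequences.

## Problem sizes and degenerate inputs

The shipped tests and the acceptance script run at desk scale: families of
4–50 sequences of 120–500 residues, 20–100 bootstrap replicates, 20–50
simulation seeds — the whole suite completes in seconds. Degenerate inputs
are defined rather than left to chance: an empty FASTA file is an empty
set; a sequence shorter than a motif scans to no matches (not an error);
percent identity over two all-gap strings is an error; dual-gap columns
are excluded from the identity denominator; `X` never matches anything,
including itself.
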