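# Methods

## The inference problem

A protein-coding gene lost from mammalian genomes ("gene with lost coding
potential", GLCP) may leave behind a transcribed locus that survives today
as a lncRNA or an unprocessed pseudogene. After >100 My, sequence homology
is usually undetectable, so the primary evidence is positional: the
candidate transcript occupies the syntenic position of the lost gene,
defined by conserved protein-coding neighbors and corroborated by
whole-genome alignment chains. Because chance placement produces many
spurious syntenic pairs, every count is referred to randomization nulls and
reported with an empirical FDR.

## GLCP calling

The species roster comprises eight core mammals (human, rhesus, marmoset,
mouse, rabbit, dog, sheep, ferret), four core fish, and six reference
species at intermediate distances (opossum, chicken, anole lizard, Xenopus,
coelacanth, dog). A reference-species gene is a GLCP when (i) at most
`mammal_allowance` species of the designated lost-in set carry a homolog
(default 1; for dog as reference the lost-in set is primates + glires and
the allowance is 0), and (ii) at least `min_vertebrate_support` (default 2)
additional non-mammalian vertebrates carry one, so that assembly/annotation
dropouts in single species do not masquerade as losses. The whole
presence/absence scheme is a config object because reasonable variants
exist; the defaults encode the scheme above.

## Two-phase synteny

**Neighbor contexts.** For a focal gene G_X, `Overlapping(G_X)` is the set
of conserved coding genes whose spans intersect its span;
`Upstream`/`Downstream` are the single closest non-overlapping conserved
coding genes on each strand-relative side, within a maximum edge-to-edge
distance of 500 kb in human, scaled for other species by the ratio of
genome sizes. Neighbors separated from the focal gene by an unbridged
assembly gap are discarded (guards against artificial "chrUn"-style
chromosomes where unrelated contigs abut). Equidistant ties break toward
the smaller gene start, then the lexicographically smaller id, so the
pipeline is deterministic.

**Phase 1 (anchors).** (G_Q, G_T) is potentially syntenic if some ortholog
pair (x, y) exists with x ∈ Upstream∨Overlapping(G_Q) and y ∈
Upstream∨Overlapping(G_T), or likewise for the Downstream sets, and the
relative orientation matches: `strand(G_Q)==strand(x)` iff
`strand(G_T)==strand(y)`. Strand parity is the minimal operationalization
of "same relative orientation" that survives whole-locus inversions.
Overlapping genes participate in both clauses.

**Phase 2 (disruptors).** Chains are pre-split wherever the inter-block
gap in either genome exceeds 10 kb, preserving the aligned-block multiset
exactly. Around each focal gene, chains whose footprint falls inside the
window from Upstream to Downstream plus a 100-kb flank are classified as
up / overlapping / down (any block or straddling footprint touching the
gene span counts as overlap; side labels are strand-relative to the gene).
A chain is a disruptor when its pair of labels is contradictory — up/down,
down/up, or overlap on exactly one side — after flipping the target-side
up/down label when the chain's strand parity disagrees with the gene
pair's strand parity. Flipping on the XOR of the two parities (rather than
on chain strands alone) is what makes a cleanly inverted locus
self-consistent regardless of which strand each gene is annotated on,
while a locally inverted or translocated segment still contradicts. One
disruptor rejects the pair; with no chains available, phase 2 is vacuous
and the potentially-syntenic set passes through.

**Sensitivity.** `ortholog_recovery` removes each orthologous coding pair
from the anchor-eligible set in turn and asks whether the two-phase caller
still links its members. On the standard benchmark scenario (20
chromosomes × 100 genes, 5% relocated genes, 5 chromosome-scale
inversions) recovery is ~93–94%, comfortably above the ≥69% power regime
in which the screen is considered informative.

## Randomization nulls and FDR

Three schemes perturb the inputs of the synteny count: `placement`
re-places candidate transcripts — clustered into bundles of overlapping
isoforms that move as a unit, structure preserved — uniformly on their own
chromosome, avoiding annotated genes and already-placed bundles (1000
iterations by default); `geneset` replaces the GLCPs with an equally sized
random draw of coding genes (1000); `both` does both freshly each
iteration (10,000). Empirical p uses the add-one estimator
(r+1)/(n+1) — never exactly zero from finite permutations — one-sided in
the enrichment direction; the 90% CI is the 5th–95th percentile band of
the null counts; excess = observed − null mean; FDR = null mean / observed
(capped at 1 for reporting, raw ratio retained). A bundle that cannot be
placed in 1000 attempts is skipped and counted, which biases the null
count downward only in pathologically crowded chromosomes.

Calibration: with no planted signal and the observed configuration itself
drawn from the null, the empirical p of all three schemes is super-uniform
(checked by a one-sided Kolmogorov–Smirnov test over 200 replicate
scenarios; a two-sided test would reject merely for the conservatism that
discrete tied counts necessarily produce).

## Sequence similarity

Local alignment is an affine-gap Smith–Waterman (Gotoh recurrences,
vectorized over anti-diagonals; a gap of length k costs open + (k−1)·ext).
Nucleotide defaults +1/−2 with gaps 5/2; N scores as a mismatch against
everything; plus strand only. The translated mode takes the best score
over the 3×3 forward reading-frame pairs under BLOSUM62, with stop codons
scored −10 against everything. Significance is empirical: the score is
compared with the scores of mononucleotide shuffles of the second sequence,
p = (r+1)/(n+1). The screen-level FDR follows the random-decoy design: for
each real (GLCP, candidate) pair, k = 10 random GLCPs (excluding the
pair's own) are aligned with identical parameters, and FDR(t) = (average
number of decoy pairs significant at t) / (real pairs significant at t) —
averaged per pair before summing, and NA where no real pair clears t.

Motif matching is an ungapped position-wise IUPAC comparison; the bundled
TISU consensus SAASATGGCGGC (S = G or C) matched against the JPX
start-codon context TAAGATGGCGGC yields 11 of 12 positions.

## Feature statistics

τ = Σᵢ(1 − xᵢ/x_max)/(N−1) over N ≥ 5 tissues: 0 for uniform, 1 for
single-tissue expression, scale-invariant; all-zero rows are NA. A gene is
"expressed" when max RPKM ≥ 1.0 in at least one tissue; breadth counts
tissues at or above that threshold. Breakpoint-interval enrichment reports
a hypergeometric tail on the 2×2 overlap table plus two permutation
p-values (uniform re-placement of the intervals, length preserved, and
bundle-shuffled re-placement of the gene set) with expected counts.
Cross-species expression correlation is Spearman's ρ on mean-across-tissue
RPKM by default (max and Pearson available); rank correlation was chosen
because RPKM scales are not comparable across species.

## The synthetic generator

Two genomes share an ancestral layout: per chromosome, genes with
log-normal lengths (median 20 kb, σ=0.6) separated by geometric spacings
(mean 60 kb), random strands, 2–6 exons. The mammalian copy then loses 5%
of its genes (biased toward multi-member families, emulating compensation
by paralogs); 40% of the emptied loci spawn a derived lncRNA (a subset of
the ancestral exon structure, same strand), 15% an unprocessed pseudogene
(full structure). Background lncRNAs fill intergenic space. Rearrangement
noise: a configurable fraction of coding genes relocate to random
positions, then disjoint chromosome-scale inversions (5–50% of a
chromosome, boundaries in feature-free space) flip coordinates, strands
and collinearity segments. Chains are synthesized segment-by-segment from
the resulting collinearity map with block gaps sampled both below and
above the 10-kb split threshold; breakpoint intervals are emitted straight
from the event log (two per inversion, excision + insertion scars per
relocation), so tests never re-derive ground truth from outputs.
Expression is a per-gene gamma scale times a Dirichlet tissue profile —
sparse (α=0.3) for GLCPs, broad (α=3) for other coding genes, intermediate
for derived lncRNAs whose scale is correlated with the parent's —
reproducing the observed contrasts (GLCPs more tissue-specific than family
members; derived lncRNAs broader than background lncRNAs). Derived
sequences are the parent's mutated at 30% substitution and 2% indel rate;
decoys are independent random DNA.

What the generator does not emulate: realistic nucleotide composition,
repeat-driven exonization, annotation noise (fragmented or merged gene
models), chain scoring artifacts, or expression measurement error. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the stated generative model, not the field performance of
the screen on real assemblies.

## Numerical and scale choices

All coordinates are 0-based half-open; minus-strand chain coordinates are
normalized to the forward strand at parse time. The benchmark scenario
(~2000 genes) and the calibration study (200 replicates × 200 iterations
on one-chromosome scenarios) are sized so the full suite runs in a couple
of minutes on one CPU while leaving every statistical check at its stated
replication. Seeds propagate from a single global seed through
SHA-256-derived per-stage seeds, making every table byte-reproducible.

## Known limitations

* Disruptor detection sees only pairwise chains; multi-genome evidence,
  chain nets and minimum-length thresholds for disruptors are out of scope
  (no minimum is applied).
* The GLCP caller trusts the homology table; it does not re-validate
  losses against protein sequence.
* The empirical alignment p-value is exchangeability-based and has a
  resolution floor of 1/(n_shuffles+1); it is not an E-value and the
  external tools' E-value thresholds apply only to their own outputs.
* On real data, the synteny screen's FDR is high (the randomizations exist
  precisely to quantify it); per-pair verdicts should be treated as
  candidates for sequence-level or experimental follow-up, not calls.
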