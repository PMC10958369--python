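# Methods

This note documents the models and procedures the package implements,
the defaults that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Conventions

Internal coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive spans are converted only at the I/O
boundary. Strands are called *J* (majority) and *N* (minority); every
per-gene statistic is computed in coding sense, i.e. N-strand genes are
reverse-complemented before codon work, because codon positions are
meaningless in genomic orientation. The genetic code is NCBI translation
table 5 (invertebrate mitochondrial) everywhere, overridable per call;
its non-standard assignments (TGA→Trp, ATA→Met, AGA/AGG→Ser) change both
translation and RSCU family structure (Ser has 8 codons, Leu 6, only
TAA/TAG stop), so using the standard code silently corrupts every family
containing those codons. Ambiguity codes other than N are rejected at
parse; N is skipped per site wherever bases are counted. Gene names are
normalized through an editable synonym table shipped as data
(`mitocompare/data/gene_synonyms.tsv`), because GenBank naming is
inconsistent across depositions.

## Composition and skew

AT skew (A−T)/(A+T) and GC skew (G−C)/(G+C) are reported per genome, per
strand group, and per codon position. Positional pools concatenate the
coding-sense PCGs of a strand group, trim trailing partial codons
(truncated stops completed by polyadenylation), and by default drop
complete terminal stop codons — termination signals are not subject to
the compositional pressures the statistic describes; the exclusion is a
flag (`exclude_stops`) so users can toggle it. A zero denominator yields
a flagged undefined value, never 0, since 0 is a meaningful symmetric
observation.

## RSCU

RSCU(c) = count(c) × |family| / family total; within any family with
nonzero usage the mean of the values is exactly 1, which the tests
assert as an identity. The "fraction of RSCU values above 1.0" statistic
reports its numerator and denominator explicitly: published percentages
for it depend on an unstated denominator convention (all 62 sense
codons, families with usage only, ...), and making both counts visible
keeps a mismatch diagnosable rather than hidden.

## Alignment

Genes are aligned at the protein level — global Needleman–Wunsch with
affine gaps (open 10, extend 1, a gap of length g costing
open + extend·(g−1)), BLOSUM62 — and back-translated, so nucleotide
alignments stay in frame for K2P, NG86 and supermatrix use. Multiple
alignment is progressive: pairwise protein p-distances, a neighbor-
joining guide tree, and profile–profile merges in guide-tree order,
with profile columns scored as frequency-weighted sums of pairs
(gap-versus-residue scoring 0). Stops translate to X for scoring.
Traceback preference (match > gap in the first profile > gap in the
second) and input-order tie-breaks make outputs deterministic. There is
no iterative refinement: congeneric mitochondrial PCGs are nearly
indel-free, and on indel-free input the result equals the trivial
positional alignment (asserted against simulation truth). The engine is
O(nm) with numpy row recurrences; the within-row affine state is
computed by a running-maximum unrolling, so no cell loop runs in Python.

## K2P distances

P and Q are transition and transversion proportions over pairwise-
deleted sites (columns with a gap or N in either sequence are skipped
for that pair only — the MEGA default, which the comparative literature
this package mirrors uses). d = −½ ln[(1−2P−Q)√(1−2Q)] is left undefined
— flagged and excluded from summaries with an exclusion count — whenever
an argument of the logarithm is non-positive. Distances are computed on
full codon-aware gene alignments including third positions. Summaries
report mean/min/max with gene and pair labels plus per-gene quartiles
(the box-plot presentation used for such data).

## Ka/Ks (NG86)

The unweighted Nei–Gojobori method, matching DnaSP's computation:
potential sites per codon are the fractions of single-base changes that
are synonymous (changes creating a stop count as nonsynonymous, which
keeps S + N = 3 × codons exact); observed differences average over all
minimal mutational pathways, excluding pathways through stop codons;
codon pairs whose every pathway is blocked are skipped and tallied in a
diagnostics column. pS and pN are Jukes–Cantor corrected. Conventions at
the boundaries: Ka = 0 pins the ratio at 0 even when Ks saturates out of
the correction's domain; Ks = 0 (or undefined) otherwise leaves the
ratio undefined. A gene is classified "purifying" when the mean of its
defined pairwise ratios is below 1.

Known property, relevant to interpreting the screen: NG86 ignores the
transition/transversion bias. Because transitions are disproportionately
synonymous, κ > 1 inflates pS relative to the unweighted site counts and
biases Ka/Ks downward (measured here: ω = 0.1 genes estimate ≈ 0.05 at
κ = 2). The selection-validation harnesses therefore simulate at κ = 1
to isolate the ω signal; this is an estimator property, not a simulator
artifact, and it affects published NG86/DnaSP screens equally.

## Nucleotide diversity

Per window, π is the pooled proportion Σ differences / Σ compared sites
over all sequence pairs, with pairwise deletion inside the window. The
pooled estimator (rather than the mean of per-pair ratios) was chosen
because it makes the aggregation identity exact — tiling windows
recombine to the whole-alignment π — while coinciding with the mean of
ratios on gap-free data. Window coordinates are alignment coordinates.
Defaults are 200 bp windows at a 20 bp step; the source literature is
internally inconsistent between 20 and 25 bp steps, so the step is a
visible parameter rather than a guess. The pipeline stage runs π over
the concatenated per-gene codon alignments: whole-genome alignment
founders on the control region, and the PCG backbone is what dominates
published π profiles; per-window compared-site counts are emitted so
low-confidence regions remain visible.

## Synteny

Gene order is the forward-strand start order of features; junctions
between consecutive features are classified overlap / spacer / abutting
with lengths in bp, closing the circle for circular genomes (junction
lengths are rotation-invariant, which the tests assert). Order
comparison uses strand-aware circular adjacencies, an adjacency equal to
its reverse-complement reading; the breakpoint count is the number of
adjacencies of one genome absent from the other.

## Circularity

Assemblers emit circular molecules as linear contigs with a duplicated
terminus. Detection scans candidate repeat lengths from half the contig
length downward and accepts the longest prefix/suffix match within a 1%
mismatch tolerance (assembler end artifacts are near-exact; the
tolerance absorbs polish errors). The trimmed circle is rotated
deterministically (anchor offset, or half the length) — a reproducible
replacement for splitting "at random" — and the former junction is
verified by read support: exact 31-mer seeding on the doubled circle,
ungapped extension within a 5% mismatch budget, counting reads that
cover the junction by ≥ 20 bp on both sides. The supporting-read
threshold (default 5) is exposed because no principled universal value
exists; at 20× coverage the expected spanning count is ≈ 14, so 5 is a
loose floor. This is a junction verifier, not a read mapper.

## Supermatrix and trees

Per-gene codon alignments are concatenated in fixed alphabetical order
(atp6, atp8, cob, cox1–3, nad1–4, nad4L, nad5, nad6) — the order is
arbitrary but must be deterministic and recorded, which the partition
map and exported partition files do. PCG12 drops every third column.
Missing genes become all-gap blocks with warnings, so nearly complete
genomes remain usable. Saturation is summarized per codon position as
transition/transversion proportions against K2P distance with
least-squares slopes; the verdict is left to the user (a transition
plateau and s/v decaying toward the random-sequence asymptote of 0.5
indicate saturation). Model-based inference is exported (relaxed PHYLIP,
NEXUS charsets, RAxML-style partitions), not reimplemented; the
neighbor-joining tree built internally — canonical Saitou–Nei, negative
branch lengths clamped to zero with the deficit moved to the sister so
path lengths are preserved, deterministic tie-breaks — exists so
topology-level claims (e.g. genus monophyly) are testable inside the
package. Monophyly is membership of the taxon set in the unrooted
tree's split set.

## Synthetic data

The generator emits the world the analyses assume, not real data:

- a circular genome (default 16,176 bp, A+T 78.3%) with the conserved
  37-gene dipteran arrangement, genes on both strands, the published
  small overlaps and spacers (atp8/atp6 7 bp, trnW/trnC 8 bp, trnE/trnF
  20 bp, trnS2/nad1 16 bp, ...), and an A+T-rich control region (89.3%)
  carrying a seeded tandem repeat;
- PCGs that are genuine ORFs under table 5 — start codon, no internal
  stops, stop codon — including inside overlap regions, where codons are
  sampled subject to the bases already fixed by the overlapping gene
  (nad6 carries a truncated stop, as real annotations do). Codon
  sampling is calibrated so that excluding the A/T-rich stop codons does
  not pull realized A+T below target;
- evolution along a newick tree: per-site Poisson substitution proposals
  (branch length = expected proposals/site) under K80 with ratio κ
  (default 2), with acceptance–rejection selection in PCGs —
  nonsynonymous proposals accepted with probability min(1, ω) and
  synonymous ones with min(1, 1/ω), so the realized rate ratio equals ω
  on both sides of 1 (the min(1, ω) rule alone cannot represent
  positive selection). Proposals creating a stop in any reading frame
  crossing the site are rejected; accepted events are logged per branch
  and gene as estimator ground truth. One consequence worth knowing:
  stop rejection thins realized nonsynonymous changes by ~5%, so the
  realized dN/dS truth sits slightly below the nominal ω;
- uniform single-end reads with iid substitution errors and a fixed
  quality string; start positions are drawn in one batch so the error
  process is orthogonal to placement under a shared seed.

One seed fixes all outputs byte-exactly; each operation draws from its
own seed-derived substream, so adding an operation never perturbs the
others. What the generator does **not** emulate: indels (alignments in
the target clade are near indel-free; the aligner is still exercised on
constructed gapped cases), rRNA/tRNA secondary structure, compositional
heterogeneity along branches, and sequencing quality profiles. A green
estimator-recovery test therefore certifies correctness of the
computation under the stated model, not robustness to alignment error or
model misspecification.

## Known limitations

- The published comparative numbers were produced from manually curated
  alignments that cannot be reproduced algorithmically; distance-level
  reproduction is therefore toleranced (±0.5 percentage points), and the
  alignment here is automated.
- The comparative set contains four *Fannia* accessions even where the
  source figure caption mentions five species; summaries are over the
  four that exist.
- NG86's κ bias (above) makes its ω estimates conservative for ω > 1;
  with four taxa and a ~1 kb gene, the mean-of-pairs classification
  statistic has a standard deviation of ~0.15, so detecting ω ≈ 1.2
  against the 1.0 threshold succeeds in only ~85% of replicates. More
  taxa, longer genes, or counting-based (pooled Sd/Nd) aggregation would
  raise the power; the package keeps the mean-of-ratios convention for
  comparability with the screen it reproduces.
- The NJ tree is a sanity check; supported phylogenetic conclusions
  should come from the exported matrices run through ML/BI tools.
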