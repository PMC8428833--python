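# Methods

This note documents the models, rules and numerical choices behind `panpav`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## The map-to-pan presence rule

Presence of a gene in an accession is decided purely from breadth of
coverage: the fraction of gene-body positions and of CDS-union positions
covered by reads at depth ≥ `depth_min`. A gene is present iff

    gene-body breadth ≥ 0.75  AND  CDS breadth ≥ 0.95,

both thresholds inclusive. The CDS condition is the stringent one (coding
sequence must be nearly fully covered); the gene-body condition tolerates
uncovered introns/UTR stretches. `depth_min` defaults to 1 — presence
evidence is "any read covers the position". No published depth cutoff exists
for this style of calling, so the choice is exposed as a parameter and echoed
in the calling metadata. Coverage is strand-agnostic; strand is carried only
as annotation. Genes on sequences absent from an accession's coverage profile
are called absent (no evidence), with a warning.

All coordinates are 0-based half-open internally; GFF3 and per-base depth
tables are 1-based at the file boundary. Breadth is computed by sorted-array
interval intersection, which is exact and invariant to how the covered
positions are fragmented into intervals (a tested property). Adding covered
positions can only raise both breadths, so presence is monotone in evidence.

## Frequency bands and core/variable classification

With presence count *c* out of *n* accessions, the frequency *f* = *c*/*n*
is kept as an exact rational and binned:

| category | band        | superclass |
|----------|-------------|------------|
| cloud    | [0, 0.05)   | variable   |
| shell    | [0.05, 0.95]| variable   |
| softcore | (0.95, 0.99]| core       |
| hardcore | (0.99, 1]   | core       |

The boundary semantics follow from requiring simultaneously that hardcore
means "present in more than 99%", cloud "fewer than 5%", and that a loss
rate of exactly 0.05 is *variable* (core is loss rate < 0.05). A gene at
f = 0.95 is therefore shell, and 202/204 ≈ 0.9902 is hardcore. Descriptions
of core as "≥ 95%" in some summaries are treated as caption rounding of the
same partition. Exact rationals matter here: at n = 204 the hardcore
boundary sits between 202/204 and 201.96/204, which float arithmetic can
misorder.

Two per-accession composition statistics are emitted because the phrase
"contains X% of the core genes" admits both readings: (a) the share of an
accession's *present* genes that are core, and (b) the fraction of the
panel's core gene *set* present in the accession. Neither is used as a test
oracle.

## Rarefaction and saturation models

Pan (union) and core (intersection) gene counts are computed for subset
sizes 1..N over `n_iterations = 100` random accession orderings; the size-n
subset within an ordering is the ordering's prefix, so each iteration's pan
curve is non-decreasing and core curve non-increasing by construction while
every prefix is still a uniform random size-n subset. An exhaustive mode
enumerates all subsets instead (used by tests on panels ≤ 5).

The study style of saturation analysis never names its fitted model, so the
standard Tettelin-family forms are used on the mean curves:

- pan: P(n) = A·n^γ + C (γ bounded to [0, 1]);
- per-step discovery: Δ(n) = P(n) − P(n−1) fitted with k·n^(−α);
- core: K(n) = B·exp(−n/τ) + Ω.

Openness verdicts: the pan-genome is **closed** iff α > 1 (the Heaps-law
criterion — discovery decaying faster than 1/n gives a convergent total); a
flat pan curve is trivially closed (α = ∞). The core genome is **open** iff
the fitted K is still dropping by more than 0.5 genes per added accession at
the full panel size. Fits use `scipy.optimize.curve_fit`; non-convergence is
reported as a diagnostic with the verdict withheld. A points-mode fit over
all iteration points is available besides the default mean-curve fit.

## Population structure

The default PAV distance is simple matching (fraction of genes whose
presence state differs), with Jaccard over present-gene sets as an option;
the metric behind published PAV trees is typically unstated, and simple
matching treats shared absence as similarity, which is the natural choice
for gene-repertoire data where absence is informative. PCA centres but does
not scale the binary gene columns (genotype-PCA convention); component signs
are fixed by making the largest-magnitude loading positive. The tree is
neighbor joining on the PAV distances (scikit-bio, negative branches clamped
to zero) — NJ replaces likelihood tree inference because the recoverable
contract is the two-clade split, not an exact topology, and NJ is exactly
testable against additive metrics. Clade assignment for the gene-loss
contrast cuts the tree at its longest internal edge (user-supplied labels
override); clade I is the side holding the lexicographically smallest
accession id.

The Mantel statistic is the Pearson correlation of upper-triangle distances;
the permutation p-value is (1 + #{r\* ≥ r}) / (1 + n_perm) under simultaneous
row/column permutation of the second matrix, one-sided "greater" by default
(the PAV–SNP correlation is claimed positive). An exact mode enumerates all
label permutations for small n. The gene-loss contrast is the Welch
two-sample t-test (scipy, Welch–Satterthwaite df).

## Nonreference sequence extraction

Contigs shorter than 500 bp are discarded; contigs with no reference
alignment are fully unaligned (the whole contig is novel); contigs with
alignments contribute every unaligned fragment strictly longer than 450 bp.
Overlapping aligned intervals in a summary are merged with a warning.
Redundancy removal is greedy longest-first clustering (CD-HIT style): a
sequence joins the first representative it matches at ≥ 90% identity
(identity = matches / alignment columns of the best local alignment;
approximated by k-mer containment of the shorter sequence when lengths
differ more than twofold). The default threshold follows the `-c 0.9`
command-line convention of CD-HIT even though prose summaries sometimes say
"> 95% identity"; the threshold is a parameter, and the two redundancy
passes described in pipelines of this kind are implemented as a single
configurable pass. Exact local alignment is affordable because in-scope
fragments are 0.5–5 kb.

Contamination filtering consumes a precomputed, taxon-classified best-hit
table: a contig is removed iff its minimum-e-value hit is not nuclear-plant;
exact e-value ties resolve deterministically by class priority (organellar >
microbial > non-Viridiplantae > nuclear plant), then lower identity.
Contigs without hits are retained. The accumulation curve reports mean /
min / max cumulative union length of novel representatives at accession
counts step, 2·step, ..., N over 100 random orderings (exhaustive
enumeration available for small N).

## Long-read validation

An absence call is *supported* when any long-read deletion on the same
sequence overlaps the gene body by at least `min_overlap_bp` (default 1 —
"partial or complete overlap", with no reciprocal-overlap requirement).
Raising the threshold can only lower the support rate (tested invariant).
Because the question of whether a pooled or per-accession-averaged rate is
reported is ambiguous in practice, both are emitted. Novel-sequence recovery
replaces read remapping with canonical k-mer containment (k = 31): a
sequence is recovered when ≥ 80% of its canonical k-mers occur among the
insertion sequences; sequences shorter than k fall back to exact substring
search on either strand. Canonical k-mers make the statistic strand
invariant. Note the interaction of mutation rate and k: point divergence ε
leaves ≈ (1−ε)^k of k-mers intact, so at k = 31 the default 0.8 containment
bar corresponds to ε ≲ 0.7%.

## NG86 dN/dS

Synonymous site counts per codon are the per-position fractions of the three
possible changes that preserve the amino acid, with changes to stop codons
counted as nonsynonymous; per-pair sites are averaged over the two codons,
and S + N equals the nucleotide length exactly. Observed differences average
the synonymous/nonsynonymous step classification over all minimal mutational
pathways between the codons, excluding pathways through a stop codon (all
pathways are used if every one is blocked). Proportions are Jukes–Cantor
corrected, d = −(3/4)·ln(1 − (4/3)p), undefined at p ≥ 3/4; the ratio is
undefined when dS = 0. Only the standard genetic code is supported; codon
pairs with ambiguity characters are skipped pairwise. The statistic is
symmetric and invariant to self-concatenation (both tested). Published
core-vs-variable dN/dS contrasts depend on ortholog selection and alignment
pipelines that are out of scope here, so no attempt is made to reproduce
any particular printed ratio; the module is validated purely against
exhaustive enumeration.

## The synthetic-data generator

The generator emulates the *statistical* structure of a resequenced crop
panel, not its sequences. Defaults are the study conditions: 204 accessions;
a category spectrum of 90.6% hardcore / 2.6% softcore / 6.2% shell / 0.5%
cloud (as exact published-count ratios); 2,000 genes as the desk-scale
stand-in for a ~55k-gene annotation (gene count scales runtime linearly and
does not change any frequency-level statistic). Category assignment is
deterministic by largest-remainder apportionment, so simulated spectra match
the configured fractions exactly. Generating frequencies: hardcore exactly
1.0 (the "> 99%" class observed in real data is a calling artifact, not a
generative one); softcore U(0.955, 0.99); shell U(0.06, 0.94); cloud
U(1/n, 0.045). The guard margins (0.005–0.01 from each class boundary) keep
binomial sampling noise at n ≈ 200 from crossing class boundaries often,
which makes parameter-recovery tests sharp; residual boundary migration is
why end-to-end category recovery is asserted at ≥ 99%, not 100%.

Presence is Bernoulli per accession. Two clades (default split 50/50) are
expressed as ±clade_bias/2 frequency shifts on half of the shell genes, with
clade II keeping more genes — reproducing the asymmetric occurrence pattern
and gene-loss contrast seen in real panels. Any gene sampled absent
everywhere is resampled: pan-genome genes exist in at least one accession.

Coverage evidence: present genes draw gene-body breadth U(0.90, 1) and CDS
breadth U(0.97, 1); absent genes U(0, 0.40) and U(0, 0.50). With probability
`coverage_noise` a gene/accession pair draws from the opposite regime, so
the expected downstream call error rate equals `coverage_noise` exactly.
Present-regime position counts round up and absent-regime counts round
down, making the noise-free pipeline identity (calls ≡ truth) exact rather
than approximate. Long-read deletions cover each absent gene's body with
endpoints jittered outward by U{0..jitter_bp} and are omitted with
probability `dropout`; the SNP distance matrix is
mixing·D_PAV + (1−mixing)·noise with the noise rescaled to the PAV
distances' mean, so the Mantel statistic responds monotonically to `mixing`.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (mappability, GC bias,
repeats), partial-gene deletions and CNV, linkage between neighbouring
genes' presence states, admixed or >2-clade population structure, and any
sequence-level mutation model. Conclusions from the synthetic end-to-end
tests are about the correctness of the pipeline's logic under its stated
evidence model, not about calling accuracy on real sequencing data.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run the full pipeline at
204 × 2,000 (and 200 × 2,000 in tests), with smaller panels for enumeration
oracles — sizes chosen so a complete run takes well under a minute on one
CPU while keeping binomial confidence bands tight enough for the asserted
tolerances. All randomness flows from explicit `numpy.random.Generator`
seeds (no global state); the same seed gives byte-identical simulator
output, and Monte-Carlo means are seed-invariant within stated bands.

## Known limitations

- Presence is binary; copy number and partial presence are out of scope.
- The saturation-fit openness verdict depends on the assumed functional
  family; it is reported with parameters and residuals so users can judge.
- Greedy clustering is order-dependent by design (longest first,
  deterministic); it approximates, not reproduces, optimal clustering.
- The Mantel permutation p has resolution 1/(1+n_perm); for very small
  panels the exact mode should be used (permutation draws can re-hit the
  identity when n! is comparable to n_perm).
- NG86 is the classic counting method; no codon-frequency or
  transition/transversion modelling (GY94-style) is attempted.
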