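# Methods

This note documents the models, the synthetic "stated world" the tests run
in, and the numerical and design choices a maintainer should know about.
No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Peptide curation

Filters are applied in a fixed order — length (10–200 aa), standard
alphabet, internal stop, cysteine count (≥ 2), exact-sequence duplicate —
and the reported rejection reason is the first failing predicate. A single
trailing `*` is treated as the translated terminal stop and stripped
silently; a `*` anywhere else is a premature stop. Deduplication keys on
the uppercased sequence and keeps the first occurrence, so filtering is
idempotent and order-stable (up to which duplicate survives).

The cysteine-motif grammar is a count rule on the examined region (the
annotated mature region when present, else the full sequence): ≥ 6
cysteines → defensin-like, 4–5 → cathelicidin-like. The band edges are
arguments (`defensin_min`, `cathelicidin_range`) because only the canonical
counts (6 and 4) are biologically fixed; 5 is assigned to the cathelicidin
band so that a peptide one cysteine short of the defensin scaffold is not
silently dropped.

## AMP classifier

Features are fully pinned so they are reproducible to the bit: amino-acid
composition over the 20 standard residues; net charge at pH 7 by
Henderson–Hasselbalch over a fixed pKa table (free-residue values:
N-terminus 9.69, C-terminus 2.34, D 3.86, E 4.25, C 8.33, Y 10.07, H 6.00,
K 10.53, R 12.48); isoelectric point by bisection of the same charge
function on [0, 14] to 10⁻⁶ pH units; mean Kyte–Doolittle hydropathy;
molecular weight from average free-residue masses minus (n−1) waters.
These descriptors capture what makes AMPs separable (short, cationic,
cysteine-rich) without depending on any external model file.

The classifier is L2-regularised logistic regression (C = 1) on
standardised features, trained with a seeded deterministic solver. Any
probability threshold is applied strictly (call iff p > threshold).
Negative training pools are length-matched to the positives with 20
equal-width bins over the positives' length range; bin shortfalls are
filled from nearest bins first and from out-of-range pool members only as a
last resort, deterministically given the seed.

Confusion metrics are reported as percentages with full precision stored
and 2-decimal rounding applied only for display; undefined ratios (empty
margins) come back as NaN with a warning rather than an exception, since a
report row is still useful when one margin is empty.

## Subfamily assignment

Local alignment is Smith–Waterman with affine gaps (open 11, extend 1; a
gap of length L costs 11 + L) under BLOSUM62. Significance uses
Karlin–Altschul statistics with published gapped-BLOSUM62 constants
(λ = 0.267, K = 0.041); composition-based adjustment is deliberately
omitted. E-values for best-hit assignment use n = total reference length,
which makes assignment invariant to reference ordering; ties break by raw
score, then lexicographic target id. The fractional bit-score filter keeps
hits strictly above fraction × best, with the best hit itself always
retained (so fraction 1.0 keeps exactly the top hit). This substitutes an
alignment-score reading for an HMM-based ortholog screen and is documented
as an approximation: both apply the same keep-above-a-fraction-of-best
rule, but the underlying scores differ.

## TE overlap resolution

Coordinates are 0-based half-open throughout (GFF3 converted on I/O).
After removing simple/low-complexity records, same-scaffold, same-strand
pairs within 10 bp are candidates. A pair merges when the overlap covers at
least 80 % of the **longer** element; the merged record spans the union and
inherits family, class and divergence from the lower-divergence member (the
least-diverged call is the best-supported identity). Overlapping candidates
that fail the coverage test keep only the lower-divergence member; nearby
but non-overlapping candidates are both kept. Sweeps repeat until a
fixpoint, so chains of fragmented calls collapse fully and the operation is
idempotent. Two ambiguities in the verbal rule are exposed as flags:
`coverage_mode="both"` demands the coverage fraction of *each* element, and
`unresolved="keep_both"` disables the drop in the unresolved case.

Gene–TE intersection counts a TE for a gene at ≥ 1 bp overlap with the gene
span, clips its length contribution to the span, and tags TEs overlapping
any exon as exonic; per-gene summaries (count, total bp, per-class counts)
cover intronic TEs only, since the downstream statistics concern TEs
embedded in introns. Cluster detection is single-linkage chaining of genes
on a scaffold with inter-gene gaps ≤ 10 kb (the upper bound of observed AMP
cluster extents); singletons are not clusters.

## Hierarchical regression of gene length

Model: log gene length = b₀ + b₁·exon count + b₂·log(TE length + 1) +
b₃·TE count + u_species + v_family + e, with u ~ N(0, σ²ₛA),
v ~ N(0, σ²_f I), e ~ N(0, σ²ₑ I). A is the relatedness matrix implied by
the ultrametric tree: A[i,j] = root-to-MRCA(i,j) path length / depth
(diagonal 1, identity for a star phylogeny, PSD by its Gram structure).
Because TE length is zero for TE-free genes, the log transform is uniformly
log1p; this is recorded in the fitted summary.

Priors are weakly informative, mirroring common animal-model defaults:
coefficients N(0, 10⁸), variances scaled-inverse-gamma(ν = 0.002, V = 1).
All conditionals are conjugate, so the sampler is blocked Gibbs with no
tuning: coefficients and species effects from multivariate normals (via
Cholesky of the precision), family effects componentwise, variances from
inverse gammas. A⁻¹ gets a 10⁻¹⁰ diagonal jitter before inversion. The
production run configuration is 1,000,000 iterations, burn-in 1,000,
thinning 500 (chain length 1,998); tests and the acceptance script use
20,000 iterations, which the coverage simulation shows is sufficient for
the synthetic-scale data.

Summaries report per-parameter posterior mean, 95 % HPD and ESS. The HPD is
the shortest window containing ⌈0.95 n⌉ sorted draws, ties broken toward
the smallest lower bound. ESS = n / (1 + 2 Σ ρ̂ₖ) with autocorrelations
truncated at the first non-positive term. A marginal variance partition
(var(Xb̄) and the three variance components over their total) is provided
as a descriptive diagnostic; no external value is asserted for it because
the partition formula behind the published "fixed effects explain ~60 %"
figure is not stated.

Note one soft identifiability issue: the global intercept and the mean of
the family intercepts trade off; with only three families the intercept
chain mixes slowly (low ESS) while the slopes are unaffected. This is
inherent to the parameterisation, not a sampler defect, and HPD coverage of
the intercept remains nominal in the recovery simulation.

## Birth–death family-size models

The process is the equal-rate linear birth–death: a family of x copies
gains or loses one copy each at rate xλ; zero copies is absorbing. The
transition law has the closed form P(c|s) = Σⱼ C(s,j) C(s+c−j−1, s−1)
α^{s+c−2j} (1−2α)ʲ, α = λt/(1+λt). Matrices over a truncated copy-number
range are built by s-fold convolution of the single-copy law — an
independent derivation that the tests check against both the scalar closed
form and a matrix-exponential oracle. If more than 10⁻⁶ of the mass reaches
the truncation bound, the bound doubles automatically with a warning.

Family likelihoods are computed by pruning over the species tree with a
uniform root prior on 1..max observed count (a count-data convention:
families in the matrix were observed, so a zero root is excluded).
Among-family rate variation uses K equal-probability discrete-gamma
categories whose rates are conditional means of Gamma(α, α) within quantile
bands — exactly mean one, so K = 1 recovers the plain model identically.
The optional observation-error model mixes the tip indicator with ±1
miscounts (probability ε/2 each, clamped at zero); default ε = 0.

Fitting maximises the pruning likelihood over log-rates (plus log-shape for
gamma variants) by Nelder–Mead from random log-uniform restarts on
[0.01, 3]; the CLI default of 30 restarts mirrors the convention of
repeated convergence runs, while library tests use 2–5 (the surface is
smooth in one or two dimensions and the restart lnL spread is recorded in
the fit object as a convergence diagnostic). Nested variants are compared
by LRT with df = difference in free-parameter counts; negative statistics
from nested optimisation noise clip to 0 with a warning.

Per-branch calls: ancestral counts by max-product (Viterbi) pruning under
the family's best-supported gamma category; a family's significance is the
add-one-corrected fraction of parametrically simulated null families whose
deviance (−log family likelihood) is at least the observed one; branch
calls are the sign of child − parent MAP counts on significant families.
The species-overlap duplication criterion is the Jaccard index of the two
child-clade species sets, with duplication at ≥ 0.5.

## The synthetic world

The generators' defaults are the stated conditions of the analysis they
emulate, and each generator is a pure function of its config:

* **Species trees** are Yule topologies rescaled to depth 1; ultrametricity
  is the only property downstream stages require, so no attempt is made to
  mimic real divergence times. Default 20 species.
* **Family counts** are simulated by exact Gillespie event simulation —
  deliberately *not* by sampling the closed-form transition rows — so the
  forward simulator and the pruning likelihood are independent routes whose
  agreement (extinction probabilities, full single-branch distributions,
  the martingale mean property) is a genuine check. Default 37 families,
  root counts uniform on 1..5.
* **Peptides**: defensin-like positives carry exactly six cysteines with
  spacers of 2–12 residues at lengths 60–120 aa; cathelicidin-like
  positives carry four cysteines with wider spacers at 130–181 aa (the
  observed precursor ranges); non-cysteine positions draw from a cationic,
  glycine-rich AMP-like composition. Negatives draw from proteome-average
  (SwissProt-like) residue frequencies with lengths uniform on [10, 200].
  The background composition is deliberately *not* uniform over the 20
  residues: a uniform alphabet has 5 % cysteine, under which a large share
  of long background peptides would pass the six-cysteine rule, defeating
  the generator's purpose; at the proteome-average 1.4 % the chance
  six-cysteine rate in negatives is ~1 %.
* **Genome fixtures**: exon-count spectra per family use the exact observed
  count fractions (α-defensins 22/3 of 25 two/three-exon; β-defensins
  30/199/5 of 234 one/two/three-exon; cathelicidins 1/4/22 of 27); intronic
  TE classes use the exact fractions of the 335 observed β-defensin
  intronic TE records (LINE 156, SINE 94, DNA 40, LTR 21, RC 12, Unknown
  11, Retroposon 1); divergences are uniform on [0, 40] % (only the
  ordering matters to resolution tie-breaks). A configurable fraction of
  TEs is emitted as overlapping same-strand near-duplicates so resolution
  has real work. Every gene's CDS reverse-translates its peptide with a
  fixed codon per residue and round-trips exactly on both strands.
* **Regression tables** follow the hierarchical model with the reported
  posterior means as default truth, b = (5.083, 0.120, 0.436, −0.030), and
  variance components (σ²ₛ, σ²_f, σ²ₑ) = (0.10, 0.05, 0.10) — unreported
  upstream, chosen once as a realistic signal-to-noise regime where species
  effects are visible but do not swamp the covariates.

What a green test does **not** establish: the synthetic world has no real
sequence homology (positives are motif-bearing random sequences), no codon
or nucleotide evolution, no annotation noise beyond the optional ±1 count
error, and no correlation between TE content and exon count. Classifier
performance near 100 % on this world is a regression check of the pipeline,
not an estimate of real-data performance; likewise the regression and
birth–death recovery tests validate estimator correctness, not the
biological conclusions.

## Scaled-down calibrations

Two acceptance checks are calibration simulations scaled to a desk budget:

* LRT type-I error: 200 replicates of 40 families on a 5-species tree,
  one-rate null refitted against a two-class (terminal vs internal
  branches) alternative; the rejection rate at α = 0.05 must land in
  [0.02, 0.09].
* HPD coverage: 50 replicates of 20 species × 30 genes at 20,000
  iterations; each sample-wide coefficient's 95 % HPD must cover its
  planted truth in ≥ 43 of 50.

## Known limitations

* The Smith–Waterman implementation is a readable O(mn) Python/NumPy DP —
  adequate for the reference-set sizes this pipeline aligns (tens of short
  peptides), not a BLAST replacement.
* Karlin–Altschul constants are pinned, not estimated per scoring system;
  e-values are comparative devices for the best-hit rule, not calibrated
  database statistics.
* The birth–death model ties birth and death to a single λ per branch
  class (the equal-rate convention of family-size analyses); separate
  birth and death rates are not estimable from count data at this scale
  and are not modelled.
* The gamma-category assignment in branch calls picks the single
  best-supported category per family rather than averaging MAP states over
  categories.
* `ampevo` does not run annotation, masking, orthology inference or tree
  estimation; it consumes their outputs (GFF3, TE tables, count matrices,
  Newick trees).
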