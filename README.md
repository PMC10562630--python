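# ampevo

Antimicrobial peptides (AMPs) — defensins and cathelicidins above all — are
short, cationic, cysteine-scaffolded host-defense peptides that evolve by
rapid gene duplication and loss. Standard genome annotation routinely misses
them, and the gaps propagate into wrong conclusions about which lineages
lost which defense genes. `ampevo` is a tested, reusable reimplementation of
an AMP discovery-and-evolution pipeline for clade-scale genome comparisons
(built with bat genomes in mind, applicable to any vertebrate clade): it
curates candidate peptides, scores AMP probability, assigns subfamilies by
local alignment, resolves transposable-element (TE) annotations inside AMP
genes, and models the evolution of AMP repertoires on a species tree.

## What it computes

**Curation and classification.** Candidate peptides are filtered (length
10–200 aa, standard residues, no premature stops, ≥ 2 cysteines,
deduplication) and classed by cysteine-motif grammar (six cysteines →
defensin-like, four to five → cathelicidin-like). An L2-regularised logistic
model over pinned physicochemical features (length, composition, net charge
at pH 7, pI, Kyte–Doolittle hydrophobicity, cysteine fraction, molecular
weight) yields AMP probabilities, thresholded strictly (e.g. > 0.7).
Negative training sets are length-matched to the positives by binned
histogram sampling.

**Subfamily assignment.** Smith–Waterman local alignment with affine gaps
under BLOSUM62, with Karlin–Altschul statistics
(bit = (λS − ln K)/ln 2, E = mn·2^−bit); each query receives the family of
its best hit when E < 10⁻⁶. A relative bit-score filter keeps hits above a
stated fraction of the per-query best (0.75 for β-defensins, 0.80 for
α-defensins and cathelicidins).

**TE resolution and gene structure.** Same-strand TE calls within 10 bp
that reciprocally cover ≥ 80 % of the longer element merge into one record
(lowest-divergence identity wins); unresolvable overlaps keep the
lowest-divergence member; simple/low-complexity repeats are discarded.
Resolved TEs are intersected with gene models to summarise intronic TE load
per gene, and AMP gene clusters are chained at ≤ 10 kb gaps.

**Hierarchical gene-length regression** (`PhyloGeneLengthModel`):

    log L_g = b0 + b1·exons_g + b2·log(TE length_g + 1) + b3·TE count_g
              + u_species(g) + v_family(g) + e_g,
    u ~ N(0, σ²ₛ A),  v ~ N(0, σ²_f I),  e ~ N(0, σ²ₑ I)

with A the species relatedness matrix from the ultrametric phylogeny.
Fully conjugate blocked Gibbs sampling; the results object reports posterior
means, 95 % HPD intervals and effective sample sizes.

**Birth–death family-size models** (`BirthDeathFamilyModel`): gene counts
evolve under the equal-rate linear birth–death process, P(c|s) in closed
form with α = λt/(1+λt); likelihoods by pruning with truncation, optional
discrete-gamma among-family rate categories (mean-one, K equal-probability
classes) and an optional ±1 tip observation-error mixture. Variants
(global-λ, multi-λ, gamma-K) are fitted by multi-start Nelder–Mead and
compared by likelihood-ratio test against χ². Per-branch
expansions/contractions are called from max-product ancestral counts on
families significant under parametric null simulation, and a
species-overlap criterion (Jaccard ≥ 0.5 of child-clade species sets) calls
duplication nodes on gene trees.

**Synthetic module.** Every input the pipeline consumes can be generated
with stated statistical structure, fully seeded: Yule species trees
(depth 1), Gillespie-simulated family counts, motif-bearing peptide sets,
genome fixtures (multi-exon AMP genes + intronic/intergenic TEs), and
regression tables with phylogenetically correlated species effects.

## Worked example

```python
from ampevo import BirthDeathFamilyModel, BDModelSpec, lrt
from ampevo.synthetic import simulate_species_tree, simulate_family_counts

tree = simulate_species_tree(20, seed=1)
fc = simulate_family_counts(tree, BDModelSpec(lambdas=(0.5,)), 37,
                            root_count_law=("uniform", 1, 5), seed=1)
model = BirthDeathFamilyModel(tree, fc.counts)
null = model.fit("global", n_starts=3, seed=1)
alt = model.fit("gamma", n_categories=3, n_starts=3, seed=1)
stat, p = lrt(null.lnL, alt.lnL, df=alt.n_params - null.n_params)
print(null.summary())
print(f"LRT stat {stat:.3f}, p {p:.3g}")
```

prints

```
Birth-death gene family size model
==========================================
families: 37
species:  20
lnL:      -1067.456
params:   1
  lambda_0       0.5766
restart lnL spread: 4.693e-10
LRT stat 0.053, p 0.818
```

The fitted global duplication/loss rate (0.58 events per gene copy per
unit tree depth) sits near the simulated value of 0.5 — 37 families is a
small sample for this rate — and —
because the counts were simulated without among-family rate variation — the
gamma model earns essentially no likelihood and the LRT correctly declines
the richer model. On a pair of fixed log-likelihoods the same test
reproduces a model comparison directly:
`lrt(-648.749, -627.106, df=2)` → statistic 43.286, p ≈ 4.0 × 10⁻¹⁰.

A command-line interface mirrors the stages
(`ampevo simulate | curate | train | predict | assign | te | structure |
clusters | regress | famsize`).

## Acceptance script

`scripts/acceptance.py` regenerates all synthetic inputs from a seed and
runs every pipeline stage end-to-end — curation, classifier training and
held-out evaluation, subfamily assignment of mutated orthologs, TE
resolution and gene–TE intersection, structure summaries, cluster
detection, both birth–death fits with their LRT, and a short-chain fit of
the hierarchical regression — printing each stage's summary:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
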