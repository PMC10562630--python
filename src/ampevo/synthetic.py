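"""Seeded generators for every input the AMP-evolution pipeline consumes.

Each generator is a pure function of its configuration (seed included):
identical configs produce byte-identical outputs.  The statistical structure
mirrors what the downstream analyses assume —

* species trees: Yule (pure-birth) topologies rescaled to depth 1, so they
  are ultrametric by construction;
* gene-family counts: exact Gillespie simulation of the equal-rate linear
  birth-death process along each branch (an independent forward route
  against which the pruning likelihood's closed-form transition
  probabilities can be checked), optionally with discrete-gamma among-family
  rate multipliers;
* peptides: motif-bearing defensin-like (six-cysteine) and cathelicidin-like
  (four-cysteine) positives over an AMP-like residue composition, and
  background negatives over proteome-average composition;
* genome fixtures: multi-exon AMP gene models on scaffolds, with intronic
  and intergenic TE annotations drawn from a configurable class mix and a
  deliberate fraction of overlapping TE pairs to exercise overlap
  resolution;
* regression tables: log gene length following the hierarchical linear
  model with phylogenetically correlated species effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .curation import PeptideRecord
from .famsize import BDModelSpec, discrete_gamma_categories
from .phyloreg import tree_to_relatedness
from .te import GeneModel, TEAnnotation

__all__ = [
    "SyntheticConfig",
    "RegressionTruth",
    "FamilyCountMatrix",
    "PeptideSets",
    "GenomeFixture",
    "simulate_species_tree",
    "simulate_family_counts",
    "generate_peptides",
    "generate_genome_fixture",
    "generate_regression_data",
]

# Proteome-average amino-acid frequencies (SwissProt-like).  The cysteine
# frequency (~1.4%) matters: it keeps chance six-cysteine motifs rare in
# background sequences.
BACKGROUND_AA_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0966, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}

# AMP-like composition for non-cysteine positions of positives: cationic and
# glycine-rich, as in mature defensins.
AMP_AA_FREQS = {
    "A": 0.055, "R": 0.110, "N": 0.040, "D": 0.025, "C": 0.0,
    "Q": 0.030, "E": 0.025, "G": 0.120, "H": 0.030, "I": 0.055,
    "L": 0.070, "K": 0.110, "M": 0.015, "F": 0.045, "P": 0.050,
    "S": 0.065, "T": 0.050, "W": 0.015, "V": 0.060, "Y": 0.030,
}

# Exon-count spectra per AMP family, as exact count fractions of full-length
# genes: alpha-defensins 2-3 exons (22/3 of 25), beta-defensins mostly
# two-exon (30/199/5 of 234), cathelicidins mostly four-exon (1/4/22 of 27).
EXON_COUNT_WEIGHTS = {
    "DEFA": {2: 22 / 25, 3: 3 / 25},
    "DEFB": {1: 30 / 234, 2: 199 / 234, 3: 5 / 234},
    "CTHL": {2: 1 / 27, 3: 4 / 27, 4: 22 / 27},
}

# Intronic TE class mix: exact count fractions of the 335 beta-defensin
# intronic TE records (DNA 40, LINE 156, LTR 21, RC 12, Retroposon 1,
# SINE 94, Unknown 11).
TE_CLASS_WEIGHTS = {
    "DNA": 40 / 335, "LINE": 156 / 335, "LTR": 21 / 335, "RC": 12 / 335,
    "Retroposon": 1 / 335, "SINE": 94 / 335, "Unknown": 11 / 335,
}

# Hierarchical-regression truth: sample-wide coefficient means from the
# fitted model (intercept, exon count, log TE length, TE count).
REGRESSION_COEFS = (5.083, 0.120, 0.436, -0.030)

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_COMP = str.maketrans("ACGT", "TGCA")


def _check_probs(name: str, weights: dict) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class RegressionTruth:
    """Planted parameters for the regression-table generator."""

    coefs: tuple[float, float, float, float] = REGRESSION_COEFS
    sigma2_species: float = 0.10
    sigma2_family: float = 0.05
    sigma2_resid: float = 0.10

    def __post_init__(self) -> None:
        if min(self.sigma2_species, self.sigma2_family, self.sigma2_resid) < 0:
            raise ValueError("variance components must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """One stated world for all generators; seeded and validated."""

    seed: int = 0
    n_species: int = 20
    tree_depth: float = 1.0
    n_families: int = 37
    lambda_true: float = 0.5
    gamma_shape: float | None = None
    n_categories: int = 1
    root_count_law: tuple = ("uniform", 1, 5)
    n_defensin: int = 150
    n_cathelicidin: int = 50
    n_negative: int = 200
    te_class_weights: dict = field(default_factory=lambda: dict(TE_CLASS_WEIGHTS))
    exon_count_weights: dict = field(
        default_factory=lambda: {f: dict(w) for f, w in EXON_COUNT_WEIGHTS.items()}
    )
    regression_truth: RegressionTruth = field(default_factory=RegressionTruth)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if self.lambda_true < 0:
            raise ValueError("birth-death rate must be non-negative")
        _check_probs("te_class_weights", self.te_class_weights)
        for fam, weights in self.exon_count_weights.items():
            _check_probs(f"exon_count_weights[{fam}]", weights)


# ---------------------------------------------------------------------------
# Species tree


def simulate_species_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) tree on ``n_species`` tips, rescaled to depth 1.

    Ultrametric by construction: all tips terminate at the present.  Tip
    labels sp01..spNN are assigned in left-to-right Newick order.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("birth", "split", "children")

        def __init__(self, birth: float):
            self.birth = birth
            self.split: float | None = None
            self.children: list["_N"] = []

    # the root lineage splits at time 0 into the first two lineages
    root = _N(0.0)
    root.split = 0.0
    root.children = [_N(0.0), _N(0.0)]
    active = list(root.children)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.split = t
        node.children = [_N(t), _N(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / n_species)

    counter = [0]
    width = max(2, len(str(n_species)))

    def newick(node: _N) -> str:
        if not node.children:
            counter[0] += 1
            return f"sp{counter[0]:0{width}d}:{(t_end - node.birth) / t_end:.10f}"
        inner = ",".join(newick(ch) for ch in node.children)
        return f"({inner}):{(node.split - node.birth) / t_end:.10f}"

    text = f"({','.join(newick(ch) for ch in root.children)});"
    return dendropy.Tree.get(data=text, schema="newick")


# ---------------------------------------------------------------------------
# Family counts


@dataclass
class FamilyCountMatrix:
    """Simulated family-by-species counts with the generating tree and the
    true internal-node counts retained for ancestral-state checks."""

    counts: pd.DataFrame
    tree: dendropy.Tree
    internal_counts: pd.DataFrame
    category_multipliers: np.ndarray


def _gillespie_branch(x: int, lam: float, t: float, rng: np.random.Generator) -> int:
    """Exact event-driven simulation of the equal-rate linear birth-death
    process over one branch (birth and death each at rate x * lam)."""
    clock = 0.0
    while x > 0:
        rate = 2.0 * lam * x
        if rate == 0:
            break
        clock += rng.exponential(1.0 / rate)
        if clock >= t:
            break
        x += 1 if rng.random() < 0.5 else -1
    return x


def simulate_family_counts(
    tree: dendropy.Tree,
    model: BDModelSpec,
    n_families: int,
    root_count_law: tuple = ("uniform", 1, 5),
    seed: int = 0,
) -> FamilyCountMatrix:
    """Forward-simulate family counts along the tree under ``model``.

    Counts evolve by Gillespie simulation of the linear birth-death process
    with branch rate lambda_class * gamma-category multiplier (mean-one,
    drawn per family); zero is absorbing.  Root counts follow
    ``root_count_law``: ("fixed", k), ("uniform", lo, hi) inclusive, or
    ("poisson", mu).
    """
    from .famsize import edge_key, _prepare_tree

    if any(l < 0 for l in model.lambdas):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    tree = _prepare_tree(tree)
    law = root_count_law[0]
    if law == "fixed":
        roots = np.full(n_families, int(root_count_law[1]))
    elif law == "uniform":
        lo, hi = int(root_count_law[1]), int(root_count_law[2])
        roots = rng.integers(lo, hi + 1, size=n_families)
    elif law == "poisson":
        roots = rng.poisson(float(root_count_law[1]), size=n_families)
    else:
        raise ValueError(f"unknown root count law {law!r}")
    if (roots < 0).any():
        raise ValueError("root counts must be non-negative")

    if model.n_categories > 1:
        cats = discrete_gamma_categories(model.gamma_shape, model.n_categories)
        mult = cats[rng.integers(0, len(cats), size=n_families)]
    else:
        mult = np.ones(n_families)

    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    internal_keys = [
        edge_key(nd) or "root"
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf()
    ]
    tip_counts = np.zeros((n_families, len(taxa)), dtype=int)
    internal = np.zeros((n_families, len(internal_keys)), dtype=int)
    tip_index = {t: i for i, t in enumerate(taxa)}
    internal_index = {k: i for i, k in enumerate(internal_keys)}

    for f in range(n_families):
        state = {id(tree.seed_node): int(roots[f])}
        internal[f, internal_index[edge_key(tree.seed_node) or "root"]] = roots[f]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            t = node.edge.length or 0.0
            cls = model.branch_class_map.get(edge_key(node), 0)
            lam = model.lambdas[cls] * mult[f]
            x = _gillespie_branch(state[id(node.parent_node)], lam, t, rng)
            state[id(node)] = x
            if node.is_leaf():
                tip_counts[f, tip_index[node.taxon.label]] = x
            else:
                internal[f, internal_index[edge_key(node)]] = x

    families = [f"fam{f + 1:04d}" for f in range(n_families)]
    return FamilyCountMatrix(
        counts=pd.DataFrame(tip_counts, index=families, columns=taxa),
        tree=tree,
        internal_counts=pd.DataFrame(internal, index=families, columns=internal_keys),
        category_multipliers=mult,
    )


# ---------------------------------------------------------------------------
# Peptides


@dataclass
class PeptideSets:
    """Labelled synthetic peptide sets for classifier training."""

    defensin: list[PeptideRecord]
    cathelicidin: list[PeptideRecord]
    negative: list[PeptideRecord]

    @property
    def positives(self) -> list[PeptideRecord]:
        return self.defensin + self.cathelicidin


def _draw_residues(n: int, freqs: dict, rng: np.random.Generator) -> str:
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p)) if n > 0 else ""


def _motif_peptide(
    n_cys: int, length: tuple[int, int], spacer: tuple[int, int],
    rng: np.random.Generator,
) -> str:
    """A peptide carrying exactly ``n_cys`` cysteines arranged as a motif:
    C separated by spacers of ``spacer`` residues, flanked by non-C runs."""
    lo, hi = spacer
    spacers = rng.integers(lo, hi + 1, size=n_cys - 1)
    motif_len = n_cys + int(spacers.sum())
    total = int(rng.integers(max(length[0], motif_len + 4), length[1] + 1))
    flank = total - motif_len
    prefix_len = int(rng.integers(2, max(3, flank - 1)))
    suffix_len = flank - prefix_len
    parts = [_draw_residues(prefix_len, AMP_AA_FREQS, rng)]
    for gap in spacers:
        parts.append("C" + _draw_residues(int(gap), AMP_AA_FREQS, rng))
    parts.append("C" + _draw_residues(suffix_len, AMP_AA_FREQS, rng))
    return "".join(parts)


def generate_peptides(config: SyntheticConfig) -> PeptideSets:
    """Generate motif-bearing positives and background negatives.

    Defensin-like positives carry six cysteines with spacers of 2-12
    residues (lengths 60-120 aa); cathelicidin-like positives carry four
    cysteines (lengths 130-181 aa, the motif sitting in the propeptide-like
    region); negatives are proteome-composition sequences with lengths
    uniform on [10, 200].  FASTA source tags encode the true labels.
    """
    if min(config.n_defensin, config.n_cathelicidin, config.n_negative) <= 0:
        raise ValueError("peptide counts must be positive")
    rng = np.random.default_rng(config.seed)
    defensin = [
        PeptideRecord(
            id=f"def6_{i + 1:04d}",
            sequence=_motif_peptide(6, (60, 120), (2, 12), rng),
            source_tag="positive_defensin6",
        )
        for i in range(config.n_defensin)
    ]
    cathelicidin = [
        PeptideRecord(
            id=f"cath4_{i + 1:04d}",
            sequence=_motif_peptide(4, (130, 181), (4, 20), rng),
            source_tag="positive_cathelicidin4",
        )
        for i in range(config.n_cathelicidin)
    ]
    negative = [
        PeptideRecord(
            id=f"neg_{i + 1:04d}",
            sequence=_draw_residues(int(rng.integers(10, 201)), BACKGROUND_AA_FREQS, rng),
            source_tag="negative_background",
        )
        for i in range(config.n_negative)
    ]
    return PeptideSets(defensin=defensin, cathelicidin=cathelicidin, negative=negative)


# ---------------------------------------------------------------------------
# Genome fixture


@dataclass
class GenomeFixture:
    """Scaffold sequences with AMP gene models, their peptides and TE calls."""

    scaffolds: dict[str, str]
    genes: list[GeneModel]
    peptides: dict[str, str]
    tes: list[TEAnnotation]


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _weighted_choice(weights: dict, rng: np.random.Generator):
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def generate_genome_fixture(
    config: SyntheticConfig,
    n_genes: int = 30,
    genes_per_scaffold: int = 5,
    n_tes_per_intron: tuple[int, int] = (0, 3),
    n_intergenic_tes: int = 3,
    overlap_pair_prob: float = 0.2,
    family_mix: dict | None = None,
) -> GenomeFixture:
    """Scaffolds carrying multi-exon AMP genes with intronic/intergenic TEs.

    Exon counts follow the per-family spectra in the config; every gene's
    CDS translates to a motif-bearing peptide; TE classes follow the
    configured mix with divergences uniform on [0, 40]%.  A fraction of TEs
    is emitted as deliberately overlapping same-strand pairs so overlap
    resolution has work to do.  Setting ``n_tes_per_intron=(0, 0)`` and
    ``n_intergenic_tes=0`` produces a TE-free fixture.
    """
    rng = np.random.default_rng(config.seed + 1)
    family_mix = family_mix or {"DEFA": 0.09, "DEFB": 0.81, "CTHL": 0.10}
    scaffolds: dict[str, str] = {}
    genes: list[GeneModel] = []
    peptides: dict[str, str] = {}
    tes: list[TEAnnotation] = []

    def emit_te(scaffold: str, start: int, end: int, strand: str) -> None:
        te_class = _weighted_choice(config.te_class_weights, rng)
        div = float(rng.uniform(0.0, 40.0))
        tes.append(
            TEAnnotation(
                scaffold=scaffold, start=start, end=end, strand=strand,
                te_family=f"{te_class}-fam{int(rng.integers(1, 9))}",
                te_class=te_class, divergence=round(div, 2),
            )
        )
        if rng.random() < overlap_pair_prob:
            # same-strand near-duplicate call covering >80% of the longer
            length = end - start
            shift = int(rng.integers(1, max(2, length // 10)))
            tes.append(
                TEAnnotation(
                    scaffold=scaffold, start=start + shift, end=end + shift,
                    strand=strand,
                    te_family=f"{te_class}-fam{int(rng.integers(1, 9))}",
                    te_class=te_class, divergence=round(float(rng.uniform(0, 40)), 2),
                )
            )

    gene_counter = 0
    scaffold_counter = 0
    while gene_counter < n_genes:
        scaffold_counter += 1
        scaffold = f"scaffold{scaffold_counter:03d}"
        parts: list[str] = []
        cursor = 0
        for _ in range(min(genes_per_scaffold, n_genes - gene_counter)):
            gene_counter += 1
            family = _weighted_choice(family_mix, rng)
            n_exons = _weighted_choice(config.exon_count_weights[family], rng)
            n_cys = 4 if family == "CTHL" else 6
            peptide = _motif_peptide(
                n_cys, (130, 181) if family == "CTHL" else (60, 120),
                (4, 20) if family == "CTHL" else (2, 12), rng,
            )
            cds = "".join(_CODON[a] for a in peptide) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            # split CDS into n_exons chunks at codon-ish boundaries
            cuts = sorted(
                rng.choice(
                    np.arange(3, len(cds) - 3, 3), size=n_exons - 1, replace=False
                )
            ) if n_exons > 1 else []
            chunks = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
            if strand == "-":
                # first CDS chunk sits in the rightmost genomic exon
                chunks = chunks[::-1]
            # lay the gene down: exon, intron(+TEs), exon, ...
            intergenic = int(rng.integers(2_000, 9_000)) if parts else int(
                rng.integers(500, 2_000)
            )
            parts.append(_draw_dna(intergenic, rng))
            cursor += intergenic
            if tes is not None and n_intergenic_tes > 0 and rng.random() < 0.5:
                te_len = int(rng.integers(100, min(800, intergenic - 2)))
                te_start = cursor - intergenic + 1
                emit_te(scaffold, te_start, te_start + te_len,
                        "+" if rng.random() < 0.5 else "-")
            gene_start = cursor
            exons: list[tuple[int, int]] = []
            for i, chunk in enumerate(chunks):
                seq = chunk if strand == "+" else _reverse_complement(chunk)
                exons.append((cursor, cursor + len(seq)))
                parts.append(seq)
                cursor += len(seq)
                if i < len(chunks) - 1:
                    intron_len = int(rng.integers(300, 2_500))
                    lo, hi = n_tes_per_intron
                    n_tes = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
                    intron_seq = _draw_dna(intron_len, rng)
                    parts.append(intron_seq)
                    intron_start = cursor
                    cursor += intron_len
                    for _ in range(n_tes):
                        te_len = int(rng.integers(80, max(120, intron_len // 2)))
                        margin = intron_len - te_len - 2
                        if margin <= 1:
                            continue
                        off = int(rng.integers(1, margin))
                        emit_te(
                            scaffold, intron_start + off,
                            intron_start + off + te_len,
                            "+" if rng.random() < 0.5 else "-",
                        )
            gene_id = f"gene{gene_counter:04d}"
            genes.append(
                GeneModel(
                    id=gene_id, scaffold=scaffold, start=gene_start, end=cursor,
                    strand=strand, exons=tuple(exons), family_label=family,
                )
            )
            peptides[gene_id] = peptide
        parts.append(_draw_dna(int(rng.integers(500, 1_500)), rng))
        scaffolds[scaffold] = "".join(parts)
    return GenomeFixture(scaffolds=scaffolds, genes=genes, peptides=peptides, tes=tes)


def _draw_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


# ---------------------------------------------------------------------------
# Regression tables


def generate_regression_data(
    tree: dendropy.Tree,
    truth: RegressionTruth | None = None,
    n_genes_per_species: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a per-gene regression table following the hierarchical model.

    log(gene_length) = b0 + b1 exon_count + b2 log(te_length + 1)
    + b3 te_count + u_species + v_family + e, with u drawn from
    N(0, sigma2_species * A) (A from :func:`tree_to_relatedness`), v from
    N(0, sigma2_family I) and e iid.  Covariates: exon counts 1-4,
    te_count ~ Poisson(2), te_length log-normal given te_count > 0.
    """
    truth = truth or RegressionTruth()
    rng = np.random.default_rng(seed)
    A = tree_to_relatedness(tree)
    species = list(A.index)
    n_sp = len(species)
    cov = truth.sigma2_species * A.to_numpy()
    u = (
        rng.multivariate_normal(np.zeros(n_sp), cov, method="cholesky")
        if truth.sigma2_species > 0
        else np.zeros(n_sp)
    )
    families = ("DEFA", "DEFB", "CTHL")
    v = (
        rng.normal(0.0, math.sqrt(truth.sigma2_family), size=len(families))
        if truth.sigma2_family > 0
        else np.zeros(len(families))
    )
    b0, b1, b2, b3 = truth.coefs
    rows = []
    gene_no = 0
    for si, sp in enumerate(species):
        for _ in range(n_genes_per_species):
            gene_no += 1
            fam_i = int(rng.integers(0, len(families)))
            exon_count = int(rng.integers(1, 5))
            te_count = int(rng.poisson(2.0))
            te_length = (
                float(np.round(rng.lognormal(mean=5.2, sigma=1.0)))
                if te_count > 0
                else 0.0
            )
            eta = (
                b0 + b1 * exon_count + b2 * math.log1p(te_length) + b3 * te_count
                + u[si] + v[fam_i]
            )
            noise = (
                rng.normal(0.0, math.sqrt(truth.sigma2_resid))
                if truth.sigma2_resid > 0
                else 0.0
            )
            rows.append(
                {
                    "gene_id": f"g{gene_no:05d}",
                    "species": sp,
                    "amp_family": families[fam_i],
                    "exon_count": exon_count,
                    "te_count": te_count,
                    "te_length": te_length,
                    "gene_length": float(np.exp(eta + noise)),
                }
            )
    return pd.DataFrame(rows)
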