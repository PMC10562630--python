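"""Synthetic generators: determinism, stated structure, forward-model checks."""

import numpy as np
import pandas as pd
import pytest

import dendropy

from ampevo.curation import cysteine_motif_class
from ampevo.famsize import BDModelSpec, bdp_transition_prob
from ampevo.synthetic import (
    RegressionTruth,
    SyntheticConfig,
    generate_genome_fixture,
    generate_peptides,
    generate_regression_data,
    simulate_family_counts,
    simulate_species_tree,
)
from ampevo.te import intersect_genes_tes


class TestSpeciesTree:
    def test_two_species(self):
        tree = simulate_species_tree(2, seed=0)
        lengths = [leaf.edge.length for leaf in tree.leaf_node_iter()]
        assert lengths == pytest.approx([1.0, 1.0])

    def test_deterministic(self):
        t1 = simulate_species_tree(20, seed=1).as_string(schema="newick")
        t2 = simulate_species_tree(20, seed=1).as_string(schema="newick")
        assert t1 == t2

    def test_ultrametric_depth_one(self):
        tree = simulate_species_tree(50, seed=2)
        tree.calc_node_root_distances()
        depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        assert depths[0] == pytest.approx(1.0, abs=1e-9)

    def test_unique_labels(self):
        tree = simulate_species_tree(30, seed=3)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        assert len(set(labels)) == 30

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)


class TestFamilyCounts:
    def test_lambda_zero_counts_frozen(self, yule_tree_10):
        fc = simulate_family_counts(
            yule_tree_10, BDModelSpec(lambdas=(0.0,)), 20,
            root_count_law=("uniform", 1, 5), seed=1,
        )
        roots = fc.internal_counts.iloc[:, 0]
        for col in fc.counts.columns:
            assert (fc.counts[col] == roots.values).all()

    def test_single_branch_extinction_matches_closed_form(self):
        # one effective branch of length 1 (partner branch negligible)
        tree = dendropy.Tree.get(data="(A:1.0,B:0.0000001);", schema="newick")
        n = 20_000
        fc = simulate_family_counts(
            tree, BDModelSpec(lambdas=(0.5,)), n,
            root_count_law=("fixed", 1), seed=3,
        )
        p_hat = (fc.counts["A"] == 0).mean()
        p = bdp_transition_prob(1, 0, 0.5, 1.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se

    def test_single_branch_distribution_matches_closed_form(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:0.0000001);", schema="newick")
        n = 20_000
        fc = simulate_family_counts(
            tree, BDModelSpec(lambdas=(0.5,)), n,
            root_count_law=("fixed", 2), seed=4,
        )
        for c in range(5):
            p = bdp_transition_prob(2, c, 0.5, 1.0)
            se = np.sqrt(p * (1 - p) / n)
            assert abs((fc.counts["A"] == c).mean() - p) < 3.5 * se

    def test_mean_preserving_martingale(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:0.0000001);", schema="newick")
        n = 5_000
        fc = simulate_family_counts(
            tree, BDModelSpec(lambdas=(0.5,)), n,
            root_count_law=("fixed", 5), seed=5,
        )
        mean = fc.counts["A"].mean()
        # Var of tip count for root 5: 5 * 2*lambda*t = 5
        se = np.sqrt(5.0 * 2 * 0.5 * 1.0 / n)
        assert abs(mean - 5.0) < 3 * se

    def test_deterministic(self, yule_tree_10):
        a = simulate_family_counts(yule_tree_10, BDModelSpec(lambdas=(0.4,)), 30,
                                   seed=9)
        b = simulate_family_counts(yule_tree_10, BDModelSpec(lambdas=(0.4,)), 30,
                                   seed=9)
        assert a.counts.equals(b.counts)
        assert a.internal_counts.equals(b.internal_counts)

    def test_negative_rate_rejected(self, yule_tree_10):
        with pytest.raises(ValueError):
            BDModelSpec(lambdas=(-0.1,))


class TestPeptides:
    def test_positives_satisfy_motif_grammar(self, peptide_sets):
        assert all(
            cysteine_motif_class(p) == "defensin6" for p in peptide_sets.defensin
        )
        assert all(
            cysteine_motif_class(p) == "cathelicidin4"
            for p in peptide_sets.cathelicidin
        )
        assert all(
            10 <= len(p.sequence) <= 200 for p in peptide_sets.positives
        )

    def test_deterministic_bytes(self, default_config):
        a = generate_peptides(default_config)
        b = generate_peptides(default_config)
        assert [(r.id, r.sequence) for r in a.positives + a.negative] == [
            (r.id, r.sequence) for r in b.positives + b.negative
        ]

    def test_negatives_rarely_match_six_cys_motif(self):
        sets = generate_peptides(SyntheticConfig(seed=0, n_negative=1000))
        frac = np.mean(
            [cysteine_motif_class(p) == "defensin6" for p in sets.negative]
        )
        assert frac <= 0.05

    def test_labels_in_source_tags(self, peptide_sets):
        assert all("positive" in p.source_tag for p in peptide_sets.positives)
        assert all("negative" in p.source_tag for p in peptide_sets.negative)


class TestGenomeFixture:
    def test_zero_tes_propagates(self, default_config):
        fx = generate_genome_fixture(
            default_config, n_genes=10, n_tes_per_intron=(0, 0),
            n_intergenic_tes=0,
        )
        assert fx.tes == []
        summaries, tags = intersect_genes_tes(fx.genes, fx.tes)
        assert all(s.te_count == 0 for s in summaries)

    def test_gene_models_valid(self, default_config):
        fx = generate_genome_fixture(default_config, n_genes=25)
        for g in fx.genes:
            assert g.strand in "+-"
            assert all(g.start <= s < e <= g.end for s, e in g.exons)
            assert g.end <= len(fx.scaffolds[g.scaffold])

    def test_cds_translates_to_emitted_peptide(self, default_config):
        from ampevo.synthetic import _CODON, _reverse_complement

        inv = {v: k for k, v in _CODON.items()}
        fx = generate_genome_fixture(default_config, n_genes=15)
        for g in fx.genes:
            chunks = [fx.scaffolds[g.scaffold][s:e] for s, e in g.exons]
            if g.strand == "-":
                cds = "".join(_reverse_complement(c) for c in reversed(chunks))
            else:
                cds = "".join(chunks)
            assert cds.endswith("TAA")
            pep = "".join(inv[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3))
            assert pep == fx.peptides[g.id]

    def test_beta_defensin_two_exon_fraction(self):
        cfg = SyntheticConfig(seed=0)
        fx = generate_genome_fixture(
            cfg, n_genes=2000, genes_per_scaffold=50,
            n_tes_per_intron=(0, 0), n_intergenic_tes=0,
            family_mix={"DEFB": 1.0},
        )
        n_two = sum(1 for g in fx.genes if len(g.exons) == 2)
        frac = n_two / len(fx.genes)
        assert abs(frac - 199 / 234) <= 0.03

    def test_te_divergences_in_stated_range(self, default_config):
        fx = generate_genome_fixture(default_config, n_genes=20)
        assert all(0.0 <= t.divergence <= 40.0 for t in fx.tes)


class TestRegressionData:
    def test_zero_variance_is_exact_linear_predictor(self, yule_tree_10):
        truth = RegressionTruth(sigma2_species=0, sigma2_family=0, sigma2_resid=0)
        df = generate_regression_data(yule_tree_10, truth,
                                      n_genes_per_species=5, seed=1)
        b0, b1, b2, b3 = truth.coefs
        eta = (
            b0 + b1 * df["exon_count"] + b2 * np.log1p(df["te_length"])
            + b3 * df["te_count"]
        )
        assert np.allclose(np.log(df["gene_length"]), eta)

    def test_star_tree_species_effects_uncorrelated(self):
        star = dendropy.Tree.get(
            data="(" + ",".join(f"s{i}:1" for i in range(6)) + ");",
            schema="newick",
        )
        truth = RegressionTruth(sigma2_species=1.0, sigma2_family=0,
                                sigma2_resid=0)
        effects = []
        for rep in range(500):
            df = generate_regression_data(star, truth, n_genes_per_species=1,
                                          seed=rep)
            b0, b1, b2, b3 = truth.coefs
            eta = (
                b0 + b1 * df["exon_count"] + b2 * np.log1p(df["te_length"])
                + b3 * df["te_count"]
            )
            effects.append((np.log(df["gene_length"]) - eta).to_numpy())
        effects = np.array(effects)
        corr = np.corrcoef(effects.T)
        off_diag = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off_diag).max() < 0.15

    def test_deterministic(self, yule_tree_10):
        a = generate_regression_data(yule_tree_10, seed=3)
        b = generate_regression_data(yule_tree_10, seed=3)
        assert a.equals(b)


class TestConfigValidation:
    def test_probability_vectors_checked(self):
        with pytest.raises(ValueError, match="probabilities"):
            SyntheticConfig(te_class_weights={"LINE": 0.5, "SINE": 0.4})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(lambda_true=-1.0)
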