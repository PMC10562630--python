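"""Birth-death family-size likelihoods, fitting, LRT and duplication calls."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import expm

from ampevo.famsize import (
    BDModelSpec,
    BirthDeathFamilyModel,
    bdp_transition_prob,
    branch_changes,
    discrete_gamma_categories,
    family_loglik,
    fit_model,
    lrt,
    species_overlap_duplications,
    transition_matrix,
)
from ampevo.synthetic import simulate_family_counts, simulate_species_tree


def expm_oracle(lam, t, n_max=200):
    """Truncated-generator matrix exponential for the linear birth-death
    process with birth = death = lam per copy."""
    Q = np.zeros((n_max + 1, n_max + 1))
    for i in range(1, n_max + 1):
        Q[i, i - 1] = i * lam
        if i < n_max:
            Q[i, i + 1] = i * lam
        Q[i, i] = -Q[i, i - 1] - (Q[i, i + 1] if i < n_max else 0.0)
    return expm(Q * t)


class TestTransitionProb:
    def test_no_time_elapsed(self):
        assert bdp_transition_prob(3, 3, 0.7, 0.0) == 1.0
        assert bdp_transition_prob(3, 2, 0.7, 0.0) == 0.0

    def test_zero_is_absorbing(self):
        assert bdp_transition_prob(0, 0, 0.5, 1.0) == 1.0
        assert bdp_transition_prob(0, 3, 0.5, 1.0) == 0.0

    def test_matches_matrix_exponential(self):
        P = expm_oracle(0.5, 1.0)
        for s in range(1, 6):
            for c in range(11):
                assert bdp_transition_prob(s, c, 0.5, 1.0) == pytest.approx(
                    P[s, c], abs=1e-8
                )

    def test_rows_sum_to_one(self):
        for s in range(1, 11):
            for lam_t in (0.2, 1.0, 2.0):
                total = sum(
                    bdp_transition_prob(s, c, lam_t, 1.0) for c in range(400)
                )
                assert total == pytest.approx(1.0, abs=1e-8)

    def test_matrix_agrees_with_scalar_form(self):
        # convolution route vs closed-form route: independent derivations
        P = transition_matrix(0.8, 0.6, 25)
        for s in range(10):
            for c in range(20):
                assert P[s, c] == pytest.approx(
                    bdp_transition_prob(s, c, 0.8, 0.6), abs=1e-10
                )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bdp_transition_prob(-1, 0, 0.5, 1.0)


class TestGammaCategories:
    @pytest.mark.parametrize("shape,k", [(0.5, 2), (1.0, 3), (2.0, 5)])
    def test_mean_one(self, shape, k):
        cats = discrete_gamma_categories(shape, k)
        assert len(cats) == k
        assert cats.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(cats) > 0)

    def test_single_category_is_unity(self):
        assert discrete_gamma_categories(None, 1).tolist() == [1.0]


class TestFamilyLoglik:
    def test_lambda_zero_constant_family_certain(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        counts = pd.DataFrame([[2, 2]], index=["f1"], columns=["A", "B"])
        spec = BDModelSpec(lambdas=(0.0,), max_count=10)
        # uniform root prior over 1..2: P = 1/2 for the matching root state
        lnl = family_loglik(tree, counts, spec)
        assert lnl == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize(
        "newick, families",
        [
            ("(A:0.4,B:0.7);", [(2, 1), (0, 3), (1, 1)]),
            ("((A:0.3,B:0.3):0.5,C:0.8);", [(2, 1, 4), (1, 1, 0), (5, 2, 2)]),
        ],
    )
    def test_matches_enumeration_oracle(self, newick, families):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        taxa = sorted(t.label for t in tree.taxon_namespace)
        counts = pd.DataFrame(families, columns=taxa,
                              index=[f"f{i}" for i in range(len(families))])
        lam = 0.6
        spec = BDModelSpec(lambdas=(lam,), max_count=80)
        lnl = family_loglik(tree, counts, spec)

        # brute force: enumerate all internal-node states up to max_count
        max_obs = counts.to_numpy().max()
        enum_max = 30

        def branch_p(s, c, t):
            return bdp_transition_prob(s, c, lam, t)

        total = 0.0
        if len(taxa) == 2:
            tA = tree.taxon_namespace.get_taxon("A")
            lens = {
                leaf.taxon.label: leaf.edge.length
                for leaf in tree.leaf_node_iter()
            }
            for _, row in counts.iterrows():
                lik = sum(
                    (1 / max_obs)
                    * branch_p(r, row["A"], lens["A"])
                    * branch_p(r, row["B"], lens["B"])
                    for r in range(1, max_obs + 1)
                )
                total += math.log(lik)
        else:
            lens = {
                leaf.taxon.label: leaf.edge.length
                for leaf in tree.leaf_node_iter()
            }
            inner_len = 0.5
            for _, row in counts.iterrows():
                lik = 0.0
                for r in range(1, max_obs + 1):
                    for m in range(enum_max + 1):
                        lik += (
                            (1 / max_obs)
                            * branch_p(r, m, inner_len)
                            * branch_p(m, row["A"], lens["A"])
                            * branch_p(m, row["B"], lens["B"])
                            * branch_p(r, row["C"], lens["C"])
                        )
                total += math.log(lik)
        assert lnl == pytest.approx(total, abs=1e-6)

    def test_one_gamma_category_equals_plain_model(self, yule_tree_10):
        fc = simulate_family_counts(
            yule_tree_10, BDModelSpec(lambdas=(0.4,)), 30, seed=2
        )
        plain = family_loglik(yule_tree_10, fc.counts,
                              BDModelSpec(lambdas=(0.4,), max_count=40))
        one_cat = family_loglik(
            yule_tree_10, fc.counts,
            BDModelSpec(lambdas=(0.4,), gamma_shape=None, n_categories=1,
                        max_count=40),
        )
        assert one_cat == pytest.approx(plain, abs=1e-10)

    def test_truncation_leak_triggers_doubling(self, yule_tree_10):
        fc = simulate_family_counts(
            yule_tree_10, BDModelSpec(lambdas=(0.4,)), 10, seed=3
        )
        tight = BDModelSpec(lambdas=(2.5,), max_count=int(fc.counts.max().max()))
        with pytest.warns(UserWarning, match="truncation"):
            lnl = family_loglik(yule_tree_10, fc.counts, tight)
        assert np.isfinite(lnl)


class TestFitting:
    def test_single_class_multi_lambda_equals_global(self, yule_tree_10):
        fc = simulate_family_counts(
            yule_tree_10, BDModelSpec(lambdas=(0.3,)), 60, seed=4
        )
        model = BirthDeathFamilyModel(yule_tree_10, fc.counts)
        g = model.fit("global", n_starts=3, seed=0)
        # multi-lambda template whose branches all map to class 0
        spec = model.spec("global")
        m = fit_model(yule_tree_10, fc.counts, spec, n_starts=3, seed=1)
        assert m.lnL == pytest.approx(g.lnL, abs=1e-5)

    def test_adding_rate_class_never_decreases_lnl(self, yule_tree_10):
        fc = simulate_family_counts(
            yule_tree_10, BDModelSpec(lambdas=(0.3,)), 60, seed=5
        )
        model = BirthDeathFamilyModel(yule_tree_10, fc.counts)
        g = model.fit("global", n_starts=3, seed=0)
        # split branches into two classes: tips vs internals
        class_map = {}
        for leaf in yule_tree_10.leaf_node_iter():
            class_map[leaf.taxon.label] = 1
        two = model.fit("multi", branch_class_map=class_map, n_starts=3, seed=0)
        assert two.lnL >= g.lnL - 1e-6
        assert two.n_params == 2

    def test_empty_counts_rejected(self, yule_tree_10):
        model = BirthDeathFamilyModel(
            yule_tree_10,
            pd.DataFrame(columns=[l.taxon.label
                                  for l in yule_tree_10.leaf_node_iter()]),
        )
        with pytest.raises(ValueError):
            model.fit("global")


class TestLRT:
    def test_headline_model_comparison(self):
        stat, p = lrt(-648.749, -627.106, df=2)
        assert stat == pytest.approx(43.286, abs=1e-3)
        assert p == pytest.approx(3.98e-10, rel=0.01)

    def test_equal_likelihoods(self):
        stat, p = lrt(-100.0, -100.0, df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        stat, p = lrt(-10.0, -10.0 + 3.841 / 2, df=1)
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_clipping_and_df_validation(self):
        with pytest.warns(UserWarning):
            stat, p = lrt(-5.0, -6.0, df=1)
        assert stat == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            lrt(-5.0, -4.0, df=0)


class TestBranchChanges:
    def test_planted_expansion_flagged(self):
        tree = simulate_species_tree(6, seed=7)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        # constant families plus one with a 10-fold expansion at one tip
        rows = [[2] * 6 for _ in range(40)]
        expanded = [2] * 6
        expanded[0] = 20
        rows.append(expanded)
        counts = pd.DataFrame(
            rows, columns=taxa, index=[f"f{i}" for i in range(41)]
        )
        model = BirthDeathFamilyModel(tree, counts)
        res = model.fit("global", n_starts=3, seed=0)
        calls = res.branch_changes(n_null_sims=400, alpha=0.05, seed=1)
        flagged = calls[(calls["family"] == "f40") & (calls["branch"] == taxa[0])]
        assert flagged.iloc[0]["significant"]
        assert flagged.iloc[0]["call"] == "expansion"
        # constant families: no branch flagged
        quiet = calls[(calls["family"] == "f0")]
        assert not quiet["significant"].any()
        assert (quiet["call"] == "none").all()

    def test_few_null_sims_warns(self, yule_tree_10):
        fc = simulate_family_counts(
            yule_tree_10, BDModelSpec(lambdas=(0.3,)), 10, seed=8
        )
        model = BirthDeathFamilyModel(yule_tree_10, fc.counts)
        res = model.fit("global", n_starts=2, seed=0)
        with pytest.warns(UserWarning, match="null simulations"):
            res.branch_changes(n_null_sims=50, seed=0)


class TestSpeciesOverlap:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_identical_species_sets_duplication(self):
        tree = self._tree("((Aa:1,Ba:1):1,(Ab:1,Bb:1):1);")
        mapping = {"Aa": "A", "Ab": "A", "Ba": "B", "Bb": "B"}
        calls = {c.node_id: c for c in species_overlap_duplications(tree, mapping)}
        root = [c for c in calls.values() if c.support == 1.0]
        assert any(c.is_duplication for c in root)

    def test_disjoint_sets_speciation(self):
        tree = self._tree("((Aa:1,Ba:1):1,(Ca:1,Da:1):1);")
        mapping = {t: t[0] for t in ["Aa", "Ba", "Ca", "Da"]}
        calls = species_overlap_duplications(tree, mapping)
        root_call = calls[-1]
        assert root_call.support == 0.0 and not root_call.is_duplication

    def test_jaccard_below_half_not_duplication(self):
        # S1 = {A, B}, S2 = {A, C}: support 1/3
        tree = self._tree("((Aa:1,Ba:1):1,(Ab:1,Ca:1):1);")
        mapping = {"Aa": "A", "Ba": "B", "Ab": "A", "Ca": "C"}
        calls = species_overlap_duplications(tree, mapping)
        root_call = calls[-1]
        assert root_call.support == pytest.approx(1 / 3)
        assert not root_call.is_duplication

    def test_unmapped_tip_rejected(self):
        tree = self._tree("(Aa:1,Ba:1);")
        with pytest.raises(ValueError):
            species_overlap_duplications(tree, {"Aa": "A"})
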