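"""Birth-death models of gene-family size evolution on a species tree.

Gene families gain and lose copies through duplication and loss.  The model
here is the linear birth-death process with equal per-copy birth and death
rate lambda: a family with x copies gains or loses one copy at rate
x * lambda each, and zero copies is absorbing (a lost family cannot return).
Over a branch of length t the transition probability has the closed form

    P(c | s) = sum_{j=0}^{min(s,c)} C(s, j) C(s+c-j-1, s-1)
               alpha^(s+c-2j) (1-2 alpha)^j,      alpha = lambda t / (1 + lambda t)

for s >= 1, with P(0|0) = 1.  Family likelihoods are computed by pruning
(truncated to a finite copy-number range), with an optional discrete-gamma
mixture of mean-one rate multipliers shared by all branches of a family
(among-family rate variation) and an optional symmetric +/-1 observation
error at the tips (assembly/annotation miscounts).

Model variants:

* global-lambda — one rate for the whole tree;
* multi-lambda — branches partitioned into classes, one rate each;
* discrete-gamma — K equal-probability mean-one categories scaling a
  global rate, shape alpha estimated.

Maximum-likelihood fits use Nelder-Mead on log-rates with random restarts;
nested variants are compared by likelihood-ratio test against chi-squared.
Per-branch expansions/contractions are called from max-product (Viterbi)
ancestral counts on families whose deviance is extreme under parametric
null simulation.  A species-overlap criterion calls duplication nodes on a
gene tree: a node is a duplication when the species sets of its two child
clades share at least half of their union (Jaccard >= 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln, gammainc

__all__ = [
    "BDModelSpec",
    "ModelFit",
    "DuplicationCall",
    "bdp_transition_prob",
    "transition_matrix",
    "discrete_gamma_categories",
    "family_loglik",
    "fit_model",
    "lrt",
    "branch_changes",
    "species_overlap_duplications",
    "BirthDeathFamilyModel",
    "BirthDeathFamilyResults",
    "edge_key",
]


# ---------------------------------------------------------------------------
# Transition probabilities


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bdp_transition_prob(s: int, c: int, lam: float, t: float) -> float:
    """P(X(t) = c | X(0) = s) for the equal-rate linear birth-death process.

    Zero is absorbing: P(0|0) = 1 and P(c>0 | 0) = 0.  At t = 0 (or lam = 0)
    the distribution is a point mass at s.
    """
    if s < 0 or c < 0 or lam < 0 or t < 0:
        raise ValueError("counts, rate and time must be non-negative")
    if s == 0:
        return 1.0 if c == 0 else 0.0
    lt = lam * t
    if lt == 0:
        return 1.0 if c == s else 0.0
    alpha = lt / (1.0 + lt)
    total = 0.0
    for j in range(min(s, c) + 1):
        term = (
            np.exp(_log_comb(s, j) + _log_comb(s + c - j - 1, s - 1))
            * alpha ** (s + c - 2 * j)
            * (1.0 - 2.0 * alpha) ** j
        )
        total += term
    return float(max(total, 0.0))


def transition_matrix(lam: float, t: float, max_count: int) -> np.ndarray:
    """(max_count+1) x (max_count+1) matrix P[s, c] of transition probabilities.

    Computed by s-fold convolution of the single-copy distribution
    (P(0|1) = alpha, P(c|1) = (1-alpha)^2 alpha^(c-1)): the copies of a
    family evolve independently, so the s-copy transition law is the s-fold
    convolution of the 1-copy law.  Truncation to c <= max_count is exact
    for the retained entries.
    """
    N = max_count
    lt = lam * t
    if lt == 0:
        return np.eye(N + 1)
    alpha = lt / (1.0 + lt)
    row1 = np.empty(N + 1)
    row1[0] = alpha
    row1[1:] = (1.0 - alpha) ** 2 * alpha ** np.arange(N)
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = 1.0
    P[1] = row1
    for s in range(2, N + 1):
        P[s] = np.convolve(P[s - 1], row1)[: N + 1]
    return P


def discrete_gamma_categories(shape: float, k: int) -> np.ndarray:
    """K equal-probability mean-one rate multipliers from Gamma(shape, shape).

    Category rates are the conditional means of the gamma distribution within
    its K probability quantile bands, so the multipliers average exactly 1.
    """
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    # cut points of Gamma(shape, rate=shape)
    probs = np.arange(1, k) / k
    cuts = stats.gamma.ppf(probs, a=shape, scale=1.0 / shape)
    cdf_plus = gammainc(shape + 1, np.concatenate([[0.0], cuts * shape, [np.inf]])[:-1])
    upper = gammainc(shape + 1, np.concatenate([cuts * shape, [np.inf]]))
    return k * (upper - cdf_plus)


# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class BDModelSpec:
    """A birth-death model variant on a fixed tree.

    ``branch_class_map`` maps edge keys (see :func:`edge_key`) to rate-class
    indices; absent keys default to class 0.  ``lambdas`` holds one rate per
    class.  ``gamma_shape``/``n_categories`` switch on among-family discrete
    gamma rate variation; ``epsilon`` is the symmetric +/-1 tip observation
    error probability.
    """

    lambdas: tuple[float, ...] = (0.5,)
    branch_class_map: Mapping[str, int] = field(default_factory=dict)
    gamma_shape: float | None = None
    n_categories: int = 1
    epsilon: float = 0.0
    max_count: int = 50

    def __post_init__(self) -> None:
        if any(l < 0 for l in self.lambdas):
            raise ValueError("rates must be non-negative")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        if self.n_categories > 1 and (self.gamma_shape is None or self.gamma_shape <= 0):
            raise ValueError("gamma model needs a positive shape")

    @property
    def n_classes(self) -> int:
        return max(self.branch_class_map.values(), default=0) + 1

    @property
    def n_params(self) -> int:
        n = len(self.lambdas)
        if self.n_categories > 1:
            n += 1
        return n


def edge_key(node: dendropy.Node) -> str:
    """Stable identifier for the edge above ``node``: taxon or node label."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


def _prepare_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Label unlabeled internal nodes deterministically (postorder index)."""
    i = 0
    for node in tree.postorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"node{i}"
        i += 1
    return tree


def _tip_likelihoods(
    counts: np.ndarray, max_count: int, epsilon: float
) -> np.ndarray:
    """(F, N+1) conditional observation likelihoods P(observed | true)."""
    F = counts.shape[0]
    N = max_count
    L = np.zeros((F, N + 1))
    idx = np.arange(F)
    if epsilon == 0.0:
        L[idx, counts] = 1.0
        return L
    L[idx, counts] = 1.0 - epsilon
    # observed = true + 1  -> true = observed - 1
    lower = counts - 1
    ok = lower >= 0
    L[idx[ok], lower[ok]] += epsilon / 2.0
    # observed = true - 1 (clamped at 0) -> true = observed + 1; and for
    # true = 0 the clamp maps the "down" move back onto observed 0
    upper = counts + 1
    ok = upper <= N
    L[idx[ok], upper[ok]] += epsilon / 2.0
    L[idx[counts == 0], 0] += epsilon / 2.0
    return L


def family_loglik(
    tree: dendropy.Tree,
    counts: pd.DataFrame,
    spec: BDModelSpec,
    return_per_family: bool = False,
):
    """Log-likelihood of a family x species count matrix under ``spec``.

    Pruning over the species tree with truncation at ``spec.max_count``; the
    root prior is uniform over 1..max observed count.  With K > 1 gamma
    categories the per-family likelihood averages over the K equal-probability
    mean-one rate multipliers.  If truncation leaks probability mass
    (> 1e-6 in the boundary state), the bound is doubled automatically with
    a warning.
    """
    tree = _prepare_tree(tree)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(taxa) - set(counts.columns)
    if missing:
        raise ValueError(f"counts missing species {sorted(missing)}")
    obs = counts[taxa].to_numpy(dtype=int)
    max_obs = int(obs.max())
    N = max(spec.max_count, max_obs)

    while True:
        per_family, leaked = _loglik_at_truncation(tree, obs, spec, N, max_obs)
        if not leaked:
            break
        warnings.warn(
            f"truncation bound {N} leaks probability mass; doubling to {2 * N}"
        )
        N *= 2
    lnL = float(np.sum(np.log(per_family)))
    if return_per_family:
        return lnL, per_family
    return lnL


def _loglik_at_truncation(tree, obs, spec, N, max_obs):
    F = obs.shape[0]
    cats = (
        discrete_gamma_categories(spec.gamma_shape, spec.n_categories)
        if spec.n_categories > 1
        else np.ones(1)
    )
    taxon_index = {}
    i = 0
    for leaf in tree.leaf_node_iter():
        taxon_index[leaf.taxon.label] = i
        i += 1

    root_max = max(max_obs, 1)
    prior = np.zeros(N + 1)
    prior[1 : root_max + 1] = 1.0 / root_max

    fam_lik = np.zeros(F)
    leaked = False
    for g, weight in zip(cats, np.full(len(cats), 1.0 / len(cats))):
        # per-edge transition matrices for this category
        P_cache: dict[tuple[float, float], np.ndarray] = {}
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                col = obs[:, taxon_index[node.taxon.label]]
                partials[id(node)] = _tip_likelihoods(col, N, spec.epsilon)
            else:
                acc = None
                for child in node.child_nodes():
                    t = child.edge.length or 0.0
                    cls = spec.branch_class_map.get(edge_key(child), 0)
                    lam = spec.lambdas[cls] * g
                    key = (lam, t)
                    if key not in P_cache:
                        P = transition_matrix(lam, t, N)
                        if lam * t > 0 and P[min(max_obs, N), N] > 1e-6:
                            leaked = True
                        P_cache[key] = P
                    msg = partials.pop(id(child)) @ P_cache[key].T
                    acc = msg if acc is None else acc * msg
                partials[id(node)] = acc
        root_partial = partials[id(tree.seed_node)]
        fam_lik += weight * (root_partial @ prior)
    return fam_lik, leaked


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one birth-death model variant."""

    spec: BDModelSpec
    lnL: float
    mle: dict[str, float]
    n_params: int
    restart_lnls: list[float]
    converged: bool = True


def fit_model(
    tree: dendropy.Tree,
    counts: pd.DataFrame,
    spec_template: BDModelSpec,
    n_starts: int = 5,
    seed: int = 0,
) -> ModelFit:
    """Maximise the pruning likelihood over free rates (and gamma shape).

    Free parameters: one lambda per branch class in the template, plus the
    gamma shape when K > 1; all searched on the log scale with Nelder-Mead
    from ``n_starts`` random log-uniform starting points in [0.01, 3].
    """
    if counts.shape[0] < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    n_classes = spec_template.n_classes
    has_shape = spec_template.n_categories > 1
    n_free = n_classes + (1 if has_shape else 0)

    def build(params: np.ndarray) -> BDModelSpec:
        lam = tuple(np.exp(params[:n_classes]))
        shape = float(np.exp(params[n_classes])) if has_shape else None
        return replace(spec_template, lambdas=lam, gamma_shape=shape)

    def nll(params: np.ndarray) -> float:
        if np.any(params > 6) or np.any(params < -12):
            return 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return -family_loglik(tree, counts, build(params))

    best = None
    restart_lnls = []
    for _ in range(n_starts):
        x0 = np.log(rng.uniform(0.01, 3.0, size=n_free))
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
        restart_lnls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed to converge in all restarts")
    spec = build(best.x)
    mle = {f"lambda_{i}": spec.lambdas[i] for i in range(n_classes)}
    if has_shape:
        mle["gamma_shape"] = spec.gamma_shape
    return ModelFit(
        spec=spec,
        lnL=-float(best.fun),
        mle=mle,
        n_params=spec.n_params,
        restart_lnls=restart_lnls,
        converged=bool(best.success),
    )


def lrt(lnL_null: float, lnL_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested models against chi-squared(df).

    statistic = 2 (lnL_alt - lnL_null); negative statistics (numerical
    artifacts of the nested optimisation) are clipped at 0 with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    statistic = 2.0 * (lnL_alt - lnL_null)
    if statistic < 0:
        warnings.warn("alternative lnL below null; clipping LRT statistic at 0")
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df))
    return statistic, p


# ---------------------------------------------------------------------------
# Ancestral counts and branch calls


def _map_ancestral_counts(
    tree: dendropy.Tree, obs_row: np.ndarray, taxon_index: Mapping[str, int],
    spec: BDModelSpec, N: int, root_max: int, gamma_mult: float = 1.0,
) -> dict[str, int]:
    """Max-product (Viterbi) ancestral copy numbers for one family."""
    up: dict[int, np.ndarray] = {}
    back: dict[int, dict[int, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = _tip_likelihoods(
                np.array([obs_row[taxon_index[node.taxon.label]]]), N, spec.epsilon
            )[0]
            up[id(node)] = v
        else:
            acc = np.ones(N + 1)
            back[id(node)] = {}
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                cls = spec.branch_class_map.get(edge_key(child), 0)
                P = transition_matrix(spec.lambdas[cls] * gamma_mult, t, N)
                scores = P * up[id(child)][None, :]  # parent x child-state
                best_child = np.argmax(scores, axis=1)
                acc = acc * scores[np.arange(N + 1), best_child]
                back[id(node)][id(child)] = best_child
            up[id(node)] = acc

    prior = np.zeros(N + 1)
    prior[1 : root_max + 1] = 1.0 / root_max
    root = tree.seed_node
    assignment: dict[str, int] = {}
    root_state = int(np.argmax(up[id(root)] * prior))
    states = {id(root): root_state}
    for node in tree.preorder_node_iter():
        if node is root:
            assignment[edge_key(node) or "root"] = root_state
            continue
        parent_state = states[id(node.parent_node)]
        st = int(back[id(node.parent_node)][id(node)][parent_state])
        states[id(node)] = st
        assignment[edge_key(node)] = st
    return assignment


def branch_changes(
    fit: ModelFit,
    tree: dendropy.Tree,
    counts: pd.DataFrame,
    n_null_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-family significance and per-branch expansion/contraction calls.

    A family's p-value is the fraction of ``n_null_sims`` families simulated
    under the fitted model whose deviance (-log per-family likelihood) is at
    least the observed family's, with an add-one correction.  Branch calls on
    significant families are the sign of the max-product ancestral count
    difference (child - parent).
    """
    if n_null_sims < 100:
        warnings.warn("fewer than 100 null simulations: p-values are unstable")
    tree = _prepare_tree(tree)
    spec = fit.spec
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    obs = counts[taxa].to_numpy(dtype=int)
    max_obs = int(obs.max())
    N = max(spec.max_count, max_obs)
    root_max = max(max_obs, 1)
    taxon_index = {t: i for i, t in enumerate(taxa)}

    _, fam_lik = family_loglik(tree, counts, spec, return_per_family=True)
    obs_dev = -np.log(fam_lik)

    rng = np.random.default_rng(seed)
    null_counts = _simulate_null_families(tree, spec, n_null_sims, root_max, rng)
    null_df = pd.DataFrame(null_counts, columns=taxa)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, null_lik = family_loglik(tree, null_df, spec, return_per_family=True)
    null_dev = -np.log(null_lik)

    rows = []
    cats = (
        discrete_gamma_categories(spec.gamma_shape, spec.n_categories)
        if spec.n_categories > 1
        else np.ones(1)
    )
    for f, family in enumerate(counts.index):
        p = (1.0 + np.sum(null_dev >= obs_dev[f])) / (1.0 + len(null_dev))
        significant = p < alpha
        if significant:
            # most supported gamma category for this family
            if len(cats) > 1:
                per_cat = []
                for g in cats:
                    spec_g = replace(spec, lambdas=tuple(l * g for l in spec.lambdas),
                                     gamma_shape=None, n_categories=1)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, lik_g = family_loglik(
                            tree, counts.iloc[[f]], spec_g, return_per_family=True
                        )
                    per_cat.append(lik_g[0])
                g_best = cats[int(np.argmax(per_cat))]
            else:
                g_best = 1.0
            anc = _map_ancestral_counts(
                tree, obs[f], taxon_index, spec, N, root_max, g_best
            )
            node_states = anc
        else:
            node_states = None
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            key = edge_key(node)
            if node_states is None:
                call = "none"
            else:
                parent_key = edge_key(node.parent_node) or "root"
                delta = node_states[key] - node_states[parent_key]
                call = "expansion" if delta > 0 else (
                    "contraction" if delta < 0 else "none"
                )
            rows.append(
                {"family": family, "branch": key, "p_value": p,
                 "significant": significant, "call": call}
            )
    return pd.DataFrame(rows)


def _simulate_null_families(tree, spec, n, root_max, rng):
    """Forward-sample families under the fitted model via transition rows."""
    cats = (
        discrete_gamma_categories(spec.gamma_shape, spec.n_categories)
        if spec.n_categories > 1
        else np.ones(1)
    )
    N = spec.max_count
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    out = np.zeros((n, len(taxa)), dtype=int)
    cat_idx = rng.integers(0, len(cats), size=n)
    P_cache: dict[tuple[float, float], np.ndarray] = {}
    for i in range(n):
        g = cats[cat_idx[i]]
        state = {id(tree.seed_node): int(rng.integers(1, root_max + 1))}
        tip_vals = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            t = node.edge.length or 0.0
            cls = spec.branch_class_map.get(edge_key(node), 0)
            lam = spec.lambdas[cls] * g
            key = (lam, t)
            if key not in P_cache:
                P_cache[key] = transition_matrix(lam, t, N)
            parent = state[id(node.parent_node)]
            row = P_cache[key][min(parent, N)]
            s = int(rng.choice(N + 1, p=row / row.sum()))
            state[id(node)] = s
            if node.is_leaf():
                tip_vals[node.taxon.label] = s
        out[i] = [tip_vals[t] for t in taxa]
    return out


# ---------------------------------------------------------------------------
# Species-overlap duplications


@dataclass(frozen=True)
class DuplicationCall:
    node_id: str
    support: float
    is_duplication: bool


def species_overlap_duplications(
    gene_tree: dendropy.Tree,
    tip_to_species: Mapping[str, str],
) -> list[DuplicationCall]:
    """Call duplication nodes on a gene tree by species-set overlap.

    For an internal node with child-clade species sets S1 and S2, support is
    the Jaccard index |S1 & S2| / |S1 | S2|; the node is a duplication when
    support >= 0.5 (at least half the species under the node retained both
    copies).
    """
    gene_tree = _prepare_tree(gene_tree)
    for leaf in gene_tree.leaf_node_iter():
        if leaf.taxon.label not in tip_to_species:
            raise ValueError(f"tip {leaf.taxon.label!r} has no species mapping")
    species_below: dict[int, frozenset] = {}
    calls = []
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            species_below[id(node)] = frozenset({tip_to_species[node.taxon.label]})
            continue
        children = node.child_nodes()
        sets = [species_below[id(ch)] for ch in children]
        species_below[id(node)] = frozenset().union(*sets)
        if len(children) != 2:
            raise ValueError("gene tree must be binary at internal nodes")
        s1, s2 = sets
        union = s1 | s2
        support = len(s1 & s2) / len(union) if union else 0.0
        calls.append(
            DuplicationCall(
                node_id=edge_key(node) or "root",
                support=support,
                is_duplication=support >= 0.5,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Model / Results objects


class BirthDeathFamilyModel:
    """Gene-family-size evolution model bound to a tree and count matrix.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted ultrametric species tree with branch lengths.
    counts : pandas.DataFrame
        Families x species copy-number matrix; columns must cover the tree's
        tips.
    """

    def __init__(self, tree: dendropy.Tree, counts: pd.DataFrame):
        self.tree = _prepare_tree(tree)
        taxa = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = taxa - set(counts.columns)
        if missing:
            raise ValueError(f"count matrix missing species {sorted(missing)}")
        self.counts = counts

    @classmethod
    def from_files(cls, tree_path: str, counts_path: str) -> "BirthDeathFamilyModel":
        tree = dendropy.Tree.get(path=tree_path, schema="newick")
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        return cls(tree, counts)

    def spec(
        self,
        variant: str = "global",
        n_categories: int = 3,
        branch_class_map: Mapping[str, int] | None = None,
        epsilon: float = 0.0,
        max_count: int | None = None,
    ) -> BDModelSpec:
        """Build a model-variant template: 'global', 'gamma' or 'multi'."""
        max_obs = int(self.counts.to_numpy().max())
        mc = max_count if max_count is not None else max(20, 2 * max_obs + 5)
        if variant == "global":
            return BDModelSpec(lambdas=(0.5,), max_count=mc, epsilon=epsilon)
        if variant == "gamma":
            return BDModelSpec(
                lambdas=(0.5,), gamma_shape=1.0, n_categories=n_categories,
                max_count=mc, epsilon=epsilon,
            )
        if variant == "multi":
            if not branch_class_map:
                raise ValueError("multi-lambda variant needs a branch_class_map")
            n_cls = max(branch_class_map.values()) + 1
            return BDModelSpec(
                lambdas=(0.5,) * n_cls, branch_class_map=dict(branch_class_map),
                max_count=mc, epsilon=epsilon,
            )
        raise ValueError(f"unknown variant {variant!r}")

    def fit(
        self,
        spec: BDModelSpec | str = "global",
        n_starts: int = 5,
        seed: int = 0,
        **spec_kwargs,
    ) -> "BirthDeathFamilyResults":
        if isinstance(spec, str):
            spec = self.spec(spec, **spec_kwargs)
        fit = fit_model(self.tree, self.counts, spec, n_starts=n_starts, seed=seed)
        return BirthDeathFamilyResults(self, fit)

    def loglik(self, spec: BDModelSpec) -> float:
        return family_loglik(self.tree, self.counts, spec)


class BirthDeathFamilyResults:
    """Fitted birth-death family-size model."""

    def __init__(self, model: BirthDeathFamilyModel, fit: ModelFit):
        self.model = model
        self.fit_ = fit

    @property
    def lnL(self) -> float:
        return self.fit_.lnL

    @property
    def params(self) -> dict[str, float]:
        return dict(self.fit_.mle)

    @property
    def n_params(self) -> int:
        return self.fit_.n_params

    def compare(self, other: "BirthDeathFamilyResults") -> tuple[float, float]:
        """LRT of self (null) against a richer alternative ``other``."""
        df = other.n_params - self.n_params
        return lrt(self.lnL, other.lnL, max(df, 1))

    def branch_changes(
        self, n_null_sims: int = 1000, alpha: float = 0.05, seed: int = 0
    ) -> pd.DataFrame:
        return branch_changes(
            self.fit_, self.model.tree, self.model.counts,
            n_null_sims=n_null_sims, alpha=alpha, seed=seed,
        )

    def summary(self) -> str:
        lines = [
            "Birth-death gene family size model",
            "=" * 42,
            f"families: {self.model.counts.shape[0]}",
            f"species:  {self.model.counts.shape[1]}",
            f"lnL:      {self.lnL:.3f}",
            f"params:   {self.n_params}",
        ]
        for name, value in self.fit_.mle.items():
            lines.append(f"  {name:<14s} {value:.4f}")
        if len(self.fit_.restart_lnls) > 1:
            spread = max(self.fit_.restart_lnls) - min(self.fit_.restart_lnls)
            lines.append(f"restart lnL spread: {spread:.4g}")
        return "\n".join(lines)
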