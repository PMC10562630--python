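"""AMP probability prediction from physicochemical peptide features.

Antimicrobial peptides are short, cationic and amphipathic; those properties
separate them well from background proteome sequences.  Each peptide is
summarised by length, amino-acid composition, net charge at pH 7, isoelectric
point, mean Kyte-Doolittle hydrophobicity, cysteine fraction and molecular
weight, and an L2-regularised logistic regression on the standardised
features yields an AMP probability.  Calls are made at a strict probability
threshold (0.7 for candidate retention, 0.8 for final positive sets).

Negative training sets are sampled from a background pool so their length
histogram matches the positives', preventing the model from learning length
alone.

All constants (pKa set, hydrophobicity scale, residue masses) are pinned
here so features are reproducible to the bit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .curation import STANDARD_AA, PeptideRecord

__all__ = [
    "FeatureVector",
    "ConfusionCounts",
    "MetricsReport",
    "extract_features",
    "feature_matrix",
    "match_length_distribution",
    "train_classifier",
    "predict_amp_probability",
    "confusion_metrics",
    "AmpClassifier",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Ionisable-group pKa values (Lehninger free-residue set).
PKA_POSITIVE = {"nterm": 9.69, "K": 10.53, "R": 12.48, "H": 6.00}
PKA_NEGATIVE = {"cterm": 2.34, "D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.07}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Average masses of the free amino acids (Da); a peptide of n residues loses
# (n - 1) waters on condensation.
AA_MASS = {
    "A": 89.0932, "R": 174.2010, "N": 132.1179, "D": 133.1027,
    "C": 121.1582, "E": 147.1293, "Q": 146.1445, "G": 75.0666,
    "H": 155.1546, "I": 131.1729, "L": 131.1729, "K": 146.1876,
    "M": 149.2113, "F": 165.1891, "P": 115.1305, "S": 105.0926,
    "T": 119.1192, "W": 204.2252, "Y": 181.1885, "V": 117.1463,
}
WATER_MASS = 18.01528


@dataclass(frozen=True)
class FeatureVector:
    """Physicochemical descriptors of one peptide."""

    length: int
    aa_composition: tuple[float, ...]  # fractions in AA_ORDER
    net_charge_pH7: float
    isoelectric_point: float
    mean_hydrophobicity: float
    cysteine_fraction: float
    molecular_weight: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.length, *self.aa_composition, self.net_charge_pH7,
             self.isoelectric_point, self.mean_hydrophobicity,
             self.cysteine_fraction, self.molecular_weight]
        )

    @staticmethod
    def feature_names() -> list[str]:
        return (
            ["length"]
            + [f"frac_{a}" for a in AA_ORDER]
            + ["net_charge_pH7", "isoelectric_point", "mean_hydrophobicity",
               "cysteine_fraction", "molecular_weight"]
        )


def net_charge(sequence: str, pH: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge including termini."""
    charge = 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["cterm"] - pH))
    for aa, pka in PKA_POSITIVE.items():
        if aa != "nterm":
            charge += sequence.count(aa) / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in PKA_NEGATIVE.items():
        if aa != "cterm":
            charge -= sequence.count(aa) / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def extract_features(record: PeptideRecord | str) -> FeatureVector:
    """Compute the pinned physicochemical descriptor set for one peptide."""
    seq = record if isinstance(record, str) else record.sequence
    seq = seq.upper().rstrip("*")
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= STANDARD_AA:
        bad = sorted(set(seq) - STANDARD_AA)
        raise ValueError(f"nonstandard residues {bad} in sequence")
    n = len(seq)
    comp = tuple(seq.count(a) / n for a in AA_ORDER)
    mw = sum(AA_MASS[a] for a in seq) - (n - 1) * WATER_MASS
    return FeatureVector(
        length=n,
        aa_composition=comp,
        net_charge_pH7=net_charge(seq, 7.0),
        isoelectric_point=isoelectric_point(seq),
        mean_hydrophobicity=sum(KYTE_DOOLITTLE[a] for a in seq) / n,
        cysteine_fraction=seq.count("C") / n,
        molecular_weight=mw,
    )


def feature_matrix(records: Sequence[PeptideRecord | str]) -> np.ndarray:
    return np.vstack([extract_features(r).to_array() for r in records])


def match_length_distribution(
    positives: Sequence[PeptideRecord],
    negative_pool: Sequence[PeptideRecord],
    n_bins: int = 20,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Sample negatives whose length histogram matches the positives'.

    Lengths are binned into ``n_bins`` equal-width bins over the positives'
    length range; for each bin, the positives' count is sampled without
    replacement from pool members falling in that bin.  When a bin runs
    short, the shortfall is drawn from the nearest bins (smallest bin
    distance first, then leftmost).  Deterministic given ``seed``.
    """
    if not negative_pool:
        raise ValueError("negative pool is empty")
    if len(negative_pool) < len(positives):
        raise ValueError("negative pool smaller than the positive set")
    rng = np.random.default_rng(seed)
    pos_lengths = np.array([len(p.sequence) for p in positives])
    lo, hi = pos_lengths.min(), pos_lengths.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    # np.digitize with right-closed final bin
    def bin_of(length: int) -> int:
        b = int(np.searchsorted(edges, length, side="right")) - 1
        return min(max(b, 0), n_bins - 1)

    target = np.zeros(n_bins, dtype=int)
    for L in pos_lengths:
        target[bin_of(L)] += 1
    pool_bins: list[list[int]] = [[] for _ in range(n_bins)]
    overflow: list[int] = []  # lengths outside the positives' range: last resort
    for idx, rec in enumerate(negative_pool):
        L = len(rec.sequence)
        if lo <= L <= hi:
            pool_bins[bin_of(L)].append(idx)
        else:
            overflow.append(idx)
    for b in range(n_bins):
        rng.shuffle(pool_bins[b])
    rng.shuffle(overflow)

    chosen: list[int] = []
    deficit = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        take = min(target[b], len(pool_bins[b]))
        chosen.extend(pool_bins[b][:take])
        pool_bins[b] = pool_bins[b][take:]
        deficit[b] = target[b] - take
    for b in np.flatnonzero(deficit):
        need = deficit[b]
        for dist in range(1, n_bins):
            for nb in (b - dist, b + dist):
                if need == 0 or not (0 <= nb < n_bins):
                    continue
                take = min(need, len(pool_bins[nb]))
                chosen.extend(pool_bins[nb][:take])
                pool_bins[nb] = pool_bins[nb][take:]
                need -= take
            if need == 0:
                break
        if need > 0:
            chosen.extend(overflow[:need])
            overflow = overflow[need:]
    return [negative_pool[i] for i in chosen]


def train_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    seed: int = 0,
    C: float = 1.0,
) -> "AmpClassifier":
    """Fit the L2 logistic model on standardised features; seeded, deterministic."""
    model = AmpClassifier(C=C, seed=seed)
    model._fit_matrix(np.asarray(features, dtype=float), np.asarray(labels))
    return model


def predict_amp_probability(
    model: "AmpClassifier",
    records: Sequence[PeptideRecord | str] | np.ndarray,
    threshold: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """AMP probabilities plus strict-threshold calls (probability > threshold)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(records, np.ndarray):
        X = records
    else:
        X = feature_matrix(records)
    probs = model.predict_proba_matrix(X)
    return probs, probs > threshold


class AmpClassifier:
    """L2-regularised logistic regression over the pinned feature set.

    The reference AMP probability model: deterministic given its seed, and
    serialisable to versioned JSON (feature schema + scaler + coefficients)
    so trained models can be shipped as text.
    """

    SCHEMA_VERSION = 1

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._mean: np.ndarray | None = None
        self._scale: np.ndarray | None = None
        self._lr: LogisticRegression | None = None

    # -- fitting ---------------------------------------------------------
    def _fit_matrix(self, X: np.ndarray, y: np.ndarray) -> "AmpClassifier":
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        self._mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self._scale = scale
        Z = (X - self._mean) / self._scale
        self._lr = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=2000, random_state=self.seed,
        )
        self._lr.fit(Z, y)
        return self

    def fit(
        self, records: Sequence[PeptideRecord | str], labels: Sequence[int]
    ) -> "AmpClassifier":
        return self._fit_matrix(feature_matrix(records), np.asarray(labels))

    # -- prediction ------------------------------------------------------
    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        if self._lr is None:
            raise ValueError("model is not fitted")
        Z = (np.asarray(X, dtype=float) - self._mean) / self._scale
        return self._lr.predict_proba(Z)[:, 1]

    def predict_proba(self, records: Sequence[PeptideRecord | str]) -> np.ndarray:
        return self.predict_proba_matrix(feature_matrix(records))

    def predict(
        self, records: Sequence[PeptideRecord | str], threshold: float = 0.7
    ) -> np.ndarray:
        return self.predict_proba(records) > threshold

    # -- persistence -----------------------------------------------------
    def to_json(self) -> str:
        if self._lr is None:
            raise ValueError("model is not fitted")
        payload = {
            "schema_version": self.SCHEMA_VERSION,
            "feature_names": FeatureVector.feature_names(),
            "C": self.C,
            "seed": self.seed,
            "scaler_mean": self._mean.tolist(),
            "scaler_scale": self._scale.tolist(),
            "coef": self._lr.coef_.tolist(),
            "intercept": self._lr.intercept_.tolist(),
            "classes": self._lr.classes_.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AmpClassifier":
        payload = json.loads(text)
        if payload.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        model = cls(C=payload["C"], seed=payload["seed"])
        model._mean = np.array(payload["scaler_mean"])
        model._scale = np.array(payload["scaler_scale"])
        lr = LogisticRegression(C=model.C, solver="lbfgs")
        lr.coef_ = np.array(payload["coef"])
        lr.intercept_ = np.array(payload["intercept"])
        lr.classes_ = np.array(payload["classes"])
        model._lr = lr
        return model


# ---------------------------------------------------------------------------
# Confusion metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("empty confusion table")


@dataclass(frozen=True)
class MetricsReport:
    """Classification performance, every field a percentage in [0, 100]."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    precision: float
    recall: float
    f1: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding only; stored values keep full precision."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Standard confusion-matrix rates, reported as percentages.

    f1 is the harmonic mean of precision and recall; balanced accuracy is
    the arithmetic mean of sensitivity and specificity.  Undefined ratios
    (zero denominators) are reported as NaN with a warning.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("a true class is empty; dependent rates will be NaN")
    total = tp + fp + fn + tn
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    ppv = _ratio(tp, tp + fp, "ppv")
    npv = _ratio(tn, tn + fn, "npv")
    if math.isnan(ppv) or math.isnan(sens) or (ppv + sens) == 0:
        warnings.warn("f1 undefined; reporting NaN")
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return MetricsReport(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        ppv=100.0 * ppv,
        npv=100.0 * npv,
        precision=100.0 * ppv,
        recall=100.0 * sens,
        f1=100.0 * f1,
        prevalence=100.0 * (tp + fn) / total,
        detection_rate=100.0 * tp / total,
        detection_prevalence=100.0 * (tp + fp) / total,
        balanced_accuracy=100.0 * 0.5 * (sens + spec),
    )


def f1_from_rates(precision_pct: float, recall_pct: float) -> float:
    """F1 (%) from precision and recall given as percentages."""
    if precision_pct + recall_pct == 0:
        return math.nan
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def balanced_accuracy_from_rates(sensitivity_pct: float, specificity_pct: float) -> float:
    """Balanced accuracy (%) from sensitivity and specificity percentages."""
    return 0.5 * (sensitivity_pct + specificity_pct)
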