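"""Value-of-information analysis over ensemble trial outcomes.

Which kinetic rate constants most determine whether a supplementation trial
comes out beneficial?  A gradient-boosted decision-tree classifier is
trained to predict the beneficial label from the 18 log10 rate constants;
Friedman's relative influence (normalized per-feature sum of squared-error
split improvements) ranks the parameters, and enrichment analyses quantify
how restricting the ensemble — by classifier prediction or by a threshold
on a single parameter — concentrates beneficial outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "LabeledEnsemble", "ClassifierConfig", "InfluenceReport", "TestMetrics",
    "EnrichmentResult",
    "split_train_test", "train_classifier", "relative_influence",
    "test_metrics", "enrichment", "conditional_threshold_analysis",
]


@dataclass
class LabeledEnsemble:
    """Feature matrix (n x p, log10 parameter values) with binary labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        self.features = np.asarray(self.features, float)
        self.labels = np.asarray(self.labels, bool)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must align")
        if np.any(~np.isfinite(self.features)):
            raise ValueError("features contain missing/non-finite values")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names must match feature count")

    def __len__(self):
        return self.labels.size

    @property
    def label_counts(self) -> tuple[int, int]:
        pos = int(self.labels.sum())
        return (len(self) - pos, pos)

    def subset(self, idx) -> "LabeledEnsemble":
        return LabeledEnsemble(self.features[idx], self.labels[idx],
                               self.feature_names)

    @classmethod
    def from_records(cls, records, network) -> "LabeledEnsemble":
        """Log10 parameter matrix and beneficial labels from ensemble records."""
        names = tuple(network.parameter_names)
        X = np.log10([[rec.values[n] for n in names] for rec in records])
        y = np.array([rec.outcome == "beneficial" for rec in records])
        return cls(X, y, names)


@dataclass(frozen=True)
class ClassifierConfig:
    """Gradient-boosted tree settings (shallow trees, logistic loss)."""

    n_estimators: int = 300
    max_depth: int = 3
    learning_rate: float = 0.1
    class_weighted: bool = True
    threshold: float = 0.5


def split_train_test(ensemble: LabeledEnsemble, train_fraction: float = 0.70,
                     rng: np.random.Generator | int = 0
                     ) -> tuple[LabeledEnsemble, LabeledEnsemble]:
    """Stratified, disjoint, exhaustive train/test split.

    The train size is floor(train_fraction * n) (so 502 points at 70% give
    351 train / 151 test).  Raises if stratification leaves a class absent
    from either side.
    """
    if len(ensemble) < 10:
        raise ValueError("need at least 10 records to split")
    seed = (int(rng.integers(2**31)) if isinstance(rng, np.random.Generator)
            else int(rng))
    idx = np.arange(len(ensemble))
    try:
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, stratify=ensemble.labels,
            random_state=seed)
    except ValueError as exc:
        raise ValueError(f"stratified split failed: {exc}") from exc
    train, test = ensemble.subset(train_idx), ensemble.subset(test_idx)
    for name, part in (("train", train), ("test", test)):
        if part.label_counts[0] == 0 or part.label_counts[1] == 0:
            raise ValueError(f"stratification left a class absent from {name}")
    return train, test


def train_classifier(train: LabeledEnsemble,
                     config: ClassifierConfig | None = None,
                     rng: np.random.Generator | int = 0
                     ) -> GradientBoostingClassifier:
    """Fit the boosted-tree classifier predicting beneficial outcomes.

    Class imbalance (beneficial sets are rare, ~4%) is handled by balanced
    sample weights unless disabled in the config.
    """
    config = config or ClassifierConfig()
    if train.label_counts[0] == 0 or train.label_counts[1] == 0:
        raise ValueError("training data contains a single class")
    seed = (int(rng.integers(2**31)) if isinstance(rng, np.random.Generator)
            else int(rng))
    model = GradientBoostingClassifier(
        n_estimators=config.n_estimators, max_depth=config.max_depth,
        learning_rate=config.learning_rate, random_state=seed)
    weights = None
    if config.class_weighted:
        n0, n1 = train.label_counts
        n = n0 + n1
        weights = np.where(train.labels, n / (2.0 * n1), n / (2.0 * n0))
    model.fit(train.features, train.labels.astype(int), sample_weight=weights)
    model._trialvoi_feature_names = train.feature_names
    model._trialvoi_threshold = config.threshold
    return model


@dataclass
class InfluenceReport:
    """Relative influence per parameter, normalized to sum to 100%."""

    feature_names: tuple[str, ...]
    influence_pct: np.ndarray

    def __post_init__(self):
        self.influence_pct = np.asarray(self.influence_pct, float)

    def ranked(self) -> list[tuple[str, float]]:
        order = np.argsort(-self.influence_pct)
        return [(self.feature_names[i], float(self.influence_pct[i]))
                for i in order]

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.ranked()[:k]]

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = [{"parameter": n, "relative_influence_pct": v, "rank": i + 1}
                for i, (n, v) in enumerate(self.ranked())]
        pd.DataFrame(rows).to_csv(path, index=False)


def relative_influence(model: GradientBoostingClassifier) -> InfluenceReport:
    """Friedman split-improvement feature importance, as percentages.

    Sums each feature's squared-error improvement over all splits of all
    trees and normalizes the vector to total 100%.
    """
    importances = getattr(model, "feature_importances_", None)
    if importances is None:
        raise ValueError("model is not fitted")
    importances = np.maximum(importances, 0.0)  # clear float round-off
    total = float(np.sum(importances))
    if total <= 0:
        raise ValueError("model contains no splits; influence undefined")
    names = getattr(model, "_trialvoi_feature_names",
                    tuple(f"x{i}" for i in range(len(importances))))
    return InfluenceReport(tuple(names), 100.0 * importances / total)


@dataclass
class TestMetrics:
    """Confusion counts and rates at the decision threshold."""

    __test__ = False  # pytest: not a test class despite the name

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                "tpr": self.tpr, "fpr": self.fpr}


def predict_positive(model, features: np.ndarray) -> np.ndarray:
    """Boolean predictions at the model's decision threshold (default 0.5)."""
    threshold = getattr(model, "_trialvoi_threshold", 0.5)
    return model.predict_proba(np.asarray(features, float))[:, 1] >= threshold


def test_metrics(model, test: LabeledEnsemble) -> TestMetrics:
    """Confusion counts, TPR and FPR on held-out data."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = predict_positive(model, test.features)
    y = test.labels
    return TestMetrics(tp=int(np.sum(pred & y)), fn=int(np.sum(~pred & y)),
                       fp=int(np.sum(pred & ~y)), tn=int(np.sum(~pred & ~y)))


@dataclass
class EnrichmentResult:
    """Beneficial/harmful composition of a restricted subset vs the full set.

    Fractions are exact rationals on the counts; ``empty`` flags an empty
    subset (all subset fractions are then zero by convention).
    """

    description: str
    subset_size: int
    beneficial_in_subset: int
    harmful_in_subset: int
    total_size: int
    beneficial_total: int
    harmful_total: int
    empty: bool = False

    @property
    def beneficial_fraction(self) -> Fraction:
        return (Fraction(0) if self.empty
                else Fraction(self.beneficial_in_subset, self.subset_size))

    @property
    def harmful_fraction(self) -> Fraction:
        return (Fraction(0) if self.empty
                else Fraction(self.harmful_in_subset, self.subset_size))

    @property
    def overall_beneficial_fraction(self) -> Fraction:
        return Fraction(self.beneficial_total, self.total_size)

    @property
    def overall_harmful_fraction(self) -> Fraction:
        return Fraction(self.harmful_total, self.total_size)

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "subset_size": self.subset_size,
            "beneficial_in_subset": self.beneficial_in_subset,
            "harmful_in_subset": self.harmful_in_subset,
            "beneficial_fraction": float(self.beneficial_fraction),
            "harmful_fraction": float(self.harmful_fraction),
            "total_size": self.total_size,
            "overall_beneficial_fraction": float(self.overall_beneficial_fraction),
            "overall_harmful_fraction": float(self.overall_harmful_fraction),
            "empty": self.empty,
        }


def _count_outcomes(records) -> tuple[int, int]:
    b = sum(1 for r in records if r.outcome == "beneficial")
    h = sum(1 for r in records if r.outcome == "harmful")
    return b, h


def enrichment(records: Sequence, selector: Callable | Sequence[bool],
               description: str = "restricted subset") -> EnrichmentResult:
    """Outcome composition of a restricted subset of ensemble records.

    ``selector`` is either a boolean mask or a predicate over records.
    """
    if callable(selector):
        mask = [bool(selector(r)) for r in records]
    else:
        mask = [bool(m) for m in selector]
        if len(mask) != len(records):
            raise ValueError("selector mask must match the record count")
    subset = [r for r, m in zip(records, mask) if m]
    b_tot, h_tot = _count_outcomes(records)
    b_sub, h_sub = _count_outcomes(subset)
    return EnrichmentResult(
        description=description, subset_size=len(subset),
        beneficial_in_subset=b_sub, harmful_in_subset=h_sub,
        total_size=len(records), beneficial_total=b_tot, harmful_total=h_tot,
        empty=(len(subset) == 0))


def conditional_threshold_analysis(records: Sequence, parameter: str,
                                   threshold: float,
                                   direction: str = "below"
                                   ) -> EnrichmentResult:
    """Enrichment when one parameter is known to lie on one side of a threshold.

    Emulates a perfect pre-trial measurement: restrict the ensemble to sets
    with ``parameter`` below (or above) ``threshold`` and report how the
    beneficial/harmful composition changes.
    """
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    for rec in records:
        if parameter not in rec.values:
            raise ValueError(f"unknown parameter {parameter!r}")
    if direction == "below":
        selector = lambda r: r.values[parameter] < threshold
    else:
        selector = lambda r: r.values[parameter] > threshold
    return enrichment(records, selector,
                      description=f"{parameter} {direction} {threshold:g}")
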