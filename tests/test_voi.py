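"""VOI machinery: splits, boosted trees, influence, metrics, enrichment."""

import numpy as np
import pytest
from scipy import stats

from trialvoi import voi
from trialvoi.ensemble import EnsembleRecord
from trialvoi.fixtures import PlantedEnsembleSpec, planted_ensemble
from trialvoi.voi import (ClassifierConfig, EnrichmentResult, LabeledEnsemble,
                          TestMetrics)


def _toy_separable(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-6, 6, size=(n, 5))
    y = X[:, 2] < 0.0
    return LabeledEnsemble(X, y, tuple(f"P{i}" for i in range(5)))


# --- split -----------------------------------------------------------------

def test_split_sizes_at_70_percent():
    """502 records at 70% train: 351 train / 151 test (floor rule)."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(502, 3))
    y = np.zeros(502, bool)
    y[:30] = True
    ens = LabeledEnsemble(X, y, ("a", "b", "c"))
    train, test = voi.split_train_test(ens, 0.70, rng=1)
    assert len(train) == 351 and len(test) == 151


def test_split_disjoint_exhaustive_stratified():
    ens = _toy_separable(200)
    train, test = voi.split_train_test(ens, 0.70, rng=2)
    assert len(train) + len(test) == 200
    pos_rate = ens.labels.mean()
    assert abs(train.labels.mean() - pos_rate) < 0.05
    assert abs(test.labels.mean() - pos_rate) < 0.05


def test_split_deterministic():
    ens = _toy_separable(100)
    a1, b1 = voi.split_train_test(ens, 0.70, rng=7)
    a2, b2 = voi.split_train_test(ens, 0.70, rng=7)
    assert np.array_equal(a1.features, a2.features)
    assert np.array_equal(b1.labels, b2.labels)


def test_split_rejects_tiny_ensembles():
    ens = _toy_separable(8)
    with pytest.raises(ValueError):
        voi.split_train_test(ens)


# --- classifier ------------------------------------------------------------

def test_separable_toy_reaches_perfect_training_accuracy():
    ens = _toy_separable()
    model = voi.train_classifier(ens, rng=0)
    pred = voi.predict_positive(model, ens.features)
    assert np.array_equal(pred, ens.labels)


def test_single_feature_toy_gets_all_influence():
    ens = _toy_separable()
    model = voi.train_classifier(ens, rng=0)
    report = voi.relative_influence(model)
    assert report.influence_pct[2] > 99.0
    assert report.top(1) == ["P2"]


def test_influence_normalizes_to_100(rng):
    ens = planted_ensemble(PlantedEnsembleSpec(n=300, seed=3))
    model = voi.train_classifier(ens, rng=1)
    report = voi.relative_influence(model)
    assert report.influence_pct.sum() == pytest.approx(100.0, abs=1e-9)
    assert np.all(report.influence_pct >= 0)


def test_permuted_labels_give_chance_level_accuracy():
    """With labels shuffled, held-out accuracy is indistinguishable from the
    majority rate (binomial test at alpha 0.01)."""
    rng = np.random.default_rng(12)
    ens = planted_ensemble(PlantedEnsembleSpec(n=400, positive_fraction=0.3,
                                               seed=5))
    y_perm = rng.permutation(ens.labels)
    shuffled = LabeledEnsemble(ens.features, y_perm, ens.feature_names)
    train, test = voi.split_train_test(shuffled, 0.70, rng=1)
    model = voi.train_classifier(train, ClassifierConfig(n_estimators=150),
                                 rng=2)
    pred = voi.predict_positive(model, test.features)
    accuracy = float(np.mean(pred == test.labels))
    majority = max(test.labels.mean(), 1 - test.labels.mean())
    p = stats.binomtest(int(accuracy * len(test)), len(test),
                        majority).pvalue
    assert p > 0.01 or accuracy <= majority


def test_single_class_training_rejected():
    ens = _toy_separable()
    degenerate = LabeledEnsemble(ens.features,
                                 np.zeros(len(ens), bool), ens.feature_names)
    with pytest.raises(ValueError):
        voi.train_classifier(degenerate)


def test_planted_signal_recovered_in_top_ranks():
    """The 4 planted features should occupy the top 4 influence ranks."""
    hits = 0
    for seed in range(4):
        ens = planted_ensemble(PlantedEnsembleSpec(n=500, seed=seed))
        train, _ = voi.split_train_test(ens, 0.70, rng=seed)
        model = voi.train_classifier(train, rng=seed)
        top4 = set(voi.relative_influence(model).top(4))
        if top4 == {"P00", "P01", "P02", "P03"}:
            hits += 1
    assert hits >= 3


# --- metrics ---------------------------------------------------------------

def test_metrics_perfect_predictor():
    m = TestMetrics(tp=6, fn=0, fp=0, tn=144)
    assert m.tpr == 1.0 and m.fpr == 0.0


def test_metrics_all_negative_predictor():
    m = TestMetrics(tp=0, fn=6, fp=0, tn=144)
    assert m.tpr == 0.0 and m.fpr == 0.0


def test_metrics_published_style_counts():
    """5/6 positives found, 11/144 negatives misflagged: TPR 83%, FPR 8%."""
    m = TestMetrics(tp=5, fn=1, fp=11, tn=133)
    assert m.tpr == pytest.approx(0.833, abs=5e-4)
    assert m.fpr == pytest.approx(0.0764, abs=5e-4)


def test_metrics_computed_from_model():
    ens = _toy_separable()
    train, test = voi.split_train_test(ens, 0.70, rng=1)
    model = voi.train_classifier(train, rng=1)
    m = voi.test_metrics(model, test)
    assert m.tp + m.fn == int(test.labels.sum())
    assert m.fp + m.tn == int((~test.labels).sum())


# --- enrichment ------------------------------------------------------------

def _records(outcomes, param_values=None):
    records = []
    for i, outcome in enumerate(outcomes):
        values = {"R3_k2": param_values[i]} if param_values else {"R3_k2": 1.0}
        rec = EnsembleRecord(id=i, values=values, baseline_residual=0.0)
        rec.outcome = outcome
        records.append(rec)
    return records


def test_enrichment_full_set_equals_overall():
    recs = _records(["beneficial"] * 18 + ["harmful"] * 11
                    + ["insignificant"] * 473)
    res = voi.enrichment(recs, [True] * 502)
    assert res.beneficial_fraction == res.overall_beneficial_fraction
    assert res.subset_size == 502


def test_enrichment_published_style_fractions():
    """15 beneficial of 37 -> 40.5%; 15 of 61 -> 24.6% (exact rationals)."""
    from fractions import Fraction
    recs = _records(["beneficial"] * 15 + ["insignificant"] * 22)
    res = voi.enrichment(recs, [True] * 37)
    assert res.beneficial_fraction == Fraction(15, 37)
    assert round(float(res.beneficial_fraction) * 100) == 41
    recs = _records(["beneficial"] * 15 + ["insignificant"] * 46)
    res = voi.enrichment(recs, [True] * 61)
    assert res.beneficial_fraction == Fraction(15, 61)
    assert round(float(res.beneficial_fraction) * 100) == 25


def test_enrichment_empty_subset_flagged():
    recs = _records(["insignificant"] * 10)
    res = voi.enrichment(recs, [False] * 10)
    assert res.empty and res.beneficial_fraction == 0


def test_threshold_analysis_infinite_threshold_is_full_set():
    recs = _records(["beneficial"] * 3 + ["insignificant"] * 7,
                    param_values=list(range(10)))
    res = voi.conditional_threshold_analysis(recs, "R3_k2", float("inf"),
                                             "below")
    assert res.subset_size == 10


def test_threshold_analysis_excluding_everything_is_empty():
    recs = _records(["beneficial"] * 3 + ["insignificant"] * 7,
                    param_values=list(range(1, 11)))
    res = voi.conditional_threshold_analysis(recs, "R3_k2", 0.0, "below")
    assert res.empty


def test_threshold_analysis_unknown_parameter():
    recs = _records(["beneficial"], param_values=[1.0])
    with pytest.raises(ValueError):
        voi.conditional_threshold_analysis(recs, "nope", 1.0)


def test_threshold_analysis_selects_correct_side():
    recs = _records(["beneficial"] * 5 + ["insignificant"] * 5,
                    param_values=[0.1] * 5 + [100.0] * 5)
    below = voi.conditional_threshold_analysis(recs, "R3_k2", 10.0, "below")
    assert below.subset_size == 5 and below.beneficial_in_subset == 5
    above = voi.conditional_threshold_analysis(recs, "R3_k2", 10.0, "above")
    assert above.beneficial_in_subset == 0


# --- property tests --------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["beneficial", "harmful", "insignificant"]),
                min_size=1, max_size=60),
       st.data())
def test_enrichment_count_identities(outcomes, data):
    """Subset counts never exceed sizes; fractions are exact rationals; a
    superset filter never shrinks the subset."""
    recs = _records(outcomes)
    mask = data.draw(st.lists(st.booleans(), min_size=len(recs),
                              max_size=len(recs)))
    res = voi.enrichment(recs, mask)
    assert res.beneficial_in_subset + res.harmful_in_subset <= res.subset_size
    assert res.subset_size <= res.total_size
    if not res.empty:
        assert res.beneficial_fraction.denominator <= res.subset_size or \
            res.beneficial_fraction == 0
    wider = [m or True for m in mask]
    res_wide = voi.enrichment(recs, wider)
    assert res_wide.subset_size >= res.subset_size
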