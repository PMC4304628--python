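"""Trial simulation: event times, Cox fit, replicates, classification."""

import math

import numpy as np
import pytest
from scipy import stats

from trialvoi import onset, trial
from trialvoi.trial import (NoInformationError, TrialDesign, TrialResult,
                            classify_outcome, cox_fit)


@pytest.fixture(scope="module")
def onset_defaults():
    return onset.OnsetParameters(nu=440.0, mu=3.65e-5, beta=762.2,
                                 delta=762.0, K=4)


@pytest.fixture(scope="module")
def small_design():
    return TrialDesign(n_per_arm=800, n_replicates=2, lag_mean=1.0)


def _models(onset_params, ratio, horizon=7.5):
    base = onset.conditional_onset_model(
        onset_params, onset_params, max_entry_age=74, horizon=horizon)
    supp = onset.conditional_onset_model(
        onset_params, onset_params.with_mutation_rate(onset_params.mu * ratio),
        max_entry_age=74, horizon=horizon)
    return base, supp


# --- Cox fit ---------------------------------------------------------------

def test_cox_two_subject_monotone_likelihood():
    """Treated fails first, control second: L(b) = e^b/(e^b+1), maximized at
    the cap; the score test stays finite."""
    res = cox_fit([1.0, 2.0], [True, True], [1, 0])
    assert res.monotone
    assert res.coef == trial.MONOTONE_COEF_CAP
    assert 0 < res.p_value < 1


def test_cox_matches_lifelines_on_continuous_times():
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd
    rng = np.random.default_rng(11)
    n = 2000
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.15 * np.exp(0.5 * x)))
    e = t < 4.0
    t = np.minimum(t, 4.0)
    ours = cox_fit(t, e, x)
    cph = lifelines.CoxPHFitter().fit(
        pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e")
    assert ours.coef == pytest.approx(cph.params_["x"], abs=1e-5)
    assert ours.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)
    assert ours.p_value == pytest.approx(cph.summary.loc["x", "p"], rel=1e-3)


def test_cox_handles_heavy_ties():
    """Discretized times exercise the Breslow tie handling."""
    rng = np.random.default_rng(4)
    n = 4000
    x = rng.integers(0, 2, n)
    t = np.ceil(rng.exponential(1.0 / (0.3 * np.exp(0.4 * x))))
    e = t < 6
    t = np.minimum(t, 6)
    res = cox_fit(t, e, x)
    assert res.coef == pytest.approx(0.4, abs=0.15)


def test_cox_type_i_error_calibrated():
    """Identical arms reject at ~alpha (quick version of the null check)."""
    rng = np.random.default_rng(5)
    rejections = 0
    n_trials = 300
    for _ in range(n_trials):
        n = 1000
        x = np.repeat([0, 1], n)
        t = rng.exponential(10.0, 2 * n)
        e = t < 5.0
        t = np.minimum(t, 5.0)
        rejections += cox_fit(t, e, x).p_value < 0.05
    assert 0.02 <= rejections / n_trials <= 0.09


def test_cox_planted_hazard_ratio_recovered():
    rng = np.random.default_rng(6)
    coefs = []
    for _ in range(200):
        n = 1500
        x = np.repeat([0, 1], n)
        t = rng.exponential(1.0 / (0.2 * np.exp(math.log(0.7) * x)))
        e = t < 6.0
        t = np.minimum(t, 6.0)
        coefs.append(cox_fit(t, e, x).coef)
    mean = np.mean(coefs)
    se = np.std(coefs, ddof=1) / math.sqrt(len(coefs))
    assert abs(mean - math.log(0.7)) < 3 * se


def test_cox_zero_events_raises():
    with pytest.raises(NoInformationError):
        cox_fit([5.0, 5.0], [False, False], [0, 1])


def test_cox_all_events_in_one_arm_is_monotone():
    times = [1.0, 2.0, 3.0, 5.0, 5.0, 5.0]
    events = [True, True, True, False, False, False]
    x = [1, 1, 1, 0, 0, 0]
    res = cox_fit(times, events, x)
    assert res.monotone and res.coef == trial.MONOTONE_COEF_CAP


# --- event-time generation -------------------------------------------------

def test_zero_hazard_censors_everyone(rng, small_design):
    p = onset.OnsetParameters(nu=1.0, mu=0.0, beta=1.0, delta=1.0, K=4)
    base, supp = _models(p, 1.0)
    res = trial.simulate_trial(small_design, base, supp, rng)
    assert res.events_control == 0 and res.events_supplement == 0


def test_subject_event_time_contract(onset_defaults, rng, small_design):
    base, supp = _models(onset_defaults, 0.5)
    for arm in ("control", "supplement"):
        subj = trial.subject_event_time(small_design, base, supp, arm,
                                        62.0, rng)
        assert 0 < subj.event_time <= small_design.follow_up
        if not subj.event:
            assert subj.event_time == small_design.follow_up


def test_event_times_exponential_with_constant_hazard(rng):
    """K=1 gives a constant onset hazard; with no lag and long follow-up the
    observed event times are exponential."""
    lam = 0.25
    p = onset.OnsetParameters(nu=lam, mu=0.0, beta=0.0, delta=0.0, K=1)
    design = TrialDesign(n_per_arm=20000, follow_up=30.0, lag_mean=0.0)
    model = onset.conditional_onset_model(p, p, max_entry_age=74,
                                          horizon=30.5)
    times, events = trial._event_times(
        model, np.full(design.n_per_arm, 62.0), design, rng)
    observed = times[events]
    # censored fraction ~ exp(-lam*30) ~ 0.06%
    assert events.mean() > 0.99
    se = (1 / lam) / math.sqrt(observed.size)
    assert abs(observed.mean() - 1 / lam) < 4 * se


def test_degenerate_switch_matches_homogeneous_distribution(onset_defaults):
    """Supplement model with identical pre/post mu equals the control model:
    the conditional cumulative-hazard tables coincide, so the sampled event
    distributions are identical by construction."""
    base, supp = _models(onset_defaults, 1.0)
    ages = np.array([56.0, 60.0, 62.0, 64.0, 68.0])
    lam_base = base.cumulative_hazard(ages)
    lam_supp = supp.cumulative_hazard(ages)
    assert np.allclose(lam_base, lam_supp, rtol=1e-10, atol=1e-14)


# --- replicates and classification -----------------------------------------

def test_run_replicates_deterministic(network, nominal, constraint,
                                      onset_defaults):
    design = TrialDesign(n_per_arm=400, n_replicates=2)
    a = trial.run_replicates(design, network, nominal, onset_defaults,
                             constraint, np.random.default_rng(9))
    b = trial.run_replicates(design, network, nominal, onset_defaults,
                             constraint, np.random.default_rng(9))
    assert [(r.hazard_ratio, r.p_value) for r in a] == \
           [(r.hazard_ratio, r.p_value) for r in b]
    assert len(a) == 2


def test_flat_dose_response_yields_null_hazard_ratio(onset_defaults, rng):
    """Identical mutation rates in both arms give mean HR ~ 1."""
    base, supp = _models(onset_defaults, 1.0)
    design = TrialDesign(n_per_arm=4000, n_replicates=1)
    hrs = [trial.simulate_trial(design, base, supp, rng).hazard_ratio
           for _ in range(20)]
    log_mean = np.mean(np.log(hrs))
    log_se = np.std(np.log(hrs), ddof=1) / math.sqrt(len(hrs))
    assert abs(log_mean) < 3 * log_se


def test_strong_effect_direction(onset_defaults, rng):
    """A halved supplemented mutation rate must push HR well below 1."""
    base, supp = _models(onset_defaults, 0.5)
    design = TrialDesign(n_per_arm=6000, n_replicates=1)
    res = trial.simulate_trial(design, base, supp, rng)
    assert res.hazard_ratio < 0.85
    assert res.p_value < 0.05


def _result(p, hr):
    return TrialResult(hazard_ratio=hr, p_value=p, events_control=50,
                       events_supplement=50, n_per_arm=1000)


@pytest.mark.parametrize("ps, hrs, expected", [
    ((0.01, 0.02, 0.8), (0.7, 0.8, 1.0), "beneficial"),
    ((0.01, 0.02), (1.1, 1.15), "harmful"),
    ((0.04, 0.2, 0.3), (0.5, 0.6, 0.7), "insignificant"),
    ((0.2, 0.3, 0.4), (1.5, 1.5, 1.5), "insignificant"),
])
def test_classification_rule(ps, hrs, expected):
    results = [_result(p, hr) for p, hr in zip(ps, hrs)]
    assert classify_outcome(results).label == expected


def test_classification_needs_two_replicates():
    with pytest.raises(ValueError):
        classify_outcome([_result(0.01, 0.5)])


def test_design_validation():
    with pytest.raises(ValueError):
        TrialDesign(n_per_arm=0)
    with pytest.raises(ValueError):
        TrialDesign(alpha=1.5)
    with pytest.raises(ValueError):
        TrialDesign(follow_up=0.0)


# --- property tests --------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.0, 1.0), st.floats(0.01, 5.0)),
                min_size=2, max_size=8),
       st.floats(0.001, 0.5))
def test_classification_is_pure_function_of_pvalues_and_hrs(pairs, alpha):
    """The label is exactly the stated rule, for any replicate summary."""
    results = [_result(p, hr) for p, hr in pairs]
    label = classify_outcome(results, alpha=alpha).label
    n_sig = sum(p < alpha for p, _ in pairs)
    mean_hr = float(np.mean([hr for _, hr in pairs]))
    if n_sig >= 2 and mean_hr < 1.0:
        assert label == "beneficial"
    elif n_sig >= 2 and mean_hr > 1.0:
        assert label == "harmful"
    else:
        assert label == "insignificant"
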