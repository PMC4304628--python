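"""Multistage onset model: extinction ODEs, hazards, sampling, oracle, fit."""

import math

import numpy as np
import pytest
from scipy import stats

from trialvoi import onset
from trialvoi.onset import FitSpec, IncidenceTable, OnsetParameters


@pytest.fixture(scope="module")
def small_params():
    return OnsetParameters(nu=1.0, mu=0.05, beta=1.0, delta=1.0, K=3)


@pytest.fixture(scope="module")
def trial_scale_params():
    return OnsetParameters(nu=440.0, mu=3.65e-5, beta=762.2, delta=762.0, K=4)


# --- extinction profile ----------------------------------------------------

def test_extinction_without_mutation_is_certain():
    p = OnsetParameters(nu=1.0, mu=0.0, beta=2.0, delta=1.0, K=4)
    prof = onset.extinction_profile(p, np.linspace(0, 20, 41))
    assert np.allclose(prof.u, 1.0, atol=1e-9)


def test_extinction_pure_waiting_time_closed_form():
    """K=2 with no division/death: u_1(tau) = exp(-mu*tau)."""
    mu = 0.3
    p = OnsetParameters(nu=1.0, mu=mu, beta=0.0, delta=0.0, K=2)
    prof = onset.extinction_profile(p, np.linspace(0, 10, 21))
    assert np.max(np.abs(prof.u[0] - np.exp(-mu * prof.tau_grid))) < 1e-8


def test_extinction_profile_invariants(small_params):
    prof = onset.extinction_profile(small_params, np.linspace(0, 30, 61))
    assert np.all(prof.u >= 0) and np.all(prof.u <= 1)
    assert np.allclose(prof.u[:, 0], 1.0)
    assert np.all(np.diff(prof.u, axis=1) <= 1e-12)  # non-increasing


def test_extinction_matches_lineage_simulation(small_params, rng):
    """ODE u_1(5) vs the fraction of simulated lineages with no 3-mutant."""
    prof = onset.extinction_profile(small_params, np.linspace(0, 5, 11))
    expected = prof.u_k(1, 5.0)
    n = 4000
    extinct = sum(onset.lineage_extinct_within(small_params, 1, 5.0, rng)
                  for _ in range(n))
    frac = extinct / n
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 3 * se


def test_extinction_grid_must_start_at_zero(small_params):
    with pytest.raises(ValueError):
        onset.extinction_profile(small_params, np.linspace(1, 5, 5))


# --- hazard ----------------------------------------------------------------

def test_hazard_zero_mutation_rate():
    p = OnsetParameters(nu=1.0, mu=0.0, beta=1.0, delta=1.0, K=4)
    curve = onset.hazard(p, np.linspace(0, 50, 51))
    assert np.allclose(curve.hazard, 0.0, atol=1e-12)
    assert np.allclose(curve.survival, 1.0)


def test_hazard_single_stage_is_constant_seeding():
    """K=1: every seeded cell is malignant, h = nu, S = exp(-nu*t)."""
    p = OnsetParameters(nu=0.07, mu=0.0, beta=0.0, delta=0.0, K=1)
    grid = np.linspace(0, 30, 31)
    curve = onset.hazard(p, grid)
    assert np.allclose(curve.hazard, 0.07)
    assert np.allclose(curve.survival, np.exp(-0.07 * grid), rtol=1e-12)


def test_hazard_armitage_doll_limit():
    """beta = delta = 0, mu*t <= 0.01: h -> nu*(mu*t)^(K-1)/(K-1)!."""
    p = OnsetParameters(nu=1e-3, mu=1e-3, beta=0.0, delta=0.0, K=4)
    grid = np.linspace(0, 10, 41)
    curve = onset.hazard(p, grid)
    expected = p.nu * (p.mu * grid) ** 3 / 6.0
    rel = np.abs(curve.hazard[1:] - expected[1:]) / expected[1:]
    assert rel.max() < 0.01


def test_hazard_monotone_in_mutation_rate(trial_scale_params):
    grid = np.linspace(0, 85, 86)
    prev = None
    for scale in (0.5, 1.0, 2.0, 4.0):
        h = onset.hazard(trial_scale_params.with_mutation_rate(
            trial_scale_params.mu * scale), grid).hazard
        if prev is not None:
            assert np.all(h >= prev - 1e-15)
        prev = h


def test_hazard_survival_consistency(small_params):
    grid = np.linspace(0, 20, 201)
    curve = onset.hazard(small_params, grid)
    # S = exp(-cumulative hazard), cumulative hazard ~ trapezoid of h
    trap = np.concatenate([[0.0], np.cumsum(
        0.5 * (curve.hazard[1:] + curve.hazard[:-1]) * np.diff(grid))])
    assert np.max(np.abs(curve.cumulative_hazard - trap)) < 1e-4
    assert np.all(np.diff(curve.survival) <= 1e-15)
    assert curve.survival[0] == 1.0


# --- onset-age sampling ----------------------------------------------------

def test_sampling_zero_hazard_never_fires(rng):
    p = OnsetParameters(nu=1.0, mu=0.0, beta=1.0, delta=1.0, K=4)
    curve = onset.hazard(p, np.linspace(0, 50, 51))
    draws = onset.sample_onset_age(curve, 10.0, rng, size=100)
    assert np.all(np.isinf(draws))


def test_sampling_constant_hazard_mean(rng):
    lam = 0.5
    p = OnsetParameters(nu=lam, mu=0.0, beta=0.0, delta=0.0, K=1)
    curve = onset.hazard(p, np.linspace(0, 60, 601))
    draws = onset.sample_onset_age(curve, 0.0, rng, size=20000)
    finite = draws[np.isfinite(draws)]
    assert finite.size > 19900  # horizon 60 ~ 30 mean lifetimes
    se = (1 / lam) / math.sqrt(finite.size)
    assert abs(finite.mean() - 1 / lam) < 3 * se


def test_sampling_memorylessness(rng):
    """Constant hazard: draws past entry a, shifted by a, match entry-0 draws."""
    lam = 0.3
    p = OnsetParameters(nu=lam, mu=0.0, beta=0.0, delta=0.0, K=1)
    curve = onset.hazard(p, np.linspace(0, 80, 801))
    a = 5.0
    from_entry = onset.sample_onset_age(curve, a, rng, size=10000) - a
    from_zero = onset.sample_onset_age(curve, 0.0, rng, size=10000)
    from_entry = from_entry[np.isfinite(from_entry) & (from_entry <= 60)]
    from_zero = from_zero[np.isfinite(from_zero) & (from_zero <= 60)]
    assert stats.ks_2samp(from_entry, from_zero).pvalue > 0.01


def test_sampling_left_truncation_consistency(rng):
    """Rejecting unconditional onsets before entry matches conditional draws."""
    p = OnsetParameters(nu=0.1, mu=0.3, beta=0.0, delta=0.0, K=2)
    curve = onset.hazard(p, np.linspace(0, 40, 401))
    a = 8.0
    unconditional = onset.sample_onset_age(curve, 0.0, rng, size=40000)
    rejected = unconditional[np.isfinite(unconditional) & (unconditional > a)]
    conditional = onset.sample_onset_age(curve, a, rng, size=10000)
    conditional = conditional[np.isfinite(conditional)]
    assert stats.ks_2samp(rejected, conditional).pvalue > 0.01


def test_sampling_requires_entry_in_domain(small_params, rng):
    curve = onset.hazard(small_params, np.linspace(0, 20, 21))
    with pytest.raises(ValueError):
        onset.sample_onset_age(curve, 25.0, rng)


# --- stochastic oracle -----------------------------------------------------

def test_oracle_no_mutation_never_fires(rng):
    p = OnsetParameters(nu=5.0, mu=0.0, beta=1.0, delta=0.5, K=3)
    assert np.isinf(onset.stochastic_onset_oracle(p, 50.0, rng))


def test_oracle_single_stage_is_poisson(rng):
    """K=1: onset is the first event of a rate-nu Poisson process."""
    nu = 1.0
    p = OnsetParameters(nu=nu, mu=0.0, beta=0.0, delta=0.0, K=1)
    n = 5000
    times = np.array([onset.stochastic_onset_oracle(p, 50.0, rng)
                      for _ in range(n)])
    finite = times[np.isfinite(times)]
    se = (1 / nu) / math.sqrt(finite.size)
    assert abs(finite.mean() - 1 / nu) < 3 * se


def test_oracle_agrees_with_hazard_survival(small_params, rng):
    """The two independent solvers agree on S(t)."""
    t_end = 5.0
    curve = onset.hazard(small_params, np.linspace(0, t_end, 51))
    expected = float(curve.survival[-1])
    n = 3000
    none = sum(np.isinf(onset.stochastic_onset_oracle(small_params, t_end, rng))
               for _ in range(n))
    frac = none / n
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 3 * se


def test_oracle_event_budget_enforced(rng):
    p = OnsetParameters(nu=50.0, mu=0.1, beta=5.0, delta=0.1, K=6)
    with pytest.raises(onset.EventBudgetError):
        onset.stochastic_onset_oracle(p, 200.0, rng, max_events=200)


# --- calendar-time switch --------------------------------------------------

def test_switched_model_identical_params_matches_homogeneous(
        trial_scale_params, rng):
    """A switch to identical parameters is the homogeneous truncated model."""
    p = trial_scale_params
    model = onset.conditional_onset_model(p, p, max_entry_age=74, horizon=10)
    curve = onset.hazard(p, np.arange(0, 90.25, 0.25))
    a = 62.0
    tau_switch = model.sample(np.full(8000, a), rng)
    ages = onset.sample_onset_age(curve, a, rng, size=8000)
    tau_hom = ages - a
    fs = tau_switch[np.isfinite(tau_switch)]
    fh = tau_hom[np.isfinite(tau_hom) & (tau_hom <= model.horizon)]
    assert stats.ks_2samp(fs, fh).pvalue > 0.01


def test_switched_model_lower_post_mu_reduces_hazard(trial_scale_params):
    p = trial_scale_params
    lower = p.with_mutation_rate(p.mu * 0.5)
    base = onset.conditional_onset_model(p, p, max_entry_age=74, horizon=8)
    supp = onset.conditional_onset_model(p, lower, max_entry_age=74, horizon=8)
    lam_b = base.cumulative_hazard(np.array([62.0]))[0]
    lam_s = supp.cumulative_hazard(np.array([62.0]))[0]
    assert np.all(lam_s[1:] < lam_b[1:])
    assert lam_s[0] == lam_b[0] == 0.0


def test_switched_model_requires_matching_K(trial_scale_params):
    other = OnsetParameters(nu=1.0, mu=0.1, beta=1.0, delta=1.0, K=3)
    with pytest.raises(ValueError):
        onset.conditional_onset_model(trial_scale_params, other)


# --- incidence fitting -----------------------------------------------------

def _table_from(params, bins=((40, 45), (45, 50), (50, 55), (55, 60),
                              (60, 65), (65, 70), (70, 75), (75, 80),
                              (80, 85))):
    from trialvoi import fixtures
    spec = fixtures.SyntheticIncidenceSpec(
        params=params, age_bins=tuple(bins), noise="none")
    return fixtures.synthetic_incidence(spec)


def test_fit_recovers_free_mutation_rate(trial_scale_params):
    """Noiseless self-generated table: a single-free-parameter fit recovers mu."""
    table = _table_from(trial_scale_params)
    spec = FitSpec(free=("mu",),
                   fixed={"nu": trial_scale_params.nu,
                          "beta": trial_scale_params.beta,
                          "growth": trial_scale_params.net_growth},
                   n_starts=6)
    fit = onset.fit_to_incidence(table, K=4, fit_spec=spec)
    assert abs(fit.params.mu - trial_scale_params.mu) / trial_scale_params.mu < 5e-3
    assert fit.objective < 1e-6


def test_fit_all_zero_rates_drives_mu_to_boundary(trial_scale_params):
    table = IncidenceTable(np.array([40.0, 50.0, 60.0]),
                           np.array([50.0, 60.0, 70.0]),
                           np.zeros(3))
    spec = FitSpec(free=("mu",),
                   fixed={"nu": trial_scale_params.nu,
                          "beta": trial_scale_params.beta,
                          "growth": trial_scale_params.net_growth},
                   n_starts=4)
    fit = onset.fit_to_incidence(table, K=4, fit_spec=spec)
    assert fit.objective < 1e-10
    assert fit.params.mu < 1e-6


def test_fit_requires_three_bins():
    table = IncidenceTable(np.array([40.0]), np.array([50.0]), np.array([10.0]))
    with pytest.raises(ValueError):
        onset.fit_to_incidence(table)


def test_fit_reports_birth_death_ridge(trial_scale_params):
    """The (beta, delta) degeneracy is surfaced, not silently collapsed."""
    table = _table_from(trial_scale_params)
    spec = FitSpec(free=("mu",),
                   fixed={"nu": trial_scale_params.nu,
                          "beta": trial_scale_params.beta,
                          "growth": trial_scale_params.net_growth},
                   n_starts=4)
    fit = onset.fit_to_incidence(table, K=4, fit_spec=spec)
    assert "beta_shift" in fit.ridge_profile
    assert len(fit.ridge_profile["relative_change"]) == 4


def test_incidence_table_validation():
    with pytest.raises(ValueError):
        IncidenceTable(np.array([40.0, 44.0]), np.array([45.0, 50.0]),
                       np.array([1.0, 2.0]))  # overlapping bins
    with pytest.raises(ValueError):
        IncidenceTable(np.array([40.0]), np.array([45.0]), np.array([-1.0]))


def test_onset_parameters_validation():
    with pytest.raises(ValueError):
        OnsetParameters(nu=-1.0, mu=0.1, beta=1.0, delta=1.0)
    with pytest.raises(ValueError):
        OnsetParameters(nu=1.0, mu=0.1, beta=1.0, delta=1.0, K=0)
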