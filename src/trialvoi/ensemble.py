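"""Constrained ensembles of kinetic parameter sets.

Links the metabolism model to the cellular mutation rate and samples
ensembles of rate-constant vectors that are (a) within biological bounds and
(b) all calibrated to reproduce the same baseline mutation rate — the
mutation rate obtained by fitting the multistage onset model to incidence
data.  Members differ only in how their mutation rate *responds* to selenium
supplementation, which is exactly the uncertainty the virtual trials
propagate.

The calibration maps damaged-DNA steady state linearly to mutation rate:
``mu(Se) = target_mutation_rate * dmDNA_ss(Se) / target_dmDNA``, so a
calibrated set has ``mu(baseline) == target_mutation_rate`` identically and
its dose-response ratio multiplies the baseline mutation rate directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .kinetics import (BASELINE_SELENIUM_MM, DoseResponse, RateParameterSet,
                       ReactionNetwork, SteadyStateError, dose_response,
                       nominal_parameters, steady_state_dmDNA)
from .trial import TrialResult

__all__ = [
    "InfeasibleConstraintError", "ParameterBounds", "CalibrationConstraint",
    "ConstrainedSample", "EnsembleRecord",
    "default_bounds", "bounds_from_csv", "bounds_to_csv",
    "reference_damage_level", "mutation_rate_at",
    "sample_constrained_set", "build_ensemble",
    "DAMAGE_CONSTANTS", "DEFAULT_SELENIUM_GRID",
]

#: Constants scaled jointly when projecting a draw onto the calibration
#: manifold: the damage-producing rate constants of the reference network.
DAMAGE_CONSTANTS = ("R1_k0", "R3_k0", "R3_k2")

#: Selenium grid (mM) for ensemble dose-response curves; spans dietary
#: baseline through supplemented levels.
DEFAULT_SELENIUM_GRID = (1.0, 1.35, 1.7, 2.1, 2.5, 3.0, 3.5, 4.0)

#: Published fitted baseline mutation rate, events per cell per year.
DEFAULT_TARGET_MUTATION_RATE = 3.65e-5


class InfeasibleConstraintError(Exception):
    """Repeated failure to project draws onto the calibration constraint."""


ParameterBounds = Mapping[str, tuple[float, float]]


def default_bounds(network: ReactionNetwork,
                   lo: float = 1e-6, hi: float = 1e6) -> dict:
    """Uniform (1e-6, 1e6) bounds for every constant (12 decades)."""
    return {name: (lo, hi) for name in network.parameter_names}


def validate_bounds(network: ReactionNetwork, bounds: ParameterBounds) -> None:
    for name in network.parameter_names:
        if name not in bounds:
            raise ValueError(f"bounds missing constant {name!r}")
        lo, hi = bounds[name]
        if not (lo > 0 and hi >= lo):
            raise ValueError(f"bounds for {name!r} must satisfy 0 < lower <= upper")


def bounds_to_csv(bounds: ParameterBounds, path) -> None:
    import pandas as pd
    pd.DataFrame([{"name": k, "lower": v[0], "upper": v[1]}
                  for k, v in bounds.items()]).to_csv(path, index=False)


def bounds_from_csv(path) -> dict:
    import pandas as pd
    df = pd.read_csv(path)
    return {row["name"]: (float(row["lower"]), float(row["upper"]))
            for _, row in df.iterrows()}


@dataclass(frozen=True)
class CalibrationConstraint:
    """Baseline calibration shared by every ensemble member.

    ``target_dmDNA`` is the reference damaged-DNA steady state that maps to
    ``target_mutation_rate``; by convention it is computed once from the
    nominal (geometric-mean-of-bounds) parameter set at baseline selenium
    (see :func:`reference_damage_level`) and then frozen for the run.
    """

    target_dmDNA: float
    baseline_selenium: float = BASELINE_SELENIUM_MM
    target_mutation_rate: float = DEFAULT_TARGET_MUTATION_RATE

    def __post_init__(self):
        for name in ("baseline_selenium", "target_mutation_rate", "target_dmDNA"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def reference_damage_level(network: ReactionNetwork,
                           params: Mapping[str, float] | None = None,
                           baseline_selenium: float = BASELINE_SELENIUM_MM) -> float:
    """Damaged-DNA steady state of the nominal parameter set at baseline."""
    params = params if params is not None else nominal_parameters(network)
    return steady_state_dmDNA(network, params, baseline_selenium)


def mutation_rate_at(network: ReactionNetwork, params: Mapping[str, float],
                     selenium_level: float,
                     constraint: CalibrationConstraint) -> float:
    """Per-cell per-year mutation rate at a selenium level (linear damage map)."""
    d = steady_state_dmDNA(network, params, selenium_level)
    return constraint.target_mutation_rate * d / constraint.target_dmDNA


@dataclass
class ConstrainedSample:
    """One calibrated parameter set with its projection metadata."""

    values: RateParameterSet
    baseline_residual: float
    damage_multiplier: float
    draws_used: int


@dataclass
class EnsembleRecord:
    """One ensemble member with downstream trial results and outcome label."""

    id: int
    values: RateParameterSet
    baseline_residual: float
    dose_response: DoseResponse | None = None
    trial_results: list[TrialResult] = field(default_factory=list)
    outcome: str | None = None  # beneficial | harmful | insignificant


def sample_constrained_set(network: ReactionNetwork, bounds: ParameterBounds,
                           constraint: CalibrationConstraint,
                           rng: np.random.Generator,
                           max_draws: int = 1000,
                           tol: float = 1e-6) -> ConstrainedSample:
    """Draw one calibrated parameter set.

    Constants are drawn log-uniformly within their bounds, then projected
    onto the calibration manifold ``dmDNA_ss(baseline) == target_dmDNA`` by
    solving for a single common multiplier on the damage-producing constants
    (:data:`DAMAGE_CONSTANTS`).  Draws whose projection would push any
    constant outside its bounds are rejected and redrawn.  The achieved
    relative residual is recorded on the returned sample.
    """
    validate_bounds(network, bounds)
    names = network.parameter_names
    log_lo = np.array([math.log10(bounds[n][0]) for n in names])
    log_hi = np.array([math.log10(bounds[n][1]) for n in names])
    for attempt in range(1, max_draws + 1):
        draw = 10.0 ** rng.uniform(log_lo, log_hi)
        values = dict(zip(names, draw))
        # allowed multiplier range keeping damage constants in bounds
        lc = max(math.log10(bounds[n][0] / values[n]) for n in DAMAGE_CONSTANTS)
        hc = min(math.log10(bounds[n][1] / values[n]) for n in DAMAGE_CONSTANTS)
        if lc >= hc:
            continue

        def residual(logc):
            scaled = dict(values)
            for n in DAMAGE_CONSTANTS:
                scaled[n] = values[n] * 10.0 ** logc
            try:
                d = steady_state_dmDNA(network, scaled,
                                       constraint.baseline_selenium)
            except SteadyStateError:
                return np.nan
            return d / constraint.target_dmDNA - 1.0

        r_lo, r_hi = residual(lc), residual(hc)
        if not (np.isfinite(r_lo) and np.isfinite(r_hi)) or r_lo * r_hi > 0:
            continue
        logc = brentq(residual, lc, hc, xtol=1e-12, rtol=1e-13)
        res = residual(logc)
        if not np.isfinite(res) or abs(res) > tol:
            continue
        for n in DAMAGE_CONSTANTS:
            values[n] = min(max(values[n] * 10.0 ** logc, bounds[n][0]),
                            bounds[n][1])
        return ConstrainedSample(values=values, baseline_residual=float(res),
                                 damage_multiplier=10.0 ** logc,
                                 draws_used=attempt)
    raise InfeasibleConstraintError(
        f"no feasible calibrated draw in {max_draws} attempts; the damage "
        f"constants {DAMAGE_CONSTANTS} cannot reach the target within bounds")


def build_ensemble(network: ReactionNetwork, bounds: ParameterBounds,
                   constraint: CalibrationConstraint, n: int = 502,
                   rng: np.random.Generator | int = 0,
                   selenium_grid: Sequence[float] = DEFAULT_SELENIUM_GRID,
                   with_dose_response: bool = True) -> list[EnsembleRecord]:
    """Build ``n`` independent calibrated parameter sets (seed-deterministic).

    Each record carries its relative baseline residual and, by default, its
    dose-response curve on ``selenium_grid`` (always including the baseline,
    where every curve equals 1.0 by construction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    records = []
    for i in range(n):
        sample = sample_constrained_set(network, bounds, constraint, rng)
        rec = EnsembleRecord(id=i, values=sample.values,
                             baseline_residual=sample.baseline_residual)
        if with_dose_response:
            rec.dose_response = dose_response(
                network, sample.values, selenium_grid,
                baseline=constraint.baseline_selenium)
        records.append(rec)
    return records


def ensemble_to_frame(records: Sequence[EnsembleRecord],
                      network: ReactionNetwork):
    """Ensemble as a DataFrame: one row per set, 18 constants + metadata."""
    import pandas as pd
    rows = []
    for rec in records:
        row = {"id": rec.id, "baseline_residual": rec.baseline_residual,
               "outcome": rec.outcome}
        row.update({name: rec.values[name] for name in network.parameter_names})
        rows.append(row)
    return pd.DataFrame(rows)
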