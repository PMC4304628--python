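"""Synthetic inputs: incidence tables, planted-signal ensembles, toy SBML.

Everything the pipeline consumes from the outside world has a synthetic
stand-in generated here, so every stage can be exercised and tested without
downloads.  The registry-style incidence generator uses the multistage onset
model itself, which turns incidence fitting into a parameter-recovery
exercise with a known ground truth; the planted ensemble provides
(parameter-vector, label) records whose labels depend on a known small set
of features, giving the VOI machinery a recoverable signal.  All generators
are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .onset import HazardCurve, IncidenceTable, OnsetParameters, hazard
from .voi import LabeledEnsemble

__all__ = [
    "SyntheticIncidenceSpec", "PlantedEnsembleSpec",
    "DEFAULT_INCIDENCE_PARAMS",
    "synthetic_incidence", "planted_ensemble", "toy_sbml",
]

#: Generating parameters for the default synthetic incidence table: the
#: published fitted multistage rates (mutation 3.65e-5, birth 762.2, death
#: 762.0 per cell per year, K = 4) with the seeding rate chosen so the model
#: matches registry-scale prostate incidence at typical trial-entry ages
#: (~450 per 100,000 person-years at age 62).
DEFAULT_INCIDENCE_PARAMS = OnsetParameters(
    nu=440.0, mu=3.65e-5, beta=762.2, delta=762.0, K=4)


@dataclass(frozen=True)
class SyntheticIncidenceSpec:
    """Registry-style incidence table generated from known onset parameters."""

    params: OnsetParameters = DEFAULT_INCIDENCE_PARAMS
    age_bins: tuple[tuple[float, float], ...] = tuple(
        (lo, lo + 5.0) for lo in np.arange(40.0, 85.0, 5.0))
    person_years: float = 1e7
    noise: str = "none"  # none | poisson
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if self.noise == "poisson" and not self.person_years > 0:
            raise ValueError("poisson noise requires person_years > 0")


def synthetic_incidence(spec: SyntheticIncidenceSpec) -> IncidenceTable:
    """Generate an age-binned incidence table from the multistage model.

    Bin rates are the model hazard averaged over the bin, per 100,000
    person-years; with ``noise='poisson'`` the observed rate is a Poisson
    count at the stated person-years exposure divided back into a rate.
    """
    lows = np.array([b[0] for b in spec.age_bins])
    highs = np.array([b[1] for b in spec.age_bins])
    top = float(highs.max())
    grid = np.arange(0.0, top + 1.0, 1.0)
    curve = hazard(spec.params, grid)
    mids = np.arange(0.25, top, 0.5)
    h_mid = curve.hazard_at(mids)
    rates = np.empty(lows.size)
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        mask = (mids >= lo) & (mids < hi)
        rates[i] = float(np.mean(h_mid[mask])) * 1e5
    person_years = np.full(lows.size, float(spec.person_years))
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        expected_counts = rates / 1e5 * person_years
        counts = rng.poisson(expected_counts)
        rates = counts / person_years * 1e5
    return IncidenceTable(lows, highs, rates, person_years)


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Labelled random ensemble with a planted low-dimensional signal.

    Features are log10 rate constants drawn uniformly on [-6, 6] (mirroring
    12-decade bounds); the label is a conjunction of per-feature threshold
    conditions on the informative features, with thresholds placed at the
    quantile that achieves the target positive fraction, plus optional label
    noise.
    """

    n: int = 500
    n_features: int = 18
    informative: tuple[int, ...] = (0, 1, 2, 3)
    positive_fraction: float = 0.05
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not set(self.informative) <= set(range(self.n_features)):
            raise ValueError("informative indices must be valid feature indices")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def planted_ensemble(spec: PlantedEnsembleSpec) -> LabeledEnsemble:
    """Generate the planted-signal ensemble.

    A record is positive when every informative feature falls below a common
    threshold; the threshold is calibrated to the sample (the empirical
    quantile of the max over informative features) so the achieved positive
    fraction matches the target up to rounding.  The label therefore remains
    a deterministic threshold rule on the informative features alone.  A
    calibration error is raised if the achieved fraction still misses the
    target by more than ±20% (possible only at tiny n or extreme noise).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(-6.0, 6.0, size=(spec.n, spec.n_features))
    k = len(spec.informative)
    if k == 0:
        y = rng.random(spec.n) < spec.positive_fraction
    else:
        score = np.max(X[:, list(spec.informative)], axis=1)
        n_pos = max(int(round(spec.n * spec.positive_fraction)), 1)
        cut = np.sort(score)[n_pos - 1]
        y = score <= cut
        if spec.label_noise > 0:
            flip = rng.random(spec.n) < spec.label_noise
            y = y ^ flip
        achieved = y.mean()
        if not (0.8 * spec.positive_fraction <= achieved
                <= 1.2 * spec.positive_fraction):
            raise ValueError(
                f"achieved positive fraction {achieved:.3f} outside ±20% of "
                f"target {spec.positive_fraction:.3f}; use a larger n or "
                "lower label noise")
    names = tuple(f"P{i:02d}" for i in range(spec.n_features))
    return LabeledEnsemble(X, y, names)


_TOY_SBML_TWO_SPECIES = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="toy_two_species">
  <listOfCompartments>
   <compartment id="cell" size="1" constant="true" spatialDimensions="3"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="cell" initialConcentration="2.0"
            boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
   <species id="B" compartment="cell" initialConcentration="0.0"
            boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k_ab" value="0.75" constant="true"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="conv" reversible="false" fast="false">
    <listOfReactants>
     <speciesReference species="A" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <listOfProducts>
     <speciesReference species="B" stoichiometry="1" constant="true"/>
    </listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci> k_ab </ci><ci> A </ci></apply>
     </math>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""

_TOY_SBML_SATURATING = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="toy_saturating">
  <listOfCompartments>
   <compartment id="cell" size="1" constant="true" spatialDimensions="3"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="S" compartment="cell" initialConcentration="5.0"
            boundaryCondition="true" constant="false" hasOnlySubstanceUnits="false"/>
   <species id="P" compartment="cell" initialConcentration="0.0"
            boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="vmax" value="1.5" constant="true"/>
   <parameter id="km" value="0.5" constant="true"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="uptake" reversible="false" fast="false">
    <listOfReactants>
     <speciesReference species="S" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <listOfProducts>
     <speciesReference species="P" stoichiometry="1" constant="true"/>
    </listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><divide/>
       <apply><times/><ci> vmax </ci><ci> S </ci></apply>
       <apply><plus/><ci> km </ci><ci> S </ci></apply>
      </apply>
     </math>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""

# exponential kinetic law: outside the mass-action/saturating subset
_TOY_SBML_UNSUPPORTED = _TOY_SBML_TWO_SPECIES.replace(
    "<apply><times/><ci> k_ab </ci><ci> A </ci></apply>",
    "<apply><exp/><ci> A </ci></apply>")

_TOY_SBML_EMPTY = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="toy_empty">
  <listOfSpecies>
   <species id="A" compartment="cell" initialConcentration="1.0"
            boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
 </model>
</sbml>
"""

_TOY_SBML = {
    "two_species": _TOY_SBML_TWO_SPECIES,
    "saturating": _TOY_SBML_SATURATING,
    "unsupported": _TOY_SBML_UNSUPPORTED,
    "empty": _TOY_SBML_EMPTY,
}


def toy_sbml(path, variant: str = "two_species") -> None:
    """Write a minimal SBML fixture.

    Variants: ``two_species`` (one mass-action reaction), ``saturating``
    (one Michaelis-Menten reaction with a clamped substrate), ``unsupported``
    (an exponential rate law that must trigger the importer's
    unsupported-construct error), ``empty`` (no reactions).
    """
    if variant not in _TOY_SBML:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {sorted(_TOY_SBML)}")
    with open(path, "w") as fh:
        fh.write(_TOY_SBML[variant])
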