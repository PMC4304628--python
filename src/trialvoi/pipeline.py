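"""End-to-end study orchestration: ensemble -> trials -> classification -> VOI.

``run_study`` executes the whole chain from a single config and master seed:
build (or import) the metabolism network, calibrate the baseline damage
level, sample the constrained parameter ensemble with per-set dose-response
curves, simulate replicate supplementation trials for every set, classify
outcomes, train the boosted-tree classifier, and compute influence rankings
and enrichment analyses.  Every stage draws from a named substream of the
master seed, so reruns are bit-reproducible and stages can be re-run
independently with identical randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ensemble as ens
from . import kinetics, onset, trial, voi

__all__ = ["RunConfig", "RunReport", "run_study", "render_report",
           "configure_logging", "DEFAULT_ONSET_PARAMS"]

log = logging.getLogger("trialvoi")

#: Default multistage parameters for the study: the published fitted rates
#: with the seeding rate calibrated to registry-scale incidence at trial
#: entry ages (see fixtures.DEFAULT_INCIDENCE_PARAMS).
DEFAULT_ONSET_PARAMS = onset.OnsetParameters(
    nu=440.0, mu=3.65e-5, beta=762.2, delta=762.0, K=4)

# named substreams of the master seed, one per stochastic stage
_STAGE_CODES = {"ensemble": 1, "trials": 2, "split": 3, "classifier": 4}


def configure_logging(logfile: str | None = None,
                      level: int = logging.INFO) -> None:
    """Structured logging to stderr, optionally duplicated to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(level)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


def _stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE_CODES[stage], int(index)]))


@dataclass
class RunConfig:
    """Full study configuration (serializable; hashed into every artifact)."""

    seed: int = 0
    network_sbml: str | None = None          # None -> bundled reference network
    bounds_csv: str | None = None            # None -> (1e-6, 1e6) everywhere
    onset_params: onset.OnsetParameters = DEFAULT_ONSET_PARAMS
    incidence_csv: str | None = None         # fit onset params when given
    fit_K: int = 4
    design: trial.TrialDesign = field(default_factory=trial.TrialDesign)
    n_sets: int = 502
    selenium_grid: tuple = ens.DEFAULT_SELENIUM_GRID
    target_mutation_rate: float = ens.DEFAULT_TARGET_MUTATION_RATE
    classifier: voi.ClassifierConfig = field(default_factory=voi.ClassifierConfig)
    train_fraction: float = 0.70
    threshold_parameter: str | None = None   # None -> top-influence parameter
    threshold_value: float = 10.0
    threshold_direction: str = "below"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "onset_params" in kwargs:
            kwargs["onset_params"] = onset.OnsetParameters(**kwargs["onset_params"])
        if "design" in kwargs:
            kwargs["design"] = trial.TrialDesign(**kwargs["design"])
        if "classifier" in kwargs:
            kwargs["classifier"] = voi.ClassifierConfig(**kwargs["classifier"])
        if "selenium_grid" in kwargs:
            kwargs["selenium_grid"] = tuple(kwargs["selenium_grid"])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Summary of one full study run (counts partition the ensemble)."""

    n_sets: int
    counts: dict
    hr_summary: dict
    records: list
    labeled: voi.LabeledEnsemble
    onset_params: onset.OnsetParameters
    constraint: ens.CalibrationConstraint
    provenance: dict
    influence: voi.InfluenceReport | None = None
    metrics: voi.TestMetrics | None = None
    classifier_enrichment: voi.EnrichmentResult | None = None
    threshold_enrichment: voi.EnrichmentResult | None = None
    model: object = None
    voi_skipped: str | None = None

    def summary_dict(self) -> dict:
        return {
            "n_sets": self.n_sets,
            "counts": self.counts,
            "fractions": {k: v / self.n_sets for k, v in self.counts.items()},
            "hr_summary": self.hr_summary,
            "influence_ranking": (self.influence.ranked()
                                  if self.influence else None),
            "test_metrics": self.metrics.to_dict() if self.metrics else None,
            "classifier_enrichment": (self.classifier_enrichment.to_dict()
                                      if self.classifier_enrichment else None),
            "threshold_enrichment": (self.threshold_enrichment.to_dict()
                                     if self.threshold_enrichment else None),
            "voi_skipped": self.voi_skipped,
            "onset_params": dataclasses.asdict(self.onset_params),
            "constraint": dataclasses.asdict(self.constraint),
            "provenance": self.provenance,
        }


def _hr_summary(records, label: str) -> dict:
    hrs = [np.mean([t.hazard_ratio for t in rec.trial_results])
           for rec in records if rec.outcome == label]
    if not hrs:
        return {"n": 0}
    return {"n": len(hrs), "median": float(np.median(hrs)),
            "min": float(np.min(hrs)), "max": float(np.max(hrs))}


def run_study(config: RunConfig, out_dir: str | None = None) -> RunReport:
    """Execute the full study; write intermediate artifacts when ``out_dir`` given."""
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.config_hash()}

    # --- stage 1: network, bounds, calibration --------------------------
    log.info("stage network: building reaction network")
    if config.network_sbml:
        imported = kinetics.import_sbml_subset(config.network_sbml)
        network = imported.network
    else:
        network = kinetics.reference_selenium_network()
    bounds = (ens.bounds_from_csv(config.bounds_csv) if config.bounds_csv
              else ens.default_bounds(network))
    onset_params = config.onset_params
    if config.incidence_csv:
        table = onset.IncidenceTable.from_csv(config.incidence_csv)
        fit = onset.fit_to_incidence(
            table, K=config.fit_K,
            fit_spec=onset.FitSpec(free=("mu", "beta", "growth"),
                                   fixed={"nu": onset_params.nu}))
        onset_params = fit.params
        log.info("fitted onset parameters: %s", onset_params)
    target_dmdna = ens.reference_damage_level(
        network, baseline_selenium=config.design.baseline_selenium)
    constraint = ens.CalibrationConstraint(
        target_dmDNA=target_dmdna,
        baseline_selenium=config.design.baseline_selenium,
        target_mutation_rate=onset_params.mu)

    # --- stage 2: constrained ensemble ----------------------------------
    log.info("stage ensemble: sampling %d calibrated parameter sets",
             config.n_sets)
    records = ens.build_ensemble(
        network, bounds, constraint, n=config.n_sets,
        rng=_stage_rng(config.seed, "ensemble"),
        selenium_grid=config.selenium_grid)
    if out:
        ens.ensemble_to_frame(records, network).to_csv(
            out / "ensemble.csv", index=False)

    # --- stage 3: replicate trials and classification --------------------
    log.info("stage trials: %d replicates x %d sets, %d/arm",
             config.design.n_replicates, config.n_sets,
             config.design.n_per_arm)
    horizon = config.design.follow_up + 0.5
    max_entry = (config.design.entry_age_mean
                 + 6 * config.design.entry_age_sd)
    control_model = onset.conditional_onset_model(
        onset_params, onset_params, max_entry_age=max_entry, horizon=horizon,
        tau_step=0.5, sigma_step=1.0)
    for rec in records:
        rng = _stage_rng(config.seed, "trials", rec.id)
        rec.trial_results = trial.run_replicates(
            config.design, network, rec.values, onset_params, constraint,
            rng, control_model=control_model)
        rec.outcome = trial.classify_outcome(
            rec.trial_results, alpha=config.design.alpha).label
    counts = {label: sum(1 for r in records if r.outcome == label)
              for label in ("beneficial", "harmful", "insignificant")}
    log.info("outcomes: %s", counts)
    if out:
        _write_trials_csv(records, out / "trials.csv")

    # --- stage 4: VOI ----------------------------------------------------
    log.info("stage voi: training classifier and computing influence")
    labeled = voi.LabeledEnsemble.from_records(records, network)
    report = RunReport(
        n_sets=len(records), counts=counts,
        hr_summary={label: _hr_summary(records, label)
                    for label in ("beneficial", "harmful", "insignificant")},
        records=records, labeled=labeled,
        onset_params=onset_params, constraint=constraint,
        provenance=provenance)
    try:
        train, test = voi.split_train_test(
            labeled, config.train_fraction,
            rng=_stage_rng(config.seed, "split"))
        model = voi.train_classifier(train, config.classifier,
                                     rng=_stage_rng(config.seed, "classifier"))
    except ValueError as exc:
        # tiny or single-class ensembles cannot support the classifier stage
        log.warning("voi stage skipped: %s", exc)
        report.voi_skipped = str(exc)
    else:
        report.model = model
        report.influence = voi.relative_influence(model)
        report.metrics = voi.test_metrics(model, test)
        predicted = voi.predict_positive(model, labeled.features)
        report.classifier_enrichment = voi.enrichment(
            records, predicted, description="classifier-predicted beneficial")
        top_param = (config.threshold_parameter
                     or report.influence.ranked()[0][0])
        report.threshold_enrichment = voi.conditional_threshold_analysis(
            records, top_param, config.threshold_value,
            config.threshold_direction)
    if out:
        render_report(report, out)
    return report


def _write_trials_csv(records, path) -> None:
    import pandas as pd
    rows = []
    for rec in records:
        for j, t in enumerate(rec.trial_results):
            rows.append({"set_id": rec.id, "replicate": j,
                         "hazard_ratio": t.hazard_ratio, "p_value": t.p_value,
                         "events_control": t.events_control,
                         "events_supplement": t.events_supplement,
                         "outcome": rec.outcome})
    pd.DataFrame(rows).to_csv(path, index=False)


_OUTCOME_COLORS = {"insignificant": "0.6", "harmful": "tab:red",
                   "beneficial": "tab:blue"}


def render_report(report: RunReport, out_dir) -> list[Path]:
    """Write CSV tables, the JSON summary, and the standard figures.

    Figures: dose-response curves coloured grey/red/blue by outcome, and the
    relative-influence bar chart.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=1, default=str)
    written.append(out / "summary.json")

    if report.influence is not None:
        report.influence.to_csv(out / "influence.csv")
        written.append(out / "influence.csv")

    rows = []
    for rec in report.records:
        if rec.dose_response is None:
            continue
        for lvl, val in zip(rec.dose_response.selenium_levels,
                            rec.dose_response.relative_mutation_rate):
            rows.append({"set_id": rec.id, "selenium_mM": lvl,
                         "relative_mutation_rate": val,
                         "outcome": rec.outcome})
    pd.DataFrame(rows).to_csv(out / "dose_response.csv", index=False)
    written.append(out / "dose_response.csv")

    # dose-response figure, beneficial/harmful drawn on top
    fig, ax = plt.subplots(figsize=(6, 4.5))
    order = {"insignificant": 0, "harmful": 1, "beneficial": 2}
    seen = set()
    for rec in sorted(report.records,
                      key=lambda r: order.get(r.outcome or "insignificant", 0)):
        if rec.dose_response is None:
            continue
        outcome = rec.outcome or "insignificant"
        color = _OUTCOME_COLORS.get(outcome, "0.6")
        label = outcome if outcome not in seen else None
        seen.add(outcome)
        ax.plot(rec.dose_response.selenium_levels,
                rec.dose_response.relative_mutation_rate,
                color=color, alpha=0.5, lw=1, label=label,
                zorder=order.get(outcome, 0))
    ax.axvline(1.7, color="k", ls=":", lw=0.8)
    ax.set_xlabel("selenium (mM)")
    ax.set_ylabel("relative mutation rate")
    ax.set_yscale("log")
    if seen:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "dose_response.png", dpi=150)
    plt.close(fig)
    written.append(out / "dose_response.png")

    if report.influence is not None:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        ranked = report.influence.ranked()
        ax.barh([n for n, _ in reversed(ranked)],
                [v for _, v in reversed(ranked)], color="tab:blue")
        ax.set_xlabel("relative influence (%)")
        fig.tight_layout()
        fig.savefig(out / "influence.png", dpi=150)
        plt.close(fig)
        written.append(out / "influence.png")
    return written
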