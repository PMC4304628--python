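# Methods

`trialvoi` links three model levels — biochemistry, carcinogenesis, and
trial statistics — to ask a decision-support question: given today's
uncertainty about selenium metabolism, what distribution of outcomes should
a selenium-supplementation prevention trial expect, and which mechanistic
quantities would be most valuable to measure before running it?

## Selenium metabolism (kinetics)

The metabolism model is an 18-rate-constant ODE network over six species:
clamped extracellular selenium (`Se_ext`, mM), intracellular selenide
(`HSe`), methylselenol (`MeSeH`), hydrogen peroxide (`H2O2`), and a
normalized genomic pool split between intact `DNA` and damaged `dmDNA`
(`DNA + dmDNA = 1`). Selenide is imported from the extracellular pool
(R8, saturating), cleared into selenoprotein synthesis (R9), methylated to
methylselenol (R4, saturating), and drives peroxide production by redox
cycling (R10). Methylselenol is protective: it catalyses peroxide reduction
(R2, saturating in peroxide) before being cleared (R5). Damage enters
through two routes: direct selenide-mediated DNA damage (R1, saturating in
selenide) and peroxide-mediated damage (R3) whose rate
`(R3_k0*[H2O2] + R3_k2*[H2O2]*[HSe]/(R3_k1+[HSe]))*[DNA]` contains a
selenium-independent oxidative term and a selenide-amplified term; R7
repairs damaged DNA saturably, R6 and R11 are constitutive peroxide
production and decay. Raising selenium therefore pulls the damaged-DNA
steady state in both directions at once — more selenide-driven damage,
more methylselenol-mediated protection — and which direction wins depends
on the rate constants. That balance is exactly the uncertainty the rest of
the pipeline propagates.

Units are mM and years. Rate-law structure is restricted to sums of
mass-action / Michaelis–Menten-style terms; this is also the subset the
SBML reader/writer supports (Level 2/3, species + global or local
parameters + irreversible reactions; events, rules and other constructs are
rejected with an error naming the reaction). Networks can equally be
supplied as SBML files, replacing the bundled reconstruction.

Steady states: for the bundled topology the damage reactions treat the
oxidant species as catalytic modifiers, so the upstream subsystem
(HSe → MeSeH → H2O2) is independent of the DNA pools and every balance is a
monotone scalar equation; the solver exploits this cascade with bisection
(`brentq`, relative tolerance 1e-15) and is exact up to root-solver
precision. Arbitrary (imported) networks use the generic path — stiff LSODA
integration in expanding time windows, refined by a bounded least-squares
solve of the derivative system with conservation-law anchors (left null
space of the stoichiometric matrix) — converged when
`max |dC/dt| < 1e-9 × max(C)`. The two routes agree to ~1e-15 on the
reference network and are cross-checked in the test suite.

Dose–response curves report the ratio `dmDNA_ss(Se) / dmDNA_ss(1.7 mM)`;
the value at the 1.7 mM dietary baseline is 1 by construction.

## Cancer onset (multistage branching process)

Cancer onset follows a multistage somatic-mutation model: a healthy pool
(not tracked) seeds first-mutation cells as a Poisson process at rate `nu`
per year; each cell divides symmetrically at `beta`, dies at `delta`, or
divides with mutation at `mu` (all per cell-year); the first cell carrying
`K` mutations (default 4) marks onset.

The deterministic kernel is the lineage extinction probability
`u_k(tau)` — the chance that one k-mutant cell's clone produces no K-mutant
within `tau` — satisfying the backward Kolmogorov system
`du_k/dtau = beta*u_k^2 + delta + mu*u_k*u_{k+1} - (beta+delta+mu)*u_k`
with `u_K = 0`. Numerically we integrate the complementary variables
`v_k = 1 - u_k` (`dv_k/dtau = (beta-delta)v_k - beta*v_k^2 +
mu*v_{k+1}(1-v_k)`), because with realistic rates `v_1` is of order 1e-5
while `u_1` sits at `1 - 1e-5`: solving for `v` keeps the solver's relative
tolerance (LSODA, rtol 1e-9, atol 1e-18) on the quantity that actually
enters the hazard. Poisson seeding gives
`h(t) = nu * v_1(t)` and `S(t) = exp(-nu * ∫ v_1)`, with the integral
carried as an extra ODE state. Closed-form checks: `mu = 0` gives `h = 0`;
`K = 1` gives constant hazard `nu`; `beta = delta = 0` with `mu*t ≪ 1`
reproduces the Armitage–Doll power law `nu*(mu*t)^(K-1)/(K-1)!` (verified
to <1%).

An exact Gillespie simulator of the same process (seed times plus
per-lineage event simulation — exact by lineage independence) provides an
independent stochastic oracle; the two solvers are required to agree on
`S(t)` within Monte-Carlo error on several parameter sets.

Supplementation changes the cellular mutation rate **at trial entry**, so a
supplement-arm subject's onset process is piecewise-homogeneous in calendar
time. This is handled exactly via the generating-function composition of
the branching process: the post-switch extinction vector `u_post(tau)` is
flowed backward through the pre-switch dynamics, and the model tabulates
`I(sigma, tau) = ∫_0^sigma (1 - F_s(u_post(tau))_1) ds` on a
(sigma, tau) grid, giving the conditional post-entry cumulative hazard
`Lambda_a(tau) = nu*(H_post(tau) + I(a,tau) - I(a,0))` for entry age `a`.
With identical pre/post parameters this reduces analytically to the
homogeneous left-truncated model (tested both as table identity and by a
distributional check against the homogeneous sampler). Default tabulation
uses tau steps of 0.25 y and sigma steps of 0.5 y; the trial pipeline uses
0.5/1.0 y, accurate to ~1e-3 in relative cumulative hazard — an error
shared by both arms and negligible against the effect sizes of interest.

Onset ages are drawn by inverse transform on the cumulative hazard,
left-truncated at entry.

### Default rates

The default parameters are `mu = 3.65e-5`, `beta = 762.2`, `delta = 762.0`
per cell-year with `K = 4` — division about twice per day, per-generation
mutation rate `mu/beta ≈ 4.8e-8`, slight net clonal growth of 0.2/yr. The
seeding rate `nu` is not separately identifiable from those sources, so it
is set to 440/yr, which places the model's hazard at registry scale for
prostate cancer at typical trial entry ages (≈450 per 100,000 person-years
at age 62) — the regime the simulated trials actually sample. A known shape
limitation: the multistage hazard keeps accelerating with age, so it
overshoots registry rates above ~75 and implies a high lifetime risk;
trial simulations never reach that regime (entry ≈ 62, follow-up 7 y).

### Fitting to incidence tables

`fit_to_incidence` minimizes the person-year-weighted squared difference
between bin-averaged model hazard (per 100k) and observed rates, searching
in log10 space over a configurable free set among
(`nu`, `mu`, net growth `beta-delta`, `beta`) via seeded Nelder–Mead
multi-starts with a polished winner. The (beta, delta) near-degeneracy —
the objective is nearly flat when both shift together at fixed net
growth — is reported as a ridge profile rather than hidden. On noiseless
self-generated tables the identifiable quantities are recovered to <1%;
with Poisson noise at 1e7 person-years per bin, net growth is recovered
within 10%.

## Linking damage to mutation rate; the calibrated ensemble

The cellular mutation rate is a linear readout of steady-state damage:
`mu(Se) = mu_target * dmDNA_ss(Se) / dmDNA_ref`, where `mu_target` is the
incidence-fitted baseline mutation rate and `dmDNA_ref` is a reference
damage level computed once from the nominal parameter set (geometric mean
of the bounds — all constants 1.0 under the default 1e-6..1e6 bounds) at
baseline selenium, then frozen for the run. The absolute damage-to-mutation
conversion never enters downstream results; only dose-response ratios do.

Ensemble sampling draws each constant log-uniformly within its bounds
(12 decades by default) and projects the draw onto the calibration manifold
`dmDNA_ss(1.7 mM) = dmDNA_ref` by solving for a single common multiplier on
the damage-producing constants (R1_k0, R3_k0, R3_k2); draws whose
projection would leave the bounds are rejected and redrawn. Every accepted
member satisfies the baseline constraint to better than 1e-6 relative.
Two emergent properties worth knowing:

* the induced dependence among parameters is *functional* rather than
  pairwise-linear — a function of the joint vector (baseline damage) is
  pinned while pairwise log-space correlations among the projected
  constants are near zero, because a different constant dominates the
  damage budget in each draw;
* acceptance is ≈ one third, and the feasibility filter measurably tilts
  the marginals of constants coupled to the attainable damage range (e.g.
  repair `R7_k0` shifts up by ~0.9 decades on average). Marginals remain
  spread over the full 12 decades; tests bound the Kolmogorov distance to
  log-uniform rather than asserting exact uniformity.

## Trial simulation and analysis

Each virtual trial randomizes `n_per_arm` subjects per arm (default
10,000), entry ages N(62, 2²) years, follow-up 7 years, 3 replicate trials
per parameter set, supplementation raising selenium from 1.7 to 2.5 mM at
entry. Onset is sampled from the arm's conditional post-entry model
(control: baseline mutation rate throughout; supplement: switched at
entry); clinical diagnosis adds an exponential natural-history lag (mean
5 years); diagnoses after follow-up are censored there. Arm sizes,
follow-up, replicate count and lag are study choices recorded in every
output artifact.

Analysis is a Cox proportional-hazards fit on time-on-study with the single
binary arm covariate, implemented directly as a Newton iteration on the
Breslow partial likelihood (risk sets by suffix counts over sorted times).
The Wald p-value is reported; a monotone likelihood (all events one-sided)
caps |log HR| at 10 and falls back to the score test; event-free trials
return a null result. The implementation matches `lifelines` to ~1e-6 on
tie-free data (where Efron and Breslow coincide) and is about two orders of
magnitude faster, which is what makes 1,000-trial calibration checks and
1,500-trial studies affordable. Type-I error at identical arms is confirmed
to lie in [0.03, 0.07] at alpha 0.05.

A parameter set's outcome label follows the replicate rule: *beneficial* if
at least two replicates reach p < 0.05 and the arithmetic-mean HR < 1,
*harmful* with mean HR > 1, otherwise *insignificant*.

At the defaults the outcome mix is asymmetric — a few beneficial sets per
502 versus a few dozen harmful — because most sampled parameter sets give a
flat or rising dose–response at 2.5 mM: a falling curve requires the
peroxide-linear damage route to dominate *and* methylselenol protection to
outcompete basal peroxide decay, a conjunction that is rare under
independent log-uniform draws. The decision-support conclusions below do
not depend on the mix being symmetric.

## Value of information

The 18 log10 rate constants of each ensemble member, labelled by whether
its trials were beneficial, train a gradient-boosted tree classifier
(300 trees, depth ≤ 3, shrinkage 0.1, logistic loss, balanced sample
weights for the ~1–5% positive class; 70/30 stratified split, decision
threshold 0.5). Relative influence is Friedman's split-improvement
importance normalized to 100%. Enrichment analyses compare the
beneficial/harmful composition of a restricted subset — classifier-predicted
beneficial, or a threshold on one parameter (a perfect pre-trial
measurement) — against the full ensemble, with exact rational fractions on
the counts. On planted-signal fixtures (4 informative of 18 features, ~5%
positives, n=500) the machinery recovers the informative features as the
top 4 influence ranks in ≥8/10 seeds with TPR−FPR ≥ 0.3; on permuted labels
it finds nothing, as it must.

## Synthetic data

All external inputs have generators: registry-style incidence tables are
produced by the multistage model itself (bin-averaged hazard per 100k, with
optional Poisson count noise at a stated person-years exposure), making
incidence fitting a parameter-recovery exercise; planted ensembles provide
labelled feature matrices with a known low-dimensional threshold rule; toy
SBML files exercise the importer's happy and error paths. Every generator
is a pure function of its spec and seed. What the synthetic SEER stand-in
does *not* emulate: real registry age-structure misfit (the multistage
shape vs. the observed plateau at high ages), cohort effects, and
screening-driven detection shifts — so a passing recovery test validates
the fitting machinery, not the model's epidemiological adequacy.

## Determinism and problem sizes

A single master seed spawns named substreams per stage (ensemble, trials
per set, split, classifier), so whole studies are bit-reproducible and
stages can be rerun independently. Full default studies (502 sets ×
3 replicates × 20,000 subjects) run in about a minute per seed on one CPU.
The test suite uses desk-scale sizes chosen for statistical decisiveness:
4,000 Gillespie realizations per solver-equivalence case, 1,000 trials for
null calibration, 500 fits for effect recovery, 20 noise seeds for fit
recovery, the full 502-set ensemble for the calibration check, and three
full studies for the enrichment check (pooled across seeds, since
beneficial counts per seed are small Poisson numbers).

## Known limitations

* The bundled network is a reconstruction honoring the documented
  constraints (18 constants, named `Rn_km`, methylselenol protective via
  peroxide reduction, selenide damaging directly and via redox-cycled
  peroxide, saturable transport/methylation/repair); an SBML file can
  replace it wholesale.
* Nothing beyond the first malignant cell is modelled — no tumour growth,
  immune clearance, competing mortality, or screening effects.
* All subjects within a trial share one parameter vector; between-subject
  metabolic variability is out of scope.
* The Cox analysis uses time-on-study; entry-age effects enter only through
  event-time generation.
* VOI is operationalized as classification/enrichment, not as a formal
  expected-value-of-perfect-information integral.
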