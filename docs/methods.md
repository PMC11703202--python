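# Methods

## The model

The early embryonic cell cycle is described as a relaxation oscillator in
two variables, total cyclin B `cyc` (nM) and active Cdk1 `cdk1a` (nM):

    d cyc/dt       = ks − kd · deg(cdk1a) · cyc
    ε · d cdk1a/dt = ka · cdc25(cdk1a) · (cyc − cdk1a) − ki · wee1(cdk1a) · cdk1a

Cyclin B is synthesized at a constant rate `ks` (nM/min) and degraded by
the APC/C–proteasome route, whose Cdk1 dependence is the increasing Hill
response `deg`.  Inactive cyclin–Cdk1 complexes (`cyc − cdk1a`) are
activated by Cdc25 and active complexes re-inhibited by Wee1; both
phosphoregulators respond to Cdk1 activity itself (`cdc25` increasing,
`wee1` decreasing), producing the bistable mitotic switch.  The responses
are treated as instantaneous (quasi-steady-state elimination of APC/C,
Cdc25 and Wee1 as dynamical variables).  `ε ≪ 1` separates the fast
switch from slow cyclin turnover, giving sawtooth cyclin oscillations with
abrupt Cdk1 spikes: slow activity ramp (interphase), abrupt jump (mitotic
entry), degradation-driven collapse (mitotic exit).  Degradation of the
switch-bound cyclin form is not modelled separately.

### Reference parameters

The packaged configuration `data/reference_params.json` is the single
source of truth for default parameter values.  Hill response shapes follow
the experimentally measured ultrasensitive steady-state responses of
APC/C, Cdc25 and Wee1 to Cdk1 activity in cycling frog egg extracts
(APC/C: EC50 32 nM, n 17; Cdc25: EC50 35 nM, n 11; Wee1: EC50 30 nM,
n 3.5).  Two calibration choices were made once,
then frozen:

* The basal (interphase) APC/C activity is 2% of maximal (basal 0.02,
  amplitude 0.98).  This sets the dynamic range of degradation and hence
  the fold-range of `ks/kd` over which the system oscillates rather than
  arresting; a ~5-fold dynamic range (basal 0.2) leaves the oscillator too
  fragile to cover a ≥ 15 °C operating range plus the synthesis titrations
  studied here.
* With that switch geometry, `ks = 1.2 nM/min`, `kd = 0.08 /min`,
  `ka = ki = 1 /min`, `ε = 0.01` yield a limit-cycle period of ≈ 30.8 min
  at the 20 °C reference temperature, with rising phase ≈ 23 min and
  falling phase ≈ 7 min (interphase constitutes the majority of the
  cycle, as observed in extracts).

### Temperature mapping

Each kinetic scale (`ks`, `kd`, `ka`, `ki`, and the rate-like `1/ε`)
carries its own rate-scaling curve — Arrhenius
`k(T) = k_ref · exp(−Ea/R · (1/T − 1/T_ref))`, or biphasic (the
reciprocal of a two-branch double-exponential duration curve, expressing a
rate optimum from, e.g., enzyme impairment at high temperature).  Hill
shape parameters are temperature independent; only the five kinetic scales
move.  Anchoring at the reference temperature keeps parameter values
interpretable and lets titration scans multiply a curve by a constant
factor without touching its activation energy.

`ε` is a *ratio* of time scales.  When all four rates share one activation
energy the dynamics is an exact time rescaling of the reference orbit, so
`ε` must stay constant in that scenario; the map therefore applies no
scaling to `1/ε` unless one is requested explicitly (as in fits where the
switch time scale is inferred separately from `ka`, `ki`).

Integration uses stiff-capable solvers: BDF at rtol 1e−8 / atol 1e−10
over 1000 min for production simulations (period detection differentiates
peak positions, so tolerances are tighter than typical defaults), and
LSODA at rtol 1e−5..1e−6 over 250–400 min inside parameter sweeps and
ABC, where tens of thousands of simulations are needed and phase-duration
errors of ≲ 1% are immaterial against the log-scale distances used.
Initial state is (cyc, cdk1a) = (0, 0) unless configured.

### The extract-calibrated map

`oscillator.extract_calibrated_map()` encodes the scaling regime inferred
from cycling-extract data: biphasic cyclin synthesis (cold-branch
Ea 113 kJ/mol, rate turning over near 30 °C with a steep 300 kJ/mol hot
branch), shallow Arrhenius degradation (Ea 49 kJ/mol), and a common
60 kJ/mol for the switch rates.  The synthesis anchor sits at 0.6× the
embryo-calibrated reference: extract cycles are slower than embryonic
ones, and this placement leaves headroom for upward synthesis titration —
rescaling by ×1.6 (synthesis) and ×0.7 (degradation) then reproduces the
faster embryonic cycling at 25 °C.  The hot-branch energy and crossover
temperature are design choices constrained qualitatively (oscillations to
≈ 32–34 °C, synthesis-rate decline above ≈ 30 °C), not fitted quantities.

## Period analysis

Peaks of the cyclin variable are detected with prominence ≥ 10% of the
series range and ≥ 5 min separation (robust for sawtooth shapes across
solver output densities).  The period is the spacing of the last two
peaks; if their heights differ by more than 5% (relative) the trajectory
is classified as damped, not oscillating.  The 5% figure is a documented
default, exposed in the API.  Rising and falling phase durations are the
trough→peak and peak→trough intervals of Cdk1 activity in the final full
cycle.  Thermal limits of a period-vs-temperature curve are the outermost
oscillating grid temperatures, refined by bisection to 0.1 °C (matching
the 1 °C experimental binning resolution); the optimal temperature is the
period argmin with quadratic refinement.  Note that a detected `T_min` can
be an operational limit — the period growing beyond what the simulation
horizon resolves — rather than a bifurcation; fixed-point analysis
distinguishes the two.

## Scaling laws and fitting

Four duration-vs-temperature forms are supported: single-exponential
Arrhenius (SE), double exponential (DE), quadratic exponential (QE) and
power-law exponential (PE).  Signs follow each law's printed convention:
the Arrhenius *duration* carries +Ea/RT while DE/QE/PE carry −Ea/RT, so a
U-shaped DE fit has branch energies of opposite sign; the helper
`apparent_ea` (slope of ln Δt vs 1/T at a stated temperature) makes
cross-law comparisons well defined.

Fitting always starts from per-integer-°C bins (round-half-to-even) of
the raw measurements, reduced to per-bin medians.  SE is ordinary least
squares of ln Δt on 1/T; QE and PE are linear in their parameters on logs
and fitted the same way.  DE uses a three-step procedure: SE fit on a
declared linear interval; SE fit to the positive duration residuals
outside it; joint nonlinear least squares *on durations* seeded by both
(falling back to a single branch, with a warning, when no positive
residuals exist).  Model comparison always uses MSE on log durations —
the refinement objective and the comparison metric are deliberately
distinct.  Dataset-specific exclusions (e.g. a suspect lowest-temperature
bin) are configuration, never hard-coded.

Uncertainty on fitted activation energies comes from a stratified
bootstrap: individual measurements are resampled with replacement within
their temperature bin (preserving the temperature design and the
per-embryo/per-droplet replication structure), re-binned, re-fitted; the
5th–95th percentiles of the resulting Ea distribution form the 90%
interval.  Resampling is seeded and bit-reproducible.

## ABC-SMC inference

Activation energies are inferred from binned-median period or
phase-duration summaries by approximate Bayesian computation with
sequential Monte Carlo, implemented in-package: generation 0 samples the
prior; each later generation sets ε to the median of the previous
generation's distances, resamples particles by weight, perturbs them with
a component-wise Gaussian kernel (sd = √2 × weighted std), and reweights
by the standard prior-to-kernel importance ratio.  Stopping: generation
budget, ε stalling (< 1% relative change), or an exhausted per-generation
simulation budget (15 × population), in which case the last completed
generation is returned with a warning.

Distances are mean squared errors on log durations over shared
temperature bins; phase-based distances average the rising and falling
channels with equal weight.  A temperature where the data oscillate but
the model does not contributes a fixed penalty π₀ = 10 to the squared-log
pool (the fits implicitly require oscillation across the data range);
π₀ is exposed in the API.  Default stand-in priors: Ea uniform on
[−100, 250] kJ/mol (negative values express biphasic branches), anchors
log-uniform within ×/÷10 of the reference.  The recovery experiment run
by the tests and the acceptance script infers (Ea(ks), Ea(kd)) with the
switch energies held at their known generator values, population 200,
≤ 5 generations — problem sizes chosen so the full posterior experiment
remains a routine desk computation.

Posterior summaries report the weighted mean, a weighted-KDE mode
(Gaussian kernel, Scott-type bandwidth) and the weighted 5th–95th
percentile interval; mode and mean are computed separately because
energy posteriors are typically skewed.

## Droplet and assay pipelines

Droplet QC keeps tracks with radius < 100 μm and track start ≤ 60 min,
with a per-droplet rejection log.  FRET-ratio traces are lightly smoothed
(3-sample moving average) before extremum picking; peaks/troughs require
prominence ≥ 20% of the per-droplet range and ≥ 15 min separation
(extract periods are ≳ 30 min).  Between consecutive peaks one trough is
enforced, placed at the *first arrival* within 5% of the valley depth
rather than at the argmin: in traces with a sharp post-peak drop and a
flat interphase valley the argmin jitters across the whole valley under
noise, while the arrival point marks mitotic exit robustly.  These
thresholds replace the manual curation step of an interactive analysis
and are all configurable.  Cycle selection follows either the cycles-2–4
convention (1-based from the first complete trough-to-trough cycle) or
all cycles whose starting trough lies before 300 min.  The interphase
slope (a cyclin-synthesis proxy) is the least-squares slope over the
central 10–90% of a rising segment.  Average waveforms rescale each
selected cycle to phase ∈ [0, 1] trough-to-trough and resample linearly
onto a fixed phase grid — a stated convention of this package.

Assay rates: synthesis/kinase/phosphatase traces yield the slope of the
initial linear window, grown greedily while the fit keeps R² ≥ 0.95;
degradation traces yield the decay constant of a log-linear fit after
subtracting a plateau baseline (mean of the final 10% of samples), with
points within 5% of the estimated plateau excluded so baseline-estimation
bias does not leak into the slope.  Per-kind activation energies then
follow the standard binning/fitting/bootstrap path on effective durations
1/rate.

## Synthetic data

The generators define the study conditions for every pipeline:

* **Event timings**: durations `law(T) · exp(ε)`, ε ~ N(0, √ln(1+cv²)) —
  multiplicative lognormal noise with zero log-mean, so per-bin *medians*
  are unbiased for the generating law (matching the median-based
  pipeline).  Default cv 5%, 10 embryos per °C.
* **Droplets**: two-ODE trajectories at each droplet's temperature,
  Cdk1 activity mapped affinely onto a FRET-like ratio range [0.9, 1.4]
  (only shape and timing matter downstream), resampled at 5 min (within
  the 3–7 min experimental imaging cadence; closure tests use 2 min),
  with optional additive Gaussian observation noise and per-cycle period
  drift (+5%/cycle emulates the slow lengthening of extract cycles; drift
  multiplies the time axis piecewise by (1+d)^j on cycle j).  Radii are
  Gaussian (60 ± 20 μm, clipped at 5) and track starts uniform, so QC has
  genuine work to do.
* **Assays**: linear traces with the true rate as slope, or
  baseline + e^(−kt) decays; Gaussian noise; all seeded.

What the generators do *not* emulate: droplet-to-droplet biochemical
variability beyond observation noise and drift, photobleaching,
temperature-gradient drift within an experiment, or segmentation/tracking
artifacts.  Passing closure tests therefore demonstrates correctness of
the analysis pipeline, not robustness to every failure mode of real
microscopy data.

## Problem sizes

Tests and the acceptance script use deliberately compact experiment
sizes, chosen as routine desk-scale computations: temperature sweeps on
1–2 °C grids over ≈ 8–36 °C with 400 min horizons; ABC with population
200 and ≤ 5 generations on five temperatures (≈ 2500 model evaluations);
droplet closure with 4 droplets × 3 temperatures; assay emulation with
4 traces × 6 temperatures per regulator.  All randomness is seeded.

## Known limitations

* The reference parameter set is a calibrated representative of its model
  family, not a transcription of a specific fitted dataset; quantities
  that depend on absolute parameter values (exact thermal limits, exact
  extract periods) are reproduced qualitatively, not digit-for-digit.
* The two-ODE model omits Greatwall/PP2A-B55 regulation; the temperature
  map interface accepts any parameter-to-map builder, so structurally
  different models can be plugged into the same sweep/ABC machinery.
* ABC results depend on the oscillation penalty π₀ and the ε schedule;
  both are exposed and documented rather than hidden.
* `distance_phases` requires the model to oscillate at the observed
  temperatures; regimes where the data themselves arrest are outside the
  fitted range.
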