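# Methods

This note records the models, conventions, and design decisions behind
`phenox`, in the spirit of a model-documentation page: what is assumed,
what is configurable, and what the synthetic benchmarks do and do not
demonstrate.

## The flux model

Reduced PCA (`PCA_red`, µM) can be oxidized by a respiring cell through
three routes, modelled as a single ODE system (time in hours):

- **Category 2 (quinone pool):** mass action per quinone species q
  (ubiquinone UQ, menaquinone MQ, demethylmenaquinone DMQ),
  `v2_q = k2_q · PCA_red · Q_ox_q`. The quinol produced is re-oxidized by
  terminal reductases at
  `v_resp_{r,q} = Vmax_r · e_r · compat[r][q] · (Q_red_q / Q_tot_q) ·
  TEA/(TEA + K_TEA)`.
- **Category 1 (direct reductase):** `v1_r = k1_r · e_r · PCA_red ·
  TEA/(TEA + K_TEA)` — reduced PCA substituting for a quinol at the
  reductase.
- **Category 3 (abiotic):** `v3 = k3 · PCA_red · TEA`.

Every PCA or quinol oxidation transfers 2 electrons; each supported
acceptor (nitrate→nitrite, fumarate→succinate, DMSO→DMS, TMAO→TMA) takes 2
electrons per molecule, so `dTEA/dt = −(v_resp + v1 + v3)` in
PCA-equivalents. The integrator (LSODA, rtol = atol = 1e−9) conserves the
PCA pool, each quinone pool, acceptor + product, and the two-electron
bookkeeping to well below 1e−6 relative (verified over 100 random
parameter/genotype draws).

**Genotype gating.** Knockouts zero their terms. Quinone availability
derives from biosynthesis genes: MQ needs *menA*; DMQ needs *menA* and
*ubiE*; UQ needs *ubiC* and *ubiE*. Acceptor→reductase mapping: nitrate
{NapA, NarG, NarZ}, fumarate {FrdA}, DMSO {DmsA}, TMAO {TorA, DmsA,
TorYZ-like} (the DMSO reductase promiscuously reduces N-oxides; a single
aggregate TorYZ-like flag stands in for additional TMAO reductases).
Compatibility defaults: Nar complexes accept all three quinones, Nap only
UQ and MQ, and the fumarate/DMSO/TMAO reductases only MQ and DMQ.

**Pregrowth expression weights** `e_r ∈ [0, 1]` encode the regulatory
state rather than measured expression. Oxic pregrowth: NarZ 1.0, NarG 0.2,
NapA 0.0 (stationary-phase σ-factor regulation dominates; the periplasmic
reductase is silent). Hypoxic pregrowth: NarG 0.8, NarZ 0.5, NapA 0.5.
These are calibration knobs chosen so the qualitative knockout hierarchy
holds — wild type > every single reductase knockout > every double >
triple = abiotic — which requires the dominant weight to stay below half
of the weight sum; NarG remains dominant under hypoxia as observed.

**Initial conditions.** Defaults: 200 µM PCA_red, 10 mM acceptor (K_TEA =
100 µM, so oxidation runs at near-saturation until the acceptor is nearly
exhausted), 10 µM per quinone pool. The quinone pools start **fully
reduced** (`q_red_frac0 = 1`): cells enter the anoxic assay without an
acceptor, so electrons back up in the pool. This matters: with oxidized
pools, a reductase-free genotype would still show a fast transient while
PCA charges the pool (~30 µM), which is not what a dead-end chain does
over assay timescales. Default rates (k2 = 0.05 /µM/h, Vmax = 12 µM/h per
reductase, k1 = 0.01 /µM/h, k3 = 1e−7 /µM/h) put the wild-type maximum
oxidation rate near 50 µM/h (half-oxidation in a few hours), the
quinone-mediated route roughly an order of magnitude above the direct
reductase route, and the abiotic route at ~0.2 µM/h (never reaching 50%
within 48 h).

Acceptor spikes are handled by piecewise re-initialization at spike times;
an optional transport lag gates all cell-dependent fluxes before `lag_h`
(lag = 0 reduces exactly to the no-lag model). An optional `k_rereduce`
term (off by default) lets cells net-reduce the provided PCA, producing
rising fluorescence and negative maximum oxidation rates downstream.

The model deliberately omits proton-motive force, growth, downstream
denitrification, and spatial structure. One observed phenotype it does not
reproduce — faster DMSO-driven oxidation after losing ubiquinone alone —
is left unmodelled rather than fitted.

## Electron tower and screens

The shipped table holds literature midpoint potentials at pH 7 (PCA
−0.116 V, pyocyanin −0.040 V, MQ −0.074 V, DMQ +0.036 V, UQ +0.100 V,
fumarate/succinate +0.033 V, TMAO +0.130 V, DMSO +0.160 V,
nitrate/nitrite +0.433 V), all 2 e⁻/2 H⁺ couples here. Users can override
the table via YAML. Favorability is strictly ΔE > 0 (ties count as
unfavorable); temperature defaults to 298.15 K — the screens are
qualitative and insensitive to the few-kelvin difference from a 30 °C
assay.

Two screens are distinct on purpose. `favorable_acceptors` is the raw
pairwise screen. `respiratory_drive_screen` asks whether a terminal
acceptor can drive phenazine oxidation *through the chain*: some quinone
must be downhill of the phenazine, uphill of the acceptor, and accepted by
that acceptor's reductase. The distinction is what makes fumarate a driver
of PCA oxidation (via MQ) but not of pyocyanin oxidation: MQ cannot oxidize
pyocyanin, DMQ (+0.036 V) sits just above fumarate (+0.033 V), and the
fumarate reductase does not engage UQ — even though the direct
pyocyanin–fumarate pairing is mildly favorable.

## Synthetic plate data

The phenomenological well family is
`F(t) = F0 · (floor + (1 − floor) · shape(s(t)))`, with
`shape(s) = w·exp(−k_fast·s) + (1−w)·exp(−k_slow·s)` a biphasic decay and
`s(t)` a softplus ramp of width `lag_transition_h` after the lag (width 0
gives a hard kink; the smooth default reflects the gradual onset seen in
real wells and keeps the maximum-rate region resolvable by a local-linear
smoother). An optional transient rise models early net reduction. Ground
truth (maximum of −dF/dt, its time, and the threshold crossing) comes from
the closed-form derivative on a dense grid, independent of the LOWESS
path. Model-backed wells use the simulated trajectory on a 0.02 h grid
with numeric differentiation instead.

Replicate structure: biological replicates jitter F0, the two rate
constants (lognormal, 5% default) and the lag; technical replicates share
the biological draw and differ only in noise. Noise is multiplicative
CV 0.5% plus 1 AU additive per time point, clipped at zero — typical
precision for a modern fluorescence reader on a ~1000 AU signal, and the
level at which the default pipeline recovers the true maximum rate within
10% for ≈98% of wells (50 seeds). The grid is 15-minute cadence over 48 h
(193 points). The abiotic control drifts slowly (single exponential,
0.002 /h) rather than staying flat. Not emulated: well-position effects,
evaporation, optical crosstalk, reader gain drift. Passing the recovery
benchmarks therefore shows the estimator is correct and noise-robust at
realistic noise, not that it is immune to structured artifacts of real
plates.

Current traces convert the instantaneous PCA oxidation flux to µA via
2F and a configurable reactor volume (default 10 mL), with the electrode
emulated by clamping `PCA_red` (the poised electrode re-reduces PCA as
fast as cells oxidize it).

## Kinetic feature extraction

LOWESS is implemented as per-point local linear weighted least squares:
for each observation, the `ceil(fraction·N)` time-nearest neighbors (ties
toward earlier points), tricube weights on distance scaled by the window
span, optional bisquare robustness passes. Both the fitted value and the
fitted **slope** are returned — the slope *is* the rate estimate, which is
why the smoother is written here rather than wrapped: generic LOWESS
implementations discard the local derivative. Equivalence with a
brute-force per-point WLS oracle is enforced to 1e−8 across all window
sizes for N ≤ 50, and fitted values match an independent LOWESS
implementation where the window conventions coincide (fraction 1).

Metric conventions, all configurable:

- the 100%-reduced **baseline** is the mean of the first 3 smoothed points
  (robust to first-point noise; for curves decaying from t = 0 the
  single-point anchor is the right choice and is available);
- `t_half` is the first linear-interpolated crossing of the smoothed
  fraction-oxidized through the threshold (0.5); wells that never cross
  report the sentinel `NOT_DETECTED` — never 0, never the assay end time;
- the maximum oxidation rate is the maximum of −slope; net-reducing wells
  report it negative, and the early-time baseline (not a later maximum)
  keeps such wells `NOT_DETECTED`;
- technical replicates are averaged *after* per-well metric extraction
  into their biological replicate, the unit carried to statistics;
- window fraction defaults to 0.05 with no robustness passes — the
  sensitivity scan (`scan_fraction`) shows a stability plateau around
  that value on synthetic wells, with heavier smoothing attenuating the
  rate peak.

Current integration is trapezoidal (µA·h → C via 3.6e−3; PCA-equivalents
at 2 e⁻ per molecule); net-negative charge is permitted and logged.

## Statistics

Default test: Welch's unequal-variance two-sided t on biological
replicates. With n = 3 per group an exact permutation test cannot reach
p = 0.1, let alone a corrected threshold like 0.00179, so corrected
significance at realistic panel sizes requires the parametric test;
Student's t and the permutation test (exact up to 20 000 assignments, then
Monte Carlo) remain available. The Bonferroni threshold is α/m with m
counting **all** unordered group pairs, including untestable groups
(n < 2), which stay in the matrix flagged `insufficient-n`. Thresholds are
displayed at 3 significant figures; decisions use full precision. The
all-null simulation (4 groups, n = 3, 2000 draws) confirms the family-wise
double-flag rate stays below α, as Bonferroni guarantees conservatively.

## Problem sizes and determinism

The benchmark suites use: 50 seeded plates × 18 sample wells for noisy
recovery; 100 random draws for conservation; N ≤ 50 instances for the
smoother oracle; 2000 all-null simulations for the error rate. All
randomness flows through explicit integer seeds (`numpy` Generators); the
ODE solver and pipeline are deterministic for fixed inputs, and pipeline
outputs carry seed/config-hash provenance headers.

## Known limitations

- Rate laws are the minimal mass-action/Michaelis–Menten scheme that
  reproduces the knockout phenotypes; rate constants are not fitted to any
  dataset, so simulated rates are in consistent but arbitrary units of the
  assay (µM/h at 1 AU/µM calibration).
- The expression weights conflate regulation, translation and enzyme
  activity into one factor per reductase.
- Fluorescence is assumed strictly linear in PCA_red with no inner-filter
  effects.
- The permutation test enumerates group labels only pairwise, not across
  the whole panel simultaneously.
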