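# Methods

## The competing-clocks model

A post-restriction-point (post-R) cell that loses mitogen signalling at
time 0 carries two independent timers: the remaining time to mitosis
`T_M` and the time to lose CDK2 activity `T_E`.  The observed fate is the
smaller of the two; the loser is censored by construction (a cell that
divides cannot later be seen to exit, and vice versa).  Independence of
the two clocks is a modelling assumption carried throughout; no
correlation knob is offered, because the package's purpose is to test
whether independent clocks already account for the observed fate
frequencies and post-competition timing distributions.

Both clocks are modelled as log-normal (positive, right-skewed times;
an empirical resampling family is available where no shape assumption is
wanted).  For log-normal clocks with medians `m_E, m_M` and log-scale
s.d. `s_E, s_M`, the exit probability has the closed form

    P(T_E < T_M) = Φ( ln(m_M / m_E) / sqrt(s_E² + s_M²) ),

used as the independent oracle for the Monte Carlo race.  Exact ties are
resolved in favour of mitosis; they have probability zero under
continuous families and only matter for point-mass inputs.

## The kinetic exit clock

Loss of CDK4/6 activity dephosphorylates p107/p130 within 1–2 h; the
active repressors shut off CCNA2 transcription.  The exit clock is then a
linear shutoff cascade: mRNA decays with half-life `h_m` (default 2 h,
matching a 50% mRNA drop 2 h after CDK4/6 inhibition), protein integrates
the mRNA and decays with half-life `h_p`, and CDK2 activity tracks
protein.  From the pre-treatment steady state,

    A(t) = (λ_p e^(−λ_m t) − λ_m e^(−λ_p t)) / (λ_p − λ_m),

with the equal-rate limit `(1 + λt)e^(−λt)`.  The deterministic exit time
solves `A(t) = 1/ρ` by bracketed root search (Brent, xtol 1e-6 h; the
curve is strictly decreasing so the root is unique).

Calibration choices:

* **ρ = 2** (pre-treatment cyclin A2 at twice the exit-threshold
  level).  Not a measured quantity; chosen once so that `h_p = 12 h`
  gives an exit clock of ≈ 15 h, the MCF-10A pair.  All other presets
  inherit ρ = 2 unchanged.
* **Instantaneous transcription shutoff** at treatment; the 1–2 h
  repressor-activation delay is absorbed into `h_m`.  In the ODE network
  model (below) the delay is explicit instead.
* Under this calibration the cross-preset regression of predicted exit
  time on half-life (12/10/5/2 h) gives slope 1.024, intercept 2.89 h,
  r² = 0.9996.  The intercept sits at the upper end of the "same order
  as the mRNA-loss time" expectation rather than below 2 h; it is
  asserted only as a 2–3 h property and deliberately not tuned.

Half-life estimation is ordinary least squares on log2(level) vs time;
half-life = −1/slope with the standard error propagated by the delta
method.  A non-negative slope is an explicit error, not an infinite
estimate.  The estimator is exactly unbiased for log-normal
multiplicative noise (the log transform makes the noise additive).

## The synthetic trace generator

The generator emulates live-cell imaging of cells carrying a CDK2
translocation sensor (dimensionless activity; 0.6 is the commitment
threshold), an APC/C activity sensor (high in G0/G1, switched off at S
entry, reactivated at division or premature exit), and optionally a
cyclin A2 abundance channel.  Defaults:

* sampling grid 0.2 h (≈ 12-min imaging), horizon 48 h, treatment at
  12 h;
* S→M duration log-normal, median 14 h, log-sd 0.18; treatment lands
  uniformly within 6 h after S entry, so the remaining-mitosis time
  `R = max(D − u, 0.5 h)` has median ≈ 11 h and is longer for cells
  treated nearer S entry — this is what produces the declining
  exit-probability-vs-offset trend;
* exit clock = kinetic prediction × a median-1 log-normal cell factor
  with log-sd 0.22.  The dispersions are calibrated so the competition
  produces an exit fraction in the 10–15% band for the idealized race;
* sensor noise: additive Gaussian s.d. 0.03 on the CDK2 and APC/C
  channels, 4% multiplicative on cyclin A2;
* treatments: DMSO and CDK1i leave mitogen signalling intact (no exit
  clock); mitogen removal, MEKi and CDK4/6i are equivalent exit-clock
  triggers; CDK1i-containing treatments disable the mitosis clock;
  `delay_hours` extends the mitosis clock (S-phase stall pulses);
  constitutive cyclin A2 disables the exit clock.  A partial MEKi dose
  maps to a mitogen level S = 1 − d for the ODE module only — the trace
  generator treats only the full dose as an exit trigger, since no
  kinetic dose–response mapping is available.

What the generator does **not** emulate: lineage trees beyond recorded
division times, cell death, cell-cycle-phase-dependent sensor dynamics
beyond simple ramps, segmentation/tracking artefacts, or correlated
noise.  Passing tests therefore demonstrate the correctness and
calibration of the analysis chain on data with the assumed statistical
structure, not robustness to microscopy artefacts.

Because the realized mitosis clock `max(D − u, 0.5)` mixes the S→M
duration with the treatment offset, its dispersion (fitted log-sd ≈ 0.30)
exceeds the nominal 0.18 of the idealized race, and the trace-level exit
fraction (≈ 0.18) runs somewhat above the idealized Monte Carlo value
(≈ 0.13).  The race on clocks *fitted from the traces* reproduces the
trace-level fraction (0.167 simulated vs 0.185 observed in the 1000-cell
study run).

## Feature extraction

S entry is the first APC/C crossing below 0.5 sustained for ≥ 1 h;
cell-cycle exit is the first post-treatment CDK2 crossing below 0.6
sustained for ≥ 2 h with no intervening division, reported at the
interpolated crossing time.  The imaging literature plots thresholded
traces without stating a debounce; the 2 h window is this package's
convention for rejecting sensor noise.  Before exit detection the CDK2
channel is passed through a 1 h centred moving-median filter — exact on
monotone segments (a clean ramp's crossing is unmoved), it prevents the
debounce from systematically delaying detected crossings in the presence
of frame-to-frame noise.  Mitosis comes from the division event channel
when present, otherwise from a one-frame CDK2 collapse of ≥ 50% of the
running maximum (while that maximum exceeds 1.0).  The post-anaphase
CDK2 collapse is explicitly excluded from exit detection by requiring no
division up to the first below-threshold frame.

Post-R status is the APC/C being off at the treatment frame, with a 1 h
grace period after APC/C inactivation.  Decided post-R fates partition
into MITOSIS / EXIT; cells with neither event and CDK2 still high are
kept as a separate right-censored COMMITTED class rather than forced
into either fate.  The logistic model of exit vs mitosis is fitted on
per-cell binary outcomes against the treatment offset (bins are for
display only); the p-value is a two-sided Wald test of the slope.
Perfect or quasi-separation (non-convergence, |slope| > 50 or SE > 10³)
is returned as a flagged degenerate result.

## Network models

Both architectures are built from the measured time scales of the
pathway (repressor activation within 1–2 h, mRNA half-life 2 h, protein
half-life per cell line); absolute rates are otherwise free choices, and
only the architectures' qualitative signatures are asserted.

**Feedback** (textbook switch): a reduced 4-variable Rb–E2F module in
the spirit of the Yao et al. serum switch — CDK4/6 tracks mitogen;
Rb phosphorylation follows zero-order-ultrasensitive
(Goldbeter–Koshland) kinetics driven by CDK4/6 + CDK2; E2F is released
by Rb phosphorylation; CDK2 synthesis follows E2F.  Note the loop here
is closed through CDK2 itself (E2F autocatalysis gated only by Rb), so
once ignited the ON state is self-sustaining at zero mitogen — the
defining property of the textbook model that the full serum-gated Yao
parameterization does not have (its E2F synthesis requires Myc and hence
serum, so it switches off at S = 0).  The switch is bistable for
S ∈ [0, ≈0.4] and hysteretic (width ≈ 0.40 on the dose axis).

**Feed-forward**: mitogen → CDK4/6 (τ = 0.25 h) ⊣ active p107/p130
(τ = 0.5 h; fully dephosphorylated within ~1.5 h) ⊣ CCNA2 transcription
→ mRNA (t½ = 2 h) → protein (t½ per preset, default 12 h) → CDK2
(saturating readout, K = 0.15); Rb phosphorylation is a passive readout
with no return edge to transcription.  The chain is monotone, so every
mitogen level has a unique steady state: no hysteresis at steady state,
but after mitogen removal the mRNA halves by ≈ 2.8 h (2 h decay plus the
explicit repression onset) while CDK2 stays above 95% of its initial
value past 9 h — the apparent-irreversibility window at the time cells
normally enter mitosis (hysteresis width ≈ 0.43 at 11 h, ≈ 0 at steady
state).  `knockout_repressor` pins the repressor at zero;
`constitutive_ccna2` pins transcription on; both pin CDK2 high after
mitogen removal, the two rescue experiments.

All rates live in `src/clockrace/data/network_params.json`.  Numerical
choices: LSODA with rtol 1e-8/atol 1e-10 (trajectories change < 1% when
tolerances are halved); steady state declared when the derivative norm
falls below 1e-8, with a 500 h cap; MEKi dose d maps linearly to mitogen
S = 1 − d (no mapping is published); half-maximal dose crossings are
located by monotone linear interpolation on a 0.005-resolution dose grid
(0.02 in the test suite).  A branch that never crosses half-maximum
contributes the dose-range endpoint, so an irreversibly-ON high branch
yields a positive width.

## Problem sizes and determinism

The study runs use 1000–2000 cells per cohort, 300 cells per decay
assay, 10⁵ Monte Carlo pairs and 48 h recordings — large enough that
the recovered medians sit well inside the 5% bands asserted for them.
Every random quantity flows from one master seed through per-stage
SHA-256-derived sub-seeds (< 2³¹), so pipeline summaries are
byte-identical across runs with the same configuration.

## Known limitations

* The exit-clock dispersion (log-sd 0.22) and the S→M dispersion (0.18)
  are calibrations, not measurements; the published per-cell-line
  dispersions were not available.
* The U2OS preset's 13 h half-life is a placeholder (the printed value
  was unavailable) and is excluded from quantitative half-life checks.
* The ODE parameterizations are qualitative reconstructions; only
  bistability/hysteresis presence or absence, steady-state levels and
  the ordering of component loss are meaningful, not absolute rates.
* The analysis treats the treatment time as known exactly per cell, as
  in a drug-spike imaging experiment; staggered or uncertain treatment
  times are not modelled.
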