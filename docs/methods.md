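# Methods

## Model structure and assumptions

The host cell is reduced to three proteome classes — metabolic (`a`),
ribosomal (`r`) and housekeeping (`q`) — plus charged and uncharged tRNA.
Housekeeping expression is condition-independent and is not modeled
explicitly: its fixed mass share `phi_q = 0.59` enters only through the
`1/(1-phi_q)` factor of the resource-competition denominator `D`, which
discounts every transcript's translation rate for competition from all
others (housekeeping mRNAs included). Competitive ribosome binding is never
simulated reaction-by-reaction; it is collapsed into effective rate
constants with apparent dissociation constants
`k_i = (k_i^- + eps/n_i)/k_i^+`, recomputed from the instantaneous
elongation rate at every evaluation.

Growth is not a parameter. The finite-proteome trade-off fixes
`lambda = eps*B/M`: the cell dilutes exactly as fast as it synthesizes
protein, so the modeled protein mass converges to `M` from any positive
start (this is asserted to 0.1% in the tests). `M` counts the modeled
(non-housekeeping) proteome; mass fractions reported by the package
(`phi_r = n_r R/M`, `phi_X = n_x p_x/M`) are shares of that modeled
proteome. Multiplying by `1-phi_q` converts them to total-proteome shares,
which is the form in which the linear burden law
`lambda/lambda_NB = 1 - phi_X_total/(1-phi_q)` holds; with that pairing the
three analytical relations (mass-fraction prediction, growth prediction,
linear law) are mutually consistent as an exact identity, which the test
suite checks on random parameter draws.

Resource allocation follows flux-parity regulation: the ppGpp level is
tracked through its reciprocal proxy `T = t_c/t_u`, and ribosomal plus tRNA
transcription are co-repressed through `F_r(T) = T/(T+tau)`. At `t_u = 0`,
`T` is capped at 1e12 so `F_r -> 1` smoothly. Metabolic transcription is
constitutive (`F_a = 1`) in every medium.

Chloramphenicol extension: the drug binds and disables translating
ribosomes at rate `k_cm*h_cm`. Apparent dissociation constants gain an
additive `k_cm*h_cm/k_i^+` term, operational ribosomes lose an inactivation
flux `k_cm*h_cm*B`, and inactivated ribosomes `B_cm` dilute only. The
experimentally visible ribosome content is `n_r*(R+B_cm)/M`. Setting
`h_cm = 0` recovers the base model exactly (tested).

## Parameters

Defaults ship in `src/rcell/data/host_default.yaml`; every function takes
parameters explicitly, so alternative parameterizations are config-only.
Literature-anchored values: `M = 1.19e9` nM-aa (about 1e9 amino-acid
residues per um^3), `phi_q = 0.59`, `eps_max = 7.2e4` aa/h (20 aa/s),
`n_a = 300` aa, `n_r = 7459` aa (summed r-protein length), `beta = 6` 1/h
(about 7-min mRNA half-life), ribosome-RBS kinetics `k^+ = 60` 1/(nM h) and
`k^- = 60` 1/h, native gene dose 1 nM (one chromosomal copy per um^3).

The remaining host rates have no single literature value and were calibrated
once, jointly, against the phenomenology the model must reproduce — a
physiological growth range (lambda from about 0.25 to 2.0 1/h over sigma in
[0.05, 1]), first/second growth-law geometry, near-optimal ppGpp allocation,
and the controller's design operating points — and then frozen:
`nu_max = 4000` 1/h, `K_eps = K_nu = 3000` nM (flux parity motivates the
equality), `psi_max = 1e4` nM, `tau = 0.04`, `alpha_a = 1e5`,
`alpha_r/alpha_a = 0.85`, `k_cm = 0.3` 1/(uM h). The half-saturation `tau`
deserves comment: because the regulated steady state lies *on* the
constant-T growth curve, near-optimality is equivalent to `tau` placing the
self-consistent point at that curve's (flat) maximum for every sigma; with
this parameterization the worst deficit over sigma in [0.05, 1] is about
0.6%.

Controller defaults (`build_aif_controller`): `u = 0.4`, `K_sens = 3722` nM,
`kappa = 1e4`, `chi = 3e5`, `theta = 500` 1/(nM h), sensor
`c = 10, alpha = 60, n = 300`, amplifier half-saturation `K_amp = 1000` nM.
`K_sens` was set by one-point calibration of the *simulated* undisturbed
closed loop at sigma = 0.25 to its design growth rate (0.566 1/h); the
sigma = 0.75 operating point (1.462 1/h) was held out and is reproduced to
within 0.3%.

## Synthetic circuits

Circuits are declarative: genes (mRNA/protein pairs), small RNAs
(transcribed, never translated, hence burden-free), Hill-type regulation
functions bounded in [0, 1] with optional leaky baselines and
inducer-modulated regulators, and annihilation pairs that remove one
molecule of each partner (the duplex is treated as instantly degraded).
Growth-uncoupled transcription (for genes driven by orthogonal machinery
such as T7 RNAP) drops the `lambda` factor from the synthesis term.

Toxicity is implemented as translation poisoning: `eps_max` is scaled by
`1/(1 + p_tox/K_tox)`. A penalty applied to `lambda` itself was tried first
and rejected because it breaks the finite-proteome constraint (synthesis no
longer balances dilution and the protein mass diverges); scaling the
elongation capacity slows growth by the same intuition while keeping
`lambda = eps*B/M` exact.

Case-study builders and their design points:

- **Winner-takes-all** (`build_winner_takes_all`): two self-activating
  switches (Hill 2, baseline 0.03, K = 6e4 nM on the inducer-bound protein,
  inducer binding constant 100 nM, `c*alpha = 1e5`). The protocol
  pre-equilibrates with no inducer, then steps both inducers in. Equal
  inducers (20 nM) co-activate; an 800 vs 20 nM asymmetry lets the fast
  switch capture the ribosome pool and hold the slow one below threshold.
  The effect is quantified as the loser-suppression ratio (loser's level
  under asymmetric induction relative to its co-activated level), which
  rises from ~0.06 at full demand to ~1 when both RBSs are weakened 5-10x.
  A 100x weakening takes the switches out of their bistable regime entirely
  for any fixed threshold, so the fading is demonstrated over the 1-10x
  range.
- **T7 self-activator** (`build_t7_self_activator`): one gene, Hill-1
  self-activation, growth-uncoupled transcription, toxicity `K_tox = 3e4`
  nM, active degradation 0.15 1/h. Bistability is genuinely
  growth-mediated: higher T7 burden and toxicity slow growth, which depletes
  the growth-coupled native transcript pool and raises the T7 translation
  share. The degradation floor keeps the high state at finite growth
  (about 0.11 1/h vs 1.32 1/h in the low state) rather than at the
  proteome-cap dormant state. Removing toxicity and weakening the feedback
  makes the circuit monostable (tested by multi-start).
- **AIF controller** (`build_aif_controller`): constitutive sensor protein
  reads ribosome availability; the annihilator sRNA is transcribed at
  `kappa*K_sens/(K_sens+p_sens)` (activated when the sensor falls), the
  actuator mRNA at the constant fraction `u*kappa`; both annihilate at rate
  `theta`; the actuator protein drives a non-annihilated amplifier mRNA
  (gain `chi`) that carries the bulk of the ribosome-sequestering action.
  Ideal annihilation pins the sensor at `K_sens*(1-u)/u`; degradation and
  dilution of the actuator/annihilator ("leakiness") leave a residual
  adaptation error, which shrinks with `kappa` and `chi` — and, as the
  tests document, too large a `kappa` or `chi` destabilizes the loop
  (non-converged oscillatory steady-state scans), so the defaults sit in
  the stable regime.

## Steady states and numerics

Deterministic integration uses LSODA (rtol 1e-8, atol 1e-6); terminal
states agree with BDF to 1e-5 relative (tested). Steady-state detection
integrates up to a 72-h horizon (480 h for heavy-burden sweeps), evaluating
on a 1-h cadence the squared-and-summed *relative* change of every variable
over a trailing 12-h window; convergence is declared below 1e-6. The
criterion is applied to relative changes because the state spans nM to
1e6 nM scales. Non-convergence is flagged, never raised. Integration is
split at gene onset times so step disturbances are resolved exactly.

For the host with chloramphenicol and/or constitutive growth-coupled or
uncoupled genes, the steady state collapses exactly onto three unknowns
(lambda, t_c, t_u); `rcell.fastss` solves this by damped log-space Newton
(numba-compiled, multi-start, overflow-guarded) roughly a thousand times
faster than integration and agrees with it to 1e-5 relative (tested). The
fitting likelihood and the large sweeps use this path; regulated circuits
always use time integration. Multi-start steady-state clustering (two
states distinct if any variable differs by >1% relative) stands in for
bifurcation continuation, which is out of scope.

The constant-T optimality scan freezes `F_r` and `psi` at `F_r(T0)` on a
25-point log grid spanning [0.01, 100]*tau, then refines by golden-section
search in log T.

## Hybrid stochastic simulation

Host variables are coarse-grained averages and are advanced
deterministically; circuit species are integer molecule counts (1 nM = 1
molecule per um^3 cell) updated by Poisson firings of transcription,
translation, degradation, dilution and annihilation channels per tau-leap.
The default leap is 1e-6 h; the host update uses per-variable exponential
Euler (`x -> x_inf + (x-x_inf)exp(-a dt)`), which is unconditionally stable
against the millisecond tRNA turnover, so a 1e-5 h leap gives
indistinguishable ensemble means (tested at 2% tolerance) and is what the
test suite and acceptance script use for speed. A leap that would drive a
count negative is redrawn as ten sub-leaps with residual negatives clamped
at zero. Dilution of stochastic species is a first-order decay channel at
rate lambda (no explicit division events). One seeded generator per run;
identical seeds give bitwise-identical paths.

## Fitting

Free parameters: `nu_max`, `k_cm`, `K_eps = K_nu`, and the
`alpha_r:alpha_a` ratio. Priors are normal with mean from the defaults
(ratio prior mean 1) and sd = mean/4 — the source description of the prior
spread is dimensionally ambiguous (variance vs sd "a quarter of the mean");
sd = mean/4 keeps the spread scale-free across parameters of different
magnitudes. Bounds span [mean/50, 50*mean]. Media nutrient qualities are
fixed at six log-spaced points on [0.08, 0.5], matched to media by
drug-free growth-rate rank; RNA:protein ratios convert to ribosomal mass
fractions via the factor 0.4558; records with growth rate <= 0.3 1/h are
excluded (the model does not describe near-stasis physiology). Observation
errors are independent Gaussians with per-observable sd equal to 5% of that
observable's range in the data (the error model is otherwise unspecified).

The sampler is a DREAM-style scheme: 10 parallel chains, differential-
evolution proposals `gamma*(x_r1 - x_r2)` restricted to an adaptively chosen
random subset of dimensions with `gamma = 2.38/sqrt(2 d_eff)` and a 10%
share of full-size (`gamma = 1`) jumps, crossover probabilities adapted
during the 20% burn-in, reflection at the bounds, and Gelman-Rubin
diagnostics on the kept samples. The reported mode is the maximum-posterior
sample. The production configuration is 20,000 steps; tests and the
acceptance script run 600-2,000 steps, which already recovers the
generating parameters of 2%-noise synthetic data to within a few percent.

## What the synthetic data generator does and does not emulate

`synthesize_growth_law_data` evaluates the model itself on the 6-sigma x
{0, 2, 4, 8} uM grid and multiplies both observables by lognormal noise of
a chosen CV. It reproduces the *structure* of classic growth-law
measurements (both laws' geometry, the drug-free/inhibited contrast) but
not their biology-vs-model mismatch: real cells inactivate ribosomes under
stress, deviate from the linear law at 8 uM and below 0.3 1/h, and carry
measurement error far from lognormal. Parameter-recovery results on this
generator therefore validate the inference machinery, not the model's
adequacy for real data.

## Known limitations

- No transcriptional (RNA-polymerase) competition, no orthogonal ribosome
  pools, no nutrient-upshift dynamics, no explicit housekeeping ODEs.
- The analytical controller setpoints neglect leakiness and burden-induced
  shifts of `eps` and `F_r`; they land within ~10-15% of simulation and are
  meant for design guidance, not replacement of simulation.
- The hybrid scheme does not support the chloramphenicol extension
  (inactivated-ribosome counts are not tracked stochastically).
- Very heavy burden or strong translation inhibition can push the cell
  outside the model's validity (and occasionally outside the algebraic
  solver's convergence region, which then reports failure rather than a
  spurious root).
- Model predictions below growth rates of about 0.3 1/h should not be
  trusted; the fitting pipeline filters that regime for the same reason.
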