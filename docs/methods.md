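# Methods

## Model structure and assumptions

The simulator tracks 23 masses (ng): upper-airway, tracheobronchial,
alveolar-surface and alveolar-phagocyte pools; lung capillary blood, lung
interstitial tissue and interstitial phagocytes; arterial and venous blood;
capillary/tissue/phagocyte triplets for liver, kidney, spleen and rest of
body (rob); and cumulative feces and urine sinks.

Assumptions:

- **Permeability-limited distribution.** Nanoparticles do not equilibrate
  instantaneously with tissue; capillary–tissue transfer is
  X_o·Q_o·(C_cab − C_tis/P_o). The partition ratio P_o is the equilibrium
  tissue:blood concentration ratio; X_o scales how fast that equilibrium is
  approached. This fits small (~20 nm) particles, whose tissue entry is
  membrane-limited rather than flow-limited.
- **Saturable, time-dependent phagocytosis.** Tissue-resident macrophages
  engulf particles at rate K_up(t) = K_max·tⁿ⁰/(K_50ⁿ⁰ + tⁿ⁰) and release
  them at K_out. The Hill clock is absolute time since exposure onset and is
  shared by all organs — it models the recruitment/activation of phagocytes
  after exposure, not a per-compartment residence time. A consequence worth
  knowing: the system is linear in state (dose scales trajectories exactly),
  because K_up(t) depends on time, not on mass.
- **Parallel perfusion.** Organ flows satisfy
  Q_li + Q_ki + Q_spl + Q_rob = QC; venous blood collects all organ
  capillary outflows; the lung capillary carries the whole cardiac output in
  series between venous and arterial blood. There is no hepatic portal
  routing of splenic outflow, since no portal flow is parameterized.
- **Respiratory clearance.** Alveolar phagocyte content is moved up the
  mucociliary escalator into the tracheobronchial pool (a gain there), which
  drains to feces; the upper airway drains to rob tissue and feces. The
  alveolar surface exchanges with the lung interstitium
  (K_alv_inter / K_inter_alv), which is the gateway to the circulation.
- **Excretion attachment.** Hepatobiliary excretion acts on the liver
  phagocyte pool (K_lipcs_feces), urinary excretion on kidney tissue
  (K_kid_urine) — following the parameter naming conventions of the rate
  constants themselves.
- **Fixed physiology.** All values refer to a 0.263 kg rat; no allometric
  scaling, growth, or sex/age variation.

## Parameters

Physiological defaults (volumes, sub-volumes, flows; L, L/h) and chemical
defaults (X, P, Hill constants, release/excretion rates; dimensionless,
1/h, h) are tabulated in `parameters.default_parameters()`. Noteworthy
values and choices:

- Hill coefficients n0 are not part of the published tables; they default
  to 1 (the least-informative choice — plain hyperbolic onset) and are
  exposed as ordinary parameters (`chemical.liver.n0`, `respiratory.n0_alv`,
  `respiratory.n0_inter`).
- P_lu = 30359 makes lung interstitium by far the largest equilibrium
  reservoir (P_lu·V_lu,tis ≈ 36 L-equivalents vs ≈ 10 for everything else),
  which is why the lung dominates both retention and the sensitivity
  ranking of every secondary organ.
- K_spl50 = 1000 h delays splenic phagocytic uptake; splenic PC loading
  therefore keeps growing over the whole 1500 h window, producing the late
  spleen maximum.
- The liver uptake/release ratio K_limax/K_liout ≈ 13.5 implies that the
  hepatic phagocyte pool holds ~13.5× the liver tissue mass once uptake has
  saturated (minutes, since K_li50 = 0.36 h). Liver phagocytes are also the
  dominant systemic excretion pathway; this ratio therefore controls both
  the simulated liver burden and the whole-body elimination rate.
- Breathing rate is accepted in L/min (the conventional unit for rat
  inhalation studies) and converted to L/h internally; aerosol
  concentrations convert as 1 mg/m³ = 10³ ng/L (centralized in
  `fixtures.mg_per_m3_to_ng_per_l`).
- Validation: strict positivity where a zero would make the equations
  singular (volumes, flows, P, K_50, n0), non-negativity elsewhere;
  sub-volume sums V_cab + V_tis ≤ V with 1e-6 relative slack; flow closure
  to 1e-3 relative (the printed flows close exactly).

## Exposure scenarios

Two presets reproduce the study designs behind the only two published rat
inhalation biodistribution datasets for 20 nm TiO₂:

- **Calibration (Kreyling et al. design).** The 2 h exposure is represented
  as a bolus at t = 0 of 40 ng tracheobronchial + 892 ng alveolar deposit
  (the reported post-exposure burdens), upper airway 0. A bolus was chosen
  over a 2 h source because the reported curves start from these values at
  0 h; the upper-airway burden is unreported and its systemic leak is
  negligible (X_rob = 1e-4). Observations at 4, 24, 168, 674 h; horizon
  1500 h.
- **Validation (Gosens et al. design).** Continuous 6 h exposure at
  20 mg/m³ (= 2×10⁴ ng/L). Breathing rate and regional deposition fractions
  were not published for this study, so the preset requires them as
  arguments rather than inventing defaults.

## Observables

Dissected-organ measurements include residual capillary blood and the
phagocyte load, so reported observables default to: systemic organs =
capillary + tissue + PCs; lung = interstitium + interstitial PCs + lung
capillary; alveolar = free + engulfed surface mass; tracheobronchial = free
mass only. The composition is data (`DEFAULT_OBSERVABLES`), not code — an
alternative reading (e.g. excluding capillary blood) is one mapping edit.

## Numerical choices

- **Integration.** LSODA (stiff-capable), rtol 1e-8, atol 1e-12 ng. The
  capillary wash-out terms make the system stiff (Q_lu/V_lu,cab ≈ 1.3e4 /h).
  Output on a uniform grid of ≤ 0.25 h spacing augmented with requested
  observation times (hit exactly, no interpolation); continuous-mode
  integration is split at the exposure cut-off. A mass-balance audit
  (|burden + sinks − dose|) is checked in tests to < 1e-4 ng per 1000 ng
  dosed; it actually holds to ~1e-11.
- **Solver cross-check.** The system is linear time-varying, y' = A(t)y, so
  an unconditionally stable, solver-independent propagator is available:
  piecewise-constant-midpoint matrix exponentials with A(t) reconstructed
  from the flux table on basis vectors. The test suite requires 0.5 %
  agreement over [0, 100] h; observed agreement is ~1e-8. (An explicit
  fixed-step Runge–Kutta oracle is not usable here: stability would require
  steps below ~2e-4 h.)
- **Peak extraction.** Discrete maximum on the ≤ 0.25 h grid refined by a
  quadratic through the three surrounding points; time-to-half-peak is the
  first post-peak downward crossing of half the (refined) peak, linearly
  interpolated between the bracketing grid points, with an explicit
  "not reached" marker (None).
- **Decay rates and half-lives.** Negated least-squares slope of ln(mass)
  vs time. Default biphasic windows 0–28 h and 28–674 h (the observed break
  in the alveolar curve); default half-life window 1–672 h (the
  elimination-phase convention), configurable because it straddles the peak
  for slow-filling organs such as the kidney.
- **Metrics.** AAFE uses log10 (the PK convention); sensitivities use
  natural logs (base cancels in d ln y/d ln θ). R² defaults to log10 space
  because contents span four orders of magnitude and linear-space
  correlation would be dominated by the lung; linear space is a flag away.
  The relative-error denominator is the measured value.
- **Sensitivity.** Central finite difference in log space, θ·e^±h with
  h = 0.01; aggregate = max |S(t)| over the evaluation times, with the rule
  tagged in the result so alternative aggregations (integral, endpoint) stay
  comparable. Halving h moves S by ≪ 1 % (smoothness), and the
  implementation matches the closed-form one-compartment result
  d ln y/d ln k = −kt to < 1e-4.
- **Calibration.** Objective Σ(ln sim − ln meas)² minimized over log
  parameters with L-BFGS-B; forward-difference gradient step 1e-4 in log
  space (above the ODE-solver noise floor, biasing the optimum < 0.01 %).
  Deterministic from a fixed start; noise-free synthetic data recovers
  twofold-displaced P_lu, K_alv_inter or P_li to ≪ 1 %.

## Synthetic observed data

`fixtures.generate_observed` emulates a measurement campaign: simulate,
sample the observables at the preset's observation times, apply independent
multiplicative lognormal noise per replicate (σ² = ln(1 + cv²), unit mean)
and report per-point mean and sd. Lognormal noise is the natural choice for
strictly positive contents spanning orders of magnitude. What it does *not*
emulate: inter-animal physiological variability (every replicate shares one
parameter set), assay detection limits and background subtraction, and any
systematic bias between radiolabel-derived and actual particle mass.
Passing the evaluation and recovery tests therefore demonstrates that the
metrics and calibration machinery are correct and self-consistent — not
that the model reproduces any particular laboratory's measurements.

## Known limitations

- The default chemical parameter table produces strong hepatic phagocytic
  sequestration (liver PC:tissue ≈ 13.5) and consequently a fecal clearance
  that removes roughly 1 %/h of the systemic burden; simulated secondary-
  organ burdens and elimination times are governed by this ratio, and users
  whose data suggest weaker hepatic sequestration should revisit
  `chemical.liver.K_max` / `K_out` / `K_excrete` before anything else.
- Organs are homogeneous; no sub-organ spatial detail, no protein-corona,
  agglomeration or dissolution kinetics, and no particle-size dependence
  (deposition fractions are inputs, expected from external dosimetry tools).
- The Hill clock is global and absolute, so re-exposure or multi-bolus
  scenarios inherit an already-saturated uptake rate; the model is
  parameterized for single acute exposures.
- No rat-to-human extrapolation and no allometric scaling.
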