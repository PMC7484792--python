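# Methods

## The mechanical model

The ankle–foot system is analysed with a six-degrees-of-freedom ankle joint
and a single-rigid-body foot treated as a deformable ("distal") power sink or
source. Two power series are computed over the stance phase of walking, plus
their sum:

**Ankle power.** The ankle transmits a full wrench: a force `F_ankle` and a
moment `M_ankle` (the load applied by the shank on the foot, moment about the
ankle centre). Its six-DOF power is

    P_ankle = F_ankle · ΔV_ankle + M_ankle · ω_ankle

where `ΔV_ankle` is the difference of the ankle-centre **material-point**
velocities of foot and shank (foot minus shank, i.e. distal minus proximal)
and `ω_ankle = ω_foot − ω_shank`. This quantity equals the net rate of work
done by all structures spanning the joint on the two adjacent segments, so
positive values are generation: the late-stance push-off burst is positive.
The translational term captures energy transfer that a pure rotational joint
model misses.

**Distal foot power.** Everything distal to the foot's proximal boundary is
summarised by the ground loads acting on the rigidly modelled foot:

    P_foot = GRF · [V_cm,foot + ω_foot × R_cop/cm] + M_free · ω_foot

with `R_cop/cm` the vector from the foot centre of mass to the centre of
pressure and `M_free` the vertical free moment. `GRF`'s dot product with the
material-point velocity of the foot at the COP measures the rate of energy
exchanged with the ground — negative in early stance (heel-pad and arch
absorption) and around push-off in the rigid-foot approximation.

**Sum.** `P_sum = P_ankle + P_foot`, an exact samplewise identity in the
implementation.

`F_ankle` and `M_ankle` come from Newton–Euler inverse dynamics of the foot:

    m a_cm = F_ankle + GRF + m g
    I ω̇ + ω × (I ω) = M_ankle + (r_ankle − r_cm) × F_ankle
                       + (r_cop − r_cm) × GRF + M_free

with the inertia tensor rotated per sample into the lab frame. All sign
conventions are pinned by a rigid-body energy balance: the total power of all
external loads on the foot (ankle wrench, ground loads at their material
points, gravity) must equal d/dt of the foot's kinetic energy. This identity
is asserted in the test suite and is the package's primary mechanical oracle;
any sign or frame error breaks it immediately.

## Processing chain and its parameters

| Parameter | Default | Why |
|---|---|---|
| marker low-pass cutoff | 10 Hz | standard gait kinematics band |
| force low-pass cutoff | 50 Hz | preserves loading-rate content |
| Butterworth order (per pass) | 2 | dual-pass (zero-phase) gives 4th-order rolloff, the de-facto gait standard |
| event threshold | 50 N | conventional vertical-GRF contact threshold |
| plausible stance duration | 0.3–1.5 s | brackets slow-to-fast overground stance times |
| time normalization | 101 points | 0–100 % stance in 1 % steps |
| anthropometric table | de Leva (1996) adjustment of Zatsiorsky | pinned, shipped as a versioned CSV, recorded in provenance |

Filtering is zero-phase (`sosfiltfilt`, reflective padding) so power timing is
not skewed; the filter order refers to one pass. Forces are filtered on their
native 300 Hz clock, so the 50 Hz cutoff keeps its meaning, then cubic-spline
interpolated onto the 150 Hz marker samples inside the stance window (exact
when the clocks coincide). Events are detected on the force clock and mapped
to the nearest marker sample. Marker gaps are flagged by the readers and never
silently interpolated; a stance window containing a gap is rejected, mirroring
manual trial selection (gaps outside stance are bridged only to stabilise the
filter). Derivatives use central differences with one-sided ends; the angular
velocity is read off the skew-symmetric part of `Ṙ Rᵀ`; `ω̇` is obtained by
differentiating `ω` rather than second-differencing `R` (lower noise
amplification). Segment poses are least-squares (Kabsch) rigid fits of ≥3
non-collinear markers; the ankle centre is the malleoli-marker midpoint for
the shank and a configured landmark in the foot's local frame. Below the force
threshold the COP is held at its last valid value and the foot-power sample is
forced to zero, so near-zero stance-edge forces cannot poison work integrals.

## Outcome features

Nine features per subject × condition, averaged across that condition's
trials: propulsion-phase peaks of the three power series and positive/negative
works. The propulsion window runs from the last negative-to-positive zero
crossing of `P_sum` to toe off (fallback: final 50 % of stance). Peaks are
maxima for `P_ankle` and `P_sum`; for `P_foot` the magnitude of the
propulsion-phase minimum is reported positive, so speed effects on all peak
features share a sign while the raw signed series is retained. Works are
trapezoidal integrals of the positive/negative parts over the full stance for
ankle and sum, and over the sub-intervals where `P_foot` is negative/positive
(the operational definition of the foot absorption phase) — for a
full-stance window the two definitions coincide and `W⁺ + W⁻` equals the net
work exactly. Time series are reported in W/kg when mass-normalised; scalar
features are computed in W/J and standardized before modelling, which makes
the normalisation choice immaterial to the standardized slopes. The per-trial
minimum defaults to 3 for synthetic work (6 is a data-collection property of
laboratory datasets, exposed as a parameter).

## Statistical model

Each standardized feature is fitted with a ladder of linear mixed-effects
models with a random intercept per subject:

    feature = β₀ + β_S·Speed + β_A·AgeGroup + β_SA·Speed×AgeGroup
              + (1|Subject) + ε

with predictor sets {S}, {A}, {S+A}, {S+A+S×A}. Speed is continuous and
standardized; AgeGroup is Young = 0 / Older = 1. Fitting is two-step: maximum
likelihood for the log-likelihood and AIC (`AIC = 2k − 2·LLF`, k counting
fixed effects plus the two variance components), REML for the coefficient
estimates. A likelihood-ratio test compares nested ML fits. R² is the squared
Pearson correlation between the feature and the fixed-effects-only
prediction; residual normality is quantified by Jarque–Bera on conditional
residuals. Conventions pinned where the choice was open: sample SD (n−1)
standardization; Wald/normal 95 % CIs and z-test p-values from the REML fit
(the large-sample approximation; a denominator-df method would change
p-values marginally, never slopes); no multiple-testing correction across the
nine features. The speed-confounding subset analysis standardizes within the
analyzed subset. An age-as-continuous variant is the same ladder with
standardized age in place of the group code.

The optimizer tries BFGS first and falls back to Powell/L-BFGS, keeping the
first finite optimum (single optimizers occasionally stall on this
likelihood, which would corrupt the LLF ordering of nested fits). When the
residual variance is numerically zero (noiseless synthetic tables) the mixed
likelihood degenerates and the fit returns the exact OLS limit, flagged
`degenerate`.

## The synthetic-data generator

**Trials.** Smooth closed-form foot and shank trajectories (low-frequency
sinusoid compositions phase-locked to stance) are prescribed: early-stance
foot lowering, a shank rotating forward over the foot, a dorsiflexion dip
followed by a late plantarflexion burst, a small ankle joint translation, and
a foot yaw in phase with the free moment. The vertical GRF is a double-hump
profile crossing the 50 N threshold inside the contact window; the COP
travels heel to toe (smoothstep); shear and free-moment profiles vanish at
the contact edges. The ankle wrench is then computed *forward* from the
foot's Newton–Euler equations, so the trial is dynamically consistent by
construction and every load, power and feature has an exact reference value.
Derivatives of the prescribed trajectories are evaluated on a 4800 Hz grid by
central differences (relative error ~1e-7 at the ≤2 Hz content used) and
subsampled exactly onto the 150 Hz marker / 300 Hz force clocks. Markers are
rigidly attached (4 per segment); defaults use a young-adult subject (68.4 kg,
1.71 m, comfortable speed 1.23 m/s), stance times 0.79/0.63/0.55 s for
slow/comfortable/fast, peak vertical force 1.1 body weights, and measurement
noise of 0.5 mm (markers) and 0.5 N (forces); noise is switched off where an
exactness check requires it. What the generator does **not** emulate: soft
tissue and marker-skin artefact, heel-pad deformation, multi-segment foot
motion, step-to-step variability, and full forward progression of the shank —
so passing tests validate the estimator chain, not the biological
interpretation of real data.

**Feature tables.** The mixed-effects model is inverted: per-subject
comfortable speeds are drawn per group (young 1.23 ± 0.17, older 1.21 ± 0.20
m/s; 24 young, 16 older), slow/fast are ∓30 %, subject intercepts and
residuals are Gaussian (defaults σ_subject = 0.3, σ_ε = 0.4 on the
standardized scale), and features follow known coefficients (defaults: the
nine reported standardized speed slopes, no age effect). A confound mode
shifts the group speed distributions (young 1.40 ± 0.10, older 1.00 ± 0.13)
with a true age effect of zero. In parameter-recovery experiments the
response is left on its generated scale: re-standardizing by the realized
sample SD (which includes both noise components) would deterministically
shrink estimates by ≈6 % and is a property of the metric, not the estimator.

## Validation experiments and problem sizes

`footpower.evaluation` re-runs each headline check from scratch: energy
balance and inverse-dynamics recovery on 20 randomized noiseless trials
(amplitudes jittered ±20 %), work/sum identities and end-to-end feature
recovery on 10 trials, estimator bias and CI coverage on a 3×3 grid of
(β_S, β_A) ∈ {0, 0.4, 0.8}² with 200 replicates of 40 subjects × 3 speeds,
and the confounding demonstration on 100 replicates. Feature-recovery errors
are relative to each feature, floored at 1 % of the trial's largest feature
magnitude because the distal foot's positive work is physically near zero and
a pure ratio there is ill-posed. Coverage is assessed as the grid-average
(per-cell binomial noise at 200 replicates is ±1.5 %).

## Known limitations

* The foot is one rigid body; distal power magnitudes are overestimates
  relative to multi-segment foot models.
* The benchmark against the deposited overground gait dataset requires that
  dataset locally (`data/open_dataset/features.csv`); it is not bundled.
* Inertial parameters are table-based, not subject-specific.
* CIs/p-values use the normal approximation; with 40 subjects this is mild,
  but small-sample use should prefer a denominator-df method.
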