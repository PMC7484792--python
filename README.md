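# footpower

Mechanical power analysis of the ankle–foot system during walking, for
biomechanists and movement scientists studying how gait speed and ageing
shape distal lower-limb energetics.

Conventional rigid-foot gait models overestimate ankle–foot kinetics. This
package implements the alternative: a **six-degrees-of-freedom ankle joint**
combined with a **distal (deformable) foot segment**, which separates the
energy flowing through the ankle from the energy exchanged by the foot
itself:

```
P_ankle = F_ankle · ΔV_ankle + M_ankle · ω_ankle
P_foot  = GRF · [V_cm,foot + ω_foot × R_cop/cm] + M_free · ω_foot
P_sum   = P_ankle + P_foot
```

`F_ankle`/`M_ankle` come from Newton–Euler inverse dynamics of the foot;
`ΔV_ankle` and `ω_ankle` are the relative translational and angular ankle
velocities (distal minus proximal); `GRF`, `R_cop/cm` and `M_free` are the
ground reaction force, the COM-to-centre-of-pressure vector, and the vertical
free moment. Nine outcome features per subject × speed condition — the
propulsion-phase peaks of the three powers and their positive/negative works
— feed a ladder of standardized linear mixed-effects models

```
feature ~ β₀ + β_S·Speed + β_A·AgeGroup + β_SA·Speed×AgeGroup + (1|Subject) + ε
```

whose standardized slopes read directly as effect sizes, with ML
log-likelihood/AIC for model comparison and REML coefficients with 95 % CIs.

The pipeline stages (I/O → filtering and gait events → segment kinematics,
COP and free moment → foot inverse dynamics → power features → mixed models)
are importable individually, and a synthetic-data module generates
dynamically consistent walking trials with analytic ground truth plus feature
tables with known mixed-effects structure, so everything is testable without
any measurement data. See `docs/methods.md` for the full model description,
conventions and limitations.

## Worked example

Run a full synthetic study (40 subjects, three speed conditions per subject,
study-scale effect sizes) and fit the model ladder for all nine features:

```bash
footpower run --mode synthetic-features --seed 7 --out demo/
```

This writes `features.csv`, `ladder.csv`, `lrt.csv`, `subset_confound.csv`
and `provenance.json`. The speed-only rows of `ladder.csv` from that exact
command:

```
   feature  beta_S  beta_S_ci_lo  beta_S_ci_hi     llf    aic   r2
   P_ankle    0.90          0.83          0.98  -69.61 147.23 0.81
    P_foot    0.87          0.79          0.95  -87.84 183.68 0.68
     P_sum    0.87          0.80          0.94  -69.13 146.27 0.78
Wpos_ankle    0.83          0.75          0.91  -92.72 193.45 0.65
 Wpos_foot    0.77          0.67          0.86 -105.83 219.66 0.60
  Wpos_sum    0.84          0.75          0.93  -95.75 199.50 0.67
Wneg_ankle    0.47          0.34          0.60 -143.08 294.17 0.23
 Wneg_foot   -0.85         -0.93         -0.77  -83.79 175.59 0.73
  Wneg_sum   -0.39         -0.51         -0.26 -143.11 294.22 0.17
```

`beta_S` is the standardized speed slope (an effect size): walking faster
raises every peak and positive work, drives the foot's negative work more
negative (`Wneg_foot`: more absorption), and each CI excludes zero. `llf`,
`aic` and `r2` are the fit metrics used to compare ladder models; the
generating effect sizes here were the study-scale slopes, and the fitted
values recover them within their CIs.

Other entry points:

```bash
footpower synth-trial --seed 3 --out dataset/       # one trial + ground truth
footpower synth-features --seed 2 --out table.csv   # feature table + truth
footpower run --mode synthetic-trials --seed 5 --out demo2/   # markers→stats
```

The `synthetic-trials` mode runs the full mechanical chain (markers and force
plate → stance powers → features) before the statistics, and adds
time-normalized ensemble curves (`curves.csv`).

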