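"""Self-contained validation experiments for the pipeline.

Each function here runs one of the package's headline checks from scratch —
generating its own synthetic inputs from a seed, executing the pipeline, and
measuring the result — and returns plain numbers.  They back both the test
suite and the reproduction script, so every reported quantity is recomputed
at call time.
"""

from __future__ import annotations

import numpy as np

from .foot_mechanics import (
    cop_and_free_moment,
    foot_inertial,
    segment_pose,
)
from .inverse_dynamics import energy_balance, newton_euler_foot
from .pipeline import process_trial
from .power_features import compute_power_series, stance_features, work
from .preprocess import PreprocessConfig, segment_stance
from .stats_models import fit_lmm
from .synthetic_data import (
    SyntheticFeatureSpec,
    SyntheticTrialSpec,
    foot_segment_def,
    generate_feature_table,
    generate_trial,
    shank_segment_def,
)

#: Published cohort summary statistics (mean, SD, n) of the walking study the
#: analysis replicates: young vs older groups.  These printed summaries are
#: the inputs of the demographic-comparison check.
COHORT_SUMMARY = {
    "height_m": {"young": (1.71, 0.11, 24), "older": (1.61, 0.10, 16)},
    "mass_kg": {"young": (68.4, 12.2, 24), "older": (65.8, 10.1, 16)},
}


def _noiseless_spec(seed: int, rng: np.random.Generator) -> SyntheticTrialSpec:
    """A randomized noiseless trial spec (amplitudes jittered +/-20%)."""
    j = lambda base: float(base * rng.uniform(0.8, 1.2))
    return SyntheticTrialSpec(
        seed=seed,
        stance_time=j(0.63),
        shank_pitch_amp=j(0.30), ankle_pf_amp=j(0.30),
        foot_yaw_amp=j(0.04), shank_yaw_amp=j(0.03),
        foot_lift_amp=j(0.020), foot_forward_shift=j(0.012),
        foot_sway_amp=j(0.004), ankle_translation_amp=j(0.004),
        free_moment_amp=j(5.0),
        marker_noise_sd=0.0, force_noise_sd=0.0,
    )


def _recovered_mechanics(trial):
    """Run the measurement-side mechanical chain for one trial."""
    cfg = PreprocessConfig()
    stance = segment_stance(trial, cfg)
    foot_kin = segment_pose(stance.markers_filtered, foot_segment_def())
    shank_kin = segment_pose(stance.markers_filtered, shank_segment_def())
    contact = cop_and_free_moment(stance.force_filtered, cfg.threshold_n)
    inertia = foot_inertial(trial.subject.mass, 0.152 * trial.subject.height)
    loads = newton_euler_foot(foot_kin, contact, inertia)
    return stance, foot_kin, shank_kin, contact, inertia, loads


def energy_balance_residuals(seed: int, n_trials: int = 20) -> np.ndarray:
    """RMS energy-balance residual as % of peak power, per noiseless trial.

    The six-DOF power bookkeeping of all external loads on the foot is
    compared against the derivative of the foot's kinetic energy on the
    pipeline-recovered kinematics and loads (interior stance samples;
    differentiation endpoints excluded).
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_trials):
        trial, _ = generate_trial(
            _noiseless_spec(int(rng.integers(0, 2 ** 31 - 1)), rng))
        _, foot_kin, _, contact, inertia, loads = _recovered_mechanics(trial)
        power_in, dE_dt = energy_balance(loads, foot_kin, contact, inertia)
        resid = (power_in - dE_dt)[2:-2]
        peak = np.max(np.abs(power_in))
        out.append(100.0 * np.sqrt(np.mean(resid ** 2)) / peak)
    return np.asarray(out)


def inverse_dynamics_recovery(seed: int, n_trials: int = 20) -> dict:
    """Pipeline-recovered ankle loads vs. forward-constructed ground truth.

    Returns RMS errors as % of the peak ground-truth magnitude, for the ankle
    force and moment, across noiseless randomized trials.
    """
    rng = np.random.default_rng(seed)
    f_err, m_err = [], []
    for k in range(n_trials):
        trial, gt = generate_trial(
            _noiseless_spec(int(rng.integers(0, 2 ** 31 - 1)), rng))
        stance, foot_kin, _, contact, inertia, loads = _recovered_mechanics(trial)
        i0, i1 = stance.marker_index_range
        sl = slice(2, loads.force.shape[0] - 2)   # trim differentiation ends
        f_ref = gt.f_ankle[i0:i1][sl]
        m_ref = gt.m_ankle[i0:i1][sl]
        f_err.append(100.0 * _rms(loads.force[sl] - f_ref)
                     / np.max(np.linalg.norm(f_ref, axis=1)))
        m_err.append(100.0 * _rms(loads.moment[sl] - m_ref)
                     / np.max(np.linalg.norm(m_ref, axis=1)))
    return {"force_rms_pct": np.asarray(f_err),
            "moment_rms_pct": np.asarray(m_err)}


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum(np.atleast_2d(x) ** 2, axis=-1))))


def work_identity_errors(seed: int, n_trials: int = 10) -> dict:
    """Exactness of W+ + W- = net work and P_sum = P_ankle + P_foot."""
    rng = np.random.default_rng(seed)
    w_err, p_err = [], []
    for k in range(n_trials):
        trial, _ = generate_trial(
            _noiseless_spec(int(rng.integers(0, 2 ** 31 - 1)), rng))
        ps = process_trial(trial)
        for series in (ps.p_ankle, ps.p_foot, ps.p_sum):
            wp = work(series, ps.time, sign="positive")
            wn = work(series, ps.time, sign="negative")
            net = work(series, ps.time, sign="net")
            w_err.append(abs(wp + wn - net))
        p_err.append(float(np.max(np.abs(ps.p_sum - (ps.p_ankle + ps.p_foot)))))
    return {"work_decomposition_j": np.asarray(w_err),
            "psum_identity_w": np.asarray(p_err)}


def feature_recovery_errors(seed: int, n_trials: int = 10) -> np.ndarray:
    """End-to-end relative feature error (%) on noiseless trials.

    Pipeline features from the 150/300 Hz measurement path vs. the dense-grid
    ground-truth features; the per-trial value is the worst feature's error.
    Features are compared relative to their own magnitude, floored at 1% of
    the trial's largest feature magnitude so that physically near-zero
    features (the distal foot's positive work can vanish) do not make the
    ratio ill-posed.
    """
    rng = np.random.default_rng(seed)
    errs = []
    for k in range(n_trials):
        trial, gt = generate_trial(
            _noiseless_spec(int(rng.integers(0, 2 ** 31 - 1)), rng))
        feats = stance_features(process_trial(trial))
        floor = 0.01 * max(abs(v) for v in gt.features.values())
        rel = [abs(feats[name] - ref) / max(abs(ref), floor) * 100.0
               for name, ref in gt.features.items()]
        errs.append(max(rel))
    return np.asarray(errs)


def lmm_recovery_grid(seed: int, n_replicates: int = 200,
                      betas=(0.0, 0.4, 0.8), n_young: int = 24,
                      n_older: int = 16) -> dict:
    """Monte-Carlo bias and CI coverage of the mixed-model estimator.

    For every (b_S, b_A) on the grid, feature tables are drawn from the known
    model (sigma_subject 0.3, sigma_eps 0.4) and refitted with the
    speed+age model; the response stays on its generated scale so estimates
    are directly comparable to the truth.
    """
    rng = np.random.default_rng(seed)
    bias_s, bias_a, cover_s, cover_a = [], [], [], []
    for b_s in betas:
        for b_a in betas:
            est_s, est_a, cov_s, cov_a = [], [], [], []
            for r in range(n_replicates):
                spec = SyntheticFeatureSpec(
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                    n_young=n_young, n_older=n_older,
                    features={"feature": (b_s, b_a, 0.0)},
                )
                table, _ = generate_feature_table(spec)
                res = fit_lmm(table, "feature", ("speed", "age"),
                              standardize_feature=False, ml_metrics=False)
                est_s.append(res.beta["beta_S"])
                est_a.append(res.beta["beta_A"])
                lo, hi = res.ci95["beta_S"]
                cov_s.append(lo <= b_s <= hi)
                lo, hi = res.ci95["beta_A"]
                cov_a.append(lo <= b_a <= hi)
            bias_s.append(np.mean(est_s) - b_s)
            bias_a.append(np.mean(est_a) - b_a)
            cover_s.append(np.mean(cov_s))
            cover_a.append(np.mean(cov_a))
    return {
        "bias_speed": np.asarray(bias_s), "bias_age": np.asarray(bias_a),
        "coverage_speed": np.asarray(cover_s),
        "coverage_age": np.asarray(cover_a),
        "n_replicates": n_replicates,
    }


def confound_significance_rates(seed: int, n_replicates: int = 100) -> dict:
    """How often a spurious age effect appears with and without speed.

    Tables are drawn with no true age effect but group-shifted speeds; the
    rates count replicates where the AgeGroup coefficient is significant
    (p < 0.05) under the age-only and the age+speed models.
    """
    rng = np.random.default_rng(seed)
    sig_a, sig_as = [], []
    for r in range(n_replicates):
        spec = SyntheticFeatureSpec.confound(
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        table, _ = generate_feature_table(spec)
        res_a = fit_lmm(table, "feature", ("age",))
        res_as = fit_lmm(table, "feature", ("age", "speed"))
        sig_a.append(res_a.p_values["beta_A"] < 0.05)
        sig_as.append(res_as.p_values["beta_A"] < 0.05)
    return {"rate_age_only": float(np.mean(sig_a)),
            "rate_age_plus_speed": float(np.mean(sig_as)),
            "n_replicates": n_replicates}


def cohort_cohens_d() -> dict:
    """Cohen's d for the published cohort group summaries (height, mass)."""
    from .stats_models import group_compare_summary

    out = {}
    for var, groups in COHORT_SUMMARY.items():
        m1, s1, n1 = groups["young"]
        m2, s2, n2 = groups["older"]
        t, p, d = group_compare_summary(m1, s1, n1, m2, s2, n2)
        out[var] = {"t": t, "p": p, "d": d, "n": n1 + n2}
    return out
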