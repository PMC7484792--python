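"""End-to-end orchestration: trials -> powers -> features -> model ladder.

``process_trial`` runs the mechanical chain for one trial (segmentation,
segment poses, COP/free moment, foot inverse dynamics, the three power
series).  ``run`` drives a full analysis from a :class:`RunConfig` — either a
synthetic feature table or a set of synthetic trials — and writes the report
bundle: a tidy feature table, a ladder table mirroring the published layout
(feature x model rows with slopes, CIs, LLF, AIC, R^2), likelihood-ratio
comparisons, ensemble curves, a speed-confounding subset report and a
provenance block.  CSVs are the canonical, deterministic outputs; plots are a
convenience and excluded from determinism guarantees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DegenerateDataError
from .foot_mechanics import cop_and_free_moment, foot_inertial, segment_pose
from .gait_io import CONDITIONS, SubjectInfo, Trial
from .inverse_dynamics import newton_euler_foot
from .power_features import (
    FEATURE_NAMES,
    FeatureRecord,
    PowerSeries,
    compute_power_series,
    stance_features,
)
from .preprocess import PreprocessConfig, segment_stance, time_normalize
from .stats_models import (
    MODEL_LADDER,
    fit_ladder,
    likelihood_ratio_test,
    subset_confound_analysis,
)
from .synthetic_data import (
    SyntheticFeatureSpec,
    SyntheticTrialSpec,
    foot_segment_def,
    generate_feature_table,
    generate_trial,
    shank_segment_def,
    trial_spec_for,
)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    mode: str = "synthetic-features"     # or "synthetic-trials"
    seed: int = 0
    out_dir: str = "footpower_out"
    n_young: int = 24
    n_older: int = 16
    trials_per_condition: int = 3        # synthetic-trials mode
    min_trials: int = 3
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    make_plots: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def process_trial(trial: Trial, foot_def=None, shank_def=None,
                  config: PreprocessConfig | None = None) -> PowerSeries:
    """Mechanical chain for one trial: stance power series of ankle and foot."""
    cfg = config or PreprocessConfig()
    foot_def = foot_def or foot_segment_def()
    shank_def = shank_def or shank_segment_def()

    stance = segment_stance(trial, cfg)
    foot_kin = segment_pose(stance.markers_filtered, foot_def)
    shank_kin = segment_pose(stance.markers_filtered, shank_def)
    contact = cop_and_free_moment(stance.force_filtered, cfg.threshold_n)
    inertia = foot_inertial(trial.subject.mass,
                            0.152 * trial.subject.height)
    loads = newton_euler_foot(foot_kin, contact, inertia)
    return compute_power_series(stance.time, loads, foot_kin, shank_kin, contact)


def ensemble_curves(series_list, keys, n_points: int = 101) -> pd.DataFrame:
    """Time-normalized mean +/- SD curves per group.

    ``keys`` is one dict of grouping labels per series (e.g. condition and
    age group); curves are resampled to ``n_points`` over 0-100% stance and
    aggregated pointwise within each distinct key combination.
    """
    if len(series_list) != len(keys):
        raise DegenerateDataError("one key dict per power series is required")
    rows = []
    for ps, key in zip(series_list, keys):
        for channel in ("p_ankle", "p_foot", "p_sum"):
            curve = time_normalize(getattr(ps, channel), n_points)
            for pct, val in zip(np.linspace(0, 100, n_points), curve):
                rows.append({**key, "channel": channel, "pct_stance": pct,
                             "value": val})
    df = pd.DataFrame(rows)
    group_cols = [c for c in df.columns if c not in ("value",)]
    agg = (df.groupby(group_cols, sort=True)["value"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=0) if len(v) > 1 else 0.0)
             .reset_index())
    return agg


def _ladder_table(ladders: dict) -> pd.DataFrame:
    """Flatten feature -> ladder fits into the published reporting layout."""
    model_names = {
        ("speed",): "S", ("age",): "A", ("speed", "age"): "S+A",
        ("speed", "age", "speed:age"): "S+A+SxA",
    }
    rows = []
    for feat, ladder in ladders.items():
        for spec in MODEL_LADDER:
            r = ladder[spec]
            row = {"feature": feat, "model": model_names[spec]}
            for coef in ("beta_S", "beta_A", "beta_SA"):
                if coef in r.beta:
                    row[coef] = r.beta[coef]
                    row[f"{coef}_ci_lo"], row[f"{coef}_ci_hi"] = r.ci95[coef]
                    row[f"{coef}_p"] = r.p_values[coef]
                else:
                    row[coef] = np.nan
                    row[f"{coef}_ci_lo"] = row[f"{coef}_ci_hi"] = np.nan
                    row[f"{coef}_p"] = np.nan
            row.update(llf=r.llf, aic=r.aic, r2=r.r2_fixed,
                       jb_stat=r.jb_stat, jb_p=r.jb_p,
                       random_intercept_var=r.random_intercept_var,
                       residual_var=r.residual_var)
            rows.append(row)
    return pd.DataFrame(rows)


def _lrt_table(ladders: dict) -> pd.DataFrame:
    pairs = [
        (("speed",), ("speed", "age")),
        (("age",), ("speed", "age")),
        (("speed", "age"), ("speed", "age", "speed:age")),
    ]
    rows = []
    for feat, ladder in ladders.items():
        for nested, full in pairs:
            try:
                stat, df, p = likelihood_ratio_test(ladder[nested], ladder[full])
            except Exception:
                stat = df = p = np.nan
            rows.append({"feature": feat,
                         "nested": "+".join(nested), "full": "+".join(full),
                         "lr_stat": stat, "df": df, "p": p})
    return pd.DataFrame(rows)


def _synthetic_trial_features(config: RunConfig) -> tuple[pd.DataFrame, list, list]:
    """Generate and process synthetic trials into a feature table."""
    rng = np.random.default_rng(config.seed)
    fspec = SyntheticFeatureSpec(seed=config.seed, n_young=config.n_young,
                                 n_older=config.n_older)
    roster, _ = generate_feature_table(fspec)
    roster = roster.drop_duplicates("subject_id")

    records, all_series, all_keys = [], [], []
    for _, srow in roster.iterrows():
        # roster keeps each subject's first row, the 'slow' (0.7x) condition
        subject = SubjectInfo(
            subject_id=srow["subject_id"], age=srow["age"],
            age_group=int(srow["age_group"]), height=1.71, mass=68.4,
            leg_length=0.88, comfortable_speed=srow["speed"] / 0.7,
        )
        for cond in CONDITIONS:
            powers = []
            for k in range(config.trials_per_condition):
                seed = int(rng.integers(0, 2 ** 31 - 1))
                spec = trial_spec_for(subject, cond, seed)
                trial, _ = generate_trial(spec)
                ps = process_trial(trial, config=config.preprocess)
                powers.append(ps)
                all_series.append(ps)
                all_keys.append({"age_group": subject.age_group,
                                 "condition": cond})
            rec = FeatureRecord(
                subject_id=subject.subject_id, condition=cond,
                speed=subject.comfortable_speed
                * {"slow": 0.7, "comfortable": 1.0, "fast": 1.3}[cond],
                features={
                    name: float(np.mean([stance_features(p)[name]
                                         for p in powers]))
                    for name in FEATURE_NAMES
                },
            )
            records.append(rec)
    rows = [{"subject_id": r.subject_id,
             "age_group": 0 if r.subject_id.startswith("Y") else 1,
             "age": np.nan, "condition": r.condition, "speed": r.speed,
             **r.features} for r in records]
    return pd.DataFrame(rows), all_series, all_keys


def run(config: RunConfig) -> dict:
    """Execute a full analysis; returns the paths of the written bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = None

    if config.mode == "synthetic-features":
        table, truth = generate_feature_table(
            SyntheticFeatureSpec(seed=config.seed, n_young=config.n_young,
                                 n_older=config.n_older))
        features = list(truth["features"])
    elif config.mode == "synthetic-trials":
        table, series, keys = _synthetic_trial_features(config)
        features = list(FEATURE_NAMES)
        curves = ensemble_curves(series, keys)
    else:
        raise DegenerateDataError(f"unknown run mode {config.mode!r}")
    if table.empty:
        raise DegenerateDataError("empty feature table; nothing to analyse")

    ladders = {feat: fit_ladder(table, feat) for feat in features}
    subset = subset_confound_analysis(table, features=features)

    paths = {}
    table.to_csv(out / "features.csv", index=False)
    paths["features"] = out / "features.csv"
    _ladder_table(ladders).to_csv(out / "ladder.csv", index=False)
    paths["ladder"] = out / "ladder.csv"
    _lrt_table(ladders).to_csv(out / "lrt.csv", index=False)
    paths["lrt"] = out / "lrt.csv"

    subset_rows = []
    for feat, pair in subset.ladders.items():
        for label, res in pair.items():
            subset_rows.append({
                "feature": feat, "model": label,
                "beta_A": res.beta.get("beta_A", np.nan),
                "beta_A_p": res.p_values.get("beta_A", np.nan),
                "beta_S": res.beta.get("beta_S", np.nan),
            })
    pd.DataFrame(subset_rows).to_csv(out / "subset_confound.csv", index=False)
    paths["subset_confound"] = out / "subset_confound.csv"

    if curves is not None:
        curves.to_csv(out / "curves.csv", index=False)
        paths["curves"] = out / "curves.csv"

    provenance = {
        "config": config.to_dict(),
        "package_version": __version__,
        "subset_speed_comparison": {"t": subset.speed_t, "p": subset.speed_p,
                                    "d": subset.speed_d},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    paths["provenance"] = out / "provenance.json"

    if config.make_plots:
        paths["plots"] = _write_plots(table, features, out)
    return paths


def _write_plots(table: pd.DataFrame, features, out: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pdir = out / "plots"
    pdir.mkdir(exist_ok=True)
    n = len(features)
    ncol = 3
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for ax, feat in zip(axes.ravel(), features):
        for grp, sub in table.groupby("age_group"):
            ax.plot(sub["speed"], sub[feat], "o", ms=3,
                    label={0: "young", 1: "older"}[grp])
        b = np.polyfit(table["speed"], table[feat], 1)
        xs = np.linspace(table["speed"].min(), table["speed"].max(), 20)
        ax.plot(xs, np.polyval(b, xs), "k-")
        ax.set_xlabel("speed (m/s)")
        ax.set_title(feat)
    axes.ravel()[0].legend()
    fig.tight_layout()
    fig.savefig(pdir / "feature_scatter.png", dpi=110)
    plt.close(fig)
    return pdir
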