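"""End-to-end orchestration: label -> sample -> bin -> fit -> score -> evaluate.

The entry point is :func:`run_pipeline`, which takes a cohort bundle (times
in hours; call ``bundle.in_hours()`` first for timestamped CSVs) and a
:class:`~sorpkit.config.RunConfig`, and returns all fitted artifacts plus a
metrics dictionary.  :func:`write_artifacts` persists the ``labels.csv``,
``samples.csv``, ``scorecard.json/csv``, ``metrics.json`` and
``trajectories.csv`` bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluate, phenotype, scorecard as sc_mod, timeline, woe
from .config import RunConfig
from .io import CohortBundle

logger = logging.getLogger("sorpkit.pipeline")


def split_patients(
    labels: pd.DataFrame,
    fracs: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.Series:
    """Disjoint, exhaustive train/val/test split, stratified by shock flag.

    Returns a Series patient_id -> {'train','val','test'}.  Stratification
    keeps the shock rate comparable across splits even in small cohorts.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[object, str] = {}
    for _, sub in labels.groupby("shock_flag"):
        pids = sub["patient_id"].to_numpy()
        pids = pids[rng.permutation(len(pids))]
        n = len(pids)
        n_train = int(round(fracs[0] * n))
        n_val = int(round(fracs[1] * n))
        for pid in pids[:n_train]:
            assignment[pid] = "train"
        for pid in pids[n_train:n_train + n_val]:
            assignment[pid] = "val"
        for pid in pids[n_train + n_val:]:
            assignment[pid] = "test"
    return pd.Series(assignment, name="split")


def fit_bins(
    samples: timeline.SampleSet,
    cfg: RunConfig,
) -> tuple[dict[str, woe.BinTable], dict[str, dict[int, float]]]:
    """Per-feature supervised binning; unusable features are dropped."""
    bins: dict[str, woe.BinTable] = {}
    curves: dict[str, dict[int, float]] = {}
    y = samples.y
    for f in samples.features:
        try:
            bt, curve = woe.fit_feature_bins(
                samples.X[f].to_numpy(), y,
                n_init=cfg.n_init, k_range=range(cfg.k_min, cfg.k_max + 1),
                tau=cfg.tau, missing_bin_frac=cfg.missing_bin_frac, feature=f,
            )
        except woe.UnusableFeatureError as err:
            logger.warning("dropping feature: %s", err)
            continue
        bins[f] = bt
        curves[f] = curve
    if not bins:
        raise ValueError("no usable features remain after binning")
    return bins, curves


def encode(X: pd.DataFrame, bins: dict[str, woe.BinTable]) -> pd.DataFrame:
    return pd.DataFrame(
        {f: woe.transform(X[f].to_numpy(), bt) for f, bt in bins.items()},
        index=X.index,
    )


def train_scorecard(
    samples: timeline.SampleSet,
    cfg: RunConfig,
) -> tuple[sc_mod.Scorecard, sc_mod.LogisticFit, dict[str, woe.BinTable]]:
    bins, _ = fit_bins(samples, cfg)
    X_woe = encode(samples.X, bins)
    fit = sc_mod.fit_logreg(X_woe, samples.y)
    card = sc_mod.build_scorecard(fit, bins, p0=cfg.p0, pdo=cfg.pdo)
    return card, fit, bins


def hourly_scores(
    grid: pd.DataFrame,
    card: sc_mod.Scorecard,
    lookback_h: int = 6,
) -> dict[object, pd.Series]:
    """Sliding-window risk score at every in-stay hour, per patient.

    Hour ``t`` uses the look-back mean over ``[t - lookback_h, t)`` (partial
    windows allowed early in the stay); still-missing features fall to the
    missing bin.  This is the real-time monitoring view.
    """
    feats = timeline._lookback_features(grid, lookback_h)
    feats = feats.dropna(how="all")
    scores = pd.Series(card.score(feats[card.features]), index=feats.index)
    return {pid: s.droplevel("patient_id")
            for pid, s in scores.groupby(level="patient_id")}


@dataclass
class PipelineResult:
    labels: pd.DataFrame
    samples: timeline.SampleSet
    split: pd.Series
    card: sc_mod.Scorecard
    fit: sc_mod.LogisticFit
    metrics: dict
    trajectories: pd.DataFrame


def run_pipeline(bundle: CohortBundle, cfg: RunConfig) -> PipelineResult:
    cfg.validate()
    bundle = bundle.in_hours()
    rng = np.random.default_rng(cfg.seed)

    labels = phenotype.label_cohort(bundle)
    n_shock = int(labels["shock_flag"].sum())
    logger.info("labeled %d patients, %d with septic shock",
                len(labels), n_shock)
    if n_shock == 0 or n_shock == len(labels):
        raise ValueError("cohort must contain both shock and non-shock patients")

    meas = bundle.measurements
    grid = timeline.forward_fill(
        timeline.hourly_discretize(
            meas.loc[meas["channel"].isin(cfg.features)],
            bundle.patients, cfg.features))
    samples = timeline.build_samples(
        grid, labels, lookback_h=cfg.lookback_h, horizon_h=cfg.horizon_h,
        sampling=cfg.sampling, rng=rng)

    split = split_patients(labels, cfg.split, seed=cfg.seed)
    frame = samples.frame.assign(split=samples.frame["patient_id"].map(split))
    train = timeline.SampleSet(frame[frame["split"] == "train"], samples.features)

    card, fit, bins = train_scorecard(train, cfg)

    scores = {name: card.score(part[samples.features])
              for name, part in frame.groupby("split")}
    ys = {name: part["label"].to_numpy(dtype=int)
          for name, part in frame.groupby("split")}
    aucs = {name: evaluate.auc(scores[name], ys[name])
            for name in scores if len(np.unique(ys[name])) == 2}
    ks = evaluate.ks_curve(scores["test"], ys["test"])
    psi_tv = evaluate.psi(scores["train"], scores["val"], cfg.cutoffs)
    psi_tt = evaluate.psi(scores["train"], scores["test"], cfg.cutoffs)

    all_scores = card.score(frame[samples.features])
    groups = evaluate.assign_groups(all_scores, cfg.cutoffs)
    incidence = evaluate.group_incidence(groups, frame["label"].to_numpy())

    # real-time trajectories for shock patients
    onsets = labels.set_index("patient_id")["t_septic_shock"].dropna()
    shock_grid = grid.loc[grid.index.get_level_values("patient_id").isin(onsets.index)]
    series = hourly_scores(shock_grid, card, cfg.lookback_h) if len(onsets) else {}
    report = evaluate.forewarning_leadtimes(series, onsets.to_dict())
    group_series = {pid: pd.Series(
        evaluate.assign_groups(s.to_numpy(), cfg.cutoffs), index=s.index)
        for pid, s in series.items()}
    # SS_LR: shock patients scored low-risk at the forewarning anchor
    ss_lr = [pid for pid, s in series.items()
             if (int(onsets[pid]) - cfg.horizon_h) in s.index
             and evaluate.assign_group(
                 float(s.loc[int(onsets[pid]) - cfg.horizon_h]), cfg.cutoffs) == "LR"]
    esc = evaluate.escalation_detect(
        {pid: group_series[pid] for pid in ss_lr}, onsets.to_dict(),
        from_group="LR", to_group="MR", within_h=cfg.escalation_within_h)

    q1, q3 = report.iqr_lead
    metrics = {
        "n_patients": int(len(labels)),
        "n_shock": n_shock,
        "n_samples": int(len(frame)),
        "auc": {k: round(v, 4) for k, v in aucs.items()},
        "ks_test": round(ks.statistic, 4),
        "ks_argmax_score": ks.argmax_score,
        "psi_train_val": round(psi_tv, 6),
        "psi_train_test": round(psi_tt, 6),
        "incidence": incidence.to_dict(orient="records"),
        "lead_median_h": report.median_lead,
        "lead_iqr_h": [q1, q3],
        "frac_hr_at_6h": round(report.frac_at(6), 4),
        "frac_hr_at_13h": round(report.frac_at(13), 4),
        "n_ss_lr": len(ss_lr),
        "escalation_lr_to_mr_frac": (
            round(evaluate.escalation_fraction(esc), 4) if esc else None),
    }

    traj_rows = []
    for pid, s in series.items():
        for h, v in s.items():
            traj_rows.append((pid, int(h), float(v),
                              evaluate.assign_group(float(v), cfg.cutoffs),
                              float(onsets[pid])))
    trajectories = pd.DataFrame(
        traj_rows, columns=["patient_id", "hour", "score", "group", "t_septic_shock"])

    return PipelineResult(labels, timeline.SampleSet(frame, samples.features),
                          split, card, fit, metrics, trajectories)


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    """Persist the artifact bundle; partial output is removed on failure."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for name, frame in [
            ("labels.csv", result.labels),
            ("samples.csv", result.samples.frame),
            ("trajectories.csv", result.trajectories),
        ]:
            path = out / name
            frame.to_csv(path, index=False)
            written.append(path)
        sc_mod.export_scorecard(result.card, out / "scorecard.json",
                                out / "scorecard.csv")
        written += [out / "scorecard.json", out / "scorecard.csv"]
        path = out / "metrics.json"
        path.write_text(json.dumps(result.metrics, indent=1))
        written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
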