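"""Logistic model on WOE features and the 0-100 points scorecard.

Points algebra
--------------
With ``factor = PDO / ln 2`` and ``offset = P0``, the raw total score is the
classical credit-scoring map of the model's log-odds:

    raw_total = offset + factor * logit(P(non-shock))
              = (P0 - factor * alpha) - factor * sum_i beta_i * WOE_i(x)

split into a base score and per-bin points ``-factor * beta_i * WOE_ij``.
A final affine rescale maps the *achievable* raw range exactly onto
[0, 100]: the most shock-enriched bin of every feature scores 0 in total and
the most NS-enriched combination scores 100.  Lower total = higher risk.
The P0/PDO choice is absorbed by the rescale, so it only affects the
intermediate raw scale, never the emitted card.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .woe import BinTable

logger = logging.getLogger("sorpkit.scorecard")

SCHEMA_VERSION = 1
DEFAULT_P0 = 60.0
DEFAULT_PDO = 20.0


@dataclass
class LogisticFit:
    """Coefficients of the WOE-space logistic model (label 1 = septic shock)."""

    features: list[str]
    coef: np.ndarray
    intercept: float

    def log_odds(self, X_woe: pd.DataFrame) -> np.ndarray:
        return self.intercept + X_woe[self.features].to_numpy() @ self.coef

    def predict_proba(self, X_woe: pd.DataFrame) -> np.ndarray:
        z = self.log_odds(X_woe)
        return 1.0 / (1.0 + np.exp(-z))


def fit_logreg(
    X_woe: pd.DataFrame,
    y,
    l2: Optional[float] = None,
    max_iter: int = 2000,
) -> LogisticFit:
    """Maximum-likelihood logistic regression on WOE-encoded features.

    Unregularized by default; on (quasi-)perfect separation — detected as a
    diverging coefficient norm — the fit falls back to a small L2 penalty
    with a warning.  ``l2`` sets an explicit penalty strength (sklearn's C
    is its inverse).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit")
    features = list(X_woe.columns)
    if l2 is not None:
        model = LogisticRegression(C=1.0 / l2, max_iter=max_iter)
        model.fit(X_woe.to_numpy(), y)
    else:
        model = LogisticRegression(C=np.inf, max_iter=max_iter)
        model.fit(X_woe.to_numpy(), y)
        if not np.all(np.isfinite(model.coef_)) or np.abs(model.coef_).max() > 1e4:
            logger.warning("perfect separation suspected; refitting with small L2")
            model = LogisticRegression(C=1e4, max_iter=max_iter)
            model.fit(X_woe.to_numpy(), y)
    return LogisticFit(features, model.coef_.ravel().copy(),
                       float(model.intercept_[0]))


@dataclass
class Scorecard:
    """Base score plus per-feature per-bin points on the 0-100 scale."""

    features: list[str]
    bins: dict[str, BinTable]
    points: dict[str, np.ndarray]          # rescaled, one entry per bin
    missing_points: dict[str, float]
    base_score: float
    p0: float = DEFAULT_P0
    pdo: float = DEFAULT_PDO
    raw_min: float = 0.0                   # rescale bookkeeping
    raw_scale: float = 1.0                 # final = (raw - raw_min) * raw_scale

    def score(self, X: pd.DataFrame, clip: bool = True) -> np.ndarray:
        """Total 0-100 score per row of raw (unencoded) feature values."""
        total = np.full(len(X), self.base_score, dtype=float)
        for f in self.features:
            idx = self.bins[f].assign(X[f].to_numpy())
            pts = self.points[f]
            vals = np.where(idx >= 0, pts[np.clip(idx, 0, len(pts) - 1)],
                            self.missing_points[f])
            total += vals
        return np.clip(total, 0.0, 100.0) if clip else total

    def score_one(self, sample: Mapping[str, float]) -> float:
        row = pd.DataFrame([{f: sample.get(f, np.nan) for f in self.features}])
        return float(self.score(row)[0])

    def rounded(self, decimals: int = 0) -> "Scorecard":
        """Integer (or fixed-decimal) points for bedside-card emulation."""
        return Scorecard(
            self.features, self.bins,
            {f: np.round(p, decimals) for f, p in self.points.items()},
            {f: round(p, decimals) for f, p in self.missing_points.items()},
            round(self.base_score, decimals), self.p0, self.pdo,
            self.raw_min, self.raw_scale,
        )


def build_scorecard(
    fit: LogisticFit,
    bins: Mapping[str, BinTable],
    p0: float = DEFAULT_P0,
    pdo: float = DEFAULT_PDO,
) -> Scorecard:
    """Turn a logistic fit plus bin tables into a rescaled 0-100 scorecard."""
    if set(fit.features) - set(bins):
        raise ValueError("fit and bin tables cover different features")
    factor = pdo / math.log(2.0)
    n = len(fit.features)
    raw_points: dict[str, np.ndarray] = {}
    raw_missing: dict[str, float] = {}
    for f, beta in zip(fit.features, fit.coef):
        bt = bins[f]
        if bt.woe_ is None:
            raise ValueError(f"{f}: bin table has no WOE values")
        raw_points[f] = -factor * beta * bt.woe_
        raw_missing[f] = -factor * beta * bt.missing_woe
    base_raw = p0 - factor * fit.intercept

    lo = base_raw + sum(min(raw_points[f].min(), raw_missing[f])
                        for f in fit.features)
    hi = base_raw + sum(max(raw_points[f].max(), raw_missing[f])
                        for f in fit.features)
    if not hi > lo:
        raise ValueError("degenerate scorecard: all achievable totals equal")
    scale = 100.0 / (hi - lo)
    return Scorecard(
        features=list(fit.features),
        bins=dict(bins),
        points={f: raw_points[f] * scale for f in fit.features},
        missing_points={f: raw_missing[f] * scale for f in fit.features},
        base_score=(base_raw - lo) * scale,
        p0=p0, pdo=pdo, raw_min=lo, raw_scale=scale,
    )


def score(X: pd.DataFrame, sc: Scorecard) -> np.ndarray:
    """Functional alias for :meth:`Scorecard.score`."""
    return sc.score(X)


def _bt_to_dict(bt: BinTable) -> dict:
    return {
        "feature": bt.feature,
        "edges": bt.edges.tolist(),
        "counts_ns": bt.counts_ns.tolist(),
        "counts_s": bt.counts_s.tolist(),
        "woe": None if bt.woe_ is None else bt.woe_.tolist(),
        "missing_counts": list(bt.missing_counts) if bt.missing_counts else None,
        "missing_woe": bt.missing_woe,
    }


def _bt_from_dict(d: dict) -> BinTable:
    return BinTable(
        feature=d["feature"],
        edges=np.asarray(d["edges"], dtype=float),
        counts_ns=np.asarray(d["counts_ns"], dtype=float),
        counts_s=np.asarray(d["counts_s"], dtype=float),
        woe_=None if d.get("woe") is None else np.asarray(d["woe"], dtype=float),
        missing_counts=tuple(d["missing_counts"]) if d.get("missing_counts") else None,
        missing_woe=float(d.get("missing_woe", 0.0)),
    )


def export_scorecard(sc: Scorecard, json_path: str | Path,
                     csv_path: Optional[str | Path] = None) -> None:
    """Write the scorecard bundle as JSON (lossless) and optionally CSV.

    The CSV is the printable bedside card: one row per (feature, bin) with
    points at two decimals, plus a base-score row.  Scoring always uses the
    unrounded JSON values.
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "p0": sc.p0, "pdo": sc.pdo,
        "base_score": sc.base_score,
        "raw_min": sc.raw_min, "raw_scale": sc.raw_scale,
        "features": sc.features,
        "bins": {f: _bt_to_dict(sc.bins[f]) for f in sc.features},
        "points": {f: sc.points[f].tolist() for f in sc.features},
        "missing_points": sc.missing_points,
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["feature", "bin", "points"])
            wr.writerow(["<base>", "", f"{sc.base_score:.2f}"])
            for f in sc.features:
                for lab, pts in zip(sc.bins[f].bin_labels(), sc.points[f]):
                    wr.writerow([f, lab, f"{pts:.2f}"])
                if sc.bins[f].missing_counts is not None:
                    wr.writerow([f, "<missing>", f"{sc.missing_points[f]:.2f}"])


def import_scorecard(json_path: str | Path) -> Scorecard:
    payload = json.loads(Path(json_path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported scorecard schema version {version!r} "
            f"(expected {SCHEMA_VERSION})")
    bins = {f: _bt_from_dict(d) for f, d in payload["bins"].items()}
    return Scorecard(
        features=list(payload["features"]),
        bins=bins,
        points={f: np.asarray(p, dtype=float)
                for f, p in payload["points"].items()},
        missing_points={f: float(v)
                        for f, v in payload["missing_points"].items()},
        base_score=float(payload["base_score"]),
        p0=float(payload["p0"]), pdo=float(payload["pdo"]),
        raw_min=float(payload["raw_min"]), raw_scale=float(payload["raw_scale"]),
    )
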