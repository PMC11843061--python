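"""Risk stratification and model evaluation statistics.

Scores live on [0, 100] with *lower = higher risk*.  The four risk groups
are fixed score intervals: HR [0,40), MR [40,60), LR [60,80), ULR [80,100]
(half-open upward; 100 belongs to ULR).  AUC is therefore computed on the
reversed score ranking, and the KS statistic is the maximum gap between the
class-wise cumulative score distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger("sorpkit.evaluate")

RISK_GROUPS = ["HR", "MR", "LR", "ULR"]           # highest to lowest risk
DEFAULT_CUTOFFS = (40.0, 60.0, 80.0)
_RISK_ORDER = {"ULR": 0, "LR": 1, "MR": 2, "HR": 3}


def assign_group(score: float, cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> str:
    """Risk group for a single score; boundaries belong to the safer group."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score {score} outside [0, 100]")
    for grp, cut in zip(RISK_GROUPS, cutoffs):
        if score < cut:
            return grp
    return RISK_GROUPS[-1]


def assign_groups(scores, cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 100)):
        raise ValueError("scores outside [0, 100]")
    idx = np.searchsorted(np.asarray(cutoffs, dtype=float), s, side="right")
    return np.asarray(RISK_GROUPS)[idx]


@dataclass
class KSCurve:
    """Class-wise cumulative score distributions and their maximum gap."""

    grid: np.ndarray        # integer score grid 0..100 (for plotting)
    cdf_s: np.ndarray       # P(score <= g | shock)
    cdf_ns: np.ndarray      # P(score <= g | non-shock)
    diff: np.ndarray        # cdf_s - cdf_ns on the grid
    statistic: float        # exact max |F_S - F_NS| over all thresholds
    argmax_score: float     # threshold attaining the maximum


def ks_curve(scores, labels) -> KSCurve:
    """Empirical KS curve of shock vs non-shock score distributions.

    The statistic is evaluated at every observed score (not just the integer
    grid), so it equals the brute-force maximum over all thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    points = np.unique(s)
    f_s = np.searchsorted(np.sort(pos), points, side="right") / len(pos)
    f_ns = np.searchsorted(np.sort(neg), points, side="right") / len(neg)
    gaps = np.abs(f_s - f_ns)
    i = int(np.argmax(gaps))
    grid = np.arange(101)
    g_s = np.searchsorted(np.sort(pos), grid, side="right") / len(pos)
    g_ns = np.searchsorted(np.sort(neg), grid, side="right") / len(neg)
    return KSCurve(grid, g_s, g_ns, g_s - g_ns,
                   float(gaps[i]), float(points[i]))


def group_incidence(groups, outcomes) -> pd.DataFrame:
    """Shock incidence per risk group.

    Returns one row per group (HR..ULR) with the group size, positive count,
    rate, and the percentage rounded to one decimal; empty groups report NaN.
    """
    g = np.asarray(groups)
    y = np.asarray(outcomes, dtype=int)
    rows = []
    for grp in RISK_GROUPS:
        mask = g == grp
        n = int(mask.sum())
        pos = int(y[mask].sum())
        rate = pos / n if n else np.nan
        rows.append((grp, n, pos, rate,
                     round(100.0 * rate, 1) if n else np.nan))
    return pd.DataFrame(rows, columns=["group", "n", "positives", "rate", "pct"])


def incidence_pct(positives: int, total: int) -> float:
    """Percentage to one decimal, as printed in incidence tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * positives / total, 1)


def psi(
    reference,
    comparison,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    eps: float = 1e-4,
) -> float:
    """Population stability index between two score distributions.

    Inputs are score arrays (binned into the risk groups) or pre-binned
    count/proportion vectors of equal length.  Zero-mass bins are smoothed
    by ``eps`` and renormalized; PSI is symmetric and >= 0.
    """
    def to_props(x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("expected a 1-D array")
        looks_binned = len(x) <= len(cutoffs) + 1
        if not looks_binned:
            grp = assign_groups(x, cutoffs)
            x = np.array([(grp == g).sum() for g in RISK_GROUPS], dtype=float)
        return x / x.sum()

    p, q = to_props(reference), to_props(comparison)
    if len(p) != len(q):
        raise ValueError("incompatible binnings")
    p = np.where(p == 0, eps, p)
    q = np.where(q == 0, eps, q)
    p, q = p / p.sum(), q / q.sum()
    return float(np.sum((p - q) * np.log(p / q)))


def auc(scores, labels) -> float:
    """Discrimination AUC with the risk orientation (lower score = riskier).

    Equals the Mann-Whitney concordance probability of the reversed score;
    ties count one half.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, -np.asarray(scores, dtype=float)))


@dataclass
class TrajectoryReport:
    """Per-patient high-risk-zone entry leads relative to shock onset."""

    leads: pd.Series                # hours before onset; NaN = never entered
    n_patients: int

    @property
    def median_lead(self) -> float:
        return float(self.leads.dropna().median()) if self.leads.notna().any() else np.nan

    @property
    def iqr_lead(self) -> tuple[float, float]:
        ok = self.leads.dropna()
        if ok.empty:
            return (np.nan, np.nan)
        return (float(ok.quantile(0.25)), float(ok.quantile(0.75)))

    def frac_at(self, lead_h: float) -> float:
        """Fraction of all SS patients already in the HR zone ``lead_h``
        hours (or more) before onset."""
        return float((self.leads >= lead_h).sum() / self.n_patients)


def forewarning_leadtimes(
    score_series: Mapping[object, pd.Series],
    onsets: Mapping[object, float],
    hr_upper: float = DEFAULT_CUTOFFS[0],
) -> TrajectoryReport:
    """First HR-zone entry lead per shock patient.

    ``score_series`` maps patient -> hourly scores (index = hour, computed
    with a sliding look-back window); the lead is ``onset - first hour with
    score < hr_upper`` among hours at or before onset.  Patients never
    entering the HR zone carry a NaN lead but stay in fraction denominators.
    """
    leads = {}
    for pid, series in score_series.items():
        onset = onsets.get(pid)
        if onset is None or (isinstance(onset, float) and np.isnan(onset)):
            continue
        pre = series.loc[series.index <= onset]
        hit = pre.loc[pre < hr_upper]
        leads[pid] = float(onset - hit.index[0]) if not hit.empty else np.nan
    s = pd.Series(leads, dtype=float)
    return TrajectoryReport(s, n_patients=len(s))


def escalation_detect(
    group_series: Mapping[object, pd.Series],
    onsets: Mapping[object, float],
    from_group: str = "LR",
    to_group: str = "MR",
    within_h: int = 3,
) -> dict[object, bool]:
    """Did the risk group escalate from ``from_group`` to at least
    ``to_group`` within ``within_h`` hours before onset?

    A jump past ``to_group`` (e.g. LR straight to HR) counts; the ordering
    is ULR < LR < MR < HR.
    """
    lo = _RISK_ORDER[from_group]
    hi = _RISK_ORDER[to_group]
    if hi <= lo:
        raise ValueError("to_group must be riskier than from_group")
    flags: dict[object, bool] = {}
    for pid, series in group_series.items():
        onset = onsets.get(pid)
        if onset is None or (isinstance(onset, float) and np.isnan(onset)):
            continue
        window = series.loc[(series.index >= onset - within_h)
                            & (series.index < onset)]
        ranks = window.map(_RISK_ORDER).to_numpy()
        flag = False
        seen_from = False
        for r in ranks:
            if r == lo:
                seen_from = True
            elif seen_from and r >= hi:
                flag = True
                break
        flags[pid] = flag
    return flags


def escalation_fraction(flags: Mapping[object, bool]) -> float:
    if not flags:
        return np.nan
    return sum(flags.values()) / len(flags)


def ks_threshold(scores, labels) -> float:
    """Score at which the class CDF gap peaks (research-mode cutoff)."""
    return ks_curve(scores, labels).argmax_score
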