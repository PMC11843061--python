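"""Supervised binning and weight-of-evidence encoding.

A feature is discretized into right-closed intervals
``(-inf, e1], (e1, e2], ..., (e_{k-1}, +inf)``.  For bin ``i`` with
non-shock (NS) and shock (S) counts ``n_NS_i`` and ``n_S_i``:

    Distribution_NS_i = n_NS_i / sum(n_NS)
    Distribution_S_i  = n_S_i  / sum(n_S)
    WOE_i = ln(Distribution_NS_i / Distribution_S_i)
    IV    = sum_i (Distribution_NS_i - Distribution_S_i) * WOE_i

Positive WOE marks an NS-enriched (safer) bin, so higher scorecard points
mean lower risk.  Binning starts from ~10 quantile bins, repairs any
single-class bin by merging toward its smaller neighbour, then bottom-up
chi-merges the adjacent pair with the largest Pearson chi-square p-value
until a target bin count; the final count is the smallest k whose IV stays
within a 5% plateau of the maximum along the merge path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("sorpkit.woe")


class UnusableFeatureError(ValueError):
    """Fewer than two mixed-class bins can be formed for this feature."""


@dataclass(frozen=True)
class BinTable:
    """Bin edges, per-class counts, and (optionally) WOE/IV for one feature."""

    feature: str
    edges: np.ndarray          # internal edges, length k-1, strictly increasing
    counts_ns: np.ndarray      # length k
    counts_s: np.ndarray       # length k
    woe_: Optional[np.ndarray] = None
    missing_counts: Optional[tuple[int, int]] = None  # (n_ns, n_s)
    missing_woe: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "counts_ns", np.asarray(self.counts_ns, dtype=float))
        object.__setattr__(self, "counts_s", np.asarray(self.counts_s, dtype=float))
        if len(self.edges) != self.k - 1:
            raise ValueError("edges length must be k-1")
        if self.k > 1 and np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.counts_ns)

    @property
    def dist_ns(self) -> np.ndarray:
        return self.counts_ns / self.counts_ns.sum()

    @property
    def dist_s(self) -> np.ndarray:
        return self.counts_s / self.counts_s.sum()

    def bin_labels(self) -> list[str]:
        bounds = [-np.inf, *self.edges, np.inf]
        return [f"({bounds[i]:.4g}, {bounds[i+1]:.4g}]" for i in range(self.k)]

    def assign(self, values: Iterable[float]) -> np.ndarray:
        """Bin index per value under the ``(a, b]`` convention; NaN -> -1."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, v, side="left")
        return np.where(np.isnan(v), -1, idx).astype(int)


def bin_table_from_edges(
    values: Sequence[float],
    labels: Sequence[int],
    edges: Sequence[float],
    feature: str = "feature",
) -> BinTable:
    """Count a BinTable over fixed internal edges (diagnostics / recovery)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    mask = ~np.isnan(v)
    v, y = v[mask], y[mask]
    e = np.asarray(edges, dtype=float)
    idx = np.searchsorted(e, v, side="left")
    k = len(e) + 1
    return BinTable(
        feature, e,
        np.bincount(idx[y == 0], minlength=k).astype(float),
        np.bincount(idx[y == 1], minlength=k).astype(float),
    )


def initial_bins(
    values: Sequence[float],
    labels: Sequence[int],
    n_init: int = 10,
    feature: str = "feature",
) -> BinTable:
    """Quantile bins repaired so every bin contains both classes.

    A single-class bin is merged into the neighbour with the smaller total
    count (ties toward the left neighbour) until every bin is mixed.  Raises
    :class:`UnusableFeatureError` when fewer than two mixed bins remain.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels must be the same length")
    mask = ~np.isnan(v)
    v, y = v[mask], y[mask]
    if y.sum() == 0 or y.sum() == len(y):
        raise UnusableFeatureError(f"{feature}: only one class present")
    qs = np.quantile(v, np.linspace(0, 1, n_init + 1)[1:-1])
    edges = np.unique(qs)
    # Interior edges equal to the max leave an empty top bin; trim them.
    edges = edges[edges < v.max()]
    if len(edges) == 0:
        raise UnusableFeatureError(f"{feature}: constant or near-constant values")
    idx = np.searchsorted(edges, v, side="left")
    k = len(edges) + 1
    counts_ns = np.bincount(idx[y == 0], minlength=k).astype(float)
    counts_s = np.bincount(idx[y == 1], minlength=k).astype(float)
    bt = BinTable(feature, edges, counts_ns, counts_s)
    bt = _repair_single_class(bt)
    if bt.k < 2:
        raise UnusableFeatureError(
            f"{feature}: cannot form two bins that both contain each class")
    return bt


def _merge_pair(bt: BinTable, i: int) -> BinTable:
    """Merge bins i and i+1 (drop edge i)."""
    ns = bt.counts_ns.copy()
    s = bt.counts_s.copy()
    ns[i] += ns[i + 1]
    s[i] += s[i + 1]
    return replace(
        bt,
        edges=np.delete(bt.edges, i),
        counts_ns=np.delete(ns, i + 1),
        counts_s=np.delete(s, i + 1),
        woe_=None,
    )


def _repair_single_class(bt: BinTable) -> BinTable:
    while bt.k > 1:
        single = np.nonzero((bt.counts_ns == 0) | (bt.counts_s == 0))[0]
        if single.size == 0:
            break
        i = int(single[0])  # leftmost offending bin
        total = bt.counts_ns + bt.counts_s
        if i == 0:
            j = 0
        elif i == bt.k - 1:
            j = i - 1
        else:
            # merge toward the neighbour with the smaller total; ties -> left
            j = i - 1 if total[i - 1] <= total[i + 1] else i
        bt = _merge_pair(bt, j)
    return bt


def _pair_pvalues(bt: BinTable) -> np.ndarray:
    """Pearson chi-square p-value (no continuity correction) per adjacent pair."""
    pvals = np.empty(bt.k - 1)
    for i in range(bt.k - 1):
        table = np.array([
            [bt.counts_ns[i], bt.counts_s[i]],
            [bt.counts_ns[i + 1], bt.counts_s[i + 1]],
        ])
        res = stats.chi2_contingency(table, correction=False)
        pvals[i] = res.pvalue
    return pvals


def chi_merge(bt: BinTable, target_k: int) -> BinTable:
    """Merge the most-homogeneous adjacent pair until ``target_k`` bins.

    Homogeneity is the largest chi-square p-value; ties merge the leftmost
    pair, keeping the procedure deterministic.  The both-classes invariant
    is preserved because merging only adds counts.
    """
    if target_k < 2:
        raise ValueError("target_k must be >= 2")
    if target_k > bt.k:
        logger.warning("target_k=%d exceeds current k=%d; returning unchanged",
                       target_k, bt.k)
        return bt
    while bt.k > target_k:
        pvals = _pair_pvalues(bt)
        bt = _merge_pair(bt, int(np.argmax(pvals)))
    return bt


def woe(bt: BinTable) -> BinTable:
    """Fill per-bin WOE (and the missing bin's WOE when it is mixed)."""
    if np.any(bt.counts_ns == 0) or np.any(bt.counts_s == 0):
        raise ValueError(f"{bt.feature}: zero class count in a bin; "
                         "repair bins before computing WOE")
    w = np.log(bt.dist_ns / bt.dist_s)
    m_woe = 0.0
    if bt.missing_counts is not None:
        m_ns, m_s = bt.missing_counts
        if m_ns > 0 and m_s > 0:
            m_woe = float(np.log((m_ns / bt.counts_ns.sum())
                                 / (m_s / bt.counts_s.sum())))
    return replace(bt, woe_=w, missing_woe=m_woe)


def iv(bt: BinTable) -> float:
    """Information value; requires WOE to be filled."""
    if bt.woe_ is None:
        raise ValueError("compute woe() before iv()")
    return float(np.sum((bt.dist_ns - bt.dist_s) * bt.woe_))


def merge_path(bt: BinTable, k_min: int = 2) -> dict[int, BinTable]:
    """Chi-merge path from the current k down to ``k_min``, WOE/IV filled."""
    path: dict[int, BinTable] = {}
    cur = woe(bt)
    path[cur.k] = cur
    while cur.k > k_min:
        cur = woe(chi_merge(cur, cur.k - 1))
        path[cur.k] = cur
    return path


def select_k(
    iv_curve: dict[int, float],
    k_range: Optional[Iterable[int]] = None,
    tau: float = 0.05,
) -> int:
    """Smallest k whose IV is within ``tau`` of the maximum over ``k_range``.

    The IV plateau rule: coarser cards are easier to use at the bedside, so
    we take the fewest bins that retain at least ``(1 - tau)`` of the best
    achievable IV.
    """
    ks = sorted(set(k_range) & set(iv_curve) if k_range is not None
                else set(iv_curve))
    if not ks:
        raise ValueError("empty k range")
    best = max(iv_curve[k] for k in ks)
    for k in ks:
        if iv_curve[k] >= (1.0 - tau) * best:
            return k
    return ks[-1]  # unreachable for tau >= 0


def transform(values: Iterable[float], bt: BinTable) -> np.ndarray:
    """WOE-encode values; missing values take the missing bin's WOE (or 0)."""
    if bt.woe_ is None:
        raise ValueError("compute woe() before transform()")
    idx = bt.assign(values)
    out = np.where(idx >= 0, bt.woe_[np.clip(idx, 0, bt.k - 1)], bt.missing_woe)
    return out


def fit_feature_bins(
    values: Sequence[float],
    labels: Sequence[int],
    n_init: int = 10,
    k_range: Optional[Iterable[int]] = None,
    tau: float = 0.05,
    missing_bin_frac: float = 0.01,
    feature: str = "feature",
) -> tuple[BinTable, dict[int, float]]:
    """End-to-end binning for one feature.

    Returns the selected :class:`BinTable` (WOE filled; a missing bin is
    attached when at least ``missing_bin_frac`` of samples are missing) and
    the IV curve along the chi-merge path.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    bt = initial_bins(v, y, n_init=n_init, feature=feature)
    path = merge_path(bt)
    iv_curve = {k: iv(t) for k, t in path.items()}
    k = select_k(iv_curve, k_range=k_range, tau=tau)
    chosen = path[k]
    miss = np.isnan(v)
    if miss.mean() >= missing_bin_frac:
        chosen = replace(
            chosen,
            missing_counts=(int((miss & (y == 0)).sum()),
                            int((miss & (y == 1)).sum())),
        )
        chosen = woe(chosen)
    return chosen, iv_curve
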