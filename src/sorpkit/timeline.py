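"""Hourly discretization, forward filling, and look-back/horizon sampling.

Conventions
-----------
* Hours are 0-based from ICU admission; a measurement at time ``t`` (float
  hours) belongs to hour ``floor(t)``, so a reading exactly on an hour
  boundary falls in the *later* hour.
* All interval arithmetic uses half-open hour intervals ``[a, b)``.
* A grid cell at hour ``h`` never depends on measurements after ``h``
  (forward fill only carries values forward), which keeps every derived
  sample causal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("sorpkit.timeline")

#: Named intervals in hours relative to an anchor (shock onset = 0).
INTERVALS: dict[str, tuple[int, int]] = {
    "look_back": (-12, -6),
    "preonset": (-6, 0),
    "postonset": (0, 6),
}


def hourly_discretize(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    channels: Iterable[str],
) -> pd.DataFrame:
    """Aggregate long-format measurements to an hourly grid.

    Multiple readings of a channel within the same hour are averaged; hours
    with no reading are left missing (NaN) for :func:`forward_fill` to carry.

    Parameters
    ----------
    measurements
        Columns ``patient_id, time, channel, value`` with ``time`` in float
        hours from admission.
    patients
        Must carry ``patient_id`` and ``stay_h`` (see ``CohortBundle.in_hours``).
    channels
        Feature names to keep.  Measurement rows with channels outside this
        list are skipped with a logged warning.

    Returns
    -------
    DataFrame indexed by ``(patient_id, hour)`` with one column per channel,
    hours running 0 .. floor(stay_h)-1 for every patient.
    """
    channels = list(channels)
    if not channels:
        raise ValueError("channels must be non-empty")
    meas = measurements
    if not pd.api.types.is_numeric_dtype(meas["value"]):
        coerced = pd.to_numeric(meas["value"], errors="coerce")
        bad = coerced.isna() & meas["value"].notna()
        if bad.any():
            row = meas.index[bad][0]
            raise ValueError(
                f"non-numeric measurement value at row {row}: "
                f"{meas.loc[row, 'value']!r}"
            )
        meas = meas.assign(value=coerced)
    unknown = set(meas["channel"].unique()) - set(channels)
    if unknown:
        logger.warning("skipping %d channel(s) not requested: %s",
                       len(unknown), sorted(unknown))
    meas = meas[meas["channel"].isin(channels)]

    stay = patients.set_index("patient_id")["stay_h"]
    n_hours = stay.apply(lambda s: max(int(math.floor(s)), 1))

    hour = np.floor(meas["time"].to_numpy(dtype=float)).astype(int)
    keep = (hour >= 0) & (hour < meas["patient_id"].map(n_hours).to_numpy())
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d measurement(s) outside the ICU stay", dropped)
    meas = meas.loc[keep].assign(hour=hour[keep])

    cells = (
        meas.groupby(["patient_id", "hour", "channel"], sort=True)["value"]
        .mean()
        .unstack("channel")
    )
    # Full per-patient hour index so gaps are explicit.
    full_index = pd.MultiIndex.from_tuples(
        [(pid, h) for pid, nh in n_hours.items() for h in range(nh)],
        names=["patient_id", "hour"],
    )
    grid = cells.reindex(index=full_index, columns=channels)
    return grid


def forward_fill(grid: pd.DataFrame) -> pd.DataFrame:
    """Carry each patient's last observation forward (unbounded).

    Cells before a channel's first observation remain missing, so filled
    values never leak information backward in time.
    """
    return grid.groupby(level="patient_id", sort=False).ffill()


def interval_mean(
    grid: pd.DataFrame,
    anchor: int,
    interval: str | tuple[int, int],
    patient_id: object | None = None,
) -> pd.Series:
    """Per-feature mean over a named interval relative to ``anchor``.

    ``interval`` is a label from :data:`INTERVALS` or an explicit ``(a, b)``
    offset pair; the hours covered are ``[anchor+a, anchor+b)``.  Means use
    non-missing cells only; an empty or fully-missing window yields NaN.
    """
    if isinstance(interval, str):
        try:
            lo_off, hi_off = INTERVALS[interval]
        except KeyError:
            raise KeyError(
                f"unknown interval {interval!r}; expected one of {list(INTERVALS)}"
            ) from None
    else:
        lo_off, hi_off = interval
    sub = grid.xs(patient_id, level="patient_id") if patient_id is not None else grid
    if isinstance(sub.index, pd.MultiIndex):
        raise ValueError("grid holds several patients; pass patient_id")
    lo, hi = anchor + lo_off, anchor + hi_off
    window = sub.loc[(sub.index >= lo) & (sub.index < hi)]
    if window.empty:
        logger.warning("interval [%d, %d) lies outside the ICU stay", lo, hi)
        return pd.Series(np.nan, index=sub.columns)
    return window.mean()


def _lookback_features(grid: pd.DataFrame, lookback_h: int) -> pd.DataFrame:
    """Rolling look-back means: row at (pid, t) = mean over hours [t-L, t)."""
    rolled = (
        grid.groupby(level="patient_id", sort=False)
        .rolling(lookback_h, min_periods=1)
        .mean()
    )
    rolled.index = rolled.index.droplevel(0)
    shifted = rolled.groupby(level="patient_id", sort=False).shift(1)
    return shifted


@dataclass
class SampleSet:
    """Feature matrix with sample provenance.

    ``frame`` has the feature columns plus ``patient_id``, ``anchor_hour``
    and ``label`` (1 = septic shock within the horizon after the anchor).
    """

    frame: pd.DataFrame
    features: list[str]
    n_dropped_incomplete: int = 0

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.features]

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)


def build_samples(
    grid: pd.DataFrame,
    labels: pd.DataFrame,
    lookback_h: int = 6,
    horizon_h: int = 6,
    sampling: str = "onset_anchored",
    rng: Optional[np.random.Generator] = None,
    drop_incomplete: bool = True,
) -> SampleSet:
    """Build supervised samples from a forward-filled grid.

    A sample anchored at hour ``t`` carries per-feature means over
    ``[t - lookback_h, t)`` and label 1 iff the patient's shock onset falls
    in ``(t, t + horizon_h]``.  Anchors require a complete look-back window
    (``t >= lookback_h``) and a horizon inside the stay
    (``t + horizon_h <= stay``).

    Sampling policies
    -----------------
    ``onset_anchored``
        One positive per shock patient at ``t = onset - horizon_h`` (the
        forewarning anchor) and one negative per non-shock patient at a
        uniformly random valid hour (seeded via ``rng``).
    ``one_per_patient``
        One random valid anchor per patient, labelled by the onset rule.
    ``all_hours``
        Every valid anchor of every patient (real-time scoring).
    """
    if sampling not in {"onset_anchored", "one_per_patient", "all_hours"}:
        raise ValueError(f"unknown sampling policy {sampling!r}")
    rng = rng or np.random.default_rng(0)
    features = list(grid.columns)
    feats = _lookback_features(grid, lookback_h)

    n_hours = grid.groupby(level="patient_id", sort=False).size()
    onset = labels.set_index("patient_id")["t_septic_shock"]

    rows: list[tuple] = []
    for pid, nh in n_hours.items():
        t_shock = onset.get(pid, np.nan)
        t_shock = float(t_shock) if pd.notna(t_shock) else None
        lo, hi = lookback_h, int(nh) - horizon_h  # valid anchors: lo..hi incl.
        if hi < lo:
            logger.info("patient %s: stay too short for any sample", pid)
            continue
        if sampling == "all_hours":
            anchors = range(lo, hi + 1)
        elif sampling == "one_per_patient":
            anchors = [int(rng.integers(lo, hi + 1))]
        else:  # onset_anchored
            if t_shock is not None:
                t = int(math.floor(t_shock)) - horizon_h
                if t < lo or t > hi:
                    logger.info(
                        "patient %s: onset at %.0f h leaves no complete "
                        "look-back window; excluded", pid, t_shock)
                    continue
                anchors = [t]
            else:
                anchors = [int(rng.integers(lo, hi + 1))]
        for t in anchors:
            label = int(t_shock is not None and t < t_shock <= t + horizon_h)
            rows.append((pid, t, label))

    if not rows:
        return SampleSet(pd.DataFrame(columns=features + ["patient_id", "anchor_hour", "label"]),
                         features)
    idx = pd.MultiIndex.from_tuples([(p, t) for p, t, _ in rows],
                                    names=["patient_id", "hour"])
    frame = feats.reindex(idx).reset_index()
    frame = frame.rename(columns={"hour": "anchor_hour"})
    frame["label"] = [lab for _, _, lab in rows]

    n_dropped = 0
    if drop_incomplete:
        complete = frame[features].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropped %d sample(s) with a missing feature", n_dropped)
        frame = frame.loc[complete].reset_index(drop=True)
    return SampleSet(frame, features, n_dropped_incomplete=n_dropped)
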