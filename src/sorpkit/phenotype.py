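"""Sepsis-3 temporal phenotyping: t_suspicion, t_sepsis, t_septic_shock.

Operationalization
------------------
* **Suspected infection**: a qualifying antibiotic/culture pair — culture
  within 24 h after an antibiotic, or antibiotic within 72 h after a
  culture — timestamped at the earlier member of the pair.
* **Sepsis onset**: within ``[t_suspicion - 48 h, t_suspicion + 24 h]``, the
  first hour at which hourly SOFA exceeds its baseline by >= 2 points.  The
  baseline is the running minimum of SOFA inside the window up to the
  candidate hour (a window-start baseline is available via ``baseline=``).
* **Septic shock onset**: earliest hour at or after sepsis onset at which a
  vasopressor is active, fluid resuscitation was adequate (> 30 mL/kg or
  > 1000 mL within the 3 h before vasopressor initiation or sustained
  hypotension, whichever came first), and the first lactate drawn within
  6 h after the resuscitation window ends exceeds 2 mmol/L.

All times are float hours from ICU admission; grid-derived onsets are
integer hours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import timeline
from .io import CohortBundle

logger = logging.getLogger("sorpkit.phenotype")

LACTATE_THRESHOLD = 2.0       # mmol/L
MBP_THRESHOLD = 65.0          # mmHg
ABX_TO_CULTURE_H = 24.0
CULTURE_TO_ABX_H = 72.0
SOFA_BEFORE_H = 48.0
SOFA_AFTER_H = 24.0
SOFA_DELTA = 2
RESUS_WINDOW_H = 3.0
RESUS_ML_PER_KG = 30.0
RESUS_ABS_ML = 1000.0
LACTATE_AFTER_RESUS_H = 6.0

#: Standard six-subsystem SOFA table.  ``direction: low`` scores i+1 when the
#: value drops below ``cuts[i]``; ``direction: high`` scores i+1 at or above
#: ``cuts[i]``.  A subsystem whose channel is absent scores 0.  The medication
#: schema carries no vasopressor dose, so any active vasopressor raises the
#: cardiovascular subscore to at least 2.
DEFAULT_SOFA_TABLE: dict[str, dict] = {
    "respiration": {"channel": "pao2_fio2", "direction": "low",
                    "cuts": [400.0, 300.0, 200.0, 100.0]},
    "coagulation": {"channel": "platelets", "direction": "low",
                    "cuts": [150.0, 100.0, 50.0, 20.0]},
    "liver": {"channel": "bilirubin", "direction": "high",
              "cuts": [1.2, 2.0, 6.0, 12.0]},
    "cardiovascular": {"channel": "mbp", "direction": "low", "cuts": [70.0]},
    "cns": {"channel": "gcs", "direction": "low",
            "cuts": [15.0, 13.0, 10.0, 6.0]},
    "renal": {"channel": "creatinine", "direction": "high",
              "cuts": [1.2, 2.0, 3.5, 5.0]},
}

SOFA_CHANNELS = [v["channel"] for v in DEFAULT_SOFA_TABLE.values()]


@dataclass
class PhenotypeLabel:
    patient_id: object
    t_suspicion: Optional[float] = None
    t_sepsis: Optional[float] = None
    t_septic_shock: Optional[float] = None
    sofa_series: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.t_sepsis is not None and self.t_suspicion is None:
            raise ValueError("t_sepsis requires t_suspicion")
        if self.t_septic_shock is not None:
            if self.t_sepsis is None or self.t_sepsis > self.t_septic_shock:
                raise ValueError("t_septic_shock requires t_sepsis <= t_septic_shock")


def suspicion_episodes(
    antibiotics: Sequence[float],
    cultures: Sequence[float],
    abx_to_culture_h: float = ABX_TO_CULTURE_H,
    culture_to_abx_h: float = CULTURE_TO_ABX_H,
) -> list[float]:
    """All qualifying suspicion times, ascending (may be empty)."""
    abx = np.sort(np.asarray(list(antibiotics), dtype=float))
    cul = np.sort(np.asarray(list(cultures), dtype=float))
    times: set[float] = set()
    for a in abx:
        if np.any((cul >= a) & (cul <= a + abx_to_culture_h)):
            times.add(float(a))
    for c in cul:
        if np.any((abx >= c) & (abx <= c + culture_to_abx_h)):
            times.add(float(c))
    return sorted(times)


def find_suspicion(
    antibiotics: Sequence[float],
    cultures: Sequence[float],
    **kwargs,
) -> Optional[float]:
    """Earliest suspected-infection time, or None if no pair qualifies."""
    eps = suspicion_episodes(antibiotics, cultures, **kwargs)
    return eps[0] if eps else None


def _subscore(value: float, direction: str, cuts: Sequence[float]) -> int:
    if np.isnan(value):
        return 0
    score = 0
    for i, cut in enumerate(cuts):
        hit = value < cut if direction == "low" else value >= cut
        if hit:
            score = i + 1
    return score


def sofa_hourly(
    grid: pd.DataFrame,
    vasopressor_hours: Optional[Iterable[int]] = None,
    table: Optional[dict] = None,
) -> pd.Series:
    """Hourly SOFA total (0-24) for one patient's forward-filled grid.

    ``grid`` is indexed by hour with SOFA channels as columns; channels that
    are absent contribute 0.  ``vasopressor_hours`` lists hours with an
    active vasopressor (cardiovascular subscore floor of 2).
    """
    table = table or DEFAULT_SOFA_TABLE
    vaso = set(int(h) for h in vasopressor_hours) if vasopressor_hours else set()
    total = pd.Series(0, index=grid.index, dtype=int)
    any_channel = False
    for system, row in table.items():
        ch = row["channel"]
        if ch not in grid.columns:
            continue
        any_channel = True
        sub = grid[ch].map(lambda v: _subscore(v, row["direction"], row["cuts"]))
        if system == "cardiovascular" and vaso:
            sub = sub.where(~sub.index.isin(list(vaso)), other=sub.clip(lower=2))
        total = total + sub.astype(int)
    if not any_channel and not vaso:
        logger.warning("no SOFA channel present; returning all-zero series")
    return total.clip(0, 24)


def find_sepsis_onset(
    t_suspicion: float,
    sofa: pd.Series,
    before_h: float = SOFA_BEFORE_H,
    after_h: float = SOFA_AFTER_H,
    delta: int = SOFA_DELTA,
    baseline: str = "running_min",
) -> Optional[int]:
    """First hour in the suspicion window with a SOFA rise >= ``delta``.

    ``baseline='running_min'`` measures the rise against the minimum SOFA
    observed in the window up to each candidate hour; ``'window_start'``
    measures against the SOFA value at the window's first hour.
    """
    if baseline not in {"running_min", "window_start"}:
        raise ValueError(f"unknown baseline rule {baseline!r}")
    lo = int(math.ceil(t_suspicion - before_h))
    hi = int(math.floor(t_suspicion + after_h))
    window = sofa.loc[(sofa.index >= lo) & (sofa.index <= hi)]
    if window.empty:
        return None
    vals = window.to_numpy()
    if baseline == "running_min":
        base = np.minimum.accumulate(vals)
    else:
        base = np.full_like(vals, vals[0])
    rise = vals - base
    hits = np.nonzero(rise >= delta)[0]
    return int(window.index[hits[0]]) if hits.size else None


def overlap_volume(
    fluids: pd.DataFrame, window_lo: float, window_hi: float
) -> float:
    """Total infused volume inside ``[window_lo, window_hi)``, pro-rata.

    Fluid events partially overlapping the window contribute in proportion
    to the overlapping duration; instantaneous boluses (start == end) count
    fully when they fall inside the window.
    """
    if fluids.empty:
        return 0.0
    start = fluids["start"].to_numpy(dtype=float)
    end = fluids["end"].to_numpy(dtype=float)
    vol = fluids["volume_ml"].to_numpy(dtype=float)
    dur = end - start
    o_lo = np.maximum(start, window_lo)
    o_hi = np.minimum(end, window_hi)
    overlap = np.clip(o_hi - o_lo, 0.0, None)
    frac = np.where(dur > 0, overlap / np.where(dur > 0, dur, 1.0),
                    ((start >= window_lo) & (start < window_hi)).astype(float))
    return float(np.sum(vol * frac))


def adequate_resuscitation(
    fluids: pd.DataFrame,
    weight_kg: Optional[float],
    t_ref: float,
    window_h: float = RESUS_WINDOW_H,
    ml_per_kg: float = RESUS_ML_PER_KG,
    abs_ml: float = RESUS_ABS_ML,
) -> bool:
    """Was fluid resuscitation adequate in the 3 h before ``t_ref``?

    True iff the infused volume in ``[t_ref - window_h, t_ref)`` exceeds
    30 mL/kg *or* 1000 mL.  With no recorded weight only the absolute
    criterion applies.
    """
    vol = overlap_volume(fluids, t_ref - window_h, t_ref)
    if weight_kg is None or (isinstance(weight_kg, float) and np.isnan(weight_kg)):
        logger.warning("weight missing; applying only the %g mL criterion", abs_ml)
        return vol > abs_ml
    return vol > ml_per_kg * weight_kg or vol > abs_ml


def _vaso_active_hours(vaso_times: Sequence[float]) -> set[int]:
    return {int(math.floor(t)) for t in vaso_times}


def find_t_ref(
    mbp: Optional[pd.Series],
    vaso_times: Sequence[float],
    after: Optional[float] = None,
    mbp_threshold: float = MBP_THRESHOLD,
) -> Optional[float]:
    """Earlier of first vasopressor start and first sustained hypotension.

    Hypotension is an hourly grid cell with MBP below threshold (>= 1 h at
    grid granularity).  ``after`` restricts the search to times >= after.
    """
    candidates: list[float] = []
    vt = [float(t) for t in vaso_times if after is None or t >= after]
    if vt:
        candidates.append(min(vt))
    if mbp is not None:
        low = mbp.loc[mbp < mbp_threshold]
        if after is not None:
            low = low.loc[low.index >= after]
        if not low.empty:
            candidates.append(float(low.index[0]))
    return min(candidates) if candidates else None


def find_shock_onset(
    t_sepsis: Optional[float],
    mbp: Optional[pd.Series],
    vaso_times: Sequence[float],
    fluids: pd.DataFrame,
    lactates: pd.DataFrame,
    weight_kg: Optional[float],
    n_hours: Optional[int] = None,
    lactate_threshold: float = LACTATE_THRESHOLD,
    mbp_threshold: float = MBP_THRESHOLD,
) -> Optional[int]:
    """Earliest hour at which all septic-shock criteria jointly hold.

    ``lactates`` holds raw (unfilled) lactate draws with columns
    ``time, value``.  Returns None when the patient is not septic, no
    vasopressor/hypotension episode exists, resuscitation was inadequate, or
    the first post-resuscitation lactate is absent or <= threshold.
    """
    if t_sepsis is None:
        return None
    t_ref = find_t_ref(mbp, vaso_times, after=t_sepsis, mbp_threshold=mbp_threshold)
    if t_ref is None:
        return None
    if not adequate_resuscitation(fluids, weight_kg, t_ref):
        return None
    lac = lactates.loc[
        (lactates["time"] > t_ref)
        & (lactates["time"] <= t_ref + LACTATE_AFTER_RESUS_H)
    ].sort_values("time")
    if lac.empty or float(lac["value"].iloc[0]) <= lactate_threshold:
        return None
    t_lac_hour = int(math.floor(float(lac["time"].iloc[0])))
    active = _vaso_active_hours(vaso_times)
    if not active:
        return None
    start = max(int(math.ceil(t_sepsis)), t_lac_hour)
    stop = n_hours if n_hours is not None else max(active) + 1
    for h in range(start, stop):
        if h in active:
            return h
    return None


def label_patient(
    patient_id: object,
    grid: pd.DataFrame,
    abx_times: Sequence[float],
    culture_times: Sequence[float],
    vaso_times: Sequence[float],
    fluids: pd.DataFrame,
    lactates: pd.DataFrame,
    weight_kg: Optional[float],
    sofa_table: Optional[dict] = None,
    baseline: str = "running_min",
) -> PhenotypeLabel:
    """Full Sepsis-3 labeling for one patient (grid must be forward-filled)."""
    sofa = sofa_hourly(grid, _vaso_active_hours(vaso_times), table=sofa_table)
    episodes = suspicion_episodes(abx_times, culture_times)
    t_susp = episodes[0] if episodes else None
    t_sep: Optional[int] = None
    for t in episodes:
        onset = find_sepsis_onset(t, sofa, baseline=baseline)
        if onset is not None and (t_sep is None or onset < t_sep):
            t_sep = onset
            t_susp = t  # the episode that yields the earliest sepsis onset
    mbp = grid["mbp"] if "mbp" in grid.columns else None
    t_shock = find_shock_onset(
        t_sep, mbp, vaso_times, fluids, lactates, weight_kg,
        n_hours=len(grid),
    )
    if t_shock is not None and t_sep is not None and t_shock < t_sep:
        t_shock = None
    return PhenotypeLabel(patient_id, t_susp,
                          None if t_sep is None else float(t_sep),
                          None if t_shock is None else float(t_shock),
                          sofa)


def label_cohort(
    bundle: CohortBundle,
    sofa_table: Optional[dict] = None,
    baseline: str = "running_min",
) -> pd.DataFrame:
    """Label every patient in a bundle (times in hours from admission).

    Returns a frame with columns ``patient_id, t_suspicion, t_sepsis,
    t_septic_shock, shock_flag`` — the ``labels.csv`` contract.
    """
    table = sofa_table or DEFAULT_SOFA_TABLE
    channels = sorted({row["channel"] for row in table.values()} | {"mbp"})
    meas = bundle.measurements
    grid = timeline.forward_fill(
        timeline.hourly_discretize(
            meas.loc[meas["channel"].isin(channels)], bundle.patients, channels)
    )
    meds = bundle.medications
    abx = meds.loc[meds["drug_class"] == "antibiotic"].groupby("patient_id")["time"]
    abx = {k: v.tolist() for k, v in abx}
    vaso = meds.loc[meds["drug_class"] == "vasopressor"].groupby("patient_id")["time"]
    vaso = {k: v.tolist() for k, v in vaso}
    cult = {k: v.tolist()
            for k, v in bundle.cultures.groupby("patient_id")["time"]}
    lac_all = bundle.measurements.loc[bundle.measurements["channel"] == "lactate",
                                      ["patient_id", "time", "value"]]
    weights = bundle.patients.set_index("patient_id")["weight_kg"]

    records = []
    empty = pd.DataFrame(columns=["time", "value"])
    fluids_by_pid = dict(tuple(bundle.fluids.groupby("patient_id")))
    lac_by_pid = dict(tuple(lac_all.groupby("patient_id")))
    for pid, sub in grid.groupby(level="patient_id", sort=True):
        sub = sub.droplevel("patient_id")
        lab = label_patient(
            pid, sub,
            abx.get(pid, []), cult.get(pid, []), vaso.get(pid, []),
            fluids_by_pid.get(pid, pd.DataFrame(columns=["start", "end", "volume_ml"])),
            lac_by_pid.get(pid, empty),
            weights.get(pid, np.nan),
            sofa_table=table, baseline=baseline,
        )
        records.append(
            (pid, lab.t_suspicion, lab.t_sepsis, lab.t_septic_shock,
             int(lab.t_septic_shock is not None))
        )
    return pd.DataFrame(
        records,
        columns=["patient_id", "t_suspicion", "t_sepsis", "t_septic_shock",
                 "shock_flag"],
    )
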