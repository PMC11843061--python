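"""Synthetic ICU cohorts with planted Sepsis-3 onsets and planted risk.

The generator emits the five-table CSV contract (measurements, medications,
fluids, cultures, patients) plus ``truth.csv`` with the planted onset times,
so the whole pipeline is testable without credentialed ICU data.

Construction guarantees (the closed loop)
-----------------------------------------
Every planted shock patient satisfies the Sepsis-3 shock criteria exactly at
the planted hour and at no earlier hour: suspicion comes from a single
antibiotic/culture pair, sepsis onset from a creatinine step that lifts SOFA
by exactly the renal subscore, and shock onset from a scripted motif —
fluid bolus in ``[T-5, T-2)``, hypotension from ``T-2``, vasopressor from
``T-1``, first post-resuscitation lactate > 2 mmol/L drawn at ``T``.
Planted non-shock patients each violate at least one criterion (no
hypotension/vasopressor episode, inadequate fluids, or lactate that never
exceeds threshold).  Channels entering onset criteria report the exact
hourly value, so the labeler's hourly means reproduce the plant exactly.

Risk structure
--------------
A per-patient severity scales a linear pre-shock ramp (lactate up, blood
pressures down, pH down, ...) over the 16 h before onset; non-shock patients
get a milder post-sepsis shift.  Severities are graded, so scores and
per-group incidences are graded as in real cohorts.  ``plant_bin_risk``
instead pins a feature to planted per-bin odds for parameter-recovery
studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import CohortBundle

logger = logging.getLogger("sorpkit.simulate")

ABG_FEATURES = ["ph", "lactate", "pao2", "paco2", "base_excess",
                "bicarbonate", "sao2", "total_co2"]
VS_FEATURES = ["heart_rate", "resp_rate", "sbp", "dbp", "mbp",
               "temperature", "spo2"]
MODEL_FEATURES = ABG_FEATURES + VS_FEATURES
SUPPORT_CHANNELS = ["platelets", "bilirubin", "creatinine", "gcs", "pao2_fio2"]

# name -> (baseline mean, sd, clip lo, clip hi, ramp target mean, sd, lo, hi)
# target None = channel does not drift with severity.
_CH = {
    "ph":          (7.40, 0.02, 7.34, 7.46, 7.26, 0.02, 7.18, 7.33),
    "lactate":     (1.20, 0.20, 0.50, 1.90, 3.40, 0.30, 2.20, 4.80),
    "pao2":        (95.0, 8.0, 78.0, 125.0, 70.0, 6.0, 55.0, 85.0),
    "paco2":       (40.0, 3.0, 33.0, 47.0, 30.0, 3.0, 24.0, 38.0),
    "base_excess": (0.0, 1.2, -3.5, 3.5, -7.0, 1.5, -12.0, -3.0),
    "bicarbonate": (24.0, 1.5, 20.0, 28.0, 16.0, 1.5, 12.0, 20.0),
    "sao2":        (97.0, 1.0, 94.0, 100.0, 90.0, 2.0, 84.0, 95.0),
    "total_co2":   (25.0, 1.5, 21.0, 29.0, 17.0, 1.5, 13.0, 21.0),
    "heart_rate":  (85.0, 7.0, 62.0, 108.0, 120.0, 8.0, 100.0, 145.0),
    "resp_rate":   (17.0, 2.5, 11.0, 23.0, 28.0, 3.0, 22.0, 38.0),
    "sbp":         (120.0, 9.0, 98.0, 145.0, 92.0, 7.0, 75.0, 108.0),
    "dbp":         (70.0, 6.0, 56.0, 86.0, 52.0, 5.0, 40.0, 62.0),
    "mbp":         (85.0, 5.0, 72.0, 100.0, 67.0, 2.0, 66.0, 80.0),
    "temperature": (37.0, 0.3, 36.2, 38.0, 38.6, 0.4, 37.6, 39.8),
    "spo2":        (97.0, 1.2, 93.0, 100.0, 91.0, 2.0, 85.0, 96.0),
    "platelets":   (250.0, 40.0, 160.0, 400.0, None, None, None, None),
    "bilirubin":   (0.7, 0.15, 0.3, 1.1, None, None, None, None),
    "creatinine":  (0.9, 0.10, 0.6, 1.15, None, None, None, None),
    "gcs":         (15.0, 0.0, 15.0, 15.0, None, None, None, None),
    "pao2_fio2":   (430.0, 25.0, 370.0, 500.0, None, None, None, None),
}

# Channels whose values feed onset criteria: measurements report the exact
# hourly value so planted onsets survive hourly averaging.
_EXACT_HOURLY = {"mbp", "lactate", "creatinine", "platelets", "bilirubin",
                 "gcs", "pao2_fio2"}
_CRITERION_CHANNELS = {"mbp", "lactate", "creatinine"}

_SEPTIC_CREATININE = (2.5, 0.2, 2.1, 3.3)   # renal SOFA subscore 2
_HYPOTENSION = (56.0, 3.0, 48.0, 62.0)      # MBP < 65 mmHg, scripted
RAMP_H = 16
NS_MOTIFS = ("quiet", "no_fluids", "low_lactate")


@dataclass(frozen=True)
class PlantedBins:
    """Per-bin odds ratios planted on one feature."""

    edges: tuple[float, ...]       # internal edges, ascending; k = len+1 bins
    ns_probs: tuple[float, ...]    # non-shock bin distribution, length k
    odds: tuple[float, ...]        # per-bin shock odds multipliers, length k
    lo: float = 0.0                # support bounds for the outer bins
    hi: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.edges) + 1
        if len(self.ns_probs) != k or len(self.odds) != k:
            raise ValueError("ns_probs and odds must have one entry per bin")
        if any(o <= 0 for o in self.odds):
            raise ValueError("planted odds must be positive")
        if any(p <= 0 for p in self.ns_probs):
            raise ValueError("ns_probs must be positive")
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("edges must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.edges) + 1

    def class_probs(self) -> tuple[np.ndarray, np.ndarray]:
        p_ns = np.asarray(self.ns_probs, dtype=float)
        p_ns = p_ns / p_ns.sum()
        p_s = p_ns * np.asarray(self.odds, dtype=float)
        p_s = p_s / p_s.sum()
        return p_ns, p_s

    def bounds(self) -> list[tuple[float, float]]:
        cuts = [self.lo, *self.edges, self.hi]
        return [(cuts[i], cuts[i + 1]) for i in range(self.k)]


@dataclass
class CohortSpec:
    """Study conditions for cohort generation."""

    n_patients: int = 500
    shock_prevalence: float = 0.15          # echoes 766 / 5125
    stay_lognorm: tuple[float, float] = (math.log(90.0), 0.45)
    stay_clip: tuple[float, float] = (40.0, 240.0)
    weight_lognorm: tuple[float, float] = (math.log(75.0), 0.2)
    ramp_h: int = RAMP_H
    vitals_dropout: float = 0.05
    abg_interval_h: tuple[float, float] = (4.0, 8.0)
    lab_interval_h: tuple[float, float] = (8.0, 16.0)
    ns_motif_probs: tuple[float, float, float] = (0.7, 0.15, 0.15)
    planted_bins: dict[str, PlantedBins] = field(default_factory=dict)

    def validate(self) -> "CohortSpec":
        if not 0.0 <= self.shock_prevalence < 1.0:
            raise ValueError("shock_prevalence must be in [0, 1)")
        if self.ramp_h < 1:
            raise ValueError("ramp length must be >= 1 h")
        if self.stay_clip[0] < 40.0:
            raise ValueError("minimum stay must be >= 40 h to fit the onset motif")
        if self.ramp_h > self.stay_clip[0]:
            raise ValueError("preshock ramp longer than the shortest stay")
        for ch in self.planted_bins:
            if ch in _CRITERION_CHANNELS:
                raise ValueError(
                    f"cannot plant bin odds on criterion channel {ch!r}")
        return self


def plant_bin_risk(spec: CohortSpec, feature: str, planted: PlantedBins) -> CohortSpec:
    """Return a spec whose ``feature`` follows planted per-bin shock odds."""
    spec.validate()
    new = dict(spec.planted_bins)
    new[feature] = planted
    return replace(spec, planted_bins=new).validate()


def _channel_values(
    rng: np.random.Generator,
    name: str,
    n_h: int,
    frac: np.ndarray,
    lactate_cap: Optional[float] = None,
) -> np.ndarray:
    base, sd, lo, hi, t_mean, t_sd, t_lo, t_hi = _CH[name]
    if t_mean is None:
        frac = np.zeros(n_h)
        t_mean, t_sd, t_lo, t_hi = base, sd, lo, hi
    mean = base + frac * (t_mean - base)
    sd_arr = sd + frac * (t_sd - sd)
    lo_arr = lo + frac * (t_lo - lo)
    hi_arr = hi + frac * (t_hi - hi)
    vals = rng.normal(mean, np.maximum(sd_arr, 0.0))
    vals = np.clip(vals, np.minimum(lo_arr, hi_arr), np.maximum(lo_arr, hi_arr))
    if name == "lactate" and lactate_cap is not None:
        vals = np.minimum(vals, lactate_cap)
    return vals


def _panel_times(rng: np.random.Generator, n_h: int,
                 interval: tuple[float, float], start_hi: float) -> np.ndarray:
    times = []
    t = rng.uniform(0.5, start_hi)
    while t < n_h:
        times.append(t)
        t += rng.uniform(*interval)
    return np.asarray(times)


def generate_cohort(spec: CohortSpec, seed: int) -> CohortBundle:
    """Simulate a cohort; deterministic for a given spec and seed.

    Time columns in the returned bundle are float hours from ICU admission;
    :func:`to_timestamps` converts to the ISO-8601 CSV contract.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    meas_rows: list[pd.DataFrame] = []
    med_rows: list[tuple] = []
    fluid_rows: list[tuple] = []
    culture_rows: list[tuple] = []
    patient_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        stay = float(np.clip(rng.lognormal(*spec.stay_lognorm), *spec.stay_clip))
        n_h = int(math.floor(stay))
        weight = round(float(rng.lognormal(*spec.weight_lognorm)), 1)
        shock = bool(rng.random() < spec.shock_prevalence)

        if shock:
            T = int(rng.integers(26, n_h - 8 + 1))
            t_susp, t_sep = float(T - 24), float(T - 18)
            motif = "shock"
            severity = float(rng.uniform(0.15, 1.0))
            t_motif = T
        else:
            motif = NS_MOTIFS[int(rng.choice(3, p=spec.ns_motif_probs))]
            severity = float(rng.beta(1.5, 3.5) * 0.8)
            if motif == "quiet":
                t_susp = float(rng.integers(2, n_h - 10))
                t_motif = None
            else:
                t_susp = float(rng.integers(2, n_h - 20))
                lo_m = int(t_susp) + 10
                t_motif = int(rng.integers(lo_m, n_h - 8 + 1))
            t_sep = t_susp + 6.0
            T = None

        hours = np.arange(n_h)
        # severity-scaled drift profile
        frac = np.zeros(n_h)
        if shock:
            ramp_lo = T - spec.ramp_h
            in_ramp = (hours >= ramp_lo) & (hours < T)
            frac[in_ramp] = (hours[in_ramp] - ramp_lo + 1) / spec.ramp_h
            post = hours >= T
            frac[post] = np.maximum(0.0, 1.0 - (hours[post] - T) / 12.0)
            frac *= severity
        else:
            frac[hours >= t_sep] = 0.55
            frac[hours < t_sep] = 0.15
            if t_motif is not None:
                near = (hours >= t_motif - 6) & (hours <= t_motif + 4)
                frac[near] = 0.8
            frac *= severity

        lactate_cap = 1.9 if motif == "low_lactate" else None
        values: dict[str, np.ndarray] = {}
        for ch in MODEL_FEATURES + SUPPORT_CHANNELS:
            if ch in spec.planted_bins:
                pb = spec.planted_bins[ch]
                p_ns, p_s = pb.class_probs()
                b = int(rng.choice(pb.k, p=p_s if shock else p_ns))
                blo, bhi = pb.bounds()[b]
                values[ch] = np.full(n_h, rng.uniform(blo, bhi))
                continue
            values[ch] = _channel_values(rng, ch, n_h, frac, lactate_cap)

        # creatinine step: lifts SOFA by exactly the renal subscore (+2)
        if "creatinine" not in spec.planted_bins:
            m, s, lo_c, hi_c = _SEPTIC_CREATININE
            sep_h = hours >= t_sep
            values["creatinine"][sep_h] = np.clip(
                rng.normal(m, s, sep_h.sum()), lo_c, hi_c)
        # scripted shock motif on the criterion channels
        if motif in ("shock", "no_fluids", "low_lactate"):
            tm = t_motif
            hyp = (hours >= tm - 2) & (hours <= tm + 3)
            m, s, lo_c, hi_c = _HYPOTENSION
            values["mbp"][hyp] = np.clip(rng.normal(m, s, hyp.sum()), lo_c, hi_c)
            if motif != "low_lactate":
                hot = (hours >= tm) & (hours <= tm + 3)
                values["lactate"][hot] = np.clip(
                    rng.normal(2.9 + 0.6 * severity, 0.2, hot.sum()), 2.4, 4.8)

        # --- measurement emission ---
        p_meas: dict[str, list[np.ndarray]] = {"time": [], "channel": [], "value": []}

        def emit(ch: str, times: np.ndarray) -> None:
            if times.size == 0:
                return
            h_idx = np.floor(times).astype(int)
            vals = values[ch][h_idx]
            if ch not in _EXACT_HOURLY and ch not in spec.planted_bins:
                sd = _CH[ch][1]
                vals = vals + rng.normal(0.0, 0.3 * sd, vals.shape)
            p_meas["time"].append(times)
            p_meas["channel"].append(np.full(times.shape, ch, dtype=object))
            p_meas["value"].append(vals)

        minutes = rng.uniform(1.0 / 60, 59.0 / 60, size=(len(VS_FEATURES), n_h))
        for j, ch in enumerate(VS_FEATURES):
            if ch == "mbp":
                keep = np.ones(n_h, dtype=bool)   # continuous monitor
            else:
                keep = rng.random(n_h) >= spec.vitals_dropout
            emit(ch, (hours + minutes[j])[keep])

        abg_t = _panel_times(rng, n_h, spec.abg_interval_h, 4.0)
        for ch in ABG_FEATURES + ["pao2_fio2"]:
            t = abg_t
            if ch == "lactate" and motif == "shock":
                # the motif's first post-resuscitation lactate is the one at T
                h_idx = np.floor(t).astype(int)
                t = t[(h_idx < T - 2) | (h_idx >= T)]
                t = np.append(t, T + 2.0 / 60)
            if ch == "lactate" and motif == "low_lactate":
                t = np.append(t, t_motif + 2.0 / 60)
            emit(ch, np.sort(t))

        lab_t = _panel_times(rng, n_h, spec.lab_interval_h, 6.0)
        for ch in ("platelets", "bilirubin", "creatinine"):
            t = lab_t
            if ch == "creatinine":
                t = np.sort(np.append(t, [0.5, t_sep + 5.0 / 60]))
            emit(ch, t)
        emit("gcs", np.arange(0.25, n_h, 4.0))

        meas_rows.append(pd.DataFrame({
            "patient_id": pid,
            "time": np.concatenate(p_meas["time"]),
            "channel": np.concatenate(p_meas["channel"]),
            "value": np.concatenate(p_meas["value"]),
        }))

        # infection events: a single qualifying antibiotic/culture pair
        med_rows.append((pid, t_susp, "antibiotic"))
        culture_rows.append((pid, t_susp + 2.0))
        if motif in ("shock", "no_fluids", "low_lactate"):
            tm = t_motif
            for h in range(tm - 1, min(tm + 4, n_h)):
                med_rows.append((pid, h + 0.1, "vasopressor"))
            if motif == "no_fluids":
                fluid_rows.append((pid, tm - 4.5, tm - 3.5, 300.0))
            else:
                vol = max(30.0 * weight, 1000.0) * rng.uniform(1.1, 1.5)
                fluid_rows.append((pid, tm - 4.9, tm - 2.1, round(vol, 1)))
        # maintenance fluids, too small to satisfy the resuscitation rule;
        # kept clear of the motif window so they never top up the scripted
        # resuscitation volume
        for _ in range(int(rng.integers(1, 4))):
            st = float(rng.uniform(0, n_h - 2))
            if t_motif is not None:
                for _retry in range(8):
                    if not (t_motif - 7 <= st <= t_motif + 1):
                        break
                    st = float(rng.uniform(0, n_h - 2))
                else:
                    continue
            fluid_rows.append((pid, st, st + 1.0, round(float(rng.uniform(100, 450)), 1)))

        death = np.nan
        if shock and rng.random() < 0.2:
            death = float(min(stay, T + rng.uniform(24, 96)))
        elif not shock and rng.random() < 0.05:
            death = float(stay * rng.uniform(0.5, 1.0))
        patient_rows.append((pid, weight, 0.0, stay, death))
        truth_rows.append((pid, int(shock), t_susp, t_sep,
                           float(T) if shock else np.nan, severity, motif))

    bundle = CohortBundle(
        measurements=pd.concat(meas_rows, ignore_index=True),
        medications=pd.DataFrame(med_rows,
                                 columns=["patient_id", "time", "drug_class"]),
        fluids=pd.DataFrame(fluid_rows,
                            columns=["patient_id", "start", "end", "volume_ml"]),
        cultures=pd.DataFrame(culture_rows, columns=["patient_id", "time"]),
        patients=pd.DataFrame(
            patient_rows,
            columns=["patient_id", "weight_kg", "icu_in", "icu_out", "death_time"]),
        truth=pd.DataFrame(
            truth_rows,
            columns=["patient_id", "shock_flag", "t_suspicion", "t_sepsis",
                     "t_septic_shock", "severity", "motif"]),
    )
    pats = bundle.patients
    pats["stay_h"] = pats["icu_out"] - pats["icu_in"]
    return bundle


def to_timestamps(bundle: CohortBundle,
                  t0: str = "2019-01-01 08:00") -> CohortBundle:
    """Convert a float-hours bundle to the ISO-8601 timestamp contract.

    Admissions are staggered one day apart; event times are rounded to whole
    minutes, which round-trips exactly through CSV.
    """
    base = pd.Timestamp(t0)
    pats = bundle.patients.copy()
    order = {pid: k for k, pid in enumerate(pats["patient_id"])}
    admit = {pid: base + pd.Timedelta(days=k) for pid, k in order.items()}

    def conv(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        df = df.copy()
        for c in cols:
            minutes = (df[c].astype(float) * 60).round()
            df[c] = df["patient_id"].map(admit) + pd.to_timedelta(minutes, unit="m")
        return df

    out_pats = conv(pats.drop(columns=["stay_h"], errors="ignore"),
                    ["icu_out", "death_time"])
    out_pats["icu_in"] = out_pats["patient_id"].map(admit)
    return CohortBundle(
        measurements=conv(bundle.measurements, ["time"]),
        medications=conv(bundle.medications, ["time"]),
        fluids=conv(bundle.fluids, ["start", "end"]),
        cultures=conv(bundle.cultures, ["time"]),
        patients=out_pats,
        truth=bundle.truth,
    )


def sample_bin_risk(
    features: dict[str, PlantedBins],
    n: int,
    prevalence: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw tabular look-back samples with planted per-bin shock odds.

    Features are class-conditionally independent; returns the feature frame,
    labels, and each sample's true (Bayes) log-odds of shock, whose ranking
    is the best achievable discriminator for this generative model.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < prevalence).astype(int)
    cols: dict[str, np.ndarray] = {}
    log_odds = np.full(n, math.log(prevalence / (1 - prevalence)))
    for name, pb in features.items():
        p_ns, p_s = pb.class_probs()
        bins = np.where(
            y == 1,
            rng.choice(pb.k, size=n, p=p_s),
            rng.choice(pb.k, size=n, p=p_ns),
        )
        bounds = np.asarray(pb.bounds())
        lo, hi = bounds[bins, 0], bounds[bins, 1]
        cols[name] = rng.uniform(lo, hi)
        with np.errstate(divide="ignore"):
            log_odds = log_odds + np.log(p_s[bins] / p_ns[bins])
    return pd.DataFrame(cols), y, log_odds
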