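"""Run configuration: feature list, windows, binning and scoring parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .simulate import MODEL_FEATURES


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs besides the input tables."""

    features: list[str] = field(default_factory=lambda: list(MODEL_FEATURES))
    lookback_h: int = 6
    horizon_h: int = 6
    sampling: str = "onset_anchored"
    n_init: int = 10
    k_min: int = 2
    k_max: int = 10
    tau: float = 0.05
    missing_bin_frac: float = 0.01
    p0: float = 60.0
    pdo: float = 20.0
    cutoffs: tuple[float, float, float] = (40.0, 60.0, 80.0)
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    escalation_within_h: int = 3

    def validate(self) -> "RunConfig":
        if self.lookback_h <= 0 or self.horizon_h <= 0:
            raise ValueError("window lengths must be positive")
        cuts = list(self.cutoffs)
        if cuts != sorted(cuts) or len(set(cuts)) != len(cuts):
            raise ValueError(f"cutoffs must be strictly increasing, got {cuts}")
        if not all(0 < c < 100 for c in cuts):
            raise ValueError("cutoffs must lie inside (0, 100)")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(s <= 0 for s in self.split):
            raise ValueError("split fractions must be positive and sum to 1")
        if not self.features:
            raise ValueError("feature list must be non-empty")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("cutoffs", "split"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        d["split"] = list(self.split)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
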