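"""Run configuration: every analysis threshold, defaulted to the trial values.

Defaults are the operational stroke-imaging thresholds (Tmax > 6 s,
ADC < 620e-6 mm^2/s, DEFUSE-3 core < 70 mL / ratio >= 1.8 / mismatch >=
15 mL, DAWN cutoffs 21/31/51 mL); everything is overridable so sensitivity
analyses need no code edits.  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    tmax_threshold_s: float = 6.0
    adc_threshold: float = 620e-6
    svd_threshold_frac: float = 0.1
    vessel_percentile: float = 0.99
    dawn_cutoffs_ml: tuple[float, float, float] = (21.0, 31.0, 51.0)
    defuse3_core_max_ml: float = 70.0
    defuse3_ratio_min: float = 1.8
    defuse3_mismatch_min_ml: float = 15.0
    aif_n: int = 10
    bolus_k_sd: float = 2.0
    baseline_frames: int = 8
    seed: int = 0
    platforms: tuple[str, str] = ("rapid", "jlk")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tmax_threshold_s <= 0:
            raise ValueError(f"tmax_threshold_s must be > 0, got {self.tmax_threshold_s}")
        if not 1e-4 <= self.adc_threshold <= 4e-3:
            raise ValueError(
                f"adc_threshold must be within [1e-4, 4e-3] mm^2/s, got {self.adc_threshold}"
            )
        if not 0 < self.svd_threshold_frac < 0.5:
            raise ValueError(f"svd_threshold_frac must be in (0, 0.5), got {self.svd_threshold_frac}")
        if not 0 < self.vessel_percentile < 1:
            raise ValueError(f"vessel_percentile must be in (0, 1), got {self.vessel_percentile}")
        cuts = tuple(self.dawn_cutoffs_ml)
        if len(cuts) != 3 or any(c <= 0 for c in cuts) or list(cuts) != sorted(cuts):
            raise ValueError(f"dawn_cutoffs_ml must be three increasing positive values, got {cuts}")
        self.dawn_cutoffs_ml = cuts
        if self.defuse3_core_max_ml <= 0 or self.defuse3_ratio_min <= 0:
            raise ValueError("DEFUSE-3 thresholds must be positive")
        if self.defuse3_mismatch_min_ml < 0:
            raise ValueError("defuse3_mismatch_min_ml must be >= 0")
        if self.aif_n < 1:
            raise ValueError(f"aif_n must be >= 1, got {self.aif_n}")
        if self.baseline_frames < 3:
            raise ValueError(f"baseline_frames must be >= 3, got {self.baseline_frames}")
        self.platforms = tuple(self.platforms)

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        if unknown := set(overrides) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def as_dict(self) -> dict:
        out = asdict(self)
        out["dawn_cutoffs_ml"] = list(self.dawn_cutoffs_ml)
        out["platforms"] = list(self.platforms)
        return out
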