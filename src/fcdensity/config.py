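"""Study configuration: every tunable parameter of the pipeline in one place.

Defaults are the analysis conditions the pipeline reproduces: drop 10
volumes, 0.01-0.1 Hz band, motion limits 1.5 mm / 1.5 deg, correlation
threshold r = 0.3, 6 mm local sphere, 6 mm FWHM smoothing, voxel p < .01
with cluster p < .05 Monte-Carlo extent correction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fcd import FcdParams
from .group_stats import CorrectionParams

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    manifest: str = ""
    mask_dir: str = ""
    out_dir: str = ""
    tr_s: float = 2.0
    n_drop: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    trans_limit_mm: float = 1.5
    rot_limit_deg: float = 1.5
    fcd: FcdParams = field(default_factory=FcdParams)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    ci_method: str = "delong"
    n_boot: int = 2000
    seed: int = 0
    group_labels: tuple[str, str] = ("A", "B")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_labels"] = list(self.group_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "fcd" in d and isinstance(d["fcd"], dict):
            d["fcd"] = FcdParams(**d["fcd"])
        if "correction" in d and isinstance(d["correction"], dict):
            d["correction"] = CorrectionParams(**d["correction"])
        if "group_labels" in d:
            d["group_labels"] = tuple(d["group_labels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
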