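"""Pipeline configuration: a strict, schema-checked YAML/JSON config."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .histogram import DEFAULT_BIN_WIDTH
from .phantom import DEFAULT_LEVELS

__all__ = ["PipelineConfig", "load_config"]

_SEQUENCES = {"ffov": "fFOV", "rfov": "rFOV"}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run (and exactly reproduce) one study."""

    sequences: tuple[str, ...] = ("fFOV",)
    seed: int = 0
    output_dir: str = "results"
    matrix: int | None = None
    n_slices: int | None = None
    pixel_mm: float | None = None
    noise_sigma: float = 4.0
    n_repeats: int = 5
    sessions: tuple[tuple[str, float], ...] = (("S1", 21.0), ("S2", 22.0))
    levels: tuple[tuple[str, float], ...] = DEFAULT_LEVELS
    voi_diameter_fraction: float = 0.8
    voi_n_slices: int = 3
    bin_width: float = DEFAULT_BIN_WIDTH
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        seqs = []
        for s in self.sequences:
            key = str(s).lower()
            if key == "both":
                seqs.extend(["fFOV", "rFOV"])
                continue
            if key not in _SEQUENCES:
                raise ValueError(f"unknown sequence {s!r}")
            seqs.append(_SEQUENCES[key])
        object.__setattr__(self, "sequences", tuple(dict.fromkeys(seqs)))
        object.__setattr__(
            self, "sessions", tuple((str(i), float(t)) for i, t in self.sessions)
        )
        object.__setattr__(
            self, "levels", tuple((str(n), float(v)) for n, v in self.levels)
        )
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if not (0 < self.voi_diameter_fraction < 1):
            raise ValueError("voi_diameter_fraction must be in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(raw)
        for key in ("sessions", "levels"):
            if key in data:
                data[key] = tuple(tuple(item) for item in data[key])
        if "sequences" in data:
            if isinstance(data["sequences"], str):
                data["sequences"] = (data["sequences"],)
            else:
                data["sequences"] = tuple(data["sequences"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sequences"] = list(self.sequences)
        d["sessions"] = [list(s) for s in self.sessions]
        d["levels"] = [list(l) for l in self.levels]
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON, which YAML subsumes) config file, strictly."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    return PipelineConfig.from_dict(raw)
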