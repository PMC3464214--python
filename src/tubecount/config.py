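"""Run configuration: defaults, TOML round-trip, CLI overrides."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .enhance import EnhanceConfig
from .segment import SegmentConfig


@dataclass(frozen=True)
class TubesConfig:
    merge_eps: float = 10.0
    snap_radius: int = 10

    def validate(self) -> None:
        if self.merge_eps < 0 or self.snap_radius < 0:
            raise ValueError("merge_eps and snap_radius must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a quantification run."""

    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    tubes: TubesConfig = field(default_factory=TubesConfig)
    pixel_size: float | None = None  # µm per pixel; None = report pixels

    def validate(self) -> None:
        self.enhance.validate()
        self.segment.validate()
        self.tubes.validate()
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def to_toml(cfg: RunConfig) -> str:
    """Serialise a RunConfig to TOML (lossless round-trip with from_toml)."""
    lines = []
    if cfg.pixel_size is not None:
        lines.append(f"pixel_size = {_toml_value(cfg.pixel_size)}")
    for section in ("enhance", "segment", "tubes"):
        sub = getattr(cfg, section)
        lines.append(f"\n[{section}]")
        for f in dataclasses.fields(sub):
            lines.append(f"{f.name} = {_toml_value(getattr(sub, f.name))}")
    return "\n".join(lines).lstrip() + "\n"


def from_toml(text: str) -> RunConfig:
    """Parse a RunConfig from TOML text; unknown keys raise."""
    doc = tomllib.loads(text)
    kwargs = {}
    sections = {"enhance": EnhanceConfig, "segment": SegmentConfig, "tubes": TubesConfig}
    for key, value in doc.items():
        if key == "pixel_size":
            kwargs["pixel_size"] = float(value)
        elif key in sections:
            cls = sections[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
            if "windows" in value:
                value = {**value, "windows": tuple(value["windows"])}
            kwargs[key] = cls(**value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a TOML file, or the defaults when path is None."""
    if path is None:
        return RunConfig()
    return from_toml(Path(path).read_text())
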