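"""Pipeline configuration: the study constants in one overridable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic study.

    Defaults carry the study constants: 50 pseudo-absences per presence, fence
    barrier resistance 100, top-10% corridor threshold, corridor widths of
    0.5/1/2/3 km, US$75 per acre removal compensation, 3-h fixes with an
    11 km (SD 9 km) step-length distribution, and 4-h validation fixes.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (70, 70)
    cell_size: float = 200.0
    n_corridors: int = 3

    # habitat model
    pseudo_ratio: int = 50
    n_animals: int = 6
    n_steps: int = 150
    step_mean_km: float = 11.0
    step_sd_km: float = 9.0
    fix_interval_h: float = 3.0
    validation_fix_interval_h: float = 4.0
    validation_step_mean_km: float = 17.3
    validation_step_sd_km: float = 8.8

    # resistance / circuit
    r_min: float = 1.0
    r_max: float = 100.0
    barrier_value: float = 100.0
    resistance_mode: str = "linear"
    top_fraction: float = 0.10

    # restoration
    widths_km: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    unit_cost_per_acre: float = 75.0

    focal_names: tuple[str, ...] = ("west", "east")
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["widths_km"] = list(self.widths_km)
        d["focal_names"] = list(self.focal_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid_shape", "widths_km", "focal_names"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f for f in cls.__dataclass_fields__}
        extra = {k: v for k, v in d.items() if k not in known}
        kwargs = {k: v for k, v in d.items() if k in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
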