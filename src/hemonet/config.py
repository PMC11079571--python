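"""Pipeline configuration: one strict, YAML-loadable object covering every
stage (generation, preparation, training, post-processing).

All defaults resolve without any external file; unknown keys are rejected so
that typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .models2d import Ann2DConfig
from .models3d import MERGER_LR_SCHEDULE, UnetConfig
from .post import CFL_THRESHOLD, PLASMA_VISCOSITY
from .synthetic import SyntheticConfig

FORMAT_VERSION = 1


@dataclass
class PrepConfig:
    n: int = 56                      # profile collocation points
    ng: int = 32                     # field grid size
    augment_count: int = 0           # rotation augments per 3D component
    delta_beta_range: tuple[float, float] = (-45.0, 45.0)
    smoothing_lambda: float | None = None   # None -> GCV


@dataclass
class PostConfig:
    plasma_viscosity: float = PLASMA_VISCOSITY
    cfl_threshold: float = CFL_THRESHOLD
    filter_window: int = 5
    n_angles: int = 64


@dataclass
class PipelineConfig:
    format_version: int = FORMAT_VERSION
    seed: int = 0
    n_generations: int = 4
    generator: SyntheticConfig = field(default_factory=SyntheticConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    model2d: dict = field(default_factory=dict)   # per-kind Ann2DConfig kwargs
    model3d: dict = field(default_factory=dict)   # per-kind UnetConfig kwargs
    post: PostConfig = field(default_factory=PostConfig)

    def ann_config(self, kind: str) -> Ann2DConfig:
        return Ann2DConfig(component_kind=kind, n=self.prep.n,
                           **self.model2d.get(kind, {}))

    def unet_config(self, kind: str) -> UnetConfig:
        kwargs = dict(self.model3d.get(kind, {}))
        if kind == "merger":
            kwargs.setdefault("lr_schedule", MERGER_LR_SCHEDULE)
        return UnetConfig(component_kind=kind, ng=self.prep.ng, **kwargs)

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_cls, d, where):
            fields = {f.name: f for f in dataclasses.fields(dc_cls)}
            unknown = set(d) - set(fields)
            if unknown:
                raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
            clean = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()}
            return dc_cls(**clean)

        data = dict(data)
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
        if data.get("format_version", FORMAT_VERSION) != FORMAT_VERSION:
            raise ValueError("unsupported config format version")
        kwargs = {}
        for key, val in data.items():
            if key == "generator":
                kwargs[key] = build(SyntheticConfig, val, "generator")
            elif key == "prep":
                kwargs[key] = build(PrepConfig, val, "prep")
            elif key == "post":
                kwargs[key] = build(PostConfig, val, "post")
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
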