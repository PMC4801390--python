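"""Run configuration: one named parameter group per pipeline stage, plus the
single RNG seed every stochastic operation derives from.  Serializes to YAML
and round-trips exactly.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .capture import CaptureModel
from .popsim import PopulationModel
from .variants import FilterConfig


@dataclass
class DigestParams:
    size_min: int = 130
    size_max: int = 190
    enzyme_a: str = "SbfI"
    enzyme_b: str = "MseI"


@dataclass
class SimulateParams:
    genome_length: int = 200_000
    gc: float = 0.42
    population: PopulationModel = field(default_factory=PopulationModel)
    coverage: float = 20.0
    read_len: int = 150
    seq_error: float = 0.001
    museum_fraction: float = 0.5
    contaminant_fraction: float = 0.0


@dataclass
class CatalogParams:
    method: str = "rad_ref"
    t_within: float = 0.91
    t_among: float = 0.71
    extension_cycles: int = 30
    extension_min_overlap: int = 30
    extension_trim_bp: int = 60
    assembly_k: int = 31
    assembly_min_kmer_cov: int = 2


@dataclass
class AlignParams:
    k: int = 15
    score_margin: int = 4


@dataclass
class VariantParams:
    min_base_q: int = 13
    damage_window: int = 12
    rescale: bool = True
    filters: FilterConfig = field(default_factory=FilterConfig)


@dataclass
class RunConfig:
    rng_seed: int = 0
    digest: DigestParams = field(default_factory=DigestParams)
    simulate: SimulateParams = field(default_factory=SimulateParams)
    capture: CaptureModel = field(default_factory=CaptureModel)
    catalog: CatalogParams = field(default_factory=CatalogParams)
    align: AlignParams = field(default_factory=AlignParams)
    variants: VariantParams = field(default_factory=VariantParams)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())


def _build(cls, data: dict):
    kwargs = {}
    valid = {f.name: f for f in fields(cls)}
    for key, value in data.items():
        if key not in valid:
            raise KeyError(f"unknown config key {key!r} for {cls.__name__}")
        ftype = valid[key].type
        target = _dataclass_for(cls, key)
        if target is not None and isinstance(value, dict):
            kwargs[key] = _build(target, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _dataclass_for(cls, key: str):
    default = cls.__dataclass_fields__[key].default_factory
    if default is not None and default is not type(None):
        try:
            instance = default()  # type: ignore[misc]
        except TypeError:
            return None
        if is_dataclass(instance):
            return type(instance)
    return None
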