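"""Pipeline configuration: nested key-value (YAML) files with strict
key checking and a mandatory seed.

Defaults follow the processing settings of the targeted linked-read
protocol: adapter-trim minimum overlap 5, allele-fraction cutoff 0.1,
phasing link distance 40 kb, and the depth-titration fraction ladder
{0.5, 0.25, 0.125, 0.0625, 0.03125, 0.0156, 0.0078}.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError
from .phasing import PhasingParams
from .simulate import DEFAULT_READ_LENGTH, SampleComposition


@dataclass(frozen=True)
class LocusSpec:
    locus_id: str
    length_bp: int
    mean_het_spacing_bp: float = 1500.0


@dataclass(frozen=True)
class SimulationParams:
    loci: tuple[LocusSpec, ...] = (LocusSpec("target", 13_000),)
    composition: SampleComposition = field(default_factory=SampleComposition)
    n_beads: int = 10_000
    bead_subsample_fraction: float = 1.0
    reads_per_kb: float = 2.0
    read_len: int = DEFAULT_READ_LENGTH
    sub_error_rate: float = 0.001
    barcode_error_rate: float = 0.005
    pcr_dup_rate: float = 0.05
    count_scale: float = 1.0


@dataclass(frozen=True)
class ProcessingParams:
    min_overlap: int = 5
    seed_k: int = 21
    af_cutoff: float = 0.1
    min_depth: int = 10
    phasing: PhasingParams = field(default_factory=PhasingParams)


@dataclass(frozen=True)
class EvaluationParams:
    fraction_ladder: tuple[float, ...] = (
        0.5, 0.25, 0.125, 0.0625, 0.03125, 0.0156, 0.0078)
    mostly_unphased_threshold: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    """All parameters of one simulated or real run; the single ``seed``
    drives every source of randomness."""

    seed: int
    simulation: SimulationParams = field(default_factory=SimulationParams)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        if "seed" not in data:
            raise ConfigError("missing required key: seed")
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_NESTED = {
    "simulation": SimulationParams,
    "processing": ProcessingParams,
    "evaluation": EvaluationParams,
    "composition": SampleComposition,
    "phasing": PhasingParams,
}


def _build(cls, data: dict[str, Any], path: str):
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in field_types:
            raise ConfigError(f"unknown config key: {where}")
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, where)
        elif key == "loci":
            if not isinstance(value, list):
                raise ConfigError(f"{where} must be a list")
            kwargs[key] = tuple(
                _build(LocusSpec, entry, f"{where}[{i}]")
                for i, entry in enumerate(value))
        elif key == "fraction_ladder" or key == "filling_lengths" \
                or key == "background_fragment_bp":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc
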