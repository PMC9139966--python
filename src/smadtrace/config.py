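"""Run configuration: a strict, JSON-serializable view of every pipeline knob.

Unknown keys are rejected with the offending dotted path, and a round trip
through ``to_dict``/``from_dict`` is lossless.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .kinetics import PRESETS, ReporterParams
from .synth import ImagingParams, PopulationParams
from .tracking import LinkPriors


@dataclass(frozen=True)
class TrackingConfig:
    """Detection and linking parameters."""

    pos_sd: float = 2.0
    logshape_sd: float = 0.08
    logint_sd: float = 0.1
    gate: float = 9.0
    min_amplitude: float = 50.0
    min_separation: float = 5.0
    init_sigma: float = 3.0
    max_gap: int = 4
    min_completeness: float = 0.8
    match_radius: float = 5.0

    def priors(self) -> LinkPriors:
        return LinkPriors(self.pos_sd, self.logshape_sd, self.logint_sd, self.gate)


@dataclass(frozen=True)
class AnalysisConfig:
    """Trace clustering and classification parameters."""

    k: int = 3
    linkage: str = "average"
    onset_threshold: float = 0.5
    sustain: int = 2
    noise_floor: float | None = None
    cluster_on_raw: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; ``seed`` feeds every random substream."""

    population: PopulationParams = field(default_factory=PopulationParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    reporter_presets: dict = field(default_factory=lambda: {k: v.to_dict() for k, v in PRESETS.items()})
    reporter: str = "dynGFP"
    seed: int = 7
    output_dir: str = "runs/out"

    def preset(self, name: str | None = None) -> ReporterParams:
        return ReporterParams.from_dict(self.reporter_presets[name or self.reporter])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build_dataclass(cls, d, path="")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _build_dataclass(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ValueError(f"config{path or ' (root)'}: expected an object, got {type(d).__name__}")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(field_map)
    if unknown:
        where = path or "root"
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        f = field_map[name]
        sub = _DATACLASS_FIELDS.get((cls, name))
        if sub is not None and value is not None:
            kwargs[name] = _build_dataclass(sub, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    (RunConfig, "population"): PopulationParams,
    (RunConfig, "imaging"): ImagingParams,
    (RunConfig, "tracking"): TrackingConfig,
    (RunConfig, "analysis"): AnalysisConfig,
}
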