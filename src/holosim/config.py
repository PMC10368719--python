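"""Structured-text (YAML) experiment configuration with strict validation.

Unknown keys are rejected, every default is documented on its dataclass,
and a config round-trips losslessly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


import yaml

from .genome import ConfigError, MutationRates

__all__ = ["RunConfig", "GenomeSection", "RegulationSection", "EcologySection",
           "ExperimentSection", "AnalysisSection", "load_config", "save_config"]

CONFIG_VERSION = 1

DEFAULT_INFLUXES = [1, 2, 5, 10, 20, 30, 40, 50, 60, 80, 100]


def _check_unknown(section: str, data: dict, known: set[str]) -> None:
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")


def _section(cls, name: str, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    _check_unknown(name, data, {f.name for f in fields(cls)})
    return cls(**data)


@dataclass
class GenomeSection:
    """households: household genes per founder genome.
    wiring: 'primitive' (the shipped clock wiring) or a bead-table path."""

    households: int = 50
    wiring: str = "primitive"

    def __post_init__(self):
        if self.households < 0:
            raise ConfigError(f"genome.households={self.households} must be >= 0")


@dataclass
class RegulationSection:
    """half_saturation: K in the binding probability A/(A+K); <= 0 selects
    the deterministic limit (testing only).
    stage_table: 'default' or a stage-table TSV path."""

    half_saturation: float = 0.02
    stage_table: str = "default"


@dataclass
class EcologySection:
    """d: random death per cell per step; inheritance_p: symbiont
    inheritance probability at host division; h_min: combined household
    minimum (host + mean over symbionts); h_min_free: per-cell minimum in
    free-living mode; rows x cols grid with ``sector_influxes`` equal-width
    ascending sectors along the columns."""

    d: float = 0.001
    inheritance_p: float = 0.5
    h_min: float = 100.0
    h_min_free: float = 50.0
    rows: int = 25
    cols: int = 275
    sector_influxes: list = field(default_factory=lambda: list(DEFAULT_INFLUXES))
    household_at_division_only: bool = False

    def __post_init__(self):
        if not (0.0 <= self.d <= 1.0):
            raise ConfigError(f"ecology.d={self.d} not in [0, 1]")
        if not (0.0 <= self.inheritance_p <= 1.0):
            raise ConfigError(f"ecology.inheritance_p={self.inheritance_p} not in [0, 1]")
        if self.h_min < 0 or self.h_min_free < 0:
            raise ConfigError("ecology.h_min/h_min_free must be >= 0")
        if self.rows < 1 or self.cols < 1:
            raise ConfigError("ecology grid dimensions must be >= 1")
        if self.cols % len(self.sector_influxes):
            raise ConfigError(
                f"ecology.cols={self.cols} not divisible into {len(self.sector_influxes)} sectors")


@dataclass
class MutationSection:
    """Per-bead per-division rates; regime 'prokaryote_like' multiplies all
    rates by 10 (innovation capped at 1)."""

    regime: str = "default"
    dup: float | None = None
    delete: float | None = None
    weight_shift: float | None = None
    threshold_shift: float | None = None
    type_flip: float | None = None
    innovation: float | None = None

    def rates(self) -> MutationRates:
        base = MutationRates.for_regime(self.regime)
        overrides = {k: v for k in ("dup", "delete", "weight_shift", "threshold_shift",
                                    "type_flip", "innovation")
                     if (v := getattr(self, k)) is not None}
        if not overrides:
            return base
        kw = {k: getattr(base, k) for k in ("dup", "delete", "weight_shift",
                                            "threshold_shift", "type_flip", "innovation")}
        kw.update(overrides)
        return MutationRates(regime=base.regime, **kw)


@dataclass
class ExperimentSection:
    """mode: primitive_feca | complex_feca | free_living.
    duration: run length in AUT (published scale is 1e7; tests use far
    smaller values).  complex_feca requires host/symbiont genome paths."""

    mode: str = "primitive_feca"
    duration: int = 10_000_000
    seed: int = 0
    snapshot_every: int = 1000
    log_every: int = 1000
    lineage_prune_horizon: int | None = None
    host_genome: str | None = None
    symbiont_genome: str | None = None
    initial_symbionts: int = 2

    def __post_init__(self):
        if self.mode not in ("primitive_feca", "complex_feca", "free_living"):
            raise ConfigError(f"experiment.mode={self.mode!r} unknown")
        if self.duration < 1:
            raise ConfigError("experiment.duration must be >= 1")
        if self.snapshot_every < 1 or self.log_every < 1:
            raise ConfigError("experiment cadences must be >= 1")
        if self.mode == "complex_feca" and (not self.host_genome or not self.symbiont_genome):
            raise ConfigError("complex_feca requires experiment.host_genome and experiment.symbiont_genome")


@dataclass
class AnalysisSection:
    """conditions: fixed nutrient set for tracking/efficiency; delta:
    external death rate entering the growth formulas; track_duration:
    single-cell tracking window (AUT)."""

    conditions: list = field(default_factory=lambda: [100, 50, 20, 10, 5, 2, 1])
    delta: float = 0.001
    track_duration: int = 10_000

    def __post_init__(self):
        if self.delta < 0:
            raise ConfigError("analysis.delta must be >= 0")
        if self.track_duration < 1:
            raise ConfigError("analysis.track_duration must be >= 1")


@dataclass
class RunConfig:
    version: int = CONFIG_VERSION
    seed: int = 0
    genome: GenomeSection = field(default_factory=GenomeSection)
    regulation: RegulationSection = field(default_factory=RegulationSection)
    ecology: EcologySection = field(default_factory=EcologySection)
    mutation: MutationSection = field(default_factory=MutationSection)
    experiment: ExperimentSection = field(default_factory=ExperimentSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        data = dict(data or {})
        _check_unknown("<top level>", data,
                       {"version", "seed", "genome", "regulation", "ecology",
                        "mutation", "experiment", "analysis"})
        version = data.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {version}")
        seed = data.pop("seed", 0)
        return cls(
            version=version,
            seed=seed,
            genome=_section(GenomeSection, "genome", data.get("genome", {})),
            regulation=_section(RegulationSection, "regulation", data.get("regulation", {})),
            ecology=_section(EcologySection, "ecology", data.get("ecology", {})),
            mutation=_section(MutationSection, "mutation", data.get("mutation", {})),
            experiment=_section(ExperimentSection, "experiment", data.get("experiment", {})),
            analysis=_section(AnalysisSection, "analysis", data.get("analysis", {})),
        )


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
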