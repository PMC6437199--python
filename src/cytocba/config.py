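"""Pipeline configuration.

Every constant of the assay protocol is named here rather than inlined:
the 0.5% PE background rate, the 1.0 antibody-index cutoff and the
50-year onset-age boundary between early- and late-onset myasthenia gravis
are all overridable for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class GatingConfig:
    """Parameters of the event-level gating stages.

    central_mass
        fraction of the robust scatter ellipsoid retained by the live gate
    fsc_floor
        forward-scatter floor below which events are treated as debris
    aad_threshold
        7-AAD intensity above which an event is called dead; can be
        recalibrated from an unstained control via
        :func:`cytocba.gating.calibrate_aad_threshold`
    gfp_mode
        ``different`` places separate GFP cut-off lines on the two cell
        lines (the default protocol); ``same`` reuses the parental line
    gfp_tail_rate
        upper-tail rate defining the parental GFP-negative cut-off (0.001
        puts the line at the 99.9th percentile of the parental control)
    min_population
        minimum gated-population size for a stable PE fraction
    """

    central_mass: float = 0.90
    fsc_floor: float = 15_000.0
    aad_threshold: float = 1_000.0
    gfp_mode: str = "different"
    gfp_tail_rate: float = 0.001
    min_population: int = 100
    min_events: int = 50
    robust_iterations: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.central_mass < 1:
            raise ParameterError("central_mass must be in (0, 1)")
        if self.gfp_mode not in ("different", "same"):
            raise ParameterError(f"unknown gfp_mode {self.gfp_mode!r}")


@dataclass
class IndexConfig:
    """Antibody-index stage parameters.

    background_rate is the PE background tail in percent (0.5 means the
    calibrated threshold leaves at most 0.5% of control events above it);
    cutoff is the seropositivity boundary on the index (strictly greater
    than); denominator_floor guards the ratio when the parental PE
    fraction falls below background.
    """

    background_rate: float = 0.5
    cutoff: float = 1.0
    denominator_floor: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.background_rate <= 5:
            raise ParameterError("background_rate (percent) must be in (0, 5]")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")
        if self.denominator_floor <= 0:
            raise ParameterError("denominator_floor must be positive")


@dataclass
class CohortConfig:
    age_cutoff: float = 50.0  # onset-age boundary between EOMG and LOMG
    sd_ddof: int = 1          # sample (n-1) standard deviation


@dataclass
class PipelineConfig:
    gating: GatingConfig = field(default_factory=GatingConfig)
    index: IndexConfig = field(default_factory=IndexConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PipelineConfig":
        with resources.files("cytocba.data").joinpath("defaults.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return cls(
            gating=GatingConfig(**raw.get("gating", {})),
            index=IndexConfig(**raw.get("index", {})),
            cohort=CohortConfig(**raw.get("cohort", {})),
            simulation=raw.get("simulation", {}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
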