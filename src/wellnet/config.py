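"""Run configuration: every threshold and simulator knob in one JSON-serializable object."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .matching import V4_FWD_PRIMER, V4_REV_PRIMER

__all__ = ["SimulatorConfig", "Thresholds", "MatchingConfig", "AssayConfig", "RunConfig"]


class SimulatorConfig(BaseModel):
    """Study conditions for the synthetic cultivation array.

    Defaults give planted-species well occupancy in the informative 0.5-0.95
    band at dilution levels 4-5 (cells_per_ul * 10^-4 / n_species ~ 2.5
    founding cells per well), which is where endpoint-abundance coupling is
    expressed as strong rank correlation.
    """

    n_species: int = Field(default=40, ge=2)
    lognormal_mu: float = 0.0
    lognormal_sigma: float = Field(default=1.0, ge=0)
    cells_per_ul: float = Field(default=1e6, gt=0)
    read_depth: int = Field(default=10_000, ge=0)
    n_wells: int = Field(default=96, ge=1)
    sample_types: list[str] = Field(default_factory=lambda: ["roots"])
    media: list[str] = Field(default_factory=lambda: ["R2A", "TSB"])
    dilution_levels: list[int] = Field(default_factory=lambda: [3, 4, 5])
    replicates: list[str] = Field(default_factory=lambda: ["A", "B", "C"])
    n_planted_pairs: int = Field(default=3, ge=0)
    planted_effect: float = Field(default=2.5, ge=0)
    planted_sign: int = 1
    co_colonization: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SimulatorConfig":
        if self.planted_sign not in (1, -1):
            raise ValueError("planted_sign must be +1 or -1")
        if 2 * self.n_planted_pairs > self.n_species:
            raise ValueError("not enough species for the requested planted pairs")
        return self


class Thresholds(BaseModel):
    """Every cutoff of the inference chain, at its documented default."""

    min_reads: int = Field(default=100, ge=1)
    min_grow_frac: float = Field(default=0.30, ge=0, le=1)
    prevalence_min_frac: float = Field(default=0.30, ge=0, le=1)
    rho_min: float = Field(default=0.6, ge=0, le=1)
    q_max: float = Field(default=0.01, gt=0, le=1)
    max_degree: int = Field(default=5, ge=1)
    fo_min: float = Field(default=0.30, ge=0)
    k_top: int = Field(default=3, ge=1)
    relative_abundance: bool = True
    prevalence_denominator: str = "growing"


class MatchingConfig(BaseModel):
    fwd_primer: str = V4_FWD_PRIMER
    rev_primer: str = V4_REV_PRIMER
    max_mismatch: int = Field(default=1, ge=0)
    identity_threshold: float = Field(default=1.0, ge=0, le=1)
    distance_cap: float = Field(default=0.03, ge=0)
    n_isolates_per_zotu: int = Field(default=2, ge=1)
    n_unrelated_isolates: int = Field(default=2, ge=0)
    isolate_mutation_rate: float = Field(default=0.0, ge=0, le=1)


class AssayConfig(BaseModel):
    epsilon: float = Field(default=0.2, gt=0)
    windows: list[tuple[float, float]] | None = None
    noise_sd: float = Field(default=0.1, ge=0)


class RunConfig(BaseModel):
    seed: int = 0
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    matching: MatchingConfig = Field(default_factory=MatchingConfig)
    assay: AssayConfig = Field(default_factory=AssayConfig)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))
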