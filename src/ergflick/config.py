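"""Run configuration: a strict, round-trippable YAML schema.

Every stage of the pipeline reads its parameters from one `RunConfig`.
Defaults equal the published processing constants where those are stated
(11 ms median window, 5 SD rejection, 1.0 / 3.2 / 0.6 µV criteria,
10,000 permutations); unknown keys are rejected loudly so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    n_intensities: int = 15
    step_log10: float = 1.0 / 3.0
    start_rel_log10: float = -1.5
    frequency: float = 10.0
    duration: float = 21.0
    exp2_drop_endpoint: Literal["low", "high"] = "high"
    exp3_interval_s: float = 240.0
    exp3_total_min: float = 60.0
    exp3_test_intensity: float = 3.84e-4


class SimulatorConfig(_Strict):
    n_crabs: int = 8
    between_crab_sd_log_i0: float = 0.15
    between_crab_sd_slope: float = 0.4
    sex_amplitude_effect: float = 0.5
    fs: float = 5000.0


class PreprocessConfig(_Strict):
    enabled: bool = True
    window_ms: float = 11.0
    k_sd: float = 5.0
    iterative: bool = False


class SpectralConfig(_Strict):
    k_per_side: int = 20
    exclude_half_width: int = 2
    mains_freq: float = 50.0
    exclude_harmonics: bool = True
    alpha_level: float = 0.05
    method: Literal["ftest", "rank"] = "ftest"


class CriteriaConfig(_Strict):
    threshold_uv: float = 1.0
    normalise_uv: float = 3.2
    fff_uv: float = 0.6
    exclude_freqs: list[float] = Field(default_factory=lambda: [50.0])


class StatsConfig(_Strict):
    n_perm: int = 10_000
    seed: int = 0


class RunConfig(_Strict):
    """Umbrella configuration for an end-to-end pipeline run."""

    experiment: Literal["exp1", "exp2", "exp3"] = "exp1"
    seed: int = 0
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = Field(default_factory=SpectralConfig)
    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(raw)
        except Exception as e:  # pydantic ValidationError or yaml error
            raise ConfigError(f"invalid config {path}: {e}") from e

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)
        )

    def config_hash(self) -> str:
        """Stable hash of the full parameter set, recorded in every output."""
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]
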