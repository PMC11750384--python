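"""Configuration objects for simulation and pipeline runs.

The :class:`SimulationConfig` holds every ground-truth parameter of the
synthetic face-detection-task (FDT) generator: task design constants
(trial counts, block structure, viewing angles), the reaction-time (RT)
model (baseline, exponential learning rates toward a fixed asymptote,
typicality offset, participant heterogeneity, trial noise), signal
detection targets (hit and false-alarm probabilities), and the moments
of the four-test face-processing battery.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

#: Battery tests in canonical column order.
BATTERY_TESTS: Tuple[str, ...] = ("cfmt_plus", "ybt", "gfmt2_s", "jbfft")

#: Legal score range per test.  The first three are correct counts, the
#: last a proportion of known celebrities identified from the face.
BATTERY_RANGES = {
    "cfmt_plus": (0.0, 102.0),
    "ybt": (0.0, 35.0),
    "gfmt2_s": (0.0, 40.0),
    "jbfft": (0.0, 1.0),
}

#: Tests whose raw score is an integer item count.
BATTERY_INTEGER_TESTS = ("cfmt_plus", "ybt", "gfmt2_s")

_DEFAULT_BATTERY_CORR = (
    (1.00, 0.40, 0.30, 0.43),
    (0.40, 1.00, 0.35, 0.25),
    (0.30, 0.35, 1.00, 0.19),
    (0.43, 0.25, 0.19, 1.00),
)


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


class SimulationConfig(BaseModel):
    """Ground-truth parameters of the synthetic FDT + battery generator.

    Defaults emulate a realistic study: 52 participants, 576 trials
    each (480 upright-face go trials from 12 identities x 40
    occurrences, 48 inverted faces and 48 chairs as no-go trials) in 11
    blocks; near-ceiling hit rate with a high false-alarm rate; a small
    constant typicality RT offset; slow exponential learning toward a
    200 ms asymptote; battery score moments typical of young-adult
    samples on these tests.
    """

    model_config = {"frozen": True}

    # --- sample / design ------------------------------------------------
    n_participants: int = Field(default=52, gt=0)
    n_identities: int = Field(default=12, gt=0)
    n_occurrences: int = Field(default=40, gt=0)
    n_inverted: int = Field(default=48, ge=0)
    n_chairs: int = Field(default=48, ge=0)
    n_blocks: int = Field(default=11, gt=0)
    n_viewing_angles: int = Field(default=10, gt=0)

    # --- RT model (ms unless noted) ------------------------------------
    baseline_rt_mean: float = Field(default=355.0, gt=0)
    baseline_rt_between_sd: float = Field(default=30.0, ge=0)
    trial_noise_sd: float = Field(default=60.0, ge=0)
    typicality_offset: float = 3.0
    alpha_typical_mean: float = Field(default=0.0025, ge=0)
    alpha_distinctive_mean: float = Field(default=0.0025, ge=0)
    alpha_between_sd: float = Field(default=0.001, ge=0)
    rt_asymptote: float = Field(default=200.0, gt=0)
    response_deadline_ms: float = Field(default=1000.0, gt=0)
    gender_rt_offset: float = 15.0
    #: ms of extra typicality effect per unit of composite mean rank
    #: (centred); 0 reproduces the null of no ability coupling.
    ability_rt_coupling: float = 0.0

    # --- signal detection targets --------------------------------------
    hit_rate_target: float = Field(default=0.99, ge=0.0, le=1.0)
    fa_rate_target: float = Field(default=0.86, ge=0.0, le=1.0)

    # --- battery --------------------------------------------------------
    battery_means: Tuple[float, float, float, float] = (66.31, 9.59, 32.57, 0.85)
    battery_sds: Tuple[float, float, float, float] = (11.15, 3.24, 3.86, 0.14)
    battery_corr: Tuple[Tuple[float, ...], ...] = _DEFAULT_BATTERY_CORR
    battery_missing_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    seed: int = 0

    # --- validators -----------------------------------------------------
    @field_validator("battery_sds")
    @classmethod
    def _sds_nonneg(cls, v):
        if any(s < 0 for s in v):
            raise ValueError("battery_sds must be non-negative")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.rt_asymptote >= self.baseline_rt_mean:
            raise ValueError(
                "rt_asymptote must be smaller than baseline_rt_mean"
            )
        if self.n_identities % 2 != 0:
            raise ValueError(
                "n_identities must be even (half typical, half distinctive)"
            )
        if self.n_occurrences % self.n_viewing_angles != 0:
            raise ValueError(
                "n_occurrences must be a multiple of n_viewing_angles "
                "(each identity is shown equally often from each angle)"
            )
        corr = np.asarray(self.battery_corr, dtype=float)
        if corr.shape != (4, 4):
            raise ValueError("battery_corr must be a 4x4 matrix")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("battery_corr must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("battery_corr must be positive semi-definite")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("battery_corr must have unit diagonal")
        return self

    # --- helpers --------------------------------------------------------
    @property
    def n_go_trials(self) -> int:
        return self.n_identities * self.n_occurrences

    @property
    def n_trials(self) -> int:
        return self.n_go_trials + self.n_inverted + self.n_chairs

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class RunConfig(BaseModel):
    """End-to-end pipeline run configuration.

    Exactly one of ``simulation`` (generate data) or ``trials_path`` +
    ``battery_path`` (ingest existing delimited tables) must be given.
    """

    simulation: Optional[SimulationConfig] = None
    trials_path: Optional[str] = None
    battery_path: Optional[str] = None
    out_dir: str = "facespace_run"
    seed: Optional[int] = None

    # model options
    random_slope: bool = True
    occurrence_term: bool = True
    holm: bool = False
    stages: List[str] = Field(
        default_factory=lambda: [
            "simulate", "preprocess", "learning", "composite", "fit",
        ]
    )

    @model_validator(mode="after")
    def _one_source(self):
        sim = self.simulation is not None
        real = self.trials_path is not None or self.battery_path is not None
        if sim and real:
            raise ValueError(
                "supply either a simulation config or real-data paths, not both"
            )
        if not sim and not (self.trials_path and self.battery_path):
            raise ValueError(
                "supply a simulation config, or both trials_path and battery_path"
            )
        return self

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded,
        so identical analyses in different directories share a stamp)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
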