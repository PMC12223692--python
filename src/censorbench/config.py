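"""Configuration objects for simulation, filtering, model and training.

All configs are plain dataclasses that validate on construction (via
``validate()``) and round-trip through nested dictionaries / YAML files, so an
experiment is fully described by one structured text file plus a seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("A", "B", "C", "D", "E")
INSURANCE_LEVELS = ("public", "private", "other")

#: Default demographic marginals for the simulated population (roughly the
#: composition of a large paediatric health-system cohort: ~52% male, five
#: race groups, a public/private insurance split).
DEFAULT_SEX_FREQS = {"male": 0.519, "female": 0.481}
DEFAULT_RACE_FREQS = {"A": 0.042, "B": 0.302, "C": 0.429, "D": 0.089, "E": 0.138}
DEFAULT_INSURANCE_FREQS = {"public": 0.534, "private": 0.462, "other": 0.004}

#: Default per-year discrete hazards for a late-event condition (ADHD-like
#: timing, mean diagnosis age ~6.2 years over a 9-year horizon).
DEFAULT_BASELINE_HAZARDS = (
    0.005, 0.008, 0.012, 0.018, 0.028, 0.040, 0.055, 0.065, 0.075,
)


def _freqs_ok(freqs: dict, levels: Sequence[str]) -> bool:
    return set(freqs) == set(levels) and all(v >= 0 for v in freqs.values()) and (
        abs(sum(freqs.values()) - 1.0) < 1e-6
    )


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The generator produces one patient per row with demographic attributes, a
    timestamped medical-code sequence, a latent event time E drawn from a
    covariate-dependent discrete-time hazard model on yearly bins, and a
    censoring time C combining administrative censoring (a fixed extraction
    date relative to birth date) with optional exponential dropout.
    """

    n_patients: int = 1000
    birth_year_range: tuple[int, int] = (2014, 2022)
    extraction_year: float = 2023.42  # early-June extraction date
    dropout_rate: float = 0.05  # per-year hazard of loss to follow-up
    baseline_hazards: tuple[float, ...] = DEFAULT_BASELINE_HAZARDS
    covariate_effects: dict = field(default_factory=lambda: {"sex:male": 0.5})
    prevalence_trend: float = 0.02  # additive log-odds drift per birth year
    vocabulary_size: int = 200
    mean_codes_per_year: float = 12.0
    risk_code_fraction: float = 0.3
    risk_effect: float = 1.0  # log-odds of hazard per unit of latent risk z
    immune_fraction: float = 0.0  # explicit cure fraction for stress tests
    emit_attribute_codes: bool = False  # sex/race/insurance/era tokens at age 0
    sex_freqs: dict = field(default_factory=lambda: dict(DEFAULT_SEX_FREQS))
    race_freqs: dict = field(default_factory=lambda: dict(DEFAULT_RACE_FREQS))
    insurance_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_INSURANCE_FREQS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.birth_year_range = tuple(int(v) for v in self.birth_year_range)
        self.baseline_hazards = tuple(float(h) for h in self.baseline_hazards)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.birth_year_range
        if hi < lo:
            raise ValueError("birth_year_range is empty")
        h = np.asarray(self.baseline_hazards, dtype=float)
        if h.size == 0 or np.any(h < 0) or np.any(h >= 1):
            raise ValueError("baseline_hazards must be non-empty, in [0, 1)")
        if self.extraction_year <= hi + 1:
            raise ValueError(
                "extraction_year must exceed the last birth year + 1 so that "
                "administrative censoring times are positive"
            )
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")
        if not 0.0 < self.risk_code_fraction < 1.0:
            raise ValueError("risk_code_fraction must lie strictly in (0, 1)")
        if not 0.0 <= self.immune_fraction <= 1.0:
            raise ValueError("immune_fraction must lie in [0, 1]")
        if self.vocabulary_size < 2:
            raise ValueError("vocabulary_size must be >= 2")
        if self.mean_codes_per_year <= 0:
            raise ValueError("mean_codes_per_year must be positive")
        for freqs, levels, name in (
            (self.sex_freqs, SEX_LEVELS, "sex_freqs"),
            (self.race_freqs, RACE_LEVELS, "race_freqs"),
            (self.insurance_freqs, INSURANCE_LEVELS, "insurance_freqs"),
        ):
            if not _freqs_ok(freqs, levels):
                raise ValueError(f"{name} must cover {levels} and sum to 1")

    @property
    def horizon(self) -> float:
        """Last year covered by the hazard model (E_max of the generator)."""
        return float(len(self.baseline_hazards))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["birth_year_range"] = list(self.birth_year_range)
        d["baseline_hazards"] = list(self.baseline_hazards)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class FilterSpec:
    """A cohort-selection rule.

    ``prediction_age_cutoff`` removes patients diagnosed or censored at or
    before the prediction age.  ``yob_max`` keeps only earlier birth years.
    ``min_followup_years`` removes short-follow-up patients; by default only
    censored ones (observed early diagnoses are real labels and are kept),
    ``drop_early_events=True`` switches to removing every patient with
    T below the threshold.
    """

    prediction_age_cutoff: float = 0.25
    yob_max: Optional[int] = None
    min_followup_years: Optional[float] = None
    drop_early_events: bool = False

    def __post_init__(self) -> None:
        if self.prediction_age_cutoff <= 0:
            raise ValueError("prediction_age_cutoff must be positive")
        if self.min_followup_years is not None and self.min_followup_years < 0:
            raise ValueError("min_followup_years must be non-negative")


@dataclass
class EncoderConfig:
    """Shared sequence-encoder hyperparameters.

    The encoder maps a padded index sequence through a frozen embedding
    layer, a per-token fully connected layer with ReLU, global mean pooling
    over non-padding positions, and a second fully connected layer with ReLU.
    """

    embedding_dim: int = 256
    max_sequence_length: int = 512
    hidden_dim: int = 256
    train_embeddings: bool = False
    #: "nonpad": divide the pooled sum by the number of real tokens
    #: (all-padding sequences pool to the zero vector);
    #: "fixed": divide by max_sequence_length.
    pool_divisor: str = "nonpad"

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.max_sequence_length, self.hidden_dim) < 1:
            raise ValueError("encoder dimensions must be positive")
        if self.pool_divisor not in ("nonpad", "fixed"):
            raise ValueError("pool_divisor must be 'nonpad' or 'fixed'")


@dataclass
class TrainConfig:
    """Optimisation and grid-search settings.

    The hyperparameter grid covers learning rate and decoupled weight decay;
    each candidate trains with early stopping on validation loss and the
    candidate with the lowest validation loss is returned.
    """

    learning_rate_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    weight_decay_grid: tuple[float, ...] = (0.0, 1e-5, 1e-4)
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        self.learning_rate_grid = tuple(float(v) for v in self.learning_rate_grid)
        self.weight_decay_grid = tuple(float(v) for v in self.weight_decay_grid)
        if not self.learning_rate_grid or not self.weight_decay_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(lr <= 0 for lr in self.learning_rate_grid):
            raise ValueError("learning rates must be positive")
        if any(wd < 0 for wd in self.weight_decay_grid):
            raise ValueError("weight decays must be non-negative")
        if self.max_epochs < 1 or self.patience < 0 or self.batch_size < 1:
            raise ValueError("invalid training loop settings")


@dataclass
class ScenarioConfig:
    """End-to-end description of one simulated experiment."""

    name: str = "scenario"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prediction_age_cutoff: float = 0.5
    bin_width: float = 0.25
    yob_max: int = 2020
    yob_max_strict: int = 2018
    min_followup_years: float = 5.0
    eval_times: tuple[float, ...] = (5.0, 7.0)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    #: initialisation of the token embeddings: "random" (trained with the
    #: encoder when the encoder allows it) or "pretrain" (frozen CBOW).
    embeddings: str = "random"
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.eval_times = tuple(float(t) for t in self.eval_times)
        if any(t <= 0 for t in self.eval_times):
            raise ValueError("evaluation times must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["eval_times"] = list(self.eval_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "encoder" in d:
            d["encoder"] = EncoderConfig(**d["encoder"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
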