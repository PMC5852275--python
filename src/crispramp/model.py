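"""Pipeline configuration and the shared domain types.

Every numeric threshold used anywhere in the pipeline lives on
:class:`PipelineConfig`; no stage carries hidden constants.  The config file
is a flat key/value YAML mapping; unknown keys are rejected so typos in
threshold names fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Default direct-repeat sequence used when none is configured: the reverse
#: complement of the repeat-anchored reverse primer (GT form), with primer
#: degeneracy collapsed.  A stand-in — override it for real locus data.
DEFAULT_REPEAT = "ACGTTCCAATTAATCTTAAACC"


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline."""

    window_size: int = 4
    q_threshold_r1: int = 10
    q_threshold_r2: int = 20
    min_len_r1: int = 200
    min_len_r2: int = 70
    qual_floor: int = 20
    qual_fraction: float = 0.80
    min_overlap: int = 60
    max_overlap: int = 301
    merge_identity: float = 0.90
    cluster_identity: float = 0.95
    cluster_coverage: float = 0.90
    repeat_sequence: str = DEFAULT_REPEAT
    repeat_max_mismatch: int = 5
    min_partial_repeat: int = 15
    spacer_min_len: int = 20
    spacer_max_len: int = 60
    spacer_max_mismatch: int = 6
    new_ct_min_novel: int = 3
    dominance_threshold: float = 0.01
    rng_seed: int = 0

    _FRACTIONS = (
        "qual_fraction",
        "merge_identity",
        "cluster_identity",
        "cluster_coverage",
        "dominance_threshold",
    )
    _NONNEG_INTS = (
        "window_size",
        "q_threshold_r1",
        "q_threshold_r2",
        "min_len_r1",
        "min_len_r2",
        "qual_floor",
        "min_overlap",
        "max_overlap",
        "repeat_max_mismatch",
        "min_partial_repeat",
        "spacer_min_len",
        "spacer_max_len",
        "spacer_max_mismatch",
        "new_ct_min_novel",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not 0.0 <= float(v) <= 1.0:
                raise ConfigError(f"{name} must be a fraction in [0, 1], got {v!r}")
        for name in self._NONNEG_INTS:
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.window_size < 1:
            raise ConfigError("window_size must be >= 1")
        if self.min_overlap > self.max_overlap:
            raise ConfigError("min_overlap must not exceed max_overlap")
        if self.spacer_min_len > self.spacer_max_len:
            raise ConfigError("spacer_min_len must not exceed spacer_max_len")
        rep = self.repeat_sequence
        if not rep or set(rep) - set("ACGT"):
            raise ConfigError(
                "repeat_sequence must be a non-empty string over {A,C,G,T}"
            )
        if not isinstance(self.rng_seed, int) or isinstance(self.rng_seed, bool):
            raise ConfigError("rng_seed must be an integer")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a flat YAML key/value file.

    Omitted keys take the built-in defaults; unknown keys are an error.
    An empty file yields the all-defaults config.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return PipelineConfig(**raw)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config so that :func:`load_config` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))


@dataclass
class Read:
    """A sequencing read: sequence plus per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # int array, one Phred score per base
    mate: str  # "R1" or "R2"

    def __post_init__(self) -> None:
        if not isinstance(self.qualities, np.ndarray):
            self.qualities = np.asarray(self.qualities, dtype=np.int16)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        if self.mate not in ("R1", "R2"):
            raise ValueError(f"{self.read_id}: mate must be R1 or R2")
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError(f"{self.read_id}: Phred scores out of [0, 60]")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.read_id}: sequence alphabet must be ACGTN")


@dataclass
class MergedAmplicon:
    """The single sequence assembled from an overlapping read pair."""

    amplicon_id: str
    sequence: str
    qualities: np.ndarray
    overlap_length: int
    source_pair: tuple[str, str]

    def __len__(self) -> int:
        return len(self.sequence)
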