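"""Pipeline configuration with the tuned hyperparameters as defaults."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Any

#: Provenance of the upstream radiomic extraction (recorded, never executed:
#: image-side extraction is out of scope for this package).
EXTRACTION_PROVENANCE: dict[str, Any] = {
    "bin_width": 20,
    "voxel_array_shift": 300,
    "resampled_spacing": [1, 1],
    "pad_distance": 10,
    "interpolator": "Bspline",
    "precrop": True,
}


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the classification/explainability pipeline.

    Defaults are the tuned values used throughout: 4 principal components as
    classifier input, dense blocks of 512/256/128/64 units, dropout 0.45,
    Adam at 1e-4, batches of 50, 150 epochs, 10,000 bootstrap resamples,
    and a 75th-percentile cut on type-level importance.
    """

    n_components: int = 4
    architecture: tuple[int, ...] = (512, 256, 128, 64)
    dropout_rate: float = 0.45
    learning_rate: float = 1e-4
    batch_size: int = 50
    epochs: int = 150
    bootstrap_n: int = 10_000
    percentile_cut: float = 75.0
    seed: int | None = None
    extraction_provenance: dict[str, Any] = dataclasses.field(
        default_factory=lambda: dict(EXTRACTION_PROVENANCE)
    )

    def __post_init__(self) -> None:
        self.architecture = tuple(int(w) for w in self.architecture)
        self.validate()

    def validate(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be a positive integer")
        if not self.architecture or any(w < 1 for w in self.architecture):
            raise ValueError("architecture must list positive block widths")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1 or self.bootstrap_n < 1:
            raise ValueError("batch_size, epochs and bootstrap_n must be positive")
        if not 0.0 <= self.percentile_cut <= 100.0:
            raise ValueError("percentile_cut must be in [0, 100]")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["architecture"] = list(self.architecture)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def setup_logging(verbose: bool = False, quiet: bool = False) -> logging.Logger:
    """Structured logging to stderr; --verbose for DEBUG, --quiet for errors only."""
    level = logging.DEBUG if verbose else (logging.ERROR if quiet else logging.INFO)
    logger = logging.getLogger("bpexplain")
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    return logger
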