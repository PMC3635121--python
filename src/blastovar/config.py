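"""Run configuration: defaults, YAML loading, provenance hashing."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .exceptions import InvalidArgumentError


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Unknown keys in a config file are rejected by name; every output table
    carries the config hash for provenance.
    """

    seed: int = 0
    genotypes: list[str] = field(default_factory=lambda: ["wildtype", "tll"])
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {f"t{i}": 40 for i in range(1, 9)}
    )
    n_nuclei: int = 1000
    genes: list[str] | None = None  # None = all stained genes

    # profile processing
    strip_height_fraction: float = 0.10
    background_quantile: float = 0.10
    background_degree: int = 2
    background_window: float = 10.0
    registration_a_bounds: tuple[float, float] = (0.9, 1.1)
    registration_b_bound: float = 5.0
    registration_enabled: bool = True
    smoothing_sigma_bins: float = 1.0
    scaling_percentile: float = 95.0
    # per-gene scaling direction overrides; "to_mutant" scales wild-type data
    # onto the mutant intensity range instead of the default mutant->wild-type
    scale_direction_overrides: dict[str, str] = field(
        default_factory=lambda: {"hkb": "to_mutant"}
    )

    # feature extraction
    min_rel_amplitude: float = 0.10
    window_pad_sigmas: float = 3.0
    window_min_half_width: float = 4.0
    stripe7_rel_amp_partial: float = 0.15
    stripe7_rel_amp_full: float = 0.50
    stripe7_valley_frac: float = 0.50

    # statistics
    alpha: float = 0.005
    n_tests: int | None = None  # None = number of grid cells

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise InvalidArgumentError("seed must be non-negative")
        self.registration_a_bounds = tuple(self.registration_a_bounds)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the full parameter set."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML config file, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidArgumentError("config file must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
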