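"""Core data containers shared across the pipeline.

Coordinate convention (used everywhere in this package): positions along the
antero-posterior (A-P) axis are expressed in percent egg length (%EL) on
[0, 100], with 0 at the anterior pole.  Dorso-ventral position is percent
embryo height on [0, 100].  Intensities are arbitrary fluorescence units on a
0-255 scale.  Integration bins are half-open intervals [b, b+1) %EL.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

#: Developmental stage bins: cleavage cycle 13, then eight ~6-7 min time
#: classes of cleavage cycle 14A.
TIME_CLASSES: tuple[str, ...] = ("c13", "t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8")

_TC_INDEX = {tc: i for i, tc in enumerate(TIME_CLASSES)}

#: Columns of a cohort table that are not gene channels.
META_COLUMNS = ("nucleus_id", "x", "y")


def time_class_index(time_class: str) -> int:
    """Map a time-class label to its integer index (c13=0, t1..t8=1..8)."""
    try:
        return _TC_INDEX[time_class]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown time class {time_class!r}; expected one of {TIME_CLASSES}"
        ) from None


@dataclass
class EmbryoRecord:
    """Per-nucleus raw measurements of one embryo plus metadata.

    ``nuclei`` holds one row per nucleus with columns ``nucleus_id``, ``x``
    (%EL), ``y`` (%height) and one intensity column per stained gene.
    """

    embryo_id: str
    genotype: str
    time_class: str
    nuclei: pd.DataFrame

    def __post_init__(self) -> None:
        time_class_index(self.time_class)
        missing = [c for c in META_COLUMNS if c not in self.nuclei.columns]
        if missing:
            raise InvalidArgumentError(f"nuclei table missing columns {missing}")
        if not self.genes:
            raise InvalidArgumentError("embryo record has no gene channels")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.nuclei.columns if c not in META_COLUMNS]

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


@dataclass
class Profile:
    """A 1-D expression trace for one embryo and one gene.

    Sample positions must be strictly increasing.
    """

    embryo_id: str
    gene: str
    time_class: str
    x: np.ndarray
    intensity: np.ndarray
    genotype: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.shape != self.intensity.shape or self.x.ndim != 1:
            raise InvalidArgumentError("x and intensity must be 1-D arrays of equal length")
        if self.x.size >= 2 and not np.all(np.diff(self.x) > 0):
            raise InvalidArgumentError("profile positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class IntegratedProfile:
    """Per-genotype, per-gene, per-time-class 100-bin averaged profile."""

    genotype: str
    gene: str
    time_class: str
    values: np.ndarray
    n_embryos: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (100,):
            raise InvalidArgumentError("integrated profile must have exactly 100 bins")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(100, dtype=float) + 0.5


@dataclass
class RegistrationMap:
    """Affine A-P registration x' = a*x + b estimated for one profile."""

    embryo_id: str
    a: float = 1.0
    b: float = 0.0
    residual: float = float("nan")
    converged: bool = True


@dataclass
class DomainFeatures:
    """Positional features of one expression domain in one profile.

    ``anterior``/``posterior`` are half-maximum boundary positions in %EL, or
    ``None`` when censored (no half-maximum crossing inside the search
    window, e.g. fused domains); ``censor_reasons`` records why.
    """

    gene: str
    domain: str
    peak: float
    peak_intensity: float
    anterior: float | None = None
    posterior: float | None = None
    embryo_id: str = ""
    time_class: str = ""
    genotype: str = ""
    censor_reasons: dict = field(default_factory=dict)

    @property
    def width(self) -> float | None:
        if self.anterior is None or self.posterior is None:
            return None
        return self.posterior - self.anterior
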