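"""Shared fixtures: presets, noise-free variants, dense analytic profiles."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from blastovar import Profile, tll_preset, wildtype_preset
from blastovar.config import RunConfig
from blastovar.synthetic import BackgroundSpec, GenotypePreset


@pytest.fixture(scope="session")
def wt_preset() -> GenotypePreset:
    return wildtype_preset()


@pytest.fixture(scope="session")
def mut_preset() -> GenotypePreset:
    return tll_preset()


@pytest.fixture(scope="session")
def eve_config() -> RunConfig:
    """Pipeline config restricted to the eve channel (fast test runs)."""
    return RunConfig(genes=["eve"])


def noise_free(preset: GenotypePreset) -> GenotypePreset:
    """Copy of a preset with all stochastic components switched off."""
    domains = tuple(
        dataclasses.replace(d, jitter_sd=0.0, amplitude_cv=0.0) for d in preset.domains
    )
    background = BackgroundSpec(
        constant=preset.background.constant,
        quadratic_coeff=preset.background.quadratic_coeff,
        noise_sd=0.0,
    )
    return dataclasses.replace(preset, domains=domains, background=background)


def gaussian_profile(
    center: float,
    amplitude: float = 100.0,
    sigma: float = 4.0,
    baseline: float = 0.0,
    x=None,
    embryo_id: str = "e0",
    gene: str = "eve",
    time_class: str = "t8",
) -> Profile:
    """Dense noise-free Gaussian trace for closed-form checks."""
    if x is None:
        x = np.arange(0.0, 100.0 + 1e-9, 0.1)
    y = baseline + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))
    return Profile(embryo_id, gene, time_class, x, y)


def make_record(x, y, intensities: dict, embryo_id="e0", genotype="wildtype", time_class="t8"):
    """Assemble an EmbryoRecord from raw arrays (for format-level tests)."""
    from blastovar import EmbryoRecord

    nuclei = pd.DataFrame({"nucleus_id": np.arange(len(x)), "x": x, "y": y, **intensities})
    return EmbryoRecord(embryo_id, genotype, time_class, nuclei)
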