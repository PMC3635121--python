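"""Seeded synthetic blastoderm cohorts with known ground truth.

This module emulates the statistical structure of per-nucleus segmentation
gene expression in the early *Drosophila* blastoderm: multi-domain/striped
intensity patterns along the A-P axis, embryo-to-embryo positional jitter
with genotype- and domain-dependent magnitude, time-class-dependent anterior
domain shifts, multiplicative amplitude noise, additive non-specific
background, and stochastic presence of the delayed posterior *eve* stripe in
the *tll*-mutant-like preset.  Every random draw is controlled by a single
integer seed, and all generating values are returned as a ground-truth table
so downstream estimators can be tested for parameter recovery.

Model for one embryo: each expression domain is a Gaussian bump

    I_d(x) = A_d * exp(-(x - c_d)^2 / (2 * sigma_d^2)),

where the realised centre c_d = centre(class) + jitter, jitter ~ N(0,
jitter_sd^2) drawn once per embryo per domain (domains may share one latent
draw via ``jitter_group``, modelling co-regulated boundaries), and the
realised amplitude A_d = amplitude * partial_factor * (1 + amplitude_cv * z).
Domain centres move anteriorly over developmental time at ``shift_per_class``
%EL per time-class step (c13=0, t1..t8=1..8).  The per-nucleus intensity is
the sum of all present domains of that gene plus a smooth background and
additive Gaussian measurement noise, clipped to [0, 255].

The Gaussian form makes half-maximum ground truth analytic: boundaries sit at
c +- sigma*sqrt(2 ln 2), so the true domain width is 2*sigma*sqrt(2 ln 2).
"""
from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import TIME_CLASSES, EmbryoRecord, time_class_index
from .exceptions import InvalidArgumentError

__all__ = [
    "DomainSpec",
    "BackgroundSpec",
    "GenotypePreset",
    "GroundTruth",
    "HALF_MAX_FACTOR",
    "generate_embryo",
    "generate_cohort",
    "wildtype_preset",
    "tll_preset",
    "preset_by_name",
]

#: Half-width of a unit-sigma Gaussian at half maximum: sqrt(2 ln 2).
HALF_MAX_FACTOR = math.sqrt(2.0 * math.log(2.0))

#: Columns of the ground-truth table.
GROUND_TRUTH_COLUMNS = (
    "embryo_id",
    "genotype",
    "time_class",
    "gene",
    "domain",
    "center",
    "anterior",
    "posterior",
    "present",
    "partial",
    "amplitude",
)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _per_class(value, time_class: str, default: float = 0.0) -> float:
    """Resolve a scalar-or-per-time-class parameter for one time class."""
    if isinstance(value, Mapping):
        return float(value.get(time_class, default))
    return float(value)


@dataclass(frozen=True)
class BackgroundSpec:
    """Smooth non-specific staining background plus measurement noise.

    ``constant`` and ``quadratic_coeff`` define a paraboloid-like baseline
    b(x) = constant + quadratic_coeff * (x - 50)^2 (intensity units);
    ``noise_sd`` is the SD of additive Gaussian per-nucleus noise.
    """

    constant: float = 8.0
    quadratic_coeff: float = 0.001
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        x = np.linspace(0.0, 100.0, 201)
        if np.any(self.evaluate(x) < 0):
            raise InvalidArgumentError("background must be non-negative on [0, 100]")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.constant + self.quadratic_coeff * (x - 50.0) ** 2


@dataclass(frozen=True)
class DomainSpec:
    """One expression domain (gap domain or pair-rule stripe) of one gene.

    Parameters
    ----------
    gene, label
        Gene channel name and unique domain label (e.g. ``eve_stripe_6``).
    center
        Domain centre in %EL at the reference time class c13.
    amplitude
        Peak intensity above background, 0-255 scale.
    sigma
        Gaussian half-width parameter in %EL.
    shift_per_class
        Anterior movement in %EL per time-class step (positive = anterior).
    jitter_sd
        Embryo-to-embryo SD of the realised centre, %EL.
    amplitude_cv
        Coefficient of variation of the realised amplitude.
    presence_prob
        Probability (scalar or per-time-class mapping, default 0 for classes
        missing from a mapping) that the domain is expressed at all.
    partial_prob
        Conditional probability, given presence, that expression is partial
        (amplitude scaled by ``partial_amplitude_frac``); models stripes not
        spanning the full D-V axis, which a 1-D trace sees as reduced height.
    jitter_group
        Optional latent-jitter group name: domains of one embryo sharing a
        group share one standard-normal draw (scaled by their own
        ``jitter_sd``), producing correlated boundary positions.
    """

    gene: str
    label: str
    center: float
    amplitude: float
    sigma: float
    shift_per_class: float = 0.0
    jitter_sd: float = 0.0
    amplitude_cv: float = 0.0
    presence_prob: float | Mapping[str, float] = 1.0
    partial_prob: float | Mapping[str, float] = 0.0
    partial_amplitude_frac: float = 0.3
    jitter_group: str | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidArgumentError(f"{self.label}: amplitude must be >= 0")
        if self.sigma <= 0:
            raise InvalidArgumentError(f"{self.label}: sigma must be > 0")
        if not 0.0 <= self.center <= 100.0:
            raise InvalidArgumentError(f"{self.label}: center must lie in [0, 100] %EL")
        if self.jitter_sd < 0 or self.amplitude_cv < 0:
            raise InvalidArgumentError(f"{self.label}: jitter_sd and amplitude_cv must be >= 0")
        for tc in TIME_CLASSES:
            for name, v in (
                ("presence_prob", _per_class(self.presence_prob, tc)),
                ("partial_prob", _per_class(self.partial_prob, tc)),
            ):
                if not 0.0 <= v <= 1.0:
                    raise InvalidArgumentError(f"{self.label}: {name} outside [0, 1] at {tc}")

    def center_at(self, time_class: str) -> float:
        """Expected (jitter-free) centre at a time class."""
        return self.center - self.shift_per_class * time_class_index(time_class)

    def presence_at(self, time_class: str) -> float:
        return _per_class(self.presence_prob, time_class)

    def partial_at(self, time_class: str) -> float:
        return _per_class(self.partial_prob, time_class)

    @property
    def half_width(self) -> float:
        """Half-maximum half-width sigma*sqrt(2 ln 2), %EL."""
        return self.sigma * HALF_MAX_FACTOR


@dataclass(frozen=True)
class GenotypePreset:
    """A named set of domain specs plus background defining one genotype."""

    name: str
    domains: tuple[DomainSpec, ...]
    background: BackgroundSpec = field(default_factory=BackgroundSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        labels = [d.label for d in self.domains]
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("domain labels must be unique within a preset")
        if not self.domains:
            raise InvalidArgumentError("preset must define at least one domain")

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for d in self.domains:
            if d.gene not in seen:
                seen.append(d.gene)
        return seen

    def domains_of(self, gene: str) -> list[DomainSpec]:
        return [d for d in self.domains if d.gene == gene]


#: Alias: the ground truth is a tidy table with GROUND_TRUTH_COLUMNS.
GroundTruth = pd.DataFrame


def _nucleus_lattice(n_nuclei: int) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-regular (x, y) nuclear positions covering the blastoderm surface.

    Nuclei sit on a jittered lattice of A-P columns, mimicking the
    quasi-hexagonal packing of the syncytial blastoderm; each column spreads
    its nuclei evenly over the D-V axis with a column-specific phase, so any
    lateral strip samples every A-P column.  The packing scatter is a
    deterministic golden-ratio sequence (not a seeded draw): nuclear
    arrangement is not one of the modelled noise sources, so noise-free
    presets yield identical embryos for any seed.
    """
    rows = max(5, int(round(n_nuclei / 100)))
    ncols = -(-n_nuclei // rows)  # ceil
    spacing = 100.0 / ncols
    j = np.arange(ncols, dtype=float)
    col_x = (j + 0.5) * spacing + (np.mod((j + 1.0) * _GOLDEN, 1.0) - 0.5) * 0.5 * spacing
    col_x = np.clip(col_x, 0.0, 100.0)
    xs, ys = [], []
    for jj in range(ncols):
        phase = math.fmod((jj + 1.0) * _GOLDEN, 1.0)
        yy = (np.arange(rows, dtype=float) + phase) / rows * 100.0
        xs.append(np.full(rows, col_x[jj]))
        ys.append(yy)
    x = np.concatenate(xs)[:n_nuclei]
    y = np.concatenate(ys)[:n_nuclei]
    order = np.lexsort((y, x))
    return x[order], y[order]


def generate_embryo(
    preset: GenotypePreset,
    time_class: str,
    n_nuclei: int = 1000,
    seed: int = 0,
    embryo_id: str | None = None,
) -> tuple[EmbryoRecord, GroundTruth]:
    """Generate one embryo's per-nucleus record and its ground truth.

    Returns a record with ``n_nuclei`` rows (columns ``nucleus_id``, ``x``,
    ``y`` and one intensity column per gene) and a ground-truth table with
    one row per domain carrying the realised centre, the analytic
    half-maximum boundaries, and presence/partial flags.  Identical inputs
    (including ``seed``) produce identical output.
    """
    time_class_index(time_class)
    if n_nuclei < 20:
        raise InvalidArgumentError(f"n_nuclei must be >= 20, got {n_nuclei}")
    if embryo_id is None:
        embryo_id = f"{preset.name}_{time_class}_s{seed}"

    rng = np.random.default_rng(seed)
    x, y = _nucleus_lattice(n_nuclei)

    genes = preset.genes
    intensity = {g: preset.background.evaluate(x) for g in genes}
    group_z: dict[str, float] = {}
    rows = []
    for dom in preset.domains:
        if dom.jitter_group is not None:
            if dom.jitter_group not in group_z:
                group_z[dom.jitter_group] = rng.standard_normal()
            z_pos = group_z[dom.jitter_group]
        else:
            z_pos = rng.standard_normal()
        u_presence = rng.random()
        u_partial = rng.random()
        z_amp = rng.standard_normal()

        present = u_presence < dom.presence_at(time_class)
        partial = bool(present and u_partial < dom.partial_at(time_class))
        center = dom.center_at(time_class) + z_pos * dom.jitter_sd
        amp = dom.amplitude * (dom.partial_amplitude_frac if partial else 1.0)
        amp *= max(0.0, 1.0 + dom.amplitude_cv * z_amp)
        if present and amp > 0:
            intensity[dom.gene] = intensity[dom.gene] + amp * np.exp(
                -((x - center) ** 2) / (2.0 * dom.sigma**2)
            )
        rows.append(
            {
                "embryo_id": embryo_id,
                "genotype": preset.name,
                "time_class": time_class,
                "gene": dom.gene,
                "domain": dom.label,
                "center": center,
                "anterior": center - dom.half_width,
                "posterior": center + dom.half_width,
                "present": bool(present),
                "partial": partial,
                "amplitude": amp if present else 0.0,
            }
        )

    noise_sd = preset.background.noise_sd
    for g in genes:
        if noise_sd > 0:
            intensity[g] = intensity[g] + rng.normal(0.0, noise_sd, n_nuclei)
        intensity[g] = np.clip(intensity[g], 0.0, 255.0)

    nuclei = pd.DataFrame({"nucleus_id": np.arange(n_nuclei), "x": x, "y": y})
    for g in genes:
        nuclei[g] = intensity[g]
    record = EmbryoRecord(embryo_id, preset.name, time_class, nuclei)
    return record, pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))


def generate_cohort(
    preset: GenotypePreset,
    n_per_class: Mapping[str, int],
    seed: int = 0,
    n_nuclei: int = 1000,
) -> tuple[list[EmbryoRecord], GroundTruth]:
    """Generate a cohort over time classes with per-embryo derived seeds.

    ``n_per_class`` maps time-class labels to embryo counts (missing classes
    mean zero).  Embryo i uses seed ``seed + i``, so cohorts are reproducible
    and individual embryos can be regenerated in isolation.
    """
    for tc, n in n_per_class.items():
        time_class_index(tc)
        if n < 0:
            raise InvalidArgumentError(f"negative embryo count for {tc}")
    records: list[EmbryoRecord] = []
    truths: list[pd.DataFrame] = []
    i = 0
    for tc in TIME_CLASSES:
        for _ in range(int(n_per_class.get(tc, 0))):
            eid = f"{preset.name}_{tc}_{i:04d}"
            rec, gt = generate_embryo(preset, tc, n_nuclei=n_nuclei, seed=seed + i, embryo_id=eid)
            records.append(rec)
            truths.append(gt)
            i += 1
    if truths:
        truth = pd.concat(truths, ignore_index=True)
    else:
        truth = pd.DataFrame(columns=list(GROUND_TRUTH_COLUMNS))
    return records, truth


def _present_from(first_class: str) -> dict[str, float]:
    """Presence map: certain from ``first_class`` onwards, absent before."""
    start = time_class_index(first_class)
    return {tc: 1.0 for tc in TIME_CLASSES[start:]}


def wildtype_preset(
    stripe_jitter_sd: float = 0.75,
    noise_sd: float = 3.0,
) -> GenotypePreset:
    """Wild-type-like preset: seven *eve* stripes plus gap domains.

    Late (t8) stripe positions span ~33-80 %EL so the stripe-1-to-stripe-7
    peak range at t8 is ~47 %EL (about one nucleus per %EL).  Anterior shift
    rates are steeper posteriorly; stripe 6 moves 2.62 %EL and stripe 7
    4.36 %EL between t3 and t8, and the posterior Gt domain 4.34 %EL.
    Positional jitter is uniform and small (default 0.75 %EL), reflecting
    the precision of the late wild-type blastoderm.  The abdominal Kni
    domain and *eve* stripe 6 share a jitter latent (Kni positions the
    stripe-6 anterior boundary).
    """
    eve_t8 = (33.0, 40.5, 47.0, 54.0, 61.0, 68.5, 80.0)
    eve_shift = (0.35, 0.35, 0.40, 0.45, 0.50, 0.524, 0.872)
    eve_amp = (180.0, 165.0, 175.0, 160.0, 170.0, 185.0, 170.0)
    domains = []
    for k, (pos, sh, amp) in enumerate(zip(eve_t8, eve_shift, eve_amp), start=1):
        domains.append(
            DomainSpec(
                gene="eve",
                label=f"eve_stripe_{k}",
                center=pos + 8.0 * sh,
                amplitude=amp,
                sigma=1.8 if k < 7 else 2.0,
                shift_per_class=sh,
                jitter_sd=stripe_jitter_sd,
                amplitude_cv=0.15,
                presence_prob=_present_from("t2" if k == 7 else "t1"),
                jitter_group="kni_eve6" if k == 6 else None,
            )
        )
    gap = [
        # gene, label, t8 centre, amp, sigma, shift/class, jitter, group
        ("hb", "hb_anterior", 20.0, 200.0, 8.0, 0.2, stripe_jitter_sd, None),
        ("hb", "hb_posterior", 85.0, 180.0, 4.0, 0.6, stripe_jitter_sd, None),
        ("Kr", "kr_central", 47.5, 220.0, 7.0, 0.35, stripe_jitter_sd, None),
        ("kni", "kni_abdominal", 60.5, 200.0, 4.5, 0.6, stripe_jitter_sd, "kni_eve6"),
        ("gt", "gt_anterior", 37.0, 180.0, 5.0, 0.3, stripe_jitter_sd, None),
        ("gt", "gt_posterior", 82.5, 200.0, 4.0, 0.868, stripe_jitter_sd, None),
        ("hkb", "hkb_anterior", 4.0, 120.0, 2.0, 0.0, stripe_jitter_sd, None),
        ("hkb", "hkb_posterior", 95.0, 150.0, 2.5, 0.1, stripe_jitter_sd, None),
    ]
    for gene, label, pos, amp, sigma, sh, jit, grp in gap:
        domains.append(
            DomainSpec(
                gene=gene,
                label=label,
                center=pos + 8.0 * sh,
                amplitude=amp,
                sigma=sigma,
                shift_per_class=sh,
                jitter_sd=jit,
                amplitude_cv=0.15,
                presence_prob=1.0,
                jitter_group=grp,
            )
        )
    return GenotypePreset("wildtype", tuple(domains), BackgroundSpec(noise_sd=noise_sd))


def tll_preset(
    anterior_jitter_sd: float = 0.75,
    posterior_jitter_sd: float = 2.0,
    stripe7_jitter_sd: float = 1.0,
    noise_sd: float = 3.0,
) -> GenotypePreset:
    """*tll*-mutant-like preset.

    Relative to the wild-type preset: no posterior Hb domain; the posterior
    Gt domain is expanded (larger sigma), located more posteriorly, and
    shifts 5.92 %EL between t3 and t8 (delayed retraction from the pole);
    stripes 4-6 of *eve* sit more posteriorly -- subtly for stripe 4,
    substantially for 5 and 6, whose six-stripe pattern spans about the same
    region as the seven wild-type stripes (stripe 6 forms near the wild-type
    stripe-7 position and is several nuclei wider).  Stripe 6 shifts
    4.16 %EL t3->t8, about as much as wild-type stripe 7; stripe 7 is absent
    through t6 and then appears stochastically, late and more posteriorly
    than its wild-type counterpart, partial or full, with class
    probabilities (six/partial/full) of 0.55/0.33/0.12 at t7 and
    0.08/0.47/0.45 at t8.  Posterior domains (stripes 5-6, abdominal Kni,
    posterior Gt) carry inflated positional jitter -- the
    loss-of-canalisation signature; stripe 7's increased variability is
    mainly temporal (its stochastic, delayed appearance), so its positional
    jitter stays moderate.
    """
    eve_t8 = (33.0, 40.5, 47.0, 55.0, 64.5, 79.5, 90.5)
    eve_shift = (0.35, 0.35, 0.40, 0.45, 0.65, 0.832, 0.6)
    eve_amp = (180.0, 165.0, 175.0, 160.0, 170.0, 185.0, 170.0)
    eve_sigma = (1.8, 1.8, 1.8, 1.8, 2.0, 3.9, 2.0)
    jit = (
        anterior_jitter_sd,
        anterior_jitter_sd,
        anterior_jitter_sd,
        anterior_jitter_sd,
        posterior_jitter_sd,
        posterior_jitter_sd,
        stripe7_jitter_sd,
    )
    # presence = P(partial or full); partial_prob = P(partial | present)
    stripe7_presence = {"t7": 0.45, "t8": 0.92}
    stripe7_partial = {"t7": 0.33 / 0.45, "t8": 0.47 / 0.92}
    domains = []
    for k, (pos, sh, amp, sig, j) in enumerate(
        zip(eve_t8, eve_shift, eve_amp, eve_sigma, jit), start=1
    ):
        domains.append(
            DomainSpec(
                gene="eve",
                label=f"eve_stripe_{k}",
                center=pos + 8.0 * sh,
                amplitude=amp,
                sigma=sig,
                shift_per_class=sh,
                jitter_sd=j,
                amplitude_cv=0.15,
                presence_prob=stripe7_presence if k == 7 else _present_from("t1"),
                partial_prob=stripe7_partial if k == 7 else 0.0,
                jitter_group="kni_eve6" if k == 6 else None,
            )
        )
    gap = [
        ("hb", "hb_anterior", 20.0, 200.0, 8.0, 0.2, anterior_jitter_sd, None),
        ("Kr", "kr_central", 47.5, 220.0, 7.0, 0.35, anterior_jitter_sd, None),
        ("kni", "kni_abdominal", 63.0, 200.0, 4.5, 0.7, 0.875 * posterior_jitter_sd, "kni_eve6"),
        ("gt", "gt_anterior", 37.0, 180.0, 5.0, 0.3, anterior_jitter_sd, None),
        ("gt", "gt_posterior", 81.0, 200.0, 6.0, 1.184, posterior_jitter_sd, None),
        ("hkb", "hkb_anterior", 4.0, 120.0, 2.0, 0.0, anterior_jitter_sd, None),
        ("hkb", "hkb_posterior", 95.0, 150.0, 2.5, 0.1, anterior_jitter_sd, None),
    ]
    for gene, label, pos, amp, sigma, sh, j, grp in gap:
        domains.append(
            DomainSpec(
                gene=gene,
                label=label,
                center=pos + 8.0 * sh,
                amplitude=amp,
                sigma=sigma,
                shift_per_class=sh,
                jitter_sd=j,
                amplitude_cv=0.15,
                presence_prob=1.0,
                jitter_group=grp,
            )
        )
    return GenotypePreset("tll", tuple(domains), BackgroundSpec(noise_sd=noise_sd))


def preset_by_name(name: str) -> GenotypePreset:
    """Look up a shipped preset (``wildtype`` or ``tll``)."""
    if name == "wildtype":
        return wildtype_preset()
    if name == "tll":
        return tll_preset()
    raise InvalidArgumentError(f"unknown preset {name!r}; expected 'wildtype' or 'tll'")


def with_domain_overrides(preset: GenotypePreset, **overrides_by_label) -> GenotypePreset:
    """Return a copy of ``preset`` with field overrides per domain label.

    Example: ``with_domain_overrides(p, eve_stripe_6={"jitter_sd": 2.0})``.
    Used to construct controlled variants for parameter-recovery experiments.
    """
    unknown = set(overrides_by_label) - {d.label for d in preset.domains}
    if unknown:
        raise InvalidArgumentError(f"unknown domain labels {sorted(unknown)}")
    new = tuple(
        replace(d, **overrides_by_label.get(d.label, {})) for d in preset.domains
    )
    return replace(preset, domains=new)
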