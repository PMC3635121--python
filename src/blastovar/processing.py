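"""Per-nucleus records -> registered per-embryo profiles -> integrated data.

Implements the quantification pipeline stages that follow image segmentation
and time classification: lateral-strip extraction, removal of non-specific
background staining, affine registration of the A-P coordinate against the
cohort mean, integration into 100 bins per gene and time class, Gaussian
smoothing of the integrated profile, and mutant-to-wild-type intensity
scaling.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .containers import EmbryoRecord, IntegratedProfile, Profile, RegistrationMap
from .exceptions import (
    DegenerateFitError,
    DegenerateScalingError,
    EmptyProfileError,
    InvalidArgumentError,
    MissingChannelError,
)

__all__ = [
    "extract_strip",
    "remove_background",
    "register",
    "integrate",
    "smooth_gaussian",
    "scale_to_reference",
]


def _strictly_increasing(x: np.ndarray) -> np.ndarray:
    """Break ties in a sorted position array with a stable infinitesimal."""
    x = x.copy()
    for start in np.flatnonzero(np.diff(x) == 0):
        # push every later duplicate of this run forward by multiples of 1e-9
        run = x == x[start]
        x[run] += np.arange(np.count_nonzero(run)) * 1e-9
    return x


def extract_strip(record: EmbryoRecord, gene: str, height_fraction: float = 0.10) -> Profile:
    """Extract the lateral-midline strip trace for one gene.

    Keeps nuclei with |y - 50| <= 100 * height_fraction / 2 (i.e. a strip
    covering ``height_fraction`` of the embryo's height, centred on the
    lateral midline) and returns their (x, intensity) pairs sorted by x.
    """
    if not 0.0 < height_fraction <= 1.0:
        raise InvalidArgumentError("height_fraction must be in (0, 1]")
    if gene not in record.genes:
        raise MissingChannelError(f"gene {gene!r} not stained in embryo {record.embryo_id}")
    half = 100.0 * height_fraction / 2.0
    nuc = record.nuclei
    mask = np.abs(nuc["y"].to_numpy(dtype=float) - 50.0) <= half
    if not mask.any():
        raise EmptyProfileError(
            f"no nuclei within the {height_fraction:.0%} lateral strip of {record.embryo_id}"
        )
    x = nuc.loc[mask, "x"].to_numpy(dtype=float)
    inten = nuc.loc[mask, gene].to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    return Profile(
        embryo_id=record.embryo_id,
        gene=gene,
        time_class=record.time_class,
        genotype=record.genotype,
        x=_strictly_increasing(x[order]),
        intensity=inten[order],
    )


def remove_background(
    profile: Profile,
    quantile: float = 0.1,
    poly_degree: int = 2,
    window: float = 10.0,
) -> Profile:
    """Subtract a smooth non-specific-staining baseline.

    In sliding windows of ``window`` %EL, the samples at or below the
    per-window intensity quantile are taken as baseline candidates; a single
    polynomial of ``poly_degree`` is least-squares fitted to all candidates
    and subtracted, clamping the result at zero.  The operation is invariant
    to adding a constant to all intensities and approximately idempotent
    (the second pass finds a near-zero baseline).
    """
    if not 0.0 < quantile < 0.5:
        raise InvalidArgumentError("quantile must be in (0, 0.5)")
    if poly_degree not in (0, 1, 2):
        raise InvalidArgumentError("poly_degree must be 0, 1 or 2")
    x, y = profile.x, profile.intensity
    sel = np.zeros(x.size, dtype=bool)
    for lo in np.arange(0.0, 100.0, window):
        in_win = (x >= lo) & (x < lo + window)
        if not in_win.any():
            continue
        thresh = np.quantile(y[in_win], quantile)
        sel |= in_win & (y <= thresh)
    if np.count_nonzero(sel) < poly_degree + 1:
        raise DegenerateFitError(
            f"only {np.count_nonzero(sel)} baseline points for degree {poly_degree}"
        )
    coeffs = np.polyfit(x[sel], y[sel], poly_degree)
    baseline = np.polyval(coeffs, x)
    cleaned = np.clip(y - baseline, 0.0, None)
    return Profile(profile.embryo_id, profile.gene, profile.time_class, x, cleaned, profile.genotype)


def _registration_cost(params, spline, grid, ref_values, support):
    a, b = params
    src = (grid - b) / a
    inside = (src >= support[0]) & (src <= support[1])
    if np.count_nonzero(inside) < 10:
        return 1e12
    diff = spline(src[inside]) - ref_values[inside]
    return float(np.mean(diff * diff))


def register(
    profiles: list[Profile],
    reference: IntegratedProfile | str = "self-mean",
    a_bounds: tuple[float, float] = (0.9, 1.1),
    b_bound: float = 5.0,
    n_iterations: int = 2,
) -> tuple[list[Profile], list[RegistrationMap]]:
    """Affinely align profiles of one gene/time class onto a reference.

    Estimates x' = a*x + b per profile by minimising the mean squared
    difference between the profile's quadratic-spline evaluation and the
    reference on a common 1-%EL grid, with a in ``a_bounds`` and |b| <=
    ``b_bound``.  With ``reference="self-mean"`` the reference is the
    binwise mean of the (current) cohort and the procedure runs
    ``n_iterations`` passes.  The cohort-mean map is re-centred to the
    identity (geometric-mean scale 1, mean offset 0) so registration never
    moves or stretches the cohort as a whole.  Profiles whose
    optimisation fails are passed through unregistered and flagged.
    """
    from .features import fit_quadratic_spline  # late import: avoids module cycle

    if len(profiles) < 2:
        raise InvalidArgumentError("registration needs at least 2 profiles")
    genes = {p.gene for p in profiles}
    tcs = {p.time_class for p in profiles}
    if len(genes) > 1 or len(tcs) > 1:
        raise InvalidArgumentError("profiles must share one gene and one time class")

    splines = [fit_quadratic_spline(p) for p in profiles]
    supports = [(p.x[0], p.x[-1]) for p in profiles]
    grid = np.arange(0.5, 100.0, 1.0)

    if isinstance(reference, IntegratedProfile):
        ref_values = np.interp(grid, reference.bin_centers, reference.values)
        passes = 1
    elif reference == "self-mean":
        ref_values = None
        passes = max(1, int(n_iterations))
    else:
        raise InvalidArgumentError("reference must be an IntegratedProfile or 'self-mean'")

    params = np.tile([1.0, 0.0], (len(profiles), 1))
    converged = np.ones(len(profiles), dtype=bool)
    residuals = np.full(len(profiles), np.nan)
    bounds = [a_bounds, (-b_bound, b_bound)]
    for _ in range(passes):
        if ref_values is None or passes > 1:
            # current-cohort mean on the grid, using current maps
            acc = np.zeros_like(grid)
            cnt = np.zeros_like(grid)
            for (a, b), spl, sup in zip(params, splines, supports):
                src = (grid - b) / a
                inside = (src >= sup[0]) & (src <= sup[1])
                acc[inside] += spl(src[inside])
                cnt[inside] += 1
            with np.errstate(invalid="ignore"):
                ref_values = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        for i, (spl, sup) in enumerate(zip(splines, supports)):
            res = optimize.minimize(
                _registration_cost,
                x0=params[i],
                args=(spl, grid, ref_values, sup),
                method="Powell",
                bounds=bounds,
            )
            if res.success:
                params[i] = res.x
                residuals[i] = res.fun
            else:
                params[i] = (1.0, 0.0)
                converged[i] = False

    if converged.any():
        params[:, 0] /= np.exp(np.mean(np.log(params[converged, 0])))
        params[:, 1] -= params[converged, 1].mean()
    params[:, 0] = np.clip(params[:, 0], *a_bounds)
    params[:, 1] = np.clip(params[:, 1], -b_bound, b_bound)

    out_profiles, maps = [], []
    for p, (a, b), res, ok in zip(profiles, params, residuals, converged):
        if ok:
            new = Profile(p.embryo_id, p.gene, p.time_class, a * p.x + b, p.intensity, p.genotype)
        else:
            new = p
        out_profiles.append(new)
        maps.append(RegistrationMap(p.embryo_id, float(a), float(b), float(res), bool(ok)))
    return out_profiles, maps


def integrate(profiles: list[Profile]) -> IntegratedProfile:
    """Average samples of all profiles into 100 half-open 1-%EL bins.

    Each sample lands in bin floor(x) (x = 100 goes to bin 99); bins average
    over all samples of all embryos; empty bins are linearly interpolated
    from their filled neighbours (edges held constant).
    """
    if not profiles:
        raise InvalidArgumentError("integrate needs at least one profile")
    genes = {p.gene for p in profiles}
    tcs = {p.time_class for p in profiles}
    gts = {p.genotype for p in profiles}
    if len(genes) > 1 or len(tcs) > 1 or len(gts) > 1:
        raise InvalidArgumentError("profiles must share gene, time class and genotype")
    x = np.concatenate([p.x for p in profiles])
    y = np.concatenate([p.intensity for p in profiles])
    bins = np.clip(np.floor(x).astype(int), 0, 99)
    sums = np.bincount(bins, weights=y, minlength=100)
    counts = np.bincount(bins, minlength=100)
    if not counts.any():
        raise EmptyProfileError("all integration bins are empty")
    filled = counts > 0
    values = np.zeros(100)
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        idx = np.arange(100)
        values[~filled] = np.interp(idx[~filled], idx[filled], values[filled])
    return IntegratedProfile(
        genotype=profiles[0].genotype or "",
        gene=profiles[0].gene,
        time_class=profiles[0].time_class,
        values=values,
        n_embryos=len({p.embryo_id for p in profiles}),
    )


def smooth_gaussian(profile: IntegratedProfile, sigma_bins: float = 1.0) -> IntegratedProfile:
    """Gaussian-filter an integrated profile (reflective boundaries).

    ``sigma_bins = 0`` is the identity.  Reflection preserves the total sum
    up to edge effects (< 0.5 % for the default sigma).
    """
    if sigma_bins < 0:
        raise InvalidArgumentError("sigma_bins must be >= 0")
    if sigma_bins == 0:
        values = profile.values.copy()
    else:
        values = ndimage.gaussian_filter1d(profile.values, sigma_bins, mode="reflect")
    return IntegratedProfile(
        profile.genotype, profile.gene, profile.time_class, values, profile.n_embryos
    )


def scale_to_reference(
    target: IntegratedProfile,
    reference: IntegratedProfile,
    percentile: float = 95.0,
) -> tuple[IntegratedProfile, float]:
    """Multiplicatively scale ``target`` onto ``reference``'s intensity range.

    The factor is the ratio of the ``percentile``-th bin values
    (reference / target); positional features are invariant under this
    scaling when the baseline is zero.
    """
    if target.gene != reference.gene or target.time_class != reference.time_class:
        raise InvalidArgumentError("scaling requires matching gene and time class")
    denom = float(np.percentile(target.values, percentile))
    if denom <= 0:
        raise DegenerateScalingError(
            f"target {target.gene}/{target.time_class} has zero {percentile}th percentile"
        )
    factor = float(np.percentile(reference.values, percentile)) / denom
    scaled = IntegratedProfile(
        target.genotype, target.gene, target.time_class, target.values * factor, target.n_embryos
    )
    return scaled, factor
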