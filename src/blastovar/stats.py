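"""Embryo-to-embryo variability statistics.

The comparison grid runs, for every (domain, positional feature, time class)
cell, two-sample tests of the mean (pooled-variance Student t) and of the
variance (Levene's test on absolute deviations from the group *median*, i.e.
the Brown-Forsythe test, chosen for robustness to small samples and
non-normality).  Each test is evaluated in both directions ("smaller than"
and "greater than"); p-values are Bonferroni-corrected over the full grid
(the default *eve* grid has 7 stripes x 3 positional features x 8 time
classes = 168 cells) and flagged significant below a corrected alpha of
0.005.  Censored feature values are excluded cell-wise with the remaining n
reported; the two directions of one test count as one corrected family
member.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import TIME_CLASSES
from .exceptions import InvalidArgumentError

__all__ = [
    "FeatureSample",
    "TestResult",
    "TestGrid",
    "t_test_directional",
    "brown_forsythe",
    "bonferroni",
    "default_eve_grid",
    "run_test_grid",
    "results_to_frame",
    "sd_summary",
    "pattern_class_frequencies",
    "boundary_correlation",
]

DIRECTIONS = ("less", "greater")

#: Positional feature kinds entering the default comparison grid.
POSITIONAL_FEATURES = ("peak", "anterior", "posterior")


@dataclass
class FeatureSample:
    """Per-embryo values of one feature in one cohort cell."""

    values: np.ndarray
    genotype: str = ""
    gene: str = ""
    domain: str = ""
    feature: str = ""
    time_class: str = ""
    embryo_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("feature values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("feature values must be finite (drop censored first)")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class TestResult:
    """One cell of the statistical grid, one test, one direction."""

    __test__ = False  # not a pytest collectable

    comparison_id: str
    test: str
    direction: str
    statistic: float
    df: float
    p_raw: float
    p_corrected: float = float("nan")
    significant: bool = False
    n_a: int = 0
    n_b: int = 0
    note: str = ""


@dataclass
class TestGrid:
    """The family of (domain, feature, time_class) cells under correction."""

    __test__ = False  # not a pytest collectable

    cells: list[tuple[str, str, str]]
    n_tests: int = 0

    def __post_init__(self) -> None:
        if not self.cells:
            raise InvalidArgumentError("test grid must contain at least one cell")
        if self.n_tests <= 0:
            self.n_tests = len(self.cells)


def _values(sample) -> np.ndarray:
    if isinstance(sample, FeatureSample):
        return sample.values
    return np.asarray(sample, dtype=float)


def t_test_directional(sample_a, sample_b, direction: str, comparison_id: str = "") -> TestResult:
    """One-sided pooled-variance two-sample Student t-test.

    ``direction="less"`` tests the alternative mean(a) < mean(b);
    ``"greater"`` the reverse.  With zero pooled variance the p-value is 0.5
    for equal means and 0/1 by the sign of the difference otherwise.
    """
    if direction not in DIRECTIONS:
        raise InvalidArgumentError(f"direction must be one of {DIRECTIONS}")
    a, b = _values(sample_a), _values(sample_b)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("t-test needs at least 2 values per group")
    na, nb = a.size, b.size
    df = na + nb - 2
    diff = a.mean() - b.mean()
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    note = ""
    if pooled == 0:
        stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
        if diff == 0:
            p = 0.5
        else:
            p = float((diff < 0) if direction == "less" else (diff > 0))
        note = "zero pooled variance"
    else:
        stat = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        p = sps.t.cdf(stat, df) if direction == "less" else sps.t.sf(stat, df)
    return TestResult(
        comparison_id=comparison_id,
        test="t_mean",
        direction=direction,
        statistic=float(stat),
        df=float(df),
        p_raw=float(p),
        n_a=na,
        n_b=nb,
        note=note,
    )


def brown_forsythe(sample_a, sample_b, direction: str, comparison_id: str = "") -> TestResult:
    """Directional two-sample Brown-Forsythe (median-Levene) variance test.

    Computes W on absolute deviations from the group medians, takes the
    two-sided p from F(1, N-2), and derives the directional p by halving
    with an ordering check on the mean absolute deviations: the direction is
    supported when the group with the larger spread matches the alternative
    (``"greater"`` = var(a) > var(b)).
    """
    if direction not in DIRECTIONS:
        raise InvalidArgumentError(f"direction must be one of {DIRECTIONS}")
    a, b = _values(sample_a), _values(sample_b)
    if a.size < 3 or b.size < 3:
        raise InvalidArgumentError("Brown-Forsythe needs at least 3 values per group")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    n = za.size + zb.size
    zbar = np.concatenate([za, zb]).mean()
    num = za.size * (za.mean() - zbar) ** 2 + zb.size * (zb.mean() - zbar) ** 2
    den = np.sum((za - za.mean()) ** 2) + np.sum((zb - zb.mean()) ** 2)
    note = ""
    if den == 0:
        if num == 0:
            stat, p2, note = 0.0, 1.0, "degenerate: all absolute deviations zero"
        else:
            stat, p2 = np.inf, 0.0
    else:
        stat = (n - 2) * num / den
        p2 = float(sps.f.sf(stat, 1, n - 2))
    delta = za.mean() - zb.mean()
    matches = delta > 0 if direction == "greater" else delta < 0
    if delta == 0:
        p = 0.5 if den > 0 else 1.0
    else:
        p = p2 / 2.0 if matches else 1.0 - p2 / 2.0
    return TestResult(
        comparison_id=comparison_id,
        test="brown_forsythe_var",
        direction=direction,
        statistic=float(stat),
        df=float(n - 2),
        p_raw=float(p),
        n_a=a.size,
        n_b=b.size,
        note=note,
    )


def bonferroni(p_raw, n_tests: int) -> np.ndarray:
    """Bonferroni correction: p' = min(1, p * n_tests), order-preserving."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if n_tests < 1:
        raise InvalidArgumentError("n_tests must be >= 1")
    return np.minimum(1.0, p * n_tests)


def default_eve_grid() -> TestGrid:
    """The default *eve* comparison grid: 7 stripes x 3 features x t1-t8."""
    cells = [
        (f"eve_stripe_{k}", feat, tc)
        for k in range(1, 8)
        for feat in POSITIONAL_FEATURES
        for tc in TIME_CLASSES[1:]
    ]
    return TestGrid(cells)


def features_long(features: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide per-embryo feature table into tidy (feature, value) rows."""
    keep = [c for c in ("embryo_id", "genotype", "time_class", "gene", "domain") if c in features]
    kinds = [c for c in ("peak", "anterior", "posterior", "width") if c in features]
    long = features.melt(id_vars=keep, value_vars=kinds, var_name="feature", value_name="value")
    return long.dropna(subset=["value"]).reset_index(drop=True)


def _cell_values(long: pd.DataFrame, domain: str, feature: str, time_class: str) -> np.ndarray:
    m = (
        (long["domain"] == domain)
        & (long["feature"] == feature)
        & (long["time_class"] == time_class)
    )
    return long.loc[m, "value"].to_numpy(dtype=float)


def run_test_grid(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    grid: TestGrid | None = None,
    alpha: float = 0.005,
    n_tests: int | None = None,
    min_n: int = 3,
) -> list[TestResult]:
    """Run the full directional test grid between two cohorts.

    ``features_a``/``features_b`` are tidy long tables (see
    :func:`features_long`); cohort a is conventionally the mutant.  Every
    grid cell runs both directional t-tests and both directional
    Brown-Forsythe tests; raw p-values are Bonferroni-corrected with
    ``n_tests`` (default: the grid's cell count) and flagged significant
    below ``alpha``.  Cells with fewer than ``min_n`` uncensored values in
    either cohort are skipped with a note.
    """
    grid = grid or default_eve_grid()
    n_corr = n_tests or grid.n_tests
    results: list[TestResult] = []
    for domain, feature, tc in grid.cells:
        cid = f"{domain}|{feature}|{tc}"
        va = _cell_values(features_a, domain, feature, tc)
        vb = _cell_values(features_b, domain, feature, tc)
        if va.size < min_n or vb.size < min_n:
            results.append(
                TestResult(cid, "skipped", "", np.nan, np.nan, np.nan, np.nan, False,
                           va.size, vb.size, f"fewer than {min_n} values in a cohort")
            )
            continue
        for direction in DIRECTIONS:
            results.append(t_test_directional(va, vb, direction, cid))
            results.append(brown_forsythe(va, vb, direction, cid))
    for r in results:
        if r.test != "skipped":
            r.p_corrected = float(bonferroni([r.p_raw], n_corr)[0])
            r.significant = bool(r.p_corrected < alpha)
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tabulate test results (one row per cell x test x direction)."""
    return pd.DataFrame([vars(r) for r in results])


def sd_summary(features_long_df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean, sample SD (n-1 denominator) and n of feature values."""
    keys = [c for c in ("genotype", "gene", "domain", "feature", "time_class")
            if c in features_long_df]
    grp = features_long_df.groupby(keys, observed=True)["value"]
    out = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def pattern_class_frequencies(classes: pd.DataFrame, by="time_class") -> pd.DataFrame:
    """Count and fraction of each stripe-pattern class per group.

    ``classes`` needs a ``pattern`` column plus the grouping column(s)
    ``by`` (a name or list of names); fractions sum to 1 within each group.
    """
    keys = [by] if isinstance(by, str) else list(by)
    counts = (
        classes.groupby(keys + ["pattern"], observed=True).size().rename("count").reset_index()
    )
    totals = counts.groupby(keys, observed=True)["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def boundary_correlation(x: pd.Series, y: pd.Series) -> tuple[float, int]:
    """Pearson correlation of two per-embryo boundary positions.

    ``x`` and ``y`` are indexed by embryo id; only embryos with both values
    uncensored enter.  Returns (r, n); r is NaN (undefined) when either
    variable has zero variance.
    """
    paired = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    n = len(paired)
    if n < 3:
        raise InvalidArgumentError("correlation needs at least 3 complete pairs")
    xv = paired["x"].to_numpy(dtype=float)
    yv = paired["y"].to_numpy(dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        return float("nan"), n
    return float(np.corrcoef(xv, yv)[0, 1]), n
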