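"""Tab-delimited file formats for cohorts, ground truth and result tables.

One tidy dialect is used throughout: per-nucleus cohort tables carry
``embryo_id, genotype, time_class, nucleus_id, x, y`` plus one intensity
column per gene; every file written by this package starts with ``#``
provenance comment lines (package version, config hash, seed) and renders
numbers at 6 significant digits for byte-reproducible output.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import EmbryoRecord, time_class_index
from .exceptions import CohortFormatError, InvalidArgumentError

COHORT_META = ["embryo_id", "genotype", "time_class", "nucleus_id", "x", "y"]


def _provenance(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"# blastovar {__version__}"]
    meta = []
    if seed is not None:
        meta.append(f"seed={seed}")
    if config_hash is not None:
        meta.append(f"config={config_hash}")
    if meta:
        parts.append("# " + " ".join(meta))
    return "\n".join(parts) + "\n"


def write_table(
    df: pd.DataFrame,
    path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a tidy table with a provenance header and fixed precision."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(_provenance(seed, config_hash) + buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cohort(records: list[EmbryoRecord], path, seed=None, config_hash=None) -> None:
    """Write a cohort in the per-nucleus dialect (deterministic order)."""
    genes = sorted({g for r in records for g in r.genes})
    frames = []
    for r in records:
        df = r.nuclei.copy()
        df.insert(0, "embryo_id", r.embryo_id)
        df.insert(1, "genotype", r.genotype)
        df.insert(2, "time_class", r.time_class)
        for g in genes:
            if g not in df:
                df[g] = np.nan
        frames.append(df[COHORT_META + genes])
    if frames:
        table = pd.concat(frames, ignore_index=True)
        table = table.sort_values(["embryo_id", "nucleus_id"], kind="stable")
    else:
        table = pd.DataFrame(columns=COHORT_META)
    write_table(table, path, seed=seed, config_hash=config_hash)


def _n_header_lines(path) -> int:
    """Comment lines before the header (for error line numbers)."""
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_cohort(path) -> list[EmbryoRecord]:
    """Read a cohort table, validating ranges and per-embryo metadata."""
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise CohortFormatError(f"{path}: malformed table ({exc})") from exc
    missing = [c for c in COHORT_META if c not in table.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    offset = _n_header_lines(path) + 2  # comments + header, 1-based data rows

    def _line(i: int) -> int:
        return int(i) + offset

    for col, lo, hi in (("x", 0.0, 100.0), ("y", 0.0, 100.0)):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() | (vals < lo) | (vals > hi)]
        if len(bad):
            raise CohortFormatError(
                f"{path}: line {_line(bad[0])}: {col}={table.loc[bad[0], col]!r} "
                f"outside [{lo}, {hi}]"
            )
    for i, tc in table["time_class"].items():
        try:
            time_class_index(str(tc))
        except InvalidArgumentError:
            raise CohortFormatError(
                f"{path}: line {_line(i)}: unknown time class {tc!r}"
            ) from None
    records = []
    genes = [c for c in table.columns if c not in COHORT_META]
    for eid, grp in table.groupby("embryo_id", sort=True):
        for col in ("genotype", "time_class"):
            if grp[col].nunique() != 1:
                raise CohortFormatError(
                    f"{path}: embryo {eid!r} has inconsistent {col} values"
                )
        present = [g for g in genes if grp[g].notna().all()]
        nuclei = grp[["nucleus_id", "x", "y"] + present].reset_index(drop=True)
        records.append(
            EmbryoRecord(
                embryo_id=str(eid),
                genotype=str(grp["genotype"].iloc[0]),
                time_class=str(grp["time_class"].iloc[0]),
                nuclei=nuclei,
            )
        )
    return records


def write_ground_truth(truth: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    write_table(truth, path, seed=seed, config_hash=config_hash)


def read_ground_truth(path) -> pd.DataFrame:
    return read_table(path)
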