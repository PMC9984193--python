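"""Readers and writers for chromatin-tracing tables.

All on-disk formats are TSV (tab-separated, UTF-8, header row).  Column
names are configurable through a :class:`TraceDialect` so deposited files
with different schemas can be mapped onto the canonical containers without
touching the parser.  Missing localizations are empty fields on disk and
``NaN`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AlleleTrajectorySet,
    GeneActivityMatrix,
    LocusTraceSet,
)

__all__ = [
    "TraceDialect",
    "FormatError",
    "read_chromatin_traces",
    "write_chromatin_traces",
    "read_gene_states",
    "write_gene_states",
    "read_allele_trajectories",
    "write_allele_trajectories",
    "read_locus_density",
]


class FormatError(ValueError):
    """Raised when an input table does not match the configured dialect."""


@dataclass
class TraceDialect:
    """Column mapping for trace and state tables."""

    chromosome: str = "chrom_copy"
    locus: str = "locus_index"
    genomic_start: str = "genomic_start_bp"
    x: str = "x_nm"
    y: str = "y_nm"
    z: str = "z_nm"
    gene: str = "gene_id"
    promoter_locus: str = "promoter_locus"
    state: str = "state"
    bin_size: int = 50_000

    @classmethod
    def from_yaml(cls, path) -> "TraceDialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


DEFAULT_DIALECT = TraceDialect()


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    return df


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")


def read_chromatin_traces(
    path,
    dialect: TraceDialect = DEFAULT_DIALECT,
    states_path=None,
):
    """Read a long-format trace table (one row per chromosome copy × locus).

    Returns ``(LocusTraceSet, GeneActivityMatrix | None)``; gene states are
    attached by chromosome-copy id when ``states_path`` is given.
    """
    df = _read_tsv(path)
    d = dialect
    _require(df, [d.chromosome, d.locus, d.genomic_start, d.x, d.y, d.z], path)

    loci = np.sort(df[d.locus].unique())
    n_loci = loci.size
    if not np.array_equal(loci, np.arange(n_loci)):
        raise FormatError(f"{path}: locus indices must be 0..L-1 without gaps")
    genomic_start = (
        df.drop_duplicates(d.locus).sort_values(d.locus)[d.genomic_start].to_numpy()
    )
    chrom_ids = df[d.chromosome].unique()  # first-appearance order
    chrom_pos = {c: k for k, c in enumerate(chrom_ids)}

    coords = np.full((chrom_ids.size, n_loci, 3), np.nan)
    rows = df[d.chromosome].map(chrom_pos).to_numpy()
    cols = df[d.locus].to_numpy()
    coords[rows, cols, 0] = df[d.x].to_numpy(dtype=float)
    coords[rows, cols, 1] = df[d.y].to_numpy(dtype=float)
    coords[rows, cols, 2] = df[d.z].to_numpy(dtype=float)

    traces = LocusTraceSet(
        coords=coords,
        genomic_start=genomic_start,
        chromosome_ids=chrom_ids,
        bin_size=d.bin_size,
    )

    activity = None
    if states_path is not None:
        activity = read_gene_states(states_path, dialect=d, chromosome_ids=chrom_ids)
    return traces, activity


def write_chromatin_traces(
    traces: LocusTraceSet, path, dialect: TraceDialect = DEFAULT_DIALECT
) -> None:
    d = dialect
    C, L = traces.n_chromosomes, traces.n_loci
    rec = {
        d.chromosome: np.repeat(traces.chromosome_ids, L),
        d.locus: np.tile(np.arange(L), C),
        d.genomic_start: np.tile(traces.genomic_start, C),
        d.x: traces.coords[:, :, 0].ravel(),
        d.y: traces.coords[:, :, 1].ravel(),
        d.z: traces.coords[:, :, 2].ravel(),
    }
    pd.DataFrame(rec).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gene_states(
    path, dialect: TraceDialect = DEFAULT_DIALECT, chromosome_ids=None
) -> GeneActivityMatrix:
    """Read a long-format gene-state table (chromosome copy × gene)."""
    d = dialect
    df = _read_tsv(path)
    _require(df, [d.chromosome, d.gene, d.promoter_locus, d.state], path)
    genes = list(df.drop_duplicates(d.gene).sort_values(d.gene)[d.gene])
    promoter = (
        df.drop_duplicates(d.gene).sort_values(d.gene)[d.promoter_locus].to_numpy()
    )
    if chromosome_ids is None:
        chromosome_ids = df[d.chromosome].unique()
    chrom_pos = {c: k for k, c in enumerate(chromosome_ids)}
    gene_pos = {g: k for k, g in enumerate(genes)}
    states = np.full((len(chromosome_ids), len(genes)), np.nan)
    unknown = ~df[d.chromosome].isin(chrom_pos).to_numpy()
    if unknown.any():
        raise FormatError(
            f"{path}: {unknown.sum()} state rows reference unknown chromosome ids"
        )
    rows = df[d.chromosome].map(chrom_pos).to_numpy()
    cols = df[d.gene].map(gene_pos).to_numpy()
    states[rows, cols] = df[d.state].to_numpy(dtype=float)
    return GeneActivityMatrix(states=states, promoter_locus=promoter, gene_ids=genes)


def write_gene_states(
    activity: GeneActivityMatrix,
    chromosome_ids,
    path,
    dialect: TraceDialect = DEFAULT_DIALECT,
) -> None:
    d = dialect
    C, G = activity.states.shape
    rec = {
        d.chromosome: np.repeat(np.asarray(chromosome_ids), G),
        d.gene: np.tile(np.asarray(activity.gene_ids, dtype=object), C),
        d.promoter_locus: np.tile(activity.promoter_locus, C),
        d.state: activity.states.ravel(),
    }
    pd.DataFrame(rec).to_csv(path, sep="\t", index=False, float_format="%.0f")


def read_allele_trajectories(path) -> AlleleTrajectorySet:
    """Read a long-format allele-position table.

    Mandatory columns: ``cell``, ``allele``, ``time_s``, ``x``, ``y``.  An
    optional ``unit`` column (``nm`` or ``um``) declares the coordinate unit;
    μm values are converted to the canonical nm.
    """
    df = _read_tsv(path)
    _require(df, ["cell", "allele", "time_s", "x", "y"], path)
    scale = np.ones(len(df))
    if "unit" in df.columns:
        units = df["unit"].astype(str).str.lower()
        bad = ~units.isin(["nm", "um"])
        if bad.any():
            raise FormatError(f"{path}: unknown units {sorted(units[bad].unique())}")
        scale = np.where(units == "um", 1000.0, 1.0)
    out = pd.DataFrame(
        {
            "cell": df["cell"],
            "allele": df["allele"],
            "time_s": df["time_s"].astype(float),
            "x_nm": df["x"].astype(float) * scale,
            "y_nm": df["y"].astype(float) * scale,
        }
    )
    dup = out.duplicated(subset=["cell", "allele", "time_s"])
    if dup.any():
        raise FormatError(f"{path}: duplicate timestamps within a trajectory")
    return AlleleTrajectorySet(out)


def write_allele_trajectories(
    trajs: AlleleTrajectorySet, path, unit: str = "nm"
) -> None:
    if unit not in ("nm", "um"):
        raise FormatError(f"unknown unit {unit!r}")
    factor = 1.0 if unit == "nm" else 1e-3
    df = trajs.frame.copy()
    out = pd.DataFrame(
        {
            "cell": df["cell"],
            "allele": df["allele"],
            "time_s": df["time_s"],
            "x": df["x_nm"] * factor,
            "y": df["y_nm"] * factor,
            "unit": unit,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_locus_density(path, n_loci: int | None = None) -> np.ndarray:
    """Read a per-locus density vector (e.g. H3K27ac read counts per 50-kb
    bin), one value per locus in locus order."""
    df = _read_tsv(path)
    col = "density" if "density" in df.columns else df.columns[-1]
    values = df[col].to_numpy(dtype=float)
    if n_loci is not None and values.size != n_loci:
        raise FormatError(
            f"{path}: density length {values.size} does not match locus count "
            f"{n_loci}"
        )
    return values
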