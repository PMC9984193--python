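"""Canonical in-memory containers for single-chromosome tracing data.

Conventions used throughout the package:

* coordinates are in **nm**, genomic positions in **bp**,
* locus indices are 0-based, genomic bins 0-based half-open,
* missing observations are encoded as ``NaN`` (coordinates and states alike).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LocusTraceSet",
    "GeneActivityMatrix",
    "AlleleTrajectorySet",
    "CouplingFunction",
]


class ConfigurationError(ValueError):
    """Raised when a container or simulation config violates its invariants."""


@dataclass
class LocusTraceSet:
    """3D centroid positions of ``L`` consecutive genomic segments on ``C``
    chromosome copies.

    Parameters
    ----------
    coords
        Array of shape ``(C, L, 3)`` in nm; ``NaN`` marks loci that were not
        localized on a given chromosome copy.
    genomic_start
        Start coordinate (bp) of each segment; strictly increasing with
        uniform spacing equal to ``bin_size``.
    chromosome_ids
        One identifier per chromosome copy.
    bin_size
        Segment size in bp (50-kb segments by default).
    """

    coords: np.ndarray
    genomic_start: np.ndarray
    chromosome_ids: np.ndarray
    bin_size: int = 50_000

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.genomic_start = np.asarray(self.genomic_start, dtype=np.int64)
        self.chromosome_ids = np.asarray(self.chromosome_ids)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConfigurationError(
                f"coords must have shape (C, L, 3), got {self.coords.shape}"
            )
        if self.n_loci < 2:
            raise ConfigurationError("need at least two loci")
        if self.genomic_start.shape != (self.n_loci,):
            raise ConfigurationError("genomic_start length must match locus count")
        steps = np.diff(self.genomic_start)
        if self.n_loci > 1 and not np.all(steps == self.bin_size):
            raise ConfigurationError(
                "genomic_start must be strictly increasing with uniform "
                f"{self.bin_size}-bp spacing"
            )
        if self.chromosome_ids.shape != (self.n_chromosomes,):
            raise ConfigurationError("chromosome_ids length must match coords")
        if np.any(np.isinf(self.coords)):
            raise ConfigurationError("coordinates must be finite where observed")

    @property
    def n_chromosomes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_loci(self) -> int:
        return self.coords.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask ``(C, L)``: locus localized on that chromosome copy."""
        return ~np.isnan(self.coords).any(axis=2)

    def pair_distances(self, locus_i: int, locus_j: int) -> np.ndarray:
        """Per-chromosome 3D distance between two loci (NaN when either is
        missing)."""
        d = self.coords[:, locus_i, :] - self.coords[:, locus_j, :]
        return np.sqrt((d**2).sum(axis=1))

    def genomic_separation(self, locus_i: int, locus_j: int) -> int:
        """Genomic distance (bp) between two loci."""
        return int(abs(self.genomic_start[locus_i] - self.genomic_start[locus_j]))


@dataclass
class GeneActivityMatrix:
    """Binary nascent-RNA on/off state per gene per chromosome copy.

    ``states`` is ``(C, G)`` with values 0, 1 or NaN (missing call);
    ``promoter_locus`` maps each gene to the segment containing its TSS.
    """

    states: np.ndarray
    promoter_locus: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.promoter_locus = np.asarray(self.promoter_locus, dtype=np.int64)
        if self.states.ndim != 2:
            raise ConfigurationError("states must be a (C, G) matrix")
        if self.promoter_locus.shape != (self.n_genes,):
            raise ConfigurationError("promoter_locus length must match gene count")
        vals = self.states[~np.isnan(self.states)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ConfigurationError("states must be 0, 1 or NaN")
        if not self.gene_ids:
            self.gene_ids = [f"gene_{k}" for k in range(self.n_genes)]
        if len(self.gene_ids) != self.n_genes:
            raise ConfigurationError("gene_ids length must match gene count")

    @property
    def n_chromosomes(self) -> int:
        return self.states.shape[0]

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]

    def gene_index(self, gene) -> int:
        if isinstance(gene, str):
            return self.gene_ids.index(gene)
        return int(gene)

    def fractional_occupancy(self) -> np.ndarray:
        """Fraction of chromosome copies on which each gene is on."""
        return np.nanmean(self.states, axis=0)


@dataclass
class AlleleTrajectorySet:
    """Time-stamped positions of bursting alleles, long format.

    ``frame`` has columns ``cell``, ``allele``, ``time_s``, ``x_nm``,
    ``y_nm``; rows are time-sorted within each (cell, allele).
    """

    frame: pd.DataFrame

    REQUIRED = ("cell", "allele", "time_s", "x_nm", "y_nm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"missing trajectory columns: {missing}")
        self.frame = self.frame.sort_values(
            ["cell", "allele", "time_s"], kind="stable"
        ).reset_index(drop=True)
        for (cell, allele), grp in self.frame.groupby(["cell", "allele"], sort=False):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ConfigurationError(
                    f"timestamps not strictly increasing for cell={cell} "
                    f"allele={allele}"
                )

    @property
    def cells(self) -> list:
        return list(self.frame["cell"].unique())

    def tracks(self, cell):
        """Yield ``(allele, times, xy)`` for one cell; xy in nm, shape (T, 2)."""
        sub = self.frame[self.frame["cell"] == cell]
        for allele, grp in sub.groupby("allele", sort=True):
            yield allele, grp["time_s"].to_numpy(), grp[["x_nm", "y_nm"]].to_numpy()


@dataclass
class CouplingFunction:
    """Distance-dependent co-burst coupling ω(r): a monotone non-increasing
    step function over uniform distance bins.

    ``values[k]`` applies on ``[k*bin_width, (k+1)*bin_width)`` nm;
    ``tail_value`` applies beyond the last edge.  All values lie in [0, 1]
    and ω is the fraction of the lower-frequency gene's bursts that are
    co-bursts at that distance.
    """

    values: np.ndarray
    bin_width: float = 200.0
    tail_value: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ConfigurationError("values must be a non-empty 1D array")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        full = np.append(self.values, self.tail_value)
        if np.any(full < 0) or np.any(full > 1):
            raise ConfigurationError("coupling values must lie in [0, 1]")
        if np.any(np.diff(full) > 1e-12):
            raise ConfigurationError("coupling must be monotone non-increasing")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def __call__(self, r) -> np.ndarray:
        """Evaluate ω at distances ``r`` (nm, scalar or array)."""
        r = np.asarray(r, dtype=float)
        idx = np.floor(r / self.bin_width).astype(int)
        out = np.where(
            idx < self.n_bins,
            self.values[np.clip(idx, 0, self.n_bins - 1)],
            self.tail_value,
        )
        return out if out.shape else float(out)

    @classmethod
    def zero(cls, n_bins: int = 7, bin_width: float = 200.0) -> "CouplingFunction":
        return cls(np.zeros(n_bins), bin_width=bin_width)
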