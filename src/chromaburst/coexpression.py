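"""Binary co-expression statistics: the ϕ coefficient and its dependence
on genomic distance, contact frequency, ensemble MPD and single-chromosome
distance.

For two on/off state vectors, ϕ is the Pearson correlation specialized to
binary data, computed from the 2×2 contingency table

    ϕ = (n11·n00 − n10·n01) / sqrt((n11+n10)(n11+n01)(n00+n10)(n00+n01)).

Cells with a zero marginal (a constant gene) have undefined ϕ and are
reported as NaN rather than imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneActivityMatrix, LocusTraceSet
from .spatial_stats import bootstrap_sem, contact_frequency

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyCounts",
    "BinnedCorrelationCurve",
    "CorrelationGrid",
    "phi_from_counts",
    "phi_coefficient",
    "phi_binary",
    "binned_phi",
    "pair_phi_table",
    "correlation_vs_covariate",
    "correlation_vs_single_chrom_distance",
    "binned_correlation_grid",
    "grid_records_single_chrom",
    "burst_frequency_vs_distance",
]

DISTANCE_BIN_NM = 200.0
GENOMIC_BIN_BP = 500_000
MIN_CHROM_PER_BIN = 100  # single-chromosome distance rule
MIN_PAIRS_PER_CELL = 40  # 2D grid rule ("more than 40 data points")


@dataclass
class ContingencyCounts:
    """2×2 table of joint on/off chromosome counts for a gene pair."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_states(cls, a, b) -> "ContingencyCounts":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok].astype(int), b[ok].astype(int)
        return cls(
            n11=int(((a == 1) & (b == 1)).sum()),
            n10=int(((a == 1) & (b == 0)).sum()),
            n01=int(((a == 0) & (b == 1)).sum()),
            n00=int(((a == 0) & (b == 0)).sum()),
        )


def phi_from_counts(n11, n10, n01, n00):
    """Vectorized ϕ from contingency counts; NaN where a marginal is zero."""
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    denom2 = (n11 + n10) * (n11 + n01) * (n00 + n10) * (n00 + n01)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            denom2 > 0, (n11 * n00 - n10 * n01) / np.sqrt(denom2), np.nan
        )
    return out if out.shape else float(out)


def phi_coefficient(c: ContingencyCounts) -> float:
    """ϕ coefficient of a 2×2 table (equals Pearson on the binary vectors);
    NaN (logged) when any marginal is zero."""
    val = phi_from_counts(c.n11, c.n10, c.n01, c.n00)
    if np.isnan(val):
        log.info("phi undefined for counts %s (zero marginal)", c)
    return float(val)


def phi_binary(a, b) -> float:
    """ϕ between two binary state vectors (NaN entries dropped pairwise)."""
    return phi_coefficient(ContingencyCounts.from_states(a, b))


def binned_phi(
    states_i,
    states_j,
    r,
    bin_width: float = DISTANCE_BIN_NM,
    n_bins: int | None = None,
    min_count: int = MIN_CHROM_PER_BIN,
):
    """ϕ per distance bin, computed only from chromosomes whose distance
    falls in that bin.

    This is the shared estimator used for both experimental and simulated
    data.  Returns ``(phi, n)`` arrays of length ``n_bins``; bins with fewer
    than ``min_count`` chromosomes are NaN.
    """
    a = np.asarray(states_i, dtype=float)
    b = np.asarray(states_j, dtype=float)
    r = np.asarray(r, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(r))
    a, b, r = a[ok].astype(int), b[ok].astype(int), r[ok]
    idx = np.floor(r / bin_width).astype(int)
    if n_bins is None:
        n_bins = int(idx.max()) + 1 if idx.size else 1
    inside = (idx >= 0) & (idx < n_bins)
    idx, a, b = idx[inside], a[inside], b[inside]
    code = idx * 4 + (a * 2 + b)  # 3=11, 2=10, 1=01, 0=00
    counts = np.bincount(code, minlength=n_bins * 4).reshape(n_bins, 4)
    n = counts.sum(axis=1)
    phi = phi_from_counts(
        counts[:, 3], counts[:, 2], counts[:, 1], counts[:, 0]
    )
    phi = np.where(n >= min_count, phi, np.nan)
    return phi, n


@dataclass
class BinnedCorrelationCurve:
    """Mean ϕ per covariate bin with the per-pair values behind it."""

    bin_edges: np.ndarray
    mean_phi: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # gene pairs contributing per bin
    pair_values: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _gene_pairs(activity: GeneActivityMatrix):
    return itertools.combinations(range(activity.n_genes), 2)


def pair_phi_table(
    traces: LocusTraceSet, activity: GeneActivityMatrix
) -> pd.DataFrame:
    """One row per gene pair: ϕ over all chromosomes plus the pair's
    genomic distance, MPD and contact frequency covariates."""
    rows = []
    for gi, gj in _gene_pairs(activity):
        pi = int(activity.promoter_locus[gi])
        pj = int(activity.promoter_locus[gj])
        if pi == pj:
            continue  # genes sharing a segment have no defined pair distance
        d = traces.pair_distances(pi, pj)
        good = ~np.isnan(d)
        rows.append(
            {
                "gene_i": activity.gene_ids[gi],
                "gene_j": activity.gene_ids[gj],
                "phi": phi_binary(activity.states[:, gi], activity.states[:, gj]),
                "genomic_distance": traces.genomic_separation(pi, pj),
                "mpd": float(np.median(d[good])) if good.any() else np.nan,
                "contact_frequency": (
                    contact_frequency(traces, pi, pj) if good.any() else np.nan
                ),
                "n_chromosomes": int(good.sum()),
            }
        )
    return pd.DataFrame(rows)


def _curve_from_pairs(
    values: np.ndarray, phis: np.ndarray, bin_edges: np.ndarray, n_boot, seed
) -> BinnedCorrelationCurve:
    nb = bin_edges.size - 1
    mean = np.full(nb, np.nan)
    sem = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    records = []
    idx = np.digitize(values, bin_edges) - 1
    for b in range(nb):
        sel = (idx == b) & ~np.isnan(phis)
        n[b] = int(sel.sum())
        if n[b] == 0:
            continue
        mean[b] = float(phis[sel].mean())
        if n[b] >= 2:
            sem[b] = bootstrap_sem(phis[sel], n_boot=n_boot, seed=seed)
        records.append(
            pd.DataFrame({"bin": b, "covariate": values[sel], "phi": phis[sel]})
        )
    pair_values = (
        pd.concat(records, ignore_index=True) if records else pd.DataFrame()
    )
    return BinnedCorrelationCurve(bin_edges, mean, sem, n, pair_values)


def correlation_vs_covariate(
    traces: LocusTraceSet,
    activity: GeneActivityMatrix,
    covariate: str = "genomic_distance",
    bins=None,
    n_boot: int = 1000,
    seed=None,
) -> BinnedCorrelationCurve:
    """Mean ϕ per bin of an ensemble covariate.

    One ϕ per gene pair (over all chromosomes), assigned to the pair's bin
    of genomic distance (0.5-Mb bins), ensemble MPD (200-nm bins) or contact
    frequency (decile bins).  SEM is a bootstrap over the pairs in the bin.
    """
    table = pair_phi_table(traces, activity)
    if covariate not in ("genomic_distance", "contact_frequency", "mpd"):
        raise ValueError(f"unknown covariate {covariate!r}")
    values = table[covariate].to_numpy(dtype=float)
    phis = table["phi"].to_numpy(dtype=float)
    if bins is None:
        if covariate == "genomic_distance":
            top = np.nanmax(values) + GENOMIC_BIN_BP
            bins = np.arange(0, top + GENOMIC_BIN_BP, GENOMIC_BIN_BP)
        elif covariate == "mpd":
            top = np.nanmax(values) + DISTANCE_BIN_NM
            bins = np.arange(0, top + DISTANCE_BIN_NM, DISTANCE_BIN_NM)
        else:  # contact frequency deciles from the data
            bins = np.unique(np.quantile(values[~np.isnan(values)], np.linspace(0, 1, 11)))
            bins[-1] += 1e-9
    return _curve_from_pairs(values, phis, np.asarray(bins, dtype=float), n_boot, seed)


def correlation_vs_single_chrom_distance(
    traces: LocusTraceSet,
    activity: GeneActivityMatrix,
    bin_width: float = DISTANCE_BIN_NM,
    n_bins: int | None = None,
    min_chrom: int = MIN_CHROM_PER_BIN,
    n_boot: int = 1000,
    seed=None,
) -> BinnedCorrelationCurve:
    """Mean ϕ per single-chromosome distance bin.

    For each gene pair and 200-nm bin, ϕ is computed from only the
    chromosome copies whose distance between the two promoters falls inside
    the bin; (pair, bin) combinations with fewer than ``min_chrom``
    chromosomes are excluded.
    """
    per_pair = []
    max_bin = 0
    for gi, gj in _gene_pairs(activity):
        pi = int(activity.promoter_locus[gi])
        pj = int(activity.promoter_locus[gj])
        if pi == pj:
            continue
        d = traces.pair_distances(pi, pj)
        good = ~np.isnan(d)
        if good.any():
            max_bin = max(max_bin, int(np.floor(d[good].max() / bin_width)) + 1)
        per_pair.append((gi, gj, d))
    if n_bins is None:
        n_bins = max_bin
    rows = []
    for gi, gj, d in per_pair:
        phi, n = binned_phi(
            activity.states[:, gi],
            activity.states[:, gj],
            d,
            bin_width=bin_width,
            n_bins=n_bins,
            min_count=min_chrom,
        )
        for b in range(n_bins):
            if not np.isnan(phi[b]):
                rows.append(
                    {
                        "gene_i": activity.gene_ids[gi],
                        "gene_j": activity.gene_ids[gj],
                        "bin": b,
                        "phi": phi[b],
                        "n_chrom": int(n[b]),
                    }
                )
    pair_values = pd.DataFrame(rows)
    edges = np.arange(n_bins + 1) * bin_width
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sub = pair_values[pair_values["bin"] == b]["phi"] if len(pair_values) else []
        vals = np.asarray(sub, dtype=float)
        n_pairs[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
        if vals.size >= 2:
            sem[b] = bootstrap_sem(vals, n_boot=n_boot, seed=seed)
    return BinnedCorrelationCurve(edges, mean, sem, n_pairs, pair_values)


@dataclass
class CorrelationGrid:
    """2D grid of mean ϕ with per-row/column monotone-trend tests."""

    row_edges: np.ndarray
    col_edges: np.ndarray
    mean_phi: np.ndarray  # (rows, cols)
    counts: np.ndarray
    row_p: np.ndarray  # trend p-value per row (NaN when untestable)
    col_p: np.ndarray
    alpha: float = 0.01

    @property
    def row_star(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.row_p < self.alpha

    @property
    def col_star(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.col_p < self.alpha


def _trend_p(cells: np.ndarray) -> float:
    """Pearson correlation test of cell means against bin index; needs at
    least 3 populated cells."""
    good = ~np.isnan(cells)
    if good.sum() < 3:
        return float("nan")
    x = np.arange(cells.size)[good].astype(float)
    y = cells[good]
    if np.allclose(y, y[0]):
        return 1.0
    return float(stats.pearsonr(x, y).pvalue)


def binned_correlation_grid(
    phi_values,
    row_values,
    col_values,
    row_bins,
    col_bins,
    min_pairs: int = MIN_PAIRS_PER_CELL,
    alpha: float = 0.01,
) -> CorrelationGrid:
    """Bin observations (one per gene pair, or per pair×bin record) on two
    covariates; report cell means only where more than ``min_pairs``
    observations contribute, and test each row/column for a monotone trend
    (Pearson correlation of cell means against bin index, starred at
    p < ``alpha``)."""
    phi_values = np.asarray(phi_values, dtype=float)
    row_values = np.asarray(row_values, dtype=float)
    col_values = np.asarray(col_values, dtype=float)
    row_bins = np.asarray(row_bins, dtype=float)
    col_bins = np.asarray(col_bins, dtype=float)
    ok = ~(np.isnan(phi_values) | np.isnan(row_values) | np.isnan(col_values))
    ri = np.digitize(row_values[ok], row_bins) - 1
    ci = np.digitize(col_values[ok], col_bins) - 1
    nr, nc = row_bins.size - 1, col_bins.size - 1
    inside = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
    ri, ci, ph = ri[inside], ci[inside], phi_values[ok][inside]
    flat = ri * nc + ci
    counts = np.bincount(flat, minlength=nr * nc).reshape(nr, nc)
    sums = np.bincount(flat, weights=ph, minlength=nr * nc).reshape(nr, nc)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > min_pairs, sums / np.maximum(counts, 1), np.nan)
    row_p = np.array([_trend_p(mean[r, :]) for r in range(nr)])
    col_p = np.array([_trend_p(mean[:, c]) for c in range(nc)])
    return CorrelationGrid(row_bins, col_bins, mean, counts, row_p, col_p, alpha)


def grid_records_single_chrom(
    traces: LocusTraceSet,
    activity: GeneActivityMatrix,
    bin_width: float = DISTANCE_BIN_NM,
    n_bins: int | None = None,
    min_chrom: int = MIN_CHROM_PER_BIN,
) -> pd.DataFrame:
    """Per (pair, single-chromosome-distance bin) records for the 2D grid of
    genomic distance × single-chromosome distance."""
    curve = correlation_vs_single_chrom_distance(
        traces,
        activity,
        bin_width=bin_width,
        n_bins=n_bins,
        min_chrom=min_chrom,
        n_boot=2,
    )
    recs = curve.pair_values.copy()
    if recs.empty:
        return recs
    gd = {
        (activity.gene_ids[gi], activity.gene_ids[gj]): traces.genomic_separation(
            int(activity.promoter_locus[gi]), int(activity.promoter_locus[gj])
        )
        for gi, gj in _gene_pairs(activity)
        if activity.promoter_locus[gi] != activity.promoter_locus[gj]
    }
    recs["genomic_distance"] = [
        gd[(r.gene_i, r.gene_j)] for r in recs.itertuples()
    ]
    recs["distance_nm"] = (recs["bin"] + 0.5) * bin_width
    return recs


def burst_frequency_vs_distance(
    activity: GeneActivityMatrix,
    distances,
    gene_i,
    gene_j,
    bin_width: float = DISTANCE_BIN_NM,
    n_bins: int | None = None,
) -> np.ndarray:
    """Normalized burst-frequency proxy for ``gene_i`` vs its distance to
    ``gene_j``: the on-fraction of gene i among chromosomes in each distance
    bin, divided by its overall on-fraction.  Empty bins are NaN."""
    gi = activity.gene_index(gene_i)
    s = activity.states[:, gi]
    d = np.asarray(distances, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(d))
    s, d = s[ok], d[ok]
    overall = s.mean() if s.size else 0.0
    if overall <= 0:
        raise ValueError("gene_i is never on; ratio undefined")
    idx = np.floor(d / bin_width).astype(int)
    if n_bins is None:
        n_bins = int(idx.max()) + 1 if idx.size else 1
    inside = (idx >= 0) & (idx < n_bins)
    idx, s = idx[inside], s[inside]
    n = np.bincount(idx, minlength=n_bins)
    on = np.bincount(idx, weights=s, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        ratio = np.where(n > 0, on / np.maximum(n, 1) / overall, np.nan)
    return ratio
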