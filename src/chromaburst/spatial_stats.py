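"""Fixed-cell spatial statistics on chromatin traces.

State-conditioned distance-summary matrices, promoter-centered metagene
maps, local-centroid analysis, promoter-pair distances, expected-MPD
baselines, contact frequency, gene/locus partitions, and the bootstrap/test
helpers used throughout the analyses.

All statistics are pairwise-complete: a chromosome copy contributes to a
locus pair only when both loci were localized on that copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GeneActivityMatrix, LocusTraceSet

log = logging.getLogger(__name__)

__all__ = [
    "DistanceSummaryMatrix",
    "CenteredMetageneMap",
    "distance_summary_matrix",
    "state_conditioned_matrix",
    "centered_metagene",
    "centroid_distance",
    "promoter_pair_distance",
    "expected_mpd",
    "expected_genomic_distance",
    "contact_frequency",
    "partition_genes_by_activity",
    "partition_loci_by_density",
    "bootstrap_sem",
    "two_sample_test",
]

DEFAULT_MIN_COUNT = 20  # chromosomes per locus pair before a summary is reported


@dataclass
class DistanceSummaryMatrix:
    """L×L matrix of a per-pair distance summary (median or std, nm)."""

    values: np.ndarray
    counts: np.ndarray
    statistic: str  # "median" | "std"

    def __post_init__(self) -> None:
        if self.values.shape != self.counts.shape or self.values.ndim != 2:
            raise ValueError("values and counts must be matching square matrices")
        if self.statistic not in ("median", "std"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class CenteredMetageneMap:
    """Promoter-centered offset maps averaged over genes, per state."""

    offsets: np.ndarray  # [-K..K]
    mean_map: dict  # state -> (2K+1, 2K+1) array
    difference_map: np.ndarray  # map(0) - map(1)
    n_genes: dict  # state -> contributing-gene count per cell


def _select_chromosomes(
    activity: GeneActivityMatrix, gene, state: int
) -> np.ndarray:
    g = activity.gene_index(gene)
    mask = activity.states[:, g] == state
    if not mask.any():
        name = activity.gene_ids[g]
        raise ValueError(f"no chromosomes with gene {name!r} in state {state}")
    return mask


def _summary(stacked: np.ndarray, statistic: str, ddof: int) -> np.ndarray:
    # stacked: (C, L, L) with NaN for unobserved pairs
    with np.errstate(all="ignore"):
        if statistic == "median":
            return np.nanmedian(stacked, axis=0)
        return np.nanstd(stacked, axis=0, ddof=ddof)


def distance_summary_matrix(
    traces: LocusTraceSet,
    statistic: str = "median",
    min_count: int = DEFAULT_MIN_COUNT,
    chromosome_mask: np.ndarray | None = None,
    ddof: int = 0,
    block: int = 64,
) -> DistanceSummaryMatrix:
    """Per locus pair summary statistic of the 3D distance over chromosome
    copies (optionally restricted by ``chromosome_mask``).

    Pairs with fewer than ``min_count`` contributing chromosomes are NaN.
    STD uses the population convention (``ddof=0``) by default.
    """
    coords = traces.coords
    if chromosome_mask is not None:
        coords = coords[chromosome_mask]
    C, L, _ = coords.shape
    values = np.full((L, L), np.nan)
    counts = np.zeros((L, L), dtype=int)
    for start in range(0, L, block):
        stop = min(start + block, L)
        diff = coords[:, start:stop, None, :] - coords[:, None, :, :]
        dist = np.sqrt((diff**2).sum(axis=3))  # (C, b, L)
        counts[start:stop] = (~np.isnan(dist)).sum(axis=0)
        values[start:stop] = _summary(dist, statistic, ddof)
    values[counts < min_count] = np.nan
    if statistic == "median":
        np.fill_diagonal(values, np.where(np.diag(counts) >= min_count, 0.0, np.nan))
    return DistanceSummaryMatrix(values=values, counts=counts, statistic=statistic)


def state_conditioned_matrix(
    traces: LocusTraceSet,
    activity: GeneActivityMatrix,
    gene,
    state: int,
    statistic: str = "median",
    min_count: int = 2,
    ddof: int = 0,
) -> DistanceSummaryMatrix:
    """Distance-summary matrix over the chromosomes where ``gene`` is in
    ``state`` (0 or 1)."""
    if state not in (0, 1):
        raise ValueError("state must be 0 or 1")
    mask = _select_chromosomes(activity, gene, state)
    if mask.sum() < 2:
        g = activity.gene_ids[activity.gene_index(gene)]
        raise ValueError(f"fewer than 2 chromosomes with gene {g!r} = {state}")
    return distance_summary_matrix(
        traces,
        statistic=statistic,
        min_count=min_count,
        chromosome_mask=mask,
        ddof=ddof,
    )


def centered_metagene(
    matrices_by_state: dict,
    promoter_loci,
    K: int,
) -> CenteredMetageneMap:
    """Average per-gene distance matrices re-indexed to promoter-relative
    offsets.

    ``matrices_by_state`` maps state (0/1) to a list of per-gene matrices
    (aligned with ``promoter_loci``).  Each gene enters the cell-wise average
    with weight one; offsets that fall outside a gene's chromosome are simply
    not contributed (truncation, no error).
    """
    promoter_loci = np.asarray(promoter_loci, dtype=int)
    if promoter_loci.size == 0:
        raise ValueError("need at least one gene")
    offsets = np.arange(-K, K + 1)
    side = 2 * K + 1
    mean_map, n_genes = {}, {}
    for state, mats in matrices_by_state.items():
        acc = np.zeros((side, side))
        cnt = np.zeros((side, side), dtype=int)
        for p, m in zip(promoter_loci, mats):
            vals = m.values if isinstance(m, DistanceSummaryMatrix) else np.asarray(m)
            L = vals.shape[0]
            for a_pos, a in enumerate(offsets):
                ia = p + a
                if not (0 <= ia < L):
                    continue
                jb = p + offsets
                valid = (jb >= 0) & (jb < L)
                row = vals[ia, jb[valid]]
                good = ~np.isnan(row)
                acc[a_pos, valid] += np.where(good, row, 0.0)
                cnt[a_pos, valid] += good
        with np.errstate(invalid="ignore"):
            mean_map[state] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        n_genes[state] = cnt
    if 0 in mean_map and 1 in mean_map:
        difference = mean_map[0] - mean_map[1]
    else:
        only = next(iter(mean_map.values()))
        difference = np.full_like(only, np.nan)
    return CenteredMetageneMap(
        offsets=offsets, mean_map=mean_map, difference_map=difference, n_genes=n_genes
    )


def centroid_distance(
    traces: LocusTraceSet,
    activity: GeneActivityMatrix,
    gene,
    window_mb: float,
    state: int,
    include_promoter: bool = True,
) -> float:
    """Mean distance (nm) from a gene's promoter to the centroid of the
    chromatin within a genomic window around it, over chromosomes in
    ``state``.

    ``window_mb`` is the total window size: half extends on each side of the
    promoter segment.  Chromosomes where the promoter or every window locus
    is unobserved are skipped (logged).
    """
    half_bins = int(round(window_mb * 1e6 / 2 / traces.bin_size))
    if half_bins < 1:
        raise ValueError("window must cover at least one bin on each side")
    g = activity.gene_index(gene)
    p = int(activity.promoter_locus[g])
    mask = _select_chromosomes(activity, gene, state)
    lo, hi = max(0, p - half_bins), min(traces.n_loci, p + half_bins + 1)
    window = np.arange(lo, hi)
    if not include_promoter:
        window = window[window != p]
    coords = traces.coords[mask]
    prom = coords[:, p, :]
    win = coords[:, window, :]
    centroid = np.nanmean(win, axis=1)  # (c, 3): NaN loci ignored
    d = np.sqrt(((prom - centroid) ** 2).sum(axis=1))
    usable = ~np.isnan(d)
    skipped = int((~usable).sum())
    if skipped:
        log.info("centroid_distance: skipped %d chromosomes without data", skipped)
    if not usable.any():
        raise ValueError("no chromosome with promoter and window loci observed")
    return float(d[usable].mean())


def promoter_pair_distance(
    traces: LocusTraceSet,
    activity: GeneActivityMatrix,
    gene_i,
    gene_j,
    joint_state: tuple,
) -> tuple[float, int]:
    """Mean promoter–promoter distance over chromosomes in the given joint
    transcription state; (0,1) pools (0,1) and (1,0).

    Returns ``(mean_nm, n)``; the mean is NaN when no chromosome matches.
    """
    gi, gj = activity.gene_index(gene_i), activity.gene_index(gene_j)
    si = activity.states[:, gi]
    sj = activity.states[:, gj]
    a, b = joint_state
    if {a, b} - {0, 1}:
        raise ValueError("joint_state entries must be 0 or 1")
    if a == b:
        mask = (si == a) & (sj == b)
    else:
        mask = ((si == 0) & (sj == 1)) | ((si == 1) & (sj == 0))
    d = traces.pair_distances(
        int(activity.promoter_locus[gi]), int(activity.promoter_locus[gj])
    )
    d = d[mask]
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan"), 0
    return float(d.mean()), int(d.size)


def expected_mpd(mpd: DistanceSummaryMatrix, bin_size: int = 50_000):
    """Average MPD over all locus pairs at each genomic separation.

    Returns ``(separations_bp, mean_mpd_nm)`` over the separations with at
    least one populated pair (separation 0 excluded).
    """
    L = mpd.values.shape[0]
    seps, means = [], []
    for s in range(1, L):
        diag = np.diagonal(mpd.values, offset=s)
        good = ~np.isnan(diag)
        if good.any():
            seps.append(s * bin_size)
            means.append(float(diag[good].mean()))
    if not seps:
        raise ValueError("matrix has no populated off-diagonal entries")
    return np.asarray(seps, dtype=np.int64), np.asarray(means)


def expected_genomic_distance(curve, mpd_query: float) -> int:
    """Invert the expected-MPD curve: the genomic separation whose average
    MPD is closest to ``mpd_query`` (ties → smaller separation; queries
    outside the observed MPD range clamp to the nearest endpoint, logged)."""
    seps, means = curve
    if mpd_query < means.min() or mpd_query > means.max():
        log.info(
            "expected_genomic_distance: query %.1f nm outside observed range "
            "[%.1f, %.1f]",
            mpd_query,
            means.min(),
            means.max(),
        )
    gaps = np.abs(means - mpd_query)
    order = np.lexsort((seps, gaps))  # smallest gap, then smaller separation
    return int(seps[order[0]])


def contact_frequency(
    traces: LocusTraceSet,
    locus_i: int,
    locus_j: int,
    threshold: float = 200.0,
) -> float:
    """Fraction of chromosome copies with inter-locus distance strictly
    below ``threshold`` nm, among copies where both loci were observed."""
    d = traces.pair_distances(locus_i, locus_j)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError(
            f"no chromosome observes both loci {locus_i} and {locus_j}"
        )
    return float((d < threshold).mean())


def partition_genes_by_activity(activity: GeneActivityMatrix) -> dict:
    """Split genes into low/high activity at the median fractional
    occupancy (ties go to low)."""
    if activity.n_genes < 2:
        raise ValueError("need at least two genes to partition")
    occ = activity.fractional_occupancy()
    med = np.nanmedian(occ)
    low = np.where(occ <= med)[0]
    high = np.where(occ > med)[0]
    return {"low": low, "high": high}


DENSITY_LABELS = ("low", "med", "high", "very_high")


def partition_loci_by_density(density_vector, n_groups: int = 4) -> np.ndarray:
    """Quantile-based density labels per locus (low → very_high).

    A constant vector yields a single group (logged)."""
    density = np.asarray(density_vector, dtype=float)
    labels = DENSITY_LABELS if n_groups == 4 else tuple(
        f"q{k}" for k in range(n_groups)
    )
    qs = np.quantile(density, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(qs)
    if edges.size < 3:
        log.info("partition_loci_by_density: degenerate vector, single group")
        return np.asarray([labels[0]] * density.size, dtype=object)
    idx = np.clip(np.searchsorted(edges[1:-1], density, side="right"), 0, edges.size - 2)
    return np.asarray([labels[i] for i in idx], dtype=object)


def bootstrap_sem(values, n_boot: int = 1000, seed=None) -> float:
    """Bootstrap standard error of the mean: std of resampled means."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(means.std(ddof=1))


def two_sample_test(a, b) -> float:
    """Welch two-sample t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per sample")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
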