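"""Live-cell relative allele motion: MSD curves and diffusion-coefficient
fits.

Tracking one bursting allele relative to another cancels whole-cell
translation, at the price of doubling the effective diffusion coefficient:
the relative position of two independent Brownian alleles is itself
Brownian with D_rel = 2 D.  The MSD of a d-dimensional Brownian track is
``MSD(Δt) = 2 d D_eff Δt``, so the fitted slope is converted back to the
single-allele coefficient by dividing D_eff by two for relative tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import AlleleTrajectorySet

log = logging.getLogger(__name__)

__all__ = ["RelativeTrack", "MSDCurve", "relative_positions", "msd", "fit_diffusion"]

NM2_PER_UM2 = 1e6


@dataclass
class RelativeTrack:
    """Relative position R(t) of one allele with respect to another."""

    cell: object
    allele_pair: tuple
    times: np.ndarray  # s
    positions: np.ndarray  # (T, 2), nm


@dataclass
class MSDCurve:
    """Time- and ensemble-averaged MSD per lag."""

    lags: np.ndarray  # s
    msd: np.ndarray  # μm²
    ci95: np.ndarray  # (2, n_lags), bootstrap over tracks
    n_observations: np.ndarray  # displacement pairs per lag
    var: np.ndarray  # variance of the per-lag mean (for WLS weights)


def relative_positions(trajs: AlleleTrajectorySet) -> list:
    """Relative tracks for every unordered allele pair within each cell, at
    the timestamps both alleles share; cells without a co-observed pair are
    skipped (logged)."""
    out = []
    for cell in trajs.cells:
        tracks = list(trajs.tracks(cell))
        found = False
        for a in range(len(tracks)):
            for b in range(a + 1, len(tracks)):
                al_a, t_a, xy_a = tracks[a]
                al_b, t_b, xy_b = tracks[b]
                common, ia, ib = np.intersect1d(t_a, t_b, return_indices=True)
                if common.size < 2:
                    continue
                found = True
                out.append(
                    RelativeTrack(
                        cell=cell,
                        allele_pair=(al_a, al_b),
                        times=common,
                        positions=xy_a[ia] - xy_b[ib],
                    )
                )
        if not found:
            log.info("cell %r skipped: no co-observed allele pair", cell)
    return out


def _track_sq_disp(track: RelativeTrack, lag_steps: int) -> np.ndarray:
    xy = track.positions
    if lag_steps >= xy.shape[0]:
        return np.empty(0)
    d = xy[lag_steps:] - xy[:-lag_steps]
    return (d**2).sum(axis=1)


def msd(
    rel_tracks: list,
    max_lag: float | None = None,
    n_boot: int = 200,
    seed=None,
) -> MSDCurve:
    """Time- and ensemble-averaged mean squared displacement.

    Squared displacements are pooled over all tracks and time origins per
    lag; the sampling interval is taken from the tracks (which must share
    it).  95% CIs come from a bootstrap over tracks.  Lags beyond the data
    are silently truncated.
    """
    if not rel_tracks:
        raise ValueError("need at least one relative track")
    dts = {round(float(np.diff(t.times).min()), 9) for t in rel_tracks}
    if len(dts) != 1:
        raise ValueError(f"tracks have inconsistent sampling intervals: {dts}")
    dt = dts.pop()
    longest = max(t.times.size for t in rel_tracks)
    max_steps = longest - 1
    if max_lag is not None:
        max_steps = min(max_steps, int(np.floor(max_lag / dt)))
    lags = np.arange(1, max_steps + 1) * dt
    n_tracks = len(rel_tracks)
    sums = np.zeros((n_tracks, max_steps))
    counts = np.zeros((n_tracks, max_steps), dtype=int)
    sq_sums = np.zeros((n_tracks, max_steps))
    for i, tr in enumerate(rel_tracks):
        for k in range(1, max_steps + 1):
            sq = _track_sq_disp(tr, k)
            counts[i, k - 1] = sq.size
            sums[i, k - 1] = sq.sum()
            sq_sums[i, k - 1] = (sq**2).sum()
    total_n = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(total_n > 0, sums.sum(axis=0) / total_n, np.nan)
        second = np.where(total_n > 0, sq_sums.sum(axis=0) / total_n, np.nan)
        var_mean = np.where(total_n > 1, (second - mean**2) / total_n, np.nan)

    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, max_steps), np.nan)
    for b in range(n_boot):
        pick = rng.integers(0, n_tracks, size=n_tracks)
        ns = counts[pick].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot[b] = np.where(ns > 0, sums[pick].sum(axis=0) / ns, np.nan)
    ci95 = np.nanpercentile(boot, [2.5, 97.5], axis=0)

    return MSDCurve(
        lags=lags,
        msd=mean / NM2_PER_UM2,
        ci95=ci95 / NM2_PER_UM2,
        n_observations=total_n,
        var=var_mean / NM2_PER_UM2**2,
    )


def fit_diffusion(
    curve: MSDCurve, n_dims: int = 2, relative: bool = True
) -> float:
    """Diffusion coefficient (μm²/s) from a linear MSD fit through the
    origin.

    Weighted least squares with per-lag inverse-variance weights; the slope
    equals ``2·n_dims·D_eff`` and, for relative two-allele tracks,
    ``D = D_eff / 2`` is the single-allele coefficient.  A non-positive
    slope yields D = 0 with a warning.
    """
    good = ~np.isnan(curve.msd) & (curve.n_observations > 0)
    weighted = good & np.isfinite(curve.var) & (curve.var > 0)
    if weighted.sum() >= 3:
        good = weighted
        w = 1.0 / curve.var[good]
    elif good.sum() >= 3:
        w = np.ones(int(good.sum()))  # degenerate variances (e.g. MSD ≡ 0)
    else:
        raise ValueError("need at least three usable lags")
    x = curve.lags[good]
    y = curve.msd[good]
    slope = float(np.sum(w * x * y) / np.sum(w * x * x))
    if slope <= 0:
        log.warning("non-positive MSD slope %.3g; reporting D = 0", slope)
        return 0.0
    d_eff = slope / (2.0 * n_dims)
    return d_eff / 2.0 if relative else d_eff
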