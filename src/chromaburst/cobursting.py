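"""Stochastic model of distance-dependent transcriptional co-bursting.

For a gene pair ordered so that ``P_i_tot <= P_j_tot``, nascent-RNA
production is split into a co-burst channel and individual channels whose
propensities depend on the instantaneous inter-gene distance r(t) through
the coupling function ω:

    co-burst   0 -> nRNA_i + nRNA_j   with propensity  ω(r(t)) · P_i_tot
    individual 0 -> nRNA_i            with propensity  P_i_tot − ω(r(t))·P_i_tot
    individual 0 -> nRNA_j            with propensity  P_j_tot − ω(r(t))·P_i_tot
    decay      nRNA -> 0              with propensity  Pd per molecule.

A gene is "on" at observation time T when its nascent-RNA count is
positive.  ω ∈ [0, 1] is the fraction of the lower-frequency gene's bursts
that are co-bursts at each distance; because ω ≤ 1 and the genes are
ordered, every propensity is non-negative at every instant.

Two simulation engines are provided.  The production engine exploits the
fact that burst propensities are independent of the molecular state and
lifetimes are i.i.d.: the three burst channels are independent
(inhomogeneous) Poisson streams, sampled exactly by thinning against the
constant bounds P_i_tot / P_j_tot, with an independent lifetime per nascent
RNA.  ``simulate_pair_gillespie`` is a literal event-driven implementation
with piecewise-constant propensities, kept as an independent cross-check.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .coexpression import binned_phi
from .datatypes import ConfigurationError, CouplingFunction
from .distance_process import (
    DistanceDistribution,
    DriftFunction,
    deconvolve_distance_distribution,
    drift_from_distribution,
    simulate_distance_ensemble,
)

log = logging.getLogger(__name__)

__all__ = [
    "PD_DEFAULT",
    "PtotLookup",
    "PairSimConfig",
    "build_ptot_lookup",
    "estimate_ptot",
    "sample_lifetimes",
    "apply_resolution_error",
    "simulate_pair",
    "simulate_pair_gillespie",
    "simulate_pair_ensemble",
    "GenePairData",
    "OmegaSearchConfig",
    "OmegaFitResult",
    "pair_data_from_observations",
    "fit_omega",
    "noise_removal_experiments",
    "NOISE_VARIANTS",
]

PD_DEFAULT = 1.0 / 800.0  # nascent-RNA decay propensity, 1/s (mean on time 800 s)
T_DEFAULT = 15_000.0  # trajectory length, s
PTOT_MAX = 0.05  # upper end of the burst-propensity grid, 1/s
RESOLUTION_SIGMA = 100.0  # per-locus per-axis localization error, nm


# --------------------------------------------------------------------------
# P_tot lookup


@dataclass
class PtotLookup:
    """Monotone map from burst propensity to steady-state on-fraction,
    built by stochastic simulation."""

    propensity: np.ndarray  # 1/s
    fraction_on: np.ndarray
    pd: float
    n_traj: int
    T: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.propensity) <= 0):
            raise ConfigurationError("propensity grid must be increasing")
        if np.any(np.diff(self.fraction_on) < 0):
            raise ConfigurationError("fraction_on must be monotone non-decreasing")
        if self.propensity[0] == 0 and self.fraction_on[0] != 0:
            raise ConfigurationError("fraction_on(0) must be 0")


def build_ptot_lookup(
    pd: float = PD_DEFAULT,
    grid: np.ndarray | None = None,
    n_traj: int = 2000,
    T: float = T_DEFAULT,
    seed=None,
) -> PtotLookup:
    """Simulate the single-gene birth–death process across a propensity grid
    and tabulate the fraction of trajectories that end with nascent RNA
    present at t = T.

    The grid spans [0, 0.05] 1/s.  All propensities share one candidate
    Poisson stream (thinning), which makes the tabulated fractions monotone
    by construction and the whole table cheap to build.
    """
    if grid is None:
        grid = np.linspace(0.0, PTOT_MAX, 26)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > PTOT_MAX + 1e-12):
        raise ConfigurationError(f"propensity grid must lie in [0, {PTOT_MAX}]")
    rng = np.random.default_rng(seed)
    p_max = grid.max()
    fractions = np.zeros(grid.size)
    if p_max > 0:
        counts = rng.poisson(p_max * T, size=n_traj)
        total = int(counts.sum())
        traj = np.repeat(np.arange(n_traj), counts)
        t = rng.uniform(0.0, T, size=total)
        u = rng.random(total)
        life = rng.exponential(1.0 / pd, size=total)
        survives = life > (T - t)
        # a trajectory is "on" at propensity p iff any surviving candidate
        # was accepted (u < p/p_max); only the per-trajectory minimum of u
        # over surviving candidates matters
        u_min = np.full(n_traj, np.inf)
        np.minimum.at(u_min, traj[survives], u[survives])
        fractions = (u_min[:, None] < grid[None, :] / p_max).mean(axis=0)
    return PtotLookup(grid, fractions, pd=pd, n_traj=n_traj, T=T)


def estimate_ptot(observed_fraction_on: float, lookup: PtotLookup) -> float:
    """Invert the lookup table: the grid propensity whose tabulated
    on-fraction is closest to the observation (ties → smaller propensity)."""
    f = float(observed_fraction_on)
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if f > lookup.fraction_on.max():
        warnings.warn(
            f"observed fraction {f:.3f} exceeds the table maximum "
            f"{lookup.fraction_on.max():.3f}; returning the largest grid value",
            stacklevel=2,
        )
        return float(lookup.propensity[-1])
    return float(lookup.propensity[np.argmin(np.abs(lookup.fraction_on - f))])


def sample_lifetimes(n: int, pd: float = PD_DEFAULT, seed=None) -> np.ndarray:
    """Draw nascent-RNA dwell times (s) from the exponential decay law."""
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / pd, size=n)


# --------------------------------------------------------------------------
# Resolution error


def apply_resolution_error(r_true, sigma: float = RESOLUTION_SIGMA, seed=None):
    """Blur true 3D distances with per-locus localization error.

    Each distance is decomposed onto an isotropic random 3D direction, each
    axis receives Gaussian noise of variance 2·sigma² (one sigma per locus),
    and the Euclidean norm is recomposed — the resulting error on r is a
    noncentral-chi law, not a Gaussian.
    """
    r = np.atleast_1d(np.asarray(r_true, dtype=float))
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        out = r.copy()
    else:
        rng = np.random.default_rng(seed)
        direction = rng.standard_normal((r.size, 3))
        norm = np.linalg.norm(direction, axis=1)
        norm[norm == 0] = 1.0
        v = direction / norm[:, None] * r[:, None]
        v = v + rng.normal(0.0, np.sqrt(2.0) * sigma, size=v.shape)
        out = np.linalg.norm(v, axis=1)
    return out if np.ndim(r_true) else float(out[0])


# --------------------------------------------------------------------------
# Pair simulation


@dataclass
class PairSimConfig:
    """Configuration for simulating one gene pair.

    ``p_i_tot`` and ``p_j_tot`` are the total burst propensities (1/s); the
    engine orders them so the co-burst channel is bounded by the smaller.
    ``resolution_sigma=None`` disables localization error on the reported
    end distance; ``deterministic_on_time`` replaces exponential decay with
    a fixed nascent-RNA dwell time.
    """

    p_i_tot: float
    p_j_tot: float
    pd: float = PD_DEFAULT
    omega: CouplingFunction = field(default_factory=CouplingFunction.zero)
    T: float = T_DEFAULT
    n_traj: int = 2000
    distance_source: str = "static"  # "static" | "langevin"
    resolution_sigma: float | None = RESOLUTION_SIGMA
    deterministic_on_time: float | None = None
    dt: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p_i_tot < 0 or self.p_j_tot < 0:
            raise ConfigurationError("burst propensities must be non-negative")
        if self.pd <= 0:
            raise ConfigurationError("pd must be positive")
        if self.distance_source not in ("static", "langevin"):
            raise ConfigurationError(
                f"unknown distance source {self.distance_source!r}"
            )
        if self.resolution_sigma is not None and self.resolution_sigma < 0:
            raise ConfigurationError("resolution sigma must be non-negative")
        if not isinstance(self.omega, CouplingFunction):
            raise ConfigurationError("omega must be a CouplingFunction")

    def ordered(self) -> "PairSimConfig":
        if self.p_i_tot > self.p_j_tot:
            log.info("pair propensities swapped so that P_i_tot <= P_j_tot")
            return replace(self, p_i_tot=self.p_j_tot, p_j_tot=self.p_i_tot)
        return self


@dataclass
class _EventDraws:
    """Pre-drawn candidate bursts for an ensemble (thinning bounds
    P_i for the co and i channels, P_j for the j channel) plus lifetimes.

    Distances at event times are filled in by a distance provider; end
    states for any ω are then pure arithmetic, which lets the ω search reuse
    one set of random numbers across all candidates (common random numbers).
    """

    n_traj: int
    T: float
    co_t: np.ndarray
    co_traj: np.ndarray
    co_u: np.ndarray
    co_life_i: np.ndarray
    co_life_j: np.ndarray
    i_t: np.ndarray
    i_traj: np.ndarray
    i_u: np.ndarray
    i_life: np.ndarray
    j_t: np.ndarray
    j_traj: np.ndarray
    j_u: np.ndarray
    j_life: np.ndarray
    r_co: np.ndarray | None = None
    r_i: np.ndarray | None = None
    r_j: np.ndarray | None = None
    r_end: np.ndarray | None = None


def _draw_events(
    p_i: float, p_j: float, pd: float, T: float, n_traj: int, rng
) -> _EventDraws:
    def stream(bound):
        if bound <= 0:
            z = np.zeros(0)
            return z, z.astype(int), z, z
        counts = rng.poisson(bound * T, size=n_traj)
        total = int(counts.sum())
        traj = np.repeat(np.arange(n_traj), counts)
        t = rng.uniform(0.0, T, size=total)
        u = rng.random(total)
        life = rng.exponential(1.0 / pd, size=total)
        return t, traj, u, life

    co_t, co_traj, co_u, co_life_i = stream(p_i)
    co_life_j = rng.exponential(1.0 / pd, size=co_t.size)
    i_t, i_traj, i_u, i_life = stream(p_i)
    j_t, j_traj, j_u, j_life = stream(p_j)
    return _EventDraws(
        n_traj=n_traj,
        T=T,
        co_t=co_t,
        co_traj=co_traj,
        co_u=co_u,
        co_life_i=co_life_i,
        co_life_j=co_life_j,
        i_t=i_t,
        i_traj=i_traj,
        i_u=i_u,
        i_life=i_life,
        j_t=j_t,
        j_traj=j_traj,
        j_u=j_u,
        j_life=j_life,
    )


def _fill_distances_static(draws: _EventDraws, r_static: np.ndarray) -> None:
    draws.r_co = r_static[draws.co_traj]
    draws.r_i = r_static[draws.i_traj]
    draws.r_j = r_static[draws.j_traj]
    draws.r_end = r_static.copy()


def _fill_distances_langevin(
    draws: _EventDraws,
    drift: DriftFunction,
    D_rel: float,
    r0: np.ndarray,
    dt: float,
    rng,
    r_max: float | None = None,
) -> None:
    n_steps = int(np.ceil(draws.T / dt))
    times = np.concatenate([draws.co_t, draws.i_t, draws.j_t])
    traj = np.concatenate([draws.co_traj, draws.i_traj, draws.j_traj])
    steps = np.clip(np.floor(times / dt).astype(int), 0, n_steps)
    r_events, r_end = simulate_distance_ensemble(
        drift,
        D_rel,
        r0,
        dt,
        n_steps,
        rng,
        r_max=r_max,
        eval_steps=steps,
        eval_traj=traj,
    )
    n_co, n_i = draws.co_t.size, draws.i_t.size
    draws.r_co = r_events[:n_co]
    draws.r_i = r_events[n_co : n_co + n_i]
    draws.r_j = r_events[n_co + n_i :]
    draws.r_end = r_end


def _survives(t, life, T, deterministic_on_time):
    if deterministic_on_time is not None:
        return (T - t) < deterministic_on_time
    return life > (T - t)


def _end_states(
    draws: _EventDraws,
    omega: CouplingFunction,
    p_i: float,
    p_j: float,
    deterministic_on_time: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary end states from pre-drawn candidates for a given ω."""
    T, n = draws.T, draws.n_traj
    w_co = omega(draws.r_co)
    acc_co = draws.co_u < w_co
    acc_i = draws.i_u < (1.0 - omega(draws.r_i))
    if p_j > 0:
        acc_j = draws.j_u < (1.0 - omega(draws.r_j) * p_i / p_j)
    else:
        acc_j = np.zeros(draws.j_u.size, dtype=bool)

    on_i = np.zeros(n, dtype=bool)
    on_j = np.zeros(n, dtype=bool)
    hit = acc_co & _survives(draws.co_t, draws.co_life_i, T, deterministic_on_time)
    on_i |= np.bincount(draws.co_traj[hit], minlength=n).astype(bool)
    hit = acc_co & _survives(draws.co_t, draws.co_life_j, T, deterministic_on_time)
    on_j |= np.bincount(draws.co_traj[hit], minlength=n).astype(bool)
    hit = acc_i & _survives(draws.i_t, draws.i_life, T, deterministic_on_time)
    on_i |= np.bincount(draws.i_traj[hit], minlength=n).astype(bool)
    hit = acc_j & _survives(draws.j_t, draws.j_life, T, deterministic_on_time)
    on_j |= np.bincount(draws.j_traj[hit], minlength=n).astype(bool)
    return on_i.astype(int), on_j.astype(int)


def simulate_pair_ensemble(
    cfg: PairSimConfig,
    static_distances: np.ndarray | None = None,
    distance_dist: DistanceDistribution | None = None,
    drift: DriftFunction | None = None,
    D_rel: float | None = None,
    rng=None,
) -> dict:
    """Simulate ``cfg.n_traj`` independent trajectories of a gene pair.

    Distance handling depends on ``cfg.distance_source``: ``static`` uses
    the supplied per-trajectory distances (or a frozen draw from
    ``distance_dist``); ``langevin`` integrates the distance SDE with the
    drift derived from ``distance_dist`` (or a supplied drift).

    Returns a dict with ``state_i``, ``state_j`` (binary end states),
    ``r_true_end`` and ``r_obs_end`` (end distance with localization error
    when ``cfg.resolution_sigma`` is set, else equal to the true one).
    """
    cfg = cfg.ordered()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    draws = _draw_events(cfg.p_i_tot, cfg.p_j_tot, cfg.pd, cfg.T, cfg.n_traj, rng)
    if cfg.distance_source == "static":
        if static_distances is None:
            if distance_dist is None:
                raise ConfigurationError(
                    "static source needs distances or a distance distribution"
                )
            static_distances = distance_dist.sample(cfg.n_traj, rng)
        r = np.asarray(static_distances, dtype=float)
        if r.size != cfg.n_traj:
            raise ConfigurationError("one static distance per trajectory required")
        _fill_distances_static(draws, r)
    else:
        if distance_dist is None and drift is None:
            raise ConfigurationError("langevin source needs a distance distribution")
        if D_rel is None:
            raise ConfigurationError("langevin source needs the relative D (nm²/s)")
        if drift is None:
            drift = drift_from_distribution(distance_dist, D_rel)
        r0 = (
            distance_dist.sample(cfg.n_traj, rng)
            if distance_dist is not None
            else np.full(cfg.n_traj, drift.r.mean())
        )
        r_max = distance_dist.r_max if distance_dist is not None else None
        _fill_distances_langevin(draws, drift, D_rel, r0, cfg.dt, rng, r_max=r_max)
    state_i, state_j = _end_states(
        draws, cfg.omega, cfg.p_i_tot, cfg.p_j_tot, cfg.deterministic_on_time
    )
    r_true_end = draws.r_end
    if cfg.resolution_sigma:
        r_obs_end = apply_resolution_error(r_true_end, cfg.resolution_sigma, seed=rng)
    else:
        r_obs_end = r_true_end.copy()
    return {
        "state_i": state_i,
        "state_j": state_j,
        "r_true_end": r_true_end,
        "r_obs_end": r_obs_end,
    }


def simulate_pair(
    cfg: PairSimConfig, distance_traj: np.ndarray, rng=None
) -> tuple[int, int]:
    """Simulate one trajectory of a gene pair along a given distance path.

    ``distance_traj`` samples r(t) on the uniform grid ``0, dt, …`` and must
    cover [0, T]; the propensities are piecewise constant between grid
    points.  Returns the binary end states ``(state_i, state_j)``.
    """
    cfg = cfg.ordered()
    r_grid = np.asarray(distance_traj, dtype=float)
    if (r_grid.size - 1) * cfg.dt < cfg.T:
        raise ConfigurationError("distance trajectory must cover [0, T]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    draws = _draw_events(cfg.p_i_tot, cfg.p_j_tot, cfg.pd, cfg.T, 1, rng)
    idx = lambda t: np.clip(np.floor(t / cfg.dt).astype(int), 0, r_grid.size - 1)
    draws.r_co = r_grid[idx(draws.co_t)]
    draws.r_i = r_grid[idx(draws.i_t)]
    draws.r_j = r_grid[idx(draws.j_t)]
    draws.r_end = r_grid[idx(np.array([cfg.T]))]
    si, sj = _end_states(
        draws, cfg.omega, cfg.p_i_tot, cfg.p_j_tot, cfg.deterministic_on_time
    )
    return int(si[0]), int(sj[0])


def simulate_pair_gillespie(
    cfg: PairSimConfig, distance_traj: np.ndarray, rng=None
) -> tuple[int, int]:
    """Event-driven stochastic simulation of one pair trajectory.

    Literal implementation with propensities re-evaluated whenever the
    piecewise-constant distance updates: the next-reaction time is drawn
    with the current propensities and, if it crosses the next distance-grid
    boundary, the clock advances to the boundary and the draw is repeated.
    Used as an independent cross-check of the vectorized engine.
    """
    cfg = cfg.ordered()
    if cfg.deterministic_on_time is not None:
        raise ConfigurationError(
            "the event-driven engine models exponential decay only"
        )
    r_grid = np.asarray(distance_traj, dtype=float)
    if (r_grid.size - 1) * cfg.dt < cfg.T:
        raise ConfigurationError("distance trajectory must cover [0, T]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = 0.0
    n_i = n_j = 0
    while t < cfg.T:
        k = min(int(t / cfg.dt), r_grid.size - 1)
        w = cfg.omega(r_grid[k])
        a = np.array(
            [
                w * cfg.p_i_tot,
                cfg.p_i_tot - w * cfg.p_i_tot,
                cfg.p_j_tot - w * cfg.p_i_tot,
                n_i * cfg.pd,
                n_j * cfg.pd,
            ]
        )
        if a.min() < 0:  # cannot happen for an ordered pair with ω ≤ 1
            raise RuntimeError(f"negative propensity at t={t:.1f}: {a}")
        a0 = a.sum()
        boundary = min((k + 1) * cfg.dt, cfg.T)
        if a0 <= 0:
            t = boundary
            continue
        tau = rng.exponential(1.0 / a0)
        if t + tau >= boundary:
            t = boundary
            continue
        t += tau
        reaction = rng.choice(5, p=a / a0)
        if reaction == 0:
            n_i += 1
            n_j += 1
        elif reaction == 1:
            n_i += 1
        elif reaction == 2:
            n_j += 1
        elif reaction == 3:
            n_i -= 1
        else:
            n_j -= 1
    return int(n_i > 0), int(n_j > 0)


# --------------------------------------------------------------------------
# ω fitting


@dataclass
class GenePairData:
    """Per-pair inputs for the ω search: the experimental ϕ-vs-distance
    curve (200-nm bins, NaN where the ≥100-chromosome rule removed a bin),
    the two burst propensities, and the (deconvolved) true-distance
    steady-state distribution."""

    phi_obs: np.ndarray
    p_i_tot: float
    p_j_tot: float
    distance_dist: DistanceDistribution
    label: str = ""

    def __post_init__(self) -> None:
        self.phi_obs = np.asarray(self.phi_obs, dtype=float)
        if self.p_i_tot < 0 or self.p_j_tot < 0:
            raise ConfigurationError("burst propensities must be non-negative")


@dataclass
class OmegaSearchConfig:
    """Search-space and simulation settings for the ω fit.

    The step function is searched over ``n_bins`` 200-nm bins and pinned to
    zero beyond them (default cutoff 1400 nm).  The coarse stage moves on a
    0.1 grid by greedy coordinate descent from the zero function (or
    exhaustively when ``n_bins <= exhaustive_max_bins``); the refinement
    stage varies bins whose left edge is below 1000 nm by ±0.05.
    """

    n_bins: int = 7
    bin_width: float = 200.0
    coarse_step: float = 0.1
    refine_step: float = 0.05
    refine_below_nm: float = 1000.0
    n_traj: int = 3000
    T: float = T_DEFAULT
    pd: float = PD_DEFAULT
    distance_source: str = "static"
    resolution_sigma: float | None = RESOLUTION_SIGMA
    deterministic_on_time: float | None = None
    diffusion_coeff: float = 0.25e-3  # single-locus D, μm²/s (langevin source)
    dt: float = 1.0
    min_chrom: int = 100
    seed: int = 0
    exhaustive_max_bins: int = 0
    max_passes: int = 10


@dataclass
class OmegaFitResult:
    omega: CouplingFunction
    error: float
    n_evaluated: int
    sim_curves: list = field(default_factory=list)  # per pair, at the optimum


class _PairContext:
    """Cached draws and distances for one pair so that evaluating a
    candidate ω is pure arithmetic (common random numbers across the
    search)."""

    def __init__(self, pair: GenePairData, search: OmegaSearchConfig, seed):
        rng = np.random.default_rng(seed)
        p_i, p_j = sorted((pair.p_i_tot, pair.p_j_tot))
        self.p_i, self.p_j = p_i, p_j
        self.pair = pair
        self.search = search
        self.draws = _draw_events(
            p_i, p_j, search.pd, search.T, search.n_traj, rng
        )
        if search.distance_source == "static":
            r = pair.distance_dist.sample(search.n_traj, rng)
            _fill_distances_static(self.draws, r)
        else:
            D_rel = 2.0 * search.diffusion_coeff * 1e6  # μm²/s → nm²/s, relative
            drift = drift_from_distribution(pair.distance_dist, D_rel)
            r0 = pair.distance_dist.sample(search.n_traj, rng)
            _fill_distances_langevin(
                self.draws,
                drift,
                D_rel,
                r0,
                search.dt,
                rng,
                r_max=pair.distance_dist.r_max,
            )
        if search.resolution_sigma:
            self.r_bin = apply_resolution_error(
                self.draws.r_end, search.resolution_sigma, seed=rng
            )
        else:
            self.r_bin = self.draws.r_end
        self.n_curve_bins = pair.phi_obs.size

    def phi_curve(self, omega: CouplingFunction) -> np.ndarray:
        si, sj = _end_states(
            self.draws, omega, self.p_i, self.p_j, self.search.deterministic_on_time
        )
        phi, _ = binned_phi(
            si,
            sj,
            self.r_bin,
            bin_width=self.search.bin_width,
            n_bins=self.n_curve_bins,
            min_count=self.search.min_chrom,
        )
        return phi

    def curve_error(self, omega: CouplingFunction) -> float:
        phi = self.phi_curve(omega)
        diff = np.abs(phi - self.pair.phi_obs)
        return float(np.nansum(diff))


def _monotone_sequences(levels_desc, n_bins):
    yield from itertools.combinations_with_replacement(levels_desc, n_bins)


def fit_omega(
    pairs: list,
    search: OmegaSearchConfig | None = None,
) -> OmegaFitResult:
    """Fit the coupling function ω by minimizing the summed absolute
    difference between simulated and experimental per-pair ϕ-vs-distance
    curves:

        Error(ω) = Σ_pairs Σ_bins |ϕ_sim(bin) − ϕ_obs(bin)|.

    Coarse search over monotone non-increasing step functions at 0.1
    resolution, then ±0.05 refinement on bins below 1000 nm.  Simulated
    curves use the same ϕ estimator and ≥100-chromosome binning rule as the
    experimental pipeline, with common random numbers across candidates.
    """
    if search is None:
        search = OmegaSearchConfig()
    pairs = list(pairs)
    if not pairs or all(np.all(np.isnan(p.phi_obs)) for p in pairs):
        raise ValueError("no experimental curves to fit")
    root = np.random.default_rng(search.seed)
    contexts = [
        _PairContext(p, search, root.integers(2**31)) for p in pairs
    ]
    cache: dict[tuple, float] = {}

    def error_of(values: np.ndarray) -> float:
        key = tuple(np.round(values, 6))
        if key not in cache:
            omega = CouplingFunction(values, bin_width=search.bin_width)
            cache[key] = sum(ctx.curve_error(omega) for ctx in contexts)
        return cache[key]

    def greedy(values: np.ndarray, step: float, movable) -> np.ndarray:
        levels = np.round(np.arange(0.0, 1.0 + step / 2, step), 6)
        values = values.copy()
        for _ in range(search.max_passes):
            improved = False
            for b in range(search.n_bins):
                if not movable[b]:
                    continue
                upper = values[b - 1] if b > 0 else 1.0
                lower = values[b + 1] if b < search.n_bins - 1 else 0.0
                cand = levels[(levels >= lower - 1e-9) & (levels <= upper + 1e-9)]
                if search.coarse_step != step:
                    # refinement: stay within ±step of the coarse optimum
                    cand = cand[np.abs(cand - values[b]) <= step + 1e-9]
                errs = []
                for v in cand:
                    trial = values.copy()
                    trial[b] = v
                    errs.append(error_of(trial))
                best = int(np.argmin(errs))
                if not np.isclose(cand[best], values[b]):
                    values[b] = cand[best]
                    improved = True
            if not improved:
                break
        return values

    all_movable = np.ones(search.n_bins, dtype=bool)
    if search.n_bins <= search.exhaustive_max_bins:
        levels_desc = np.round(
            np.arange(1.0, -search.coarse_step / 2, -search.coarse_step), 6
        )
        best_vals, best_err = None, np.inf
        for seq in _monotone_sequences(levels_desc, search.n_bins):
            err = error_of(np.asarray(seq))
            if err < best_err:
                best_vals, best_err = np.asarray(seq, dtype=float), err
        values = best_vals
    else:
        # initialize from the best constant plateau (level v out to a cutoff
        # bin, zero beyond): a cheap exhaustive sweep over a family that
        # already brackets the typical shapes, which keeps the coordinate
        # descent from over-fitting the first bin before later bins move
        levels = np.round(
            np.arange(0.0, 1.0 + search.coarse_step / 2, search.coarse_step), 6
        )
        init, init_err = np.zeros(search.n_bins), error_of(np.zeros(search.n_bins))
        for cut in range(1, search.n_bins + 1):
            for v in levels[1:]:
                cand = np.zeros(search.n_bins)
                cand[:cut] = v
                err = error_of(cand)
                if err < init_err:
                    init, init_err = cand, err
        values = greedy(init, search.coarse_step, all_movable)

    edges_left = np.arange(search.n_bins) * search.bin_width
    movable = edges_left < search.refine_below_nm
    values = greedy(values, search.refine_step, movable)

    omega = CouplingFunction(values, bin_width=search.bin_width)
    curves = [ctx.phi_curve(omega) for ctx in contexts]
    return OmegaFitResult(
        omega=omega,
        error=error_of(values),
        n_evaluated=len(cache),
        sim_curves=curves,
    )


def pair_data_from_observations(
    state_i,
    state_j,
    r_obs,
    lookup: PtotLookup,
    sigma: float = RESOLUTION_SIGMA,
    bin_width: float = 200.0,
    n_bins: int | None = None,
    min_chrom: int = 100,
    dist_bin_width: float = 25.0,
    label: str = "",
) -> GenePairData:
    """Assemble a :class:`GenePairData` from per-chromosome observations:
    ϕ-vs-distance curve (shared estimator), burst propensities via the
    lookup table, and the localization-error-deconvolved distance
    distribution."""
    phi_obs, _ = binned_phi(
        state_i, state_j, r_obs, bin_width=bin_width, n_bins=n_bins,
        min_count=min_chrom,
    )
    s_i = np.asarray(state_i, dtype=float)
    s_j = np.asarray(state_j, dtype=float)
    p_i = estimate_ptot(np.nanmean(s_i), lookup)
    p_j = estimate_ptot(np.nanmean(s_j), lookup)
    observed = DistanceDistribution.from_samples(
        np.asarray(r_obs, dtype=float), bin_width=dist_bin_width
    )
    dist = deconvolve_distance_distribution(observed, sigma)
    return GenePairData(
        phi_obs=phi_obs, p_i_tot=p_i, p_j_tot=p_j, distance_dist=dist, label=label
    )


# --------------------------------------------------------------------------
# Noise-removal experiments

NOISE_VARIANTS = (
    "all_noise",
    "no_resolution",
    "deterministic_on",
    "no_diffusion",
)


def noise_removal_experiments(
    omega: CouplingFunction,
    pairs: list,
    search: OmegaSearchConfig | None = None,
    variants=NOISE_VARIANTS,
    seed=0,
) -> dict:
    """Re-simulate each pair under a ladder of noise-removal variants.

    ``all_noise``        distance diffusion + localization error +
                         stochastic on times (the fixed-cell experiment);
    ``no_resolution``    same but distances binned without localization
                         error;
    ``deterministic_on`` additionally every nascent RNA lasts exactly the
                         mean on time (1/Pd);
    ``no_diffusion``     additionally distances frozen at their
                         steady-state draw.

    Returns ``{variant: {"mean_phi": per-bin mean over pairs,
    "per_pair": list of curves}}``.
    """
    if search is None:
        search = OmegaSearchConfig()
    for v in variants:
        if v not in NOISE_VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    root = np.random.default_rng(seed)
    pair_seeds = [root.integers(2**31) for _ in pairs]
    out = {}
    for variant in variants:
        mods = dict(
            distance_source="langevin",
            resolution_sigma=search.resolution_sigma,
            deterministic_on_time=None,
        )
        if variant in ("no_resolution", "deterministic_on", "no_diffusion"):
            mods["resolution_sigma"] = None
        if variant in ("deterministic_on", "no_diffusion"):
            mods["deterministic_on_time"] = 1.0 / search.pd
        if variant == "no_diffusion":
            mods["distance_source"] = "static"
        vsearch = replace(search, **mods)
        curves = []
        for pair, s in zip(pairs, pair_seeds):
            ctx = _PairContext(pair, vsearch, s)
            curves.append(ctx.phi_curve(omega))
        stacked = np.vstack(curves)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_phi = np.nanmean(stacked, axis=0)
        out[variant] = {"mean_phi": mean_phi, "per_pair": curves}
    return out
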