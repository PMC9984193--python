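"""The co-bursting engine: lookup-table calibration, resolution error,
pair simulation (vectorized vs event-driven), and the ω search."""

import warnings

import numpy as np
import pytest
from scipy import stats

from chromaburst import cobursting as cob
from chromaburst import coexpression as cx
from chromaburst import distance_process as dp
from chromaburst.datatypes import ConfigurationError, CouplingFunction

PD = cob.PD_DEFAULT


def chi_dist(step, sep, bw=25.0, rmax=2500.0):
    """True-distance law of a freely-jointed chain pair at a given bin
    separation (chi with 3 dof)."""
    sax = step * np.sqrt(sep / 3.0)
    centers = np.arange(bw / 2, rmax, bw)
    pmf = stats.chi.pdf(centers / sax, 3)
    return dp.DistanceDistribution(centers, pmf / pmf.sum(), "model")


class TestPtotLookup:
    def test_matches_stationary_birth_death_law(self):
        """fraction_on(p) = 1 − exp(−p/Pd) — the analytic oracle for the
        whole birth–death engine."""
        grid = np.array([0.0, 0.5 * PD, PD, 2 * PD, 0.01, 0.05])
        lk = cob.build_ptot_lookup(grid=grid, n_traj=4000, seed=1)
        pred = 1.0 - np.exp(-grid / PD)
        se = np.sqrt(np.maximum(pred * (1 - pred), 1e-12) / 4000)
        assert lk.fraction_on[0] == 0.0
        assert np.all(np.abs(lk.fraction_on - pred) <= 3 * se + 1e-12)
        # the printed anchors: Pd → 0.632, 2·Pd → 0.865
        assert lk.fraction_on[2] == pytest.approx(0.632, abs=0.03)
        assert lk.fraction_on[3] == pytest.approx(0.865, abs=0.03)

    def test_monotone_by_construction(self):
        lk = cob.build_ptot_lookup(n_traj=500, seed=2)
        assert np.all(np.diff(lk.fraction_on) >= 0)

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            cob.build_ptot_lookup(grid=np.array([0.0, 0.06]))

    def test_estimate_inverts_the_table(self):
        grid = np.linspace(0.0, 0.05, 501)
        lk = cob.build_ptot_lookup(grid=grid, n_traj=4000, seed=3)
        assert cob.estimate_ptot(0.0, lk) == 0.0
        assert cob.estimate_ptot(0.632, lk) == pytest.approx(PD, rel=0.1)
        # round trip: propensity → fraction → propensity
        for p in (0.25 * PD, PD, 3 * PD):
            f = 1.0 - np.exp(-p / PD)
            assert cob.estimate_ptot(f, lk) == pytest.approx(
                p, abs=3 * (grid[1] - grid[0])
            )

    def test_fraction_above_table_clamps_with_warning(self):
        lk = cob.PtotLookup(
            np.array([0.0, 0.001]), np.array([0.0, 0.5]), PD, 10, 100.0
        )
        with pytest.warns(UserWarning, match="exceeds"):
            assert cob.estimate_ptot(0.9, lk) == 0.001

    def test_invalid_fraction_rejected(self):
        lk = cob.build_ptot_lookup(n_traj=100, seed=0)
        with pytest.raises(ValueError):
            cob.estimate_ptot(1.5, lk)


class TestLifetimes:
    def test_mean_dwell_time(self):
        life = cob.sample_lifetimes(50_000, seed=4)
        assert life.mean() == pytest.approx(800.0, rel=0.02)


class TestResolutionError:
    def test_sigma_zero_identity(self):
        r = np.array([0.0, 123.0, 456.0])
        np.testing.assert_array_equal(cob.apply_resolution_error(r, 0.0, seed=0), r)

    def test_moment_identity(self):
        r = cob.apply_resolution_error(np.full(60_000, 400.0), 100.0, seed=5)
        se = (r**2).std() / np.sqrt(r.size)
        assert abs((r**2).mean() - (400.0**2 + 6 * 100.0**2)) < 4 * se

    def test_zero_distance_chi_mean(self):
        r = cob.apply_resolution_error(np.zeros(60_000), 100.0, seed=6)
        expect = np.sqrt(2) * 100.0 * stats.chi(3).mean()  # ≈ 225.7 nm
        assert r.mean() == pytest.approx(expect, rel=0.01)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cob.apply_resolution_error(np.array([-1.0]), 100.0)


def _static_cfg(p_i, p_j, omega, n_traj, seed, **kw):
    return cob.PairSimConfig(
        p_i_tot=p_i,
        p_j_tot=p_j,
        omega=omega,
        n_traj=n_traj,
        distance_source="static",
        resolution_sigma=None,
        seed=seed,
        **kw,
    )


class TestPairSimulation:
    def test_uncoupled_genes_are_independent(self):
        cfg = _static_cfg(PD, PD, CouplingFunction.zero(), 20_000, seed=7)
        res = cob.simulate_pair_ensemble(cfg, static_distances=np.full(20_000, 100.0))
        assert abs(cx.phi_binary(res["state_i"], res["state_j"])) < 3 / np.sqrt(20_000)

    def test_zero_propensities_always_off(self):
        cfg = _static_cfg(0.0, 0.0, CouplingFunction.zero(), 500, seed=8)
        res = cob.simulate_pair_ensemble(cfg, static_distances=np.full(500, 100.0))
        assert res["state_i"].sum() == 0 and res["state_j"].sum() == 0

    def test_full_coupling_matches_brute_force_oracle(self):
        """ω ≡ 1 with equal propensities: every burst is shared.  The
        independent oracle samples shared Poisson birth times with a fresh
        exponential lifetime per gene copy."""
        n, T, p = 30_000, 15_000.0, PD
        rng = np.random.default_rng(9)
        on_i = np.zeros(n, dtype=int)
        on_j = np.zeros(n, dtype=int)
        for k in range(n):
            times = rng.uniform(0, T, rng.poisson(p * T))
            on_i[k] = np.any(rng.exponential(800.0, times.size) > T - times)
            on_j[k] = np.any(rng.exponential(800.0, times.size) > T - times)
        phi_oracle = cx.phi_binary(on_i, on_j)

        cfg = _static_cfg(p, p, CouplingFunction(np.ones(7)), n, seed=10)
        res = cob.simulate_pair_ensemble(cfg, static_distances=np.full(n, 50.0))
        phi_engine = cx.phi_binary(res["state_i"], res["state_j"])
        assert phi_engine == pytest.approx(phi_oracle, abs=0.02)
        assert res["state_i"].mean() == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_exchangeable_after_propensity_swap(self):
        om = CouplingFunction(np.full(7, 0.5))
        a = cob.simulate_pair_ensemble(
            _static_cfg(PD, 2 * PD, om, 2000, seed=11),
            static_distances=np.full(2000, 100.0),
        )
        b = cob.simulate_pair_ensemble(
            _static_cfg(2 * PD, PD, om, 2000, seed=11),
            static_distances=np.full(2000, 100.0),
        )
        np.testing.assert_array_equal(a["state_i"], b["state_i"])
        np.testing.assert_array_equal(a["state_j"], b["state_j"])

    def test_vectorized_engine_agrees_with_gillespie(self):
        """Dual-route check on a piecewise-constant distance path: exact
        event-driven simulation vs the Poisson-stream engine."""
        om = CouplingFunction(np.array([0.6, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0]))
        # distance jumps from 100 nm to 900 nm halfway through
        dt = 7500.0
        r_traj = np.array([100.0, 900.0, 900.0])
        n = 3000
        cfg = cob.PairSimConfig(
            p_i_tot=0.8 * PD,
            p_j_tot=1.4 * PD,
            omega=om,
            n_traj=1,
            distance_source="static",
            resolution_sigma=None,
            dt=dt,
        )
        rng = np.random.default_rng(12)
        g = np.array(
            [cob.simulate_pair_gillespie(cfg, r_traj, rng) for _ in range(n)]
        )
        v = np.array([cob.simulate_pair(cfg, r_traj, rng) for _ in range(n)])
        for col in (0, 1):
            pg, pv = g[:, col].mean(), v[:, col].mean()
            se = np.sqrt(pg * (1 - pg) / n + pv * (1 - pv) / n)
            assert abs(pg - pv) < 4 * se
        phi_g = cx.phi_binary(g[:, 0], g[:, 1])
        phi_v = cx.phi_binary(v[:, 0], v[:, 1])
        assert phi_g == pytest.approx(phi_v, abs=4 * np.sqrt(2.0 / n))

    def test_marginal_on_fraction_unchanged_by_coupling(self):
        """Eqs. of the propensity split conserve each gene's total burst
        rate, so coupling must not move the marginals."""
        om = CouplingFunction(np.full(7, 0.8))
        cfg = _static_cfg(0.5 * PD, 1.5 * PD, om, 30_000, seed=13)
        res = cob.simulate_pair_ensemble(
            cfg, static_distances=np.full(30_000, 100.0)
        )
        for state, p in ((res["state_i"], 0.5 * PD), (res["state_j"], 1.5 * PD)):
            expect = 1 - np.exp(-p / PD)
            assert state.mean() == pytest.approx(expect, abs=0.012)

    def test_distance_trajectory_must_cover_horizon(self):
        cfg = cob.PairSimConfig(p_i_tot=PD, p_j_tot=PD, dt=1.0)
        with pytest.raises(ConfigurationError, match="cover"):
            cob.simulate_pair(cfg, np.zeros(100))

    def test_deterministic_on_time_boosts_coupling(self):
        om = CouplingFunction(np.full(7, 0.5))
        base = _static_cfg(PD, PD, om, 30_000, seed=14)
        det = _static_cfg(
            PD, PD, om, 30_000, seed=14, deterministic_on_time=800.0
        )
        r = np.full(30_000, 100.0)
        phi_sto = cx.phi_binary(
            *(lambda d: (d["state_i"], d["state_j"]))(
                cob.simulate_pair_ensemble(base, static_distances=r)
            )
        )
        phi_det = cx.phi_binary(
            *(lambda d: (d["state_i"], d["state_j"]))(
                cob.simulate_pair_ensemble(det, static_distances=r)
            )
        )
        assert phi_det > phi_sto + 0.1


class TestOmegaFit:
    def _pair_from_model(self, omega, n_chrom, seed, dist, p_i=0.4 * PD, p_j=0.6 * PD):
        cfg = cob.PairSimConfig(
            p_i_tot=p_i,
            p_j_tot=p_j,
            omega=omega,
            n_traj=n_chrom,
            distance_source="static",
            resolution_sigma=None,
            seed=seed,
        )
        res = cob.simulate_pair_ensemble(cfg, distance_dist=dist)
        phi_obs, _ = cx.binned_phi(
            res["state_i"], res["state_j"], res["r_obs_end"], n_bins=7
        )
        return cob.GenePairData(phi_obs, p_i, p_j, dist)

    def test_exhaustive_search_not_worse_than_greedy(self):
        om = CouplingFunction(np.array([0.4, 0.2, 0.0]), bin_width=200.0)
        dist = chi_dist(300, 1)
        pairs = [
            self._pair_from_model(om, 6000, s, dist) for s in (21, 22)
        ]
        base = dict(
            n_bins=3, n_traj=6000, seed=3, resolution_sigma=None,
            refine_step=0.1,  # skip the 0.05 stage to compare coarse optima
        )
        greedy = cob.fit_omega(pairs, cob.OmegaSearchConfig(**base))
        full = cob.fit_omega(
            pairs, cob.OmegaSearchConfig(**base, exhaustive_max_bins=3)
        )
        assert full.error <= greedy.error + 1e-9

    def test_empty_experimental_curves_rejected(self):
        pair = cob.GenePairData(
            np.full(7, np.nan), 0.4 * PD, 0.6 * PD, chi_dist(300, 1)
        )
        with pytest.raises(ValueError):
            cob.fit_omega([pair])

    def test_fitted_omega_is_monotone_and_bounded(self):
        om = CouplingFunction(np.array([0.4, 0.4, 0, 0, 0, 0, 0.0]))
        dist = chi_dist(300, 1)
        pairs = [self._pair_from_model(om, 5000, s, dist) for s in (31, 32)]
        fit = cob.fit_omega(
            pairs,
            cob.OmegaSearchConfig(n_traj=8000, seed=4, resolution_sigma=None),
        )
        vals = fit.omega.values
        assert np.all(np.diff(vals) <= 1e-12)
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestNoiseRemoval:
    def test_unknown_variant_rejected(self):
        pair = cob.GenePairData(np.zeros(7), 0.4 * PD, 0.6 * PD, chi_dist(300, 1))
        with pytest.raises(ValueError, match="unknown variant"):
            cob.noise_removal_experiments(
                CouplingFunction.zero(), [pair], variants=("nope",)
            )

    def test_null_coupling_gives_null_curves(self):
        pair = cob.GenePairData(
            np.full(7, np.nan), 0.4 * PD, 0.6 * PD, chi_dist(300, 1)
        )
        search = cob.OmegaSearchConfig(n_traj=4000, T=3000.0, seed=5)
        out = cob.noise_removal_experiments(
            CouplingFunction.zero(), [pair], search, seed=6
        )
        for variant in cob.NOISE_VARIANTS:
            curve = out[variant]["mean_phi"]
            good = ~np.isnan(curve)
            assert np.all(np.abs(curve[good]) < 0.06)


class TestConfigValidation:
    def test_negative_propensity_rejected(self):
        with pytest.raises(ConfigurationError):
            cob.PairSimConfig(p_i_tot=-1.0, p_j_tot=1.0)

    def test_coupling_function_invariants(self):
        with pytest.raises(ConfigurationError):
            CouplingFunction(np.array([0.2, 0.5]))  # increasing
        with pytest.raises(ConfigurationError):
            CouplingFunction(np.array([1.2]))  # out of range
        om = CouplingFunction(np.array([0.4, 0.1]), bin_width=200.0)
        np.testing.assert_allclose(om([50.0, 250.0, 900.0]), [0.4, 0.1, 0.0])
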