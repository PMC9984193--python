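"""Ground-truth properties of the synthetic generators: chain scaling,
planted activity marginals, Brownian tracks and localization noise."""

import numpy as np
import pytest
from scipy import stats

from chromaburst import cobursting, synthetic
from chromaburst.datatypes import ConfigurationError, CouplingFunction
from chromaburst import coexpression as cx


class TestPolymerTraces:
    def test_zero_chromosomes_empty_set_with_loci_defined(self):
        cfg = synthetic.SyntheticConfig(n_chromosomes=0, n_loci=10)
        traces = synthetic.generate_polymer_traces(cfg)
        assert traces.n_chromosomes == 0 and traces.n_loci == 10

    def test_no_missing_and_positive_distances(self):
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=5, n_loci=6, missing_rate=0.0, rng_seed=1
        )
        traces = synthetic.generate_polymer_traces(cfg)
        assert traces.observed.all()
        for i in range(6):
            for j in range(i + 1, 6):
                assert np.all(traces.pair_distances(i, j) > 0)

    def test_random_walk_scaling_exponent_half(self):
        """Median distance vs genomic separation fits exponent ≈ 0.5 over
        1–100 bins — the freely-jointed chain's closed-form scaling."""
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=2000, n_loci=101, missing_rate=0.0, rng_seed=2
        )
        traces = synthetic.generate_polymer_traces(cfg)
        seps = np.array([1, 2, 4, 8, 16, 32, 64, 100])
        med = [
            np.median(traces.pair_distances(0, s)) for s in seps
        ]
        slope = np.polyfit(np.log(seps), np.log(med), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.03)

    def test_bit_reproducible_under_seed(self):
        cfg = synthetic.SyntheticConfig(n_chromosomes=4, n_loci=8, rng_seed=9)
        a = synthetic.generate_polymer_traces(cfg)
        b = synthetic.generate_polymer_traces(cfg)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_missing_rate_realized(self):
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=200, n_loci=50, missing_rate=0.2, rng_seed=3
        )
        traces = synthetic.generate_polymer_traces(cfg)
        assert (~traces.observed).mean() == pytest.approx(0.2, abs=0.02)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.SyntheticConfig(n_chromosomes=-1)
        with pytest.raises(ConfigurationError):
            synthetic.SyntheticConfig(n_chromosomes=1, missing_rate=1.5)
        with pytest.raises(ConfigurationError):
            synthetic.SyntheticConfig(
                n_chromosomes=1, n_loci=5, gene_promoter_loci=[7], gene_ptot=[0.1]
            )


class TestGeneActivity:
    def test_marginal_on_fraction_matches_birth_death_law(self):
        """P(on) = 1 − exp(−P_tot/Pd) within 3 standard errors, for both
        paired and independent genes."""
        pd_ = cobursting.PD_DEFAULT
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=2000,
            n_loci=6,
            missing_rate=0.0,
            gene_promoter_loci=[0, 2, 4],
            gene_ptot=[pd_, 0.5 * pd_, 2.0 * pd_],
            omega_true=CouplingFunction(np.full(7, 0.3)),
            coburst_pairs=[(0, 1)],
            rng_seed=5,
        )
        traces = synthetic.generate_polymer_traces(cfg)
        activity = synthetic.generate_gene_activity(traces, cfg)
        occ = activity.fractional_occupancy()
        for k, p in enumerate(cfg.gene_ptot):
            expect = 1.0 - np.exp(-p / pd_)
            se = np.sqrt(expect * (1 - expect) / 2000)
            assert abs(occ[k] - expect) < 3 * se

    def test_uncoupled_pair_phi_is_null(self):
        cfg = synthetic.coburst_study_config(n_chromosomes=2000, rng_seed=6)
        traces = synthetic.generate_polymer_traces(cfg)
        activity = synthetic.generate_gene_activity(traces, cfg)
        for gi, gj in cfg.coburst_pairs:
            phi = cx.phi_binary(activity.states[:, gi], activity.states[:, gj])
            assert abs(phi) < 3.0 / np.sqrt(2000)

    def test_short_range_coupling_raises_phi_at_short_distances(self):
        omega = CouplingFunction(np.array([0.4, 0.4, 0, 0, 0, 0, 0.0]))
        cfg = synthetic.coburst_study_config(
            n_chromosomes=4000, omega_true=omega, rng_seed=7
        )
        traces = synthetic.generate_polymer_traces(cfg)
        activity = synthetic.generate_gene_activity(traces, cfg)
        gi, gj = cfg.coburst_pairs[0]
        d = traces.pair_distances(
            cfg.gene_promoter_loci[gi], cfg.gene_promoter_loci[gj]
        )
        phi, n = cx.binned_phi(
            activity.states[:, gi], activity.states[:, gj], d, min_count=50
        )
        beyond = phi[3:][~np.isnan(phi[3:])]
        assert phi[0] > (beyond.max() if beyond.size else 0.05)

    def test_negative_propensity_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.SyntheticConfig(
                n_chromosomes=1, n_loci=4, gene_promoter_loci=[0], gene_ptot=[-1.0]
            )


class TestAlleleTrajectories:
    def test_zero_diffusion_static_positions(self):
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=0, n_loci=2, diffusion_coeff=0.0, rng_seed=1
        )
        trajs = synthetic.generate_allele_trajectories(
            cfg, n_cells=2, duration=100.0, dt=10.0
        )
        for cell in trajs.cells:
            for _, _, xy in trajs.tracks(cell):
                assert np.ptp(xy, axis=0).max() == 0.0

    def test_single_track_msd_slope(self):
        """MSD of one 2D Brownian track ≈ 4 D Δt (closed form)."""
        cfg = synthetic.SyntheticConfig(n_chromosomes=0, n_loci=2, rng_seed=2)
        trajs = synthetic.generate_allele_trajectories(
            cfg, n_cells=50, duration=2000.0, dt=10.0
        )
        d_nm = cfg.diffusion_coeff * 1e6
        disp2 = []
        for cell in trajs.cells:
            for _, t, xy in trajs.tracks(cell):
                d = xy[1:] - xy[:-1]
                disp2.append((d**2).sum(axis=1))
        mean_step = np.concatenate(disp2).mean()
        assert mean_step == pytest.approx(4 * d_nm * 10.0, rel=0.05)

    def test_relative_track_msd_slope_doubles(self):
        cfg = synthetic.SyntheticConfig(n_chromosomes=0, n_loci=2, rng_seed=3)
        trajs = synthetic.generate_allele_trajectories(
            cfg, n_cells=60, duration=1500.0, dt=10.0
        )
        d_nm = cfg.diffusion_coeff * 1e6
        steps = []
        for cell in trajs.cells:
            tracks = list(trajs.tracks(cell))
            rel = tracks[0][2] - tracks[1][2]
            d = rel[1:] - rel[:-1]
            steps.append((d**2).sum(axis=1))
        assert np.concatenate(steps).mean() == pytest.approx(
            8 * d_nm * 10.0, rel=0.05
        )

    def test_duration_must_exceed_dt(self):
        cfg = synthetic.SyntheticConfig(n_chromosomes=0, n_loci=2)
        with pytest.raises(ConfigurationError):
            synthetic.generate_allele_trajectories(cfg, 1, duration=5.0, dt=10.0)


class TestLocalizationNoise:
    def test_sigma_zero_identity(self):
        cfg = synthetic.SyntheticConfig(n_chromosomes=3, n_loci=5, rng_seed=4)
        traces = synthetic.generate_polymer_traces(cfg)
        noisy = synthetic.add_localization_noise(traces, 0.0, seed=0)
        np.testing.assert_array_equal(noisy.coords, traces.coords)

    def test_negative_sigma_rejected(self):
        cfg = synthetic.SyntheticConfig(n_chromosomes=1, n_loci=3, rng_seed=4)
        traces = synthetic.generate_polymer_traces(cfg)
        with pytest.raises(ValueError):
            synthetic.add_localization_noise(traces, -1.0)

    def test_pairwise_distance_moment_identity(self):
        """E[r_obs²] = r_true² + 6σ² — per-axis displacement noise has
        variance 2σ² and there are three axes."""
        n = 40_000
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 700.0
        traces = synthetic.LocusTraceSet(
            coords,
            np.arange(2, dtype=np.int64) * 50_000,
            np.array([f"c{k}" for k in range(n)]),
        )
        noisy = synthetic.add_localization_noise(traces, 100.0, seed=8)
        r2 = noisy.pair_distances(0, 1) ** 2
        se = r2.std() / np.sqrt(n)
        assert abs(r2.mean() - (700.0**2 + 6 * 100.0**2)) < 4 * se

    def test_coincident_loci_mean_observed_distance(self):
        """r_true = 0, σ = 100 → mean r_obs is the chi(3) mean with scale
        √2·σ ≈ 225.7 nm."""
        n = 40_000
        coords = np.zeros((n, 2, 3))
        traces = synthetic.LocusTraceSet(
            coords,
            np.arange(2, dtype=np.int64) * 50_000,
            np.array([f"c{k}" for k in range(n)]),
        )
        noisy = synthetic.add_localization_noise(traces, 100.0, seed=9)
        r = noisy.pair_distances(0, 1)
        expect = np.sqrt(2) * 100.0 * stats.chi(3).mean()
        assert r.mean() == pytest.approx(expect, rel=0.01)
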