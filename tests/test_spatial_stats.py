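"""Hand-computed examples and invariances of the fixed-cell spatial
statistics."""

import numpy as np
import pytest

from conftest import make_activity

from chromaburst import spatial_stats as sps
from chromaburst import synthetic
from chromaburst.datatypes import LocusTraceSet


def traces_from_x(x_rows):
    """Traces with all loci on the x axis; one row per chromosome copy."""
    x = np.asarray(x_rows, dtype=float)
    coords = np.zeros((x.shape[0], x.shape[1], 3))
    coords[:, :, 0] = x
    return LocusTraceSet(
        coords=coords,
        genomic_start=np.arange(x.shape[1], dtype=np.int64) * 50_000,
        chromosome_ids=np.array([f"c{k}" for k in range(x.shape[0])]),
    )


class TestStateConditionedMatrix:
    def test_identical_chromosomes_have_zero_std(self):
        traces = traces_from_x([[0, 300, 600], [0, 300, 600]])
        activity = make_activity([[1], [1]], promoters=[1])
        m = sps.state_conditioned_matrix(traces, activity, 0, 1, "std")
        np.testing.assert_allclose(m.values, 0.0)

    def test_population_std_of_two_distances(self):
        # pair (0,1) distances 400 and 600 across the two copies
        traces = traces_from_x([[0, 400, 800], [0, 600, 1200]])
        activity = make_activity([[0], [0]], promoters=[0])
        m = sps.state_conditioned_matrix(traces, activity, 0, 0, "std")
        assert m.values[0, 1] == pytest.approx(100.0)

    def test_median_of_three_distances(self):
        traces = traces_from_x([[0, 100], [0, 200], [0, 900]])
        activity = make_activity([[1], [1], [1]], promoters=[0])
        m = sps.state_conditioned_matrix(traces, activity, 0, 1, "median")
        assert m.values[0, 1] == pytest.approx(200.0)

    def test_empty_state_class_raises_with_gene_name(self):
        traces = traces_from_x([[0, 100], [0, 200]])
        activity = make_activity([[1], [1]], promoters=[0], gene_ids=["myc"])
        with pytest.raises(ValueError, match="myc"):
            sps.state_conditioned_matrix(traces, activity, "myc", 0)

    def test_symmetry_and_chromosome_order_invariance(self, rng):
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=40, n_loci=8, missing_rate=0.2, rng_seed=5
        )
        traces = synthetic.generate_polymer_traces(cfg)
        m = sps.distance_summary_matrix(traces, "median", min_count=2)
        np.testing.assert_allclose(m.values, m.values.T, equal_nan=True)
        perm = rng.permutation(40)
        shuffled = LocusTraceSet(
            traces.coords[perm],
            traces.genomic_start,
            traces.chromosome_ids[perm],
        )
        m2 = sps.distance_summary_matrix(shuffled, "median", min_count=2)
        np.testing.assert_allclose(m.values, m2.values, equal_nan=True)


class TestCenteredMetagene:
    def test_single_gene_map_is_its_own_centered_matrix(self):
        vals = np.arange(25, dtype=float).reshape(5, 5)
        vals = (vals + vals.T) / 2
        m = sps.DistanceSummaryMatrix(vals, np.full((5, 5), 10), "median")
        out = sps.centered_metagene({0: [m], 1: [m]}, [2], K=1)
        np.testing.assert_allclose(out.mean_map[0], vals[1:4, 1:4])
        np.testing.assert_allclose(out.difference_map, 0.0)

    def test_constant_offset_propagates_linearly(self):
        vals = np.random.default_rng(0).random((5, 5))
        vals = (vals + vals.T) / 2
        m0 = sps.DistanceSummaryMatrix(vals, np.full((5, 5), 9), "median")
        m1 = sps.DistanceSummaryMatrix(vals + 7.0, np.full((5, 5), 9), "median")
        out = sps.centered_metagene({0: [m0, m0], 1: [m1, m1]}, [2, 2], K=1)
        np.testing.assert_allclose(out.difference_map, -7.0)

    def test_offsets_beyond_chromosome_are_truncated_not_errors(self):
        vals = np.ones((3, 3))
        m = sps.DistanceSummaryMatrix(vals, np.full((3, 3), 5), "median")
        out = sps.centered_metagene({0: [m]}, [0], K=2)
        # offsets reaching locus -2,-1 contribute nothing
        assert np.isnan(out.mean_map[0][0, 0])
        assert out.n_genes[0][2, 2] == 1

    def test_shuffled_states_give_null_difference_map(self, rng):
        cfg = synthetic.SyntheticConfig(
            n_chromosomes=400,
            n_loci=9,
            missing_rate=0.0,
            gene_promoter_loci=[4],
            gene_ptot=[0.7 * synthetic.cobursting.PD_DEFAULT],
            rng_seed=3,
        )
        traces = synthetic.generate_polymer_traces(cfg)
        activity = synthetic.generate_gene_activity(traces, cfg)
        # shuffle state labels: difference map should be zero within noise
        shuffled = make_activity(
            rng.permutation(activity.states[:, 0])[:, None], promoters=[4]
        )
        mats = {
            s: [sps.state_conditioned_matrix(traces, shuffled, 0, s, "median")]
            for s in (0, 1)
        }
        out = sps.centered_metagene(mats, [4], K=2)
        vals = out.difference_map[~np.isnan(out.difference_map)]
        # typical inter-locus distances are hundreds of nm; the permuted
        # difference should be consistent with zero
        assert np.abs(vals).max() < 120.0


class TestCentroidDistance:
    def _traces_and_activity(self, promoter):
        traces = traces_from_x([[0, 300, 600]])
        activity = make_activity([[1]], promoters=[promoter])
        return traces, activity

    def test_promoter_at_centroid_gives_zero(self):
        traces, activity = self._traces_and_activity(1)
        assert sps.centroid_distance(traces, activity, 0, 0.2, 1) == pytest.approx(0.0)

    def test_promoter_at_chain_end(self):
        traces, activity = self._traces_and_activity(0)
        # window covers all three loci; centroid at x=300
        assert sps.centroid_distance(traces, activity, 0, 0.2, 1) == pytest.approx(
            300.0
        )

    def test_window_must_cover_a_bin(self):
        traces, activity = self._traces_and_activity(1)
        with pytest.raises(ValueError):
            sps.centroid_distance(traces, activity, 0, 0.01, 1)

    def test_active_genes_sit_closer_to_centroid_when_planted(self):
        """Constructed repositioning: active copies are compressed toward
        the local centroid, and the statistic picks the direction up."""
        rng = np.random.default_rng(8)
        n = 300
        coords = rng.normal(0, 400, size=(n, 7, 3)).cumsum(axis=1)
        states = (rng.random(n) < 0.5).astype(float)
        centered = coords - coords.mean(axis=1, keepdims=True)
        coords[states == 1] = 0.6 * centered[states == 1]
        traces = LocusTraceSet(
            coords,
            np.arange(7, dtype=np.int64) * 50_000,
            np.array([f"c{k}" for k in range(n)]),
        )
        activity = make_activity(states[:, None], promoters=[3])
        d_on = sps.centroid_distance(traces, activity, 0, 0.3, 1)
        d_off = sps.centroid_distance(traces, activity, 0, 0.3, 0)
        assert d_on < d_off


class TestPromoterPairDistance:
    def test_mean_and_pooling(self):
        traces = traces_from_x([[0, 500], [0, 700], [0, 900]])
        activity = make_activity(
            [[1, 1], [1, 1], [0, 1]], promoters=[0, 1]
        )
        mean, n = sps.promoter_pair_distance(traces, activity, 0, 1, (1, 1))
        assert (mean, n) == (pytest.approx(600.0), 2)
        mean01, n01 = sps.promoter_pair_distance(traces, activity, 0, 1, (0, 1))
        assert (mean01, n01) == (pytest.approx(900.0), 1)

    def test_empty_class_returns_missing_not_error(self):
        traces = traces_from_x([[0, 500]])
        activity = make_activity([[0, 0]], promoters=[0, 1])
        mean, n = sps.promoter_pair_distance(traces, activity, 0, 1, (1, 1))
        assert np.isnan(mean) and n == 0


class TestExpectedMPD:
    def _mpd(self):
        traces = traces_from_x(
            [[0, 200, 500, 900], [0, 240, 560, 1000]]
        )
        return sps.distance_summary_matrix(traces, "median", min_count=1)

    def test_forward_map_matches_enumeration(self):
        m = self._mpd()
        seps, means = sps.expected_mpd(m)
        # brute force: average the median-matrix diagonals directly
        for s_bp, mean in zip(seps, means):
            k = s_bp // 50_000
            diag = np.diagonal(m.values, offset=k)
            assert mean == pytest.approx(np.nanmean(diag))

    def test_round_trip_on_exact_values(self):
        seps, means = sps.expected_mpd(self._mpd())
        for s, mu in zip(seps, means):
            assert sps.expected_genomic_distance((seps, means), mu) == s

    def test_tie_breaks_to_smaller_separation(self):
        curve = (np.array([50_000, 100_000]), np.array([400.0, 600.0]))
        assert sps.expected_genomic_distance(curve, 500.0) == 50_000

    def test_out_of_range_clamps_to_endpoint(self):
        curve = (np.array([50_000, 100_000]), np.array([400.0, 600.0]))
        assert sps.expected_genomic_distance(curve, 10_000.0) == 100_000


class TestContactFrequency:
    def test_strict_threshold_counting(self):
        traces = traces_from_x([[0, 150], [0, 250], [0, 199], [0, 201]])
        f = sps.contact_frequency(traces, 0, 1, threshold=200.0)
        assert f == pytest.approx(0.5)

    def test_all_below_gives_one_and_zero_threshold_gives_zero(self):
        traces = traces_from_x([[0, 10], [0, 20]])
        assert sps.contact_frequency(traces, 0, 1) == 1.0
        assert sps.contact_frequency(traces, 0, 1, threshold=0.0) == 0.0

    def test_no_observable_chromosome_is_an_error(self):
        traces = traces_from_x([[0, 100]])
        traces.coords[0, 1] = np.nan
        with pytest.raises(ValueError):
            sps.contact_frequency(traces, 0, 1)


class TestPartitions:
    def test_median_split_with_ties_to_low(self):
        states = np.array(
            [[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 1], [0, 1, 1, 1], [1, 1, 1, 1]],
            dtype=float,
        )  # occupancies .2 .4 .6 .8
        activity = make_activity(states)
        groups = sps.partition_genes_by_activity(activity)
        assert list(groups["low"]) == [0, 1] and list(groups["high"]) == [2, 3]

    def test_all_equal_occupancy_all_low(self):
        activity = make_activity(np.ones((4, 3)))
        groups = sps.partition_genes_by_activity(activity)
        assert list(groups["low"]) == [0, 1, 2] and groups["high"].size == 0

    def test_density_quartiles_match_rank_oracle(self, rng):
        density = rng.random(40)
        labels = sps.partition_loci_by_density(density)
        order = np.argsort(density, kind="stable")
        expected = np.empty(40, dtype=object)
        for pos, idx in enumerate(order):
            expected[idx] = sps.DENSITY_LABELS[min(pos // 10, 3)]
        assert list(labels) == list(expected)

    def test_eight_distinct_values_two_per_group(self):
        labels = sps.partition_loci_by_density(np.arange(8.0))
        counts = {lab: (labels == lab).sum() for lab in sps.DENSITY_LABELS}
        assert all(c == 2 for c in counts.values())

    def test_constant_density_single_group(self):
        labels = sps.partition_loci_by_density(np.full(6, 3.3))
        assert set(labels) == {"low"}


class TestResamplingHelpers:
    def test_constant_vector_sem_zero(self):
        assert sps.bootstrap_sem(np.full(10, 2.0), seed=0) == 0.0

    def test_gaussian_sem_close_to_closed_form(self, rng):
        x = rng.normal(0, 3.0, size=400)
        sem = sps.bootstrap_sem(x, n_boot=2000, seed=1)
        assert sem == pytest.approx(x.std(ddof=1) / 20.0, rel=0.15)

    def test_identical_samples_p_near_one(self):
        a = np.arange(10.0)
        assert sps.two_sample_test(a, a) == pytest.approx(1.0)

    def test_too_small_samples_raise(self):
        with pytest.raises(ValueError):
            sps.bootstrap_sem([1.0])
        with pytest.raises(ValueError):
            sps.two_sample_test([1.0], [1.0, 2.0])
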