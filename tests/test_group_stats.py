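"""Inference procedures: INT, t-tests, corrections, bootstrap AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fcnet.connectivity import ConnectivityMatrix, compute_fc
from fcnet.graph import DensityGrid
from fcnet.stats import (
    BootstrapConfig,
    bonferroni,
    bootstrap_mean_matrices,
    compare_edges,
    compare_graph_metrics,
    compare_networks,
    fdr_bh,
    inverse_normal_transform,
    two_sample_t,
    two_sample_t_from_summary,
)
from fcnet.synthetic import (
    GroupDesign,
    ModularCovSpec,
    sample_group_dataset,
    spec_atlas,
)

from conftest import symmetric_matrix


class TestInverseNormalTransform:
    def test_median_maps_to_zero(self):
        y = inverse_normal_transform([10.0, 3.0, 7.0, 1.0, 5.0])
        assert y[np.argsort([10, 3, 7, 1, 5])[2]] == pytest.approx(0.0, abs=1e-12)

    def test_three_values_blom(self):
        y = inverse_normal_transform([1.0, 2.0, 3.0])
        expected = sps.norm.ppf((np.array([1, 2, 3]) - 3 / 8) / 3.25)
        assert np.allclose(y, expected)
        assert y[0] == pytest.approx(-0.869, abs=1e-3)
        assert y[1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(y, -y[::-1])  # symmetric about zero

    def test_ties_get_average_ranks(self):
        y = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert y[1] == y[2]
        assert y[0] < y[1] < y[3]

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            inverse_normal_transform([2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3, max_size=40, unique=True,
        )
    )
    def test_preserves_rank_order_and_centers(self, xs):
        x = np.asarray(xs)
        y = inverse_normal_transform(x)
        assert np.array_equal(np.argsort(x), np.argsort(y))
        assert abs(y.mean()) < 1e-8
        if len(xs) >= 8:
            assert abs(sps.skew(y)) < 1e-8  # quantile symmetry kills skewness


class TestTwoSampleT:
    def test_identical_groups_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(x, x)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_age_summary_statistics(self):
        # group summaries n=15/15, 39.5 +- 11.6 vs 33.5 +- 8.5
        res = two_sample_t_from_summary(15, 39.5, 11.6, 15, 33.5, 8.5)
        assert res.t == pytest.approx(1.61, abs=0.01)
        assert res.p == pytest.approx(0.12, abs=0.005)
        assert res.df == 28

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(2, 30))
            y = rng.standard_normal(rng.integers(2, 30)) + rng.uniform(-1, 1)
            ours = two_sample_t(x, y)
            ref_t, ref_p = sps.ttest_ind(x, y, equal_var=True)
            assert ours.t == pytest.approx(ref_t, abs=1e-10)
            assert ours.p == pytest.approx(ref_p, abs=1e-10)

    def test_raw_equals_summary_route(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(12), rng.standard_normal(9) + 0.3
        a = two_sample_t(x, y)
        b = two_sample_t_from_summary(
            len(x), x.mean(), x.std(ddof=1), len(y), y.mean(), y.std(ddof=1)
        )
        assert a.t == pytest.approx(b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestCorrections:
    def test_bonferroni_network_family_of_seven(self):
        _, threshold = bonferroni(np.full(7, 0.5), m=7, alpha=0.05)
        assert threshold == pytest.approx(0.05 / 7)
        assert round(threshold, 3) == 0.007

    def test_bonferroni_identity_and_family_of_three(self):
        p = np.array([0.02, 0.8])
        corrected, _ = bonferroni(p, m=1)
        assert np.array_equal(corrected, p)
        _, thr3 = bonferroni(p, m=3, alpha=0.05)
        assert thr3 == pytest.approx(0.0167, abs=1e-4)

    def test_bonferroni_caps_at_one(self):
        corrected, _ = bonferroni([0.4], m=5)
        assert corrected[0] == 1.0

    def test_fdr_bh_step_up_hand_case(self):
        reject, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_fdr_bh_all_zero_and_single(self):
        reject, _ = fdr_bh(np.zeros(4), q=0.05)
        assert reject.all()
        reject, adj = fdr_bh(np.array([0.03]), q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.03)

    def test_fdr_rejects_at_least_as_much_as_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0, 1, size=15) ** 2
            bh_reject, _ = fdr_bh(p, q=0.05)
            bonf_p, _ = bonferroni(p, m=p.size)
            assert bh_reject.sum() >= (bonf_p < 0.05).sum()


def _cm(z, sid="s"):
    return ConnectivityMatrix(z=z, parcel_ids=tuple(map(str, range(z.shape[0]))), subject_id=sid)


class TestBootstrapMeanMatrices:
    def test_identical_matrices_reproduce_themselves(self):
        z = symmetric_matrix(5, seed=0)
        boots = bootstrap_mean_matrices([_cm(z, "a"), _cm(z, "b"), _cm(z, "c")], 10, seed=1)
        assert boots.shape == (10, 5, 5)
        assert np.allclose(boots, z)

    def test_deterministic_and_replicate_addressable(self):
        group = [_cm(symmetric_matrix(5, seed=s), str(s)) for s in range(4)]
        a = bootstrap_mean_matrices(group, 8, seed=3)
        b = bootstrap_mean_matrices(group, 8, seed=3)
        assert np.array_equal(a, b)
        # replicate b depends only on (seed, b): a shorter run is a prefix
        c = bootstrap_mean_matrices(group, 3, seed=3)
        assert np.array_equal(a[:3], c)

    def test_replicate_mean_converges_to_group_mean(self):
        group = [_cm(symmetric_matrix(6, seed=s), str(s)) for s in range(5)]
        target = np.mean([cm.z for cm in group], axis=0)
        boots = bootstrap_mean_matrices(group, 2000, seed=0)
        assert np.abs(boots.mean(axis=0) - target).max() < 0.05


def _small_design(seed, control_within=0.5, case_within=0.1):
    shared = dict(n_parcels=12, n_modules=3, between_r=0.05, n_timepoints=200)
    return GroupDesign(
        control_spec=ModularCovSpec.balanced(within_r=control_within, **shared),
        case_spec=ModularCovSpec.balanced(within_r=case_within, **shared),
        n_per_group=5,
        seed=seed,
    )


def _fc_groups(design):
    controls, cases = sample_group_dataset(design)
    return [compute_fc(t) for t in controls], [compute_fc(t) for t in cases]


SMALL_GRID = DensityGrid.from_range(0.15, 0.35, 0.05)


class TestCompareGraphMetrics:
    def test_identical_groups_give_small_t(self):
        """Same matrices on both sides: only bootstrap noise separates them."""
        hits = 0
        for seed in range(5):
            design = _small_design(seed, control_within=0.4, case_within=0.4)
            fc_c, _ = _fc_groups(design)
            res, _ = compare_graph_metrics(
                fc_c, fc_c, BootstrapConfig(n_boot=50, seed=seed, grid=SMALL_GRID)
            )
            if all(r.p_corrected > 0.05 for r in res.values()):
                hits += 1
        assert hits >= 3  # no rejections expected when the groups coincide

    def test_bit_reproducible_under_seed(self):
        design = _small_design(0)
        fc_c, fc_a = _fc_groups(design)
        cfg = BootstrapConfig(n_boot=40, seed=7, grid=SMALL_GRID)
        r1, _ = compare_graph_metrics(fc_c, fc_a, cfg)
        r2, _ = compare_graph_metrics(fc_c, fc_a, cfg)
        assert all(r1[m].t == r2[m].t for m in r1)

    def test_t_magnitude_grows_with_n_boot(self):
        """Replicates resample the same subjects, so |t| inflates with n_boot.

        This reproduces (and surfaces) the mechanism behind the very
        large bootstrap t statistics such pipelines report.
        """
        design = _small_design(3)  # strong fixed effect
        fc_c, fc_a = _fc_groups(design)
        t_by_nboot = []
        for n_boot in (50, 200, 800):
            res, meta = compare_graph_metrics(
                fc_c, fc_a, BootstrapConfig(n_boot=n_boot, seed=1, grid=SMALL_GRID)
            )
            t_by_nboot.append(abs(res["transitivity"].t))
            assert meta["df"] == 2 * n_boot - 2
            assert "n_boot" in meta["note"] or "n_boot" in meta
        assert t_by_nboot[0] < t_by_nboot[1] < t_by_nboot[2]

    def test_sign_stable_when_reducing_n_boot(self):
        design = _small_design(4)
        fc_c, fc_a = _fc_groups(design)
        signs = []
        for n_boot in (100, 1000):
            res, _ = compare_graph_metrics(
                fc_c, fc_a, BootstrapConfig(n_boot=n_boot, seed=2, grid=SMALL_GRID)
            )
            signs.append(res["transitivity"].direction)
        assert signs[0] == signs[1]

    def test_metadata_and_correction_bookkeeping(self):
        design = _small_design(5)
        fc_c, fc_a = _fc_groups(design)
        res, meta = compare_graph_metrics(
            fc_c, fc_a, BootstrapConfig(n_boot=30, seed=0, grid=SMALL_GRID, family_size=4)
        )
        assert set(res) == {"clustering", "transitivity", "global_efficiency", "assortativity"}
        for r in res.values():
            assert r.p_corrected >= r.p_raw
            assert r.correction == "bonferroni"
        assert meta["family_size"] == 4


class TestNetworkAndEdgeComparisons:
    def test_network_table_shape_and_invariants(self):
        design = _small_design(0)
        fc_c, fc_a = _fc_groups(design)
        atlas = spec_atlas(design.control_spec)
        df = compare_networks(fc_c, fc_a, atlas)
        assert len(df) == 3
        assert (df["p_corrected"] >= df["p_raw"] - 1e-15).all()
        assert (df["correction"] == "bonferroni").all()

    def test_segregation_deficit_detected_at_network_level(self):
        design = _small_design(1, control_within=0.6, case_within=0.2)
        fc_c, fc_a = _fc_groups(design)
        atlas = spec_atlas(design.control_spec)
        df = compare_networks(fc_c, fc_a, atlas)  # control - case contrast
        assert (df["t"] > 0).all()

    def test_edge_table_covers_all_pairs(self):
        design = _small_design(2)
        fc_c, fc_a = _fc_groups(design)
        df = compare_edges(fc_c, fc_a)
        assert len(df) == 12 * 11 // 2
        assert (df["correction"] == "fdr_bh").all()
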