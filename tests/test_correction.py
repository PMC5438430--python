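import numpy as np
import pytest

from oosda.correction import (
    LatentNuisanceCorrector,
    PCASubtractor,
    centroid_spread_b,
    correct_unwanted_variation,
    merge_replicates,
    pca_compress,
    pca_subtract,
    tune_dimension,
)
from oosda.correction import _select_d_best
from oosda.table import ValidationError, align_metadata
from oosda.prefilter import log2_transform

from conftest import make_meta, make_table


class TestPcaCompress:
    def test_low_rank_data_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        # rank-3 data, 10 features x 8 samples, k = 2 keeps 6 >= 3 dims
        X = rng.uniform(0.5, 2, size=(10, 3)) @ rng.uniform(0.5, 2, size=(3, 8))
        table = make_table(X)
        comp = pca_compress(table, k=2)
        recon = comp.reconstruct(comp.scores)
        np.testing.assert_allclose(recon, table.values, atol=1e-8)
        G = comp.loadings.T @ comp.loadings
        assert np.max(np.abs(G - np.eye(G.shape[0]))) < 1e-8

    def test_k0_preserves_pairwise_distances(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.uniform(1, 10, size=(12, 6)))
        comp = pca_compress(table, k=0)
        centered = table.values - table.values.mean(axis=1, keepdims=True)
        for i in range(6):
            for j in range(i + 1, 6):
                d_orig = np.linalg.norm(centered[:, i] - centered[:, j])
                d_score = np.linalg.norm(
                    comp.scores[:, i] - comp.scores[:, j]
                )
                assert d_score == pytest.approx(d_orig, rel=1e-8)

    def test_k_too_large_rejected(self):
        table = make_table(np.ones((4, 3)))
        with pytest.raises(ValidationError):
            pca_compress(table, k=2)


class TestSpreadB:
    def test_two_centroid_analytic_case(self):
        scores = np.array([[0.0, 10.0], [0.0, 0.0]])
        assert centroid_spread_b(scores, ["a", "b"]) == pytest.approx(5.0)

    def test_identical_anchors_give_zero(self):
        scores = np.ones((3, 6))
        assert centroid_spread_b(scores, ["a", "a", "b", "b", "c", "c"]) == 0.0

    def test_matches_direct_formula_three_classes(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(2, 9))
        labels = np.repeat(["a", "b", "c"], 3)
        centroids = [scores[:, labels == c].mean(axis=1) for c in "abc"]
        m = np.mean(centroids, axis=0)
        expected = np.mean([np.linalg.norm(c - m) for c in centroids])
        assert centroid_spread_b(scores, labels) == pytest.approx(
            expected, rel=1e-12
        )


class TestStoppingRule:
    @pytest.mark.parametrize(
        "b, expected, converged",
        [
            ([10.0, 5.0, 4.99, 4.98], 2, True),   # 0.2% change at d=2
            ([7.0, 7.0, 7.0], 1, True),           # flat from the start
            ([10.0, 8.0, 6.0, 4.0], 4, False),    # never stabilizes
        ],
    )
    def test_selection(self, b, expected, converged):
        d_best, conv = _select_d_best(np.asarray(b), rel_tol=0.01)
        assert d_best == expected and conv is converged


def _sim_filtered(seed=0, **overrides):
    import oosda

    cfg = oosda.SimConfig(n_features=100, seed=seed, **overrides)
    table, meta, truth = oosda.simulate_experiment(cfg)
    nonblank = meta.loc[meta["sample_type"] != "blank", "sample_id"]
    t = log2_transform(table.select_samples(nonblank))
    return t, meta, truth


class TestCorrector:
    def test_auto_requires_anchor_info(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="anchor"):
            LatentNuisanceCorrector(k=2, d="auto").fit(X, y)

    def test_single_level_nuisance_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        with pytest.raises(ValueError, match="two levels"):
            LatentNuisanceCorrector(k=2, d=1).fit(X, np.zeros(20))

    def test_d0_roundtrip_within_truncation_residual(self):
        t, meta, _ = _sim_filtered()
        corrected, corrector = correct_unwanted_variation(
            t, meta, nuisance="batch", d=0
        )
        # with d = 0 the only change is the PCA compress/reconstruct cycle
        detected = ~np.isnan(t.values)
        assert corrector.d_ == 0
        X = np.where(np.isnan(t.values), 0.0, t.values)
        expected = corrector.compression_.reconstruct(
            corrector.compression_.compress(X)
        )
        np.testing.assert_allclose(
            corrected.values[detected], expected[detected], atol=1e-8
        )
        # and the truncation residual itself is small on this data
        resid = np.abs(expected - X).max()
        assert resid < 0.1

    def test_mask_conserved(self):
        t, meta, _ = _sim_filtered(seed=5)
        corrected, _ = correct_unwanted_variation(
            t, meta, nuisance="shift", shift_break=55
        )
        np.testing.assert_array_equal(
            corrected.missing_mask, t.missing_mask
        )

    def test_nuisance_criterion_collapses_after_correction(self):
        """Refitting the discriminant on shift labels after correction
        yields a drastically reduced leading Fisher criterion."""
        from oosda.correction import pca_compress as _pc
        from oosda.discriminant import OOSDA
        from oosda.correction import shift_labels

        t, meta, _ = _sim_filtered(seed=6, shift_size=2.0)
        m = align_metadata(t, meta)
        y = shift_labels(m, 55)
        corrected, _ = correct_unwanted_variation(
            t, meta, nuisance="shift", shift_break=55, d=10
        )

        def crit(tab):
            # probe in a low-dimensional score space where the chance
            # level of the refit criterion is small
            comp = _pc(tab, k=tab.n_samples - 20)
            return OOSDA(n_components=1).fit(comp.scores.T, y).criterion_values_[0]

        assert crit(corrected) < 0.2 * crit(t)

    def test_sequential_correction_shrinks_anchor_spread(self):
        t, meta, _ = _sim_filtered(seed=7)
        m = align_metadata(t, meta)
        aidx = (m["compound"] == "Mebendazole").to_numpy()
        batches = m["batch"].to_numpy()[aidx]

        def anchor_b(tab):
            X = np.where(np.isnan(tab.values), 0.0, tab.values)
            return centroid_spread_b(X[:, aidx], batches)

        step6, _ = correct_unwanted_variation(
            t, meta, nuisance="shift", shift_break=55
        )
        step7, _ = correct_unwanted_variation(step6, meta, nuisance="batch")
        assert anchor_b(step6) < anchor_b(t)
        assert anchor_b(step7) < anchor_b(step6)


class TestPcaSubtract:
    def test_q0_is_identity_up_to_centering(self):
        t, _, _ = _sim_filtered(seed=8)
        out = pca_subtract(t, q=0)
        det = ~np.isnan(t.values)
        np.testing.assert_allclose(out.values[det], t.values[det], atol=1e-8)

    def test_rank1_structure_removed(self):
        rng = np.random.default_rng(9)
        u = rng.normal(size=30)
        coeff = rng.normal(0, 5, size=12)
        noise = rng.normal(0, 0.1, size=(30, 12))
        table = make_table(
            np.outer(u, coeff) + noise + 20.0, scale="log2",
            sample_ids=[f"S{i}" for i in range(12)],
        )
        out = pca_subtract(table, q=1)
        resid_var = np.var(out.values - out.values.mean(axis=1, keepdims=True))
        assert resid_var == pytest.approx(0.01, rel=0.5)

    def test_q_bound(self):
        table = make_table(np.ones((5, 4)), scale="log2")
        with pytest.raises(ValueError):
            pca_subtract(table, q=3)


class TestMergeReplicates:
    def test_median_masked_and_all_masked(self):
        nan = np.nan
        meta = make_meta(
            [
                ("S1", "treated", "1", 1, "g1", "d", "c"),
                ("S2", "treated", "1", 2, "g1", "d", "c"),
                ("S3", "treated", "2", 3, "g1", "d", "c"),
            ]
        )
        table = make_table(
            [[2.0, 4.0, 9.0], [2.0, nan, 6.0], [nan, nan, nan]],
            scale="log2", sample_ids=["S1", "S2", "S3"],
        )
        merged, merged_meta = merge_replicates(table, meta)
        assert merged.sample_ids == ["g1"]
        np.testing.assert_array_equal(
            merged.values[:, 0], [4.0, 4.0, nan]
        )
        # anchor-style group spanning batches keeps both batch ids
        assert merged_meta.loc["g1", "batch"] == "1;2"
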