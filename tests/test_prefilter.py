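import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oosda.prefilter import (
    blank_filter,
    log2_transform,
    remove_batch_specific,
    replicate_concordance_filter,
    tic_outlier_filter,
)
from oosda.table import ValidationError

from conftest import make_meta, make_table

BLANK_META = make_meta(
    [
        ("B1", "blank", "X1", 1, "", "DMSO", "blank"),
        ("B2", "blank", "X1", 2, "", "DMSO", "blank"),
        ("B3", "blank", "X2", 3, "", "DMSO", "blank"),
        ("T1", "treated", "X1", 4, "rg1", "drugA", "cA"),
        ("T2", "treated", "X2", 5, "rg1", "drugA", "cA"),
    ]
)


def blank_table(blank_vals, other_vals):
    rows = [list(b) + list(o) for b, o in zip(blank_vals, other_vals)]
    return make_table(rows, sample_ids=["B1", "B2", "B3", "T1", "T2"])


class TestBlankFilter:
    def test_contaminant_removed_kept_boundary(self):
        table = blank_table(
            [[1, 2, 3], [0.5, 0.5, 0.5], [np.nan, np.nan, np.nan]],
            [[100, 50], [100, 50], [100, 50]],
        )
        out, report = blank_filter(table, BLANK_META, ratio=0.01)
        # median 2 > 1% of 100 -> contaminant; median 0.5 <= 1 -> kept;
        # absent from blanks (median 0) -> kept
        assert report.removed_ids == ["F1"]
        assert out.feature_ids == ["F2", "F3"]

    def test_requires_blanks_and_raw_scale(self):
        table = make_table([[1.0, 2.0]], sample_ids=["T1", "T2"])
        with pytest.raises(ValidationError, match="blank"):
            blank_filter(table, BLANK_META)
        logged = blank_table([[1, 1, 1]], [[10, 10]])
        logged.scale = "log2"
        with pytest.raises(ValidationError, match="raw"):
            blank_filter(logged, BLANK_META)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        """Vectorized filter equals a literal per-feature re-derivation on
        random tables with random mask patterns."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 50, size=(6, 5))
        vals[rng.random((6, 5)) < 0.3] = np.nan
        table = make_table(vals, sample_ids=["B1", "B2", "B3", "T1", "T2"])
        _, report = blank_filter(table, BLANK_META, ratio=0.05)
        expected = []
        for i in range(6):
            blanks = [0.0 if np.isnan(v) else v for v in vals[i, :3]]
            others = [v for v in vals[i, 3:] if not np.isnan(v)]
            other_max = max(others) if others else 0.0
            if np.median(blanks) > 0.05 * other_max:
                expected.append(f"F{i + 1}")
        assert report.removed_ids == expected

    def test_idempotent_and_leaves_values_untouched(self):
        table = blank_table(
            [[5, 5, 5], [0.1, 0.1, 0.1]], [[10, 10], [10, 10]]
        )
        once, _ = blank_filter(table, BLANK_META)
        twice, rep = blank_filter(once, BLANK_META)
        assert rep.removed_ids == []
        np.testing.assert_array_equal(once.values, twice.values)


class TestBatchSpecific:
    META = make_meta(
        [
            ("T1", "treated", "1", 1, "r1", "d", "c"),
            ("T2", "treated", "2", 2, "r1", "d", "c"),
            ("T3", "treated", "3", 3, "r2", "d", "c"),
            ("T4", "treated", "4", 4, "r2", "d", "c"),
        ]
    )

    def test_single_batch_feature_removed(self):
        nan = np.nan
        table = make_table(
            [
                [nan, 7.0, nan, nan],   # only batch 2 -> removed
                [1.0, nan, 2.0, nan],   # two batches -> kept
                [nan, nan, nan, nan],   # never detected -> removed
            ],
            sample_ids=["T1", "T2", "T3", "T4"],
        )
        out, report = remove_batch_specific(table, self.META)
        assert report.removed_ids == ["F1", "F3"]
        assert out.feature_ids == ["F2"]

    def test_single_batch_design_is_noop(self):
        meta = make_meta(
            [
                ("T1", "treated", "1", 1, "r1", "d", "c"),
                ("T2", "treated", "1", 2, "r1", "d", "c"),
            ]
        )
        table = make_table([[1.0, np.nan]], sample_ids=["T1", "T2"])
        with pytest.warns(UserWarning):
            out, report = remove_batch_specific(table, meta)
        assert out.n_features == 1 and report.removed_ids == []


class TestLog2:
    def test_closed_form_and_mask_preserved(self):
        table = make_table([[8.0, 1.0], [2.0, np.nan]])
        out = log2_transform(table)
        np.testing.assert_allclose(
            out.values, [[3.0, 0.0], [1.0, np.nan]]
        )
        assert out.scale == "log2"
        assert out.raw_values is not None
        with pytest.raises(ValidationError, match="already"):
            log2_transform(out)

    def test_unmasked_zero_rejected(self):
        table = make_table([[0.0, 1.0]])
        table.values[0, 0] = 0.0
        with pytest.raises(ValidationError, match="F1"):
            log2_transform(table)


class TestTicOutlier:
    META = make_meta(
        [
            ("S1", "treated", "1", 1, "r1", "d", "c"),
            ("S2", "treated", "1", 2, "r1", "d", "c"),
            ("S3", "treated", "2", 3, "r2", "d", "c"),
            ("S4", "treated", "2", 4, "r2", "d", "c"),
        ]
    )

    def test_low_tic_sample_removed(self):
        # TICs 100, 100, 100, 50: mean 87.5, cutoff 61.25
        table = make_table(np.array([[60.0, 60, 60, 30], [40.0, 40, 40, 20]]))
        out, report = tic_outlier_filter(table, self.META, fraction=0.7)
        assert report.removed_ids == ["S4"]
        assert out.sample_ids == ["S1", "S2", "S3"]

    def test_equal_tics_none_removed(self):
        table = make_table(np.full((3, 4), 5.0))
        out, report = tic_outlier_filter(table, self.META)
        assert report.removed_ids == []

    def test_borderline_sample_survives(self):
        # TICs 100 and 69.99: mean 84.995, cutoff 59.4965
        meta = make_meta(
            [
                ("S1", "treated", "1", 1, "r1", "d", "c"),
                ("S2", "treated", "2", 2, "r1", "d", "c"),
            ]
        )
        table = make_table([[100.0, 69.99]], sample_ids=["S1", "S2"])
        _, report = tic_outlier_filter(table, meta)
        assert report.removed_ids == []

    def test_uses_raw_matrix_after_log2(self):
        table = make_table(np.array([[60.0, 60, 60, 30], [40.0, 40, 40, 20]]))
        logged = log2_transform(table)
        _, report = tic_outlier_filter(logged, self.META)
        assert report.removed_ids == ["S4"]


class TestReplicateConcordance:
    META = make_meta(
        [
            ("R1", "treated", "1", 1, "g1", "d", "c"),
            ("R2", "treated", "1", 2, "g1", "d", "c"),
            ("R3", "treated", "2", 3, "g1", "d", "c"),
        ]
    )

    def _trio(self, seed, third_like_base):
        rng = np.random.default_rng(seed)
        base = rng.normal(10, 2, 40)
        x1 = base + rng.normal(0, 0.3, 40)
        x2 = base + rng.normal(0, 0.3, 40)
        x3 = (
            base + rng.normal(0, 0.3, 40)
            if third_like_base
            else rng.normal(10, 2, 40)
        )
        # sanity on the intended correlation structure
        assert np.corrcoef(x1, x2)[0, 1] > 0.9
        r3 = max(np.corrcoef(x3, x1)[0, 1], np.corrcoef(x3, x2)[0, 1])
        assert (r3 > 0.9) if third_like_base else (r3 < 0.5)
        return make_table(
            np.column_stack([x1, x2, x3]), scale="log2",
            sample_ids=["R1", "R2", "R3"],
        )

    def test_discordant_replicate_removed(self):
        table = self._trio(1, third_like_base=False)
        out, report = replicate_concordance_filter(table, self.META)
        assert report.removed_ids == ["R3"]
        assert out.sample_ids == ["R1", "R2"]

    def test_concordant_trio_all_kept(self):
        table = self._trio(2, third_like_base=True)
        out, report = replicate_concordance_filter(table, self.META)
        assert report.removed_ids == []

    def test_identical_replicate_kept(self):
        rng = np.random.default_rng(3)
        base = rng.normal(10, 2, 40)
        table = make_table(
            np.column_stack([base, base, rng.normal(10, 2, 40)]),
            scale="log2", sample_ids=["R1", "R2", "R3"],
        )
        _, report = replicate_concordance_filter(table, self.META)
        assert "R1" not in report.removed_ids  # r = 1 to its twin

    def test_too_few_shared_features_flags_not_removes(self):
        vals = np.full((4, 3), np.nan)
        vals[:, 0] = [1, 2, 3, 4]
        vals[:2, 1] = [1, 2]
        vals[:2, 2] = [1, 2]
        table = make_table(vals, scale="log2", sample_ids=["R1", "R2", "R3"])
        out, report = replicate_concordance_filter(table, self.META)
        assert "R1" in report.flagged_ids
        assert out.n_samples == 3
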