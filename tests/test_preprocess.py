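"""Denoising, averaging, normalization and filter rules."""

import numpy as np
import pandas as pd
import pytest

from lpscourse import (
    ExpressionFilter,
    SimConfig,
    TimeCourseTensor,
    aggregate_gene_expression,
    average_donors,
    filter_features,
    gen_timecourse,
    replace_outliers,
    tpm_normalize,
)
from lpscourse.errors import NormalizationError, SchemaError

from conftest import make_table


class TestTpmNormalize:
    def test_scaling_examples(self):
        table = make_table([[50.0]], unit="tags")
        out = tpm_normalize(table)
        assert out.data.iloc[0, 0] == pytest.approx(1e6)
        table = make_table([[25.0], [25.0]], unit="tags")
        out = tpm_normalize(table)
        assert np.allclose(out.data.to_numpy(), 5e5)

    def test_column_sums_and_rank_preservation(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 500, (30, 4)).astype(float), unit="tags")
        out = tpm_normalize(table)
        assert np.allclose(out.data.sum(axis=0), 1e6, rtol=1e-6)
        for col in table.data.columns:
            orig = table.data[col].rank(method="average")
            new = out.data[col].rank(method="average")
            pd.testing.assert_series_equal(orig, new)

    def test_double_normalization_guard(self):
        with pytest.raises(NormalizationError):
            tpm_normalize(make_table([[1.0]], unit="tpm"))

    def test_zero_sum_column_names_sample(self):
        table = make_table([[0.0, 5.0]], unit="tags")
        with pytest.raises(NormalizationError, match="s0"):
            tpm_normalize(table)


class TestReplaceOutliers:
    def _tensor(self, values):
        values = np.asarray(values, dtype=float)
        f, t, d = values.shape
        return TimeCourseTensor(
            [f"f{i}" for i in range(f)],
            np.arange(t) * 15,
            [f"d{i}" for i in range(d)],
            values,
        )

    def test_interior_pool_has_eight_members_and_replaces_spike(self):
        """Pool {10 x 7, 12} has mean 10.25, sample SD ~0.707; a candidate of
        100 deviates far beyond 3 SD and is replaced by the pool mean."""
        values = np.full((1, 3, 3), 10.0)
        values[0, 1, 0] = 100.0   # candidate cell (interior t, donor 0)
        values[0, 1, 2] = 12.0    # one discordant pool member
        tensor = self._tensor(values)
        out, mask = replace_outliers(tensor, k=3.0)
        assert mask[0, 1, 0]
        assert out.values[0, 1, 0] == pytest.approx(10.25)
        # hand check of the pool statistics the rule used
        pool = np.array([10, 10, 10, 10, 10, 10, 10, 12.0])
        assert pool.mean() == pytest.approx(10.25)
        assert pool.std(ddof=1) == pytest.approx(0.7071, abs=1e-4)

    def test_zero_deviation_never_replaced(self):
        values = np.full((2, 4, 3), 10.0)
        _, mask = replace_outliers(self._tensor(values))
        assert not mask.any()

    def test_degenerate_sd_replaces_any_differing_candidate(self):
        values = np.full((1, 3, 3), 10.0)
        values[0, 1, 0] = 10.000001
        out, mask = replace_outliers(self._tensor(values))
        assert mask[0, 1, 0]
        assert out.values[0, 1, 0] == pytest.approx(10.0)

    def test_decisions_use_original_values_no_cascade(self):
        """Two spikes sitting in each other's pools mask one another under
        simultaneous original-value decisions: each contaminated pool has
        mean 21.25 and SD ~31.8, so |100 - 21.25| < 3 SD and neither cell is
        replaced (sequential replacement would have flagged the second)."""
        values = np.full((1, 4, 3), 10.0)
        values[0, 1, 0] = 100.0
        values[0, 2, 1] = 100.0
        _, mask_sim = replace_outliers(self._tensor(values))
        pool = np.array([10.0] * 7 + [100.0])
        assert abs(100.0 - pool.mean()) < 3 * pool.std(ddof=1)  # the rule, by hand
        assert not mask_sim[0, 1, 0] and not mask_sim[0, 2, 1]
        # the same spikes far apart (not in each other's pools) are both hit
        values2 = np.full((1, 6, 3), 10.0)
        values2[0, 1, 0] = 100.0
        values2[0, 4, 1] = 100.0
        _, mask_far = replace_outliers(self._tensor(values2))
        assert mask_far[0, 1, 0] and mask_far[0, 4, 1]

    def test_endpoint_pools_are_truncated_not_skipped(self):
        values = np.full((1, 3, 3), 10.0)
        values[0, 0, 0] = 100.0   # t=0 endpoint, pool of 5
        _, mask = replace_outliers(self._tensor(values))
        assert mask[0, 0, 0]

    def test_requires_replicates(self):
        values = np.full((1, 4, 1), 10.0)
        with pytest.raises(SchemaError):
            replace_outliers(self._tensor(values))

    def test_planted_spike_recovery_and_conservative_null(self):
        """>=95% of planted x10 spikes replaced; untouched data nearly never
        replaced (below 3x the nominal 3-sigma tail)."""
        recalls, false_rates, null_rates = [], [], []
        for seed in range(3):
            cfg = SimConfig(n_features=700, spike_rate=0.05,
                            spike_magnitude=10.0, seed=seed)
            tensor, _, truth = gen_timecourse(cfg)
            _, mask = replace_outliers(tensor)
            spikes = truth.outlier_mask
            recalls.append((mask & spikes).sum() / spikes.sum())
            false_rates.append((mask & ~spikes).sum() / (~spikes).sum())
            cfg0 = SimConfig(n_features=700, spike_rate=0.0, seed=seed)
            tensor0, _, _ = gen_timecourse(cfg0)
            _, mask0 = replace_outliers(tensor0)
            null_rates.append(mask0.mean())
        assert np.mean(recalls) >= 0.95
        assert np.mean(false_rates) < 0.01
        assert np.mean(null_rates) < 3 * 0.0027


class TestAverageDonors:
    def test_mean_and_permutation_invariance(self):
        values = np.zeros((2, 2, 3))
        values[0, 0] = [3, 6, 9]
        tensor = TimeCourseTensor(["a", "b"], [0, 15], ["d1", "d2", "d3"], values)
        table = average_donors(tensor)
        assert table.data.loc["a", "t0"] == pytest.approx(6.0)
        flipped = TimeCourseTensor(
            ["b", "a"], [0, 15], ["d1", "d2", "d3"], values[::-1]
        )
        pd.testing.assert_frame_equal(
            average_donors(flipped).data.sort_index(), table.data.sort_index()
        )


class TestFilterFeatures:
    def test_threshold_examples(self):
        table = make_table(
            [
                [10, 10, 10],    # CV 0 -> removed
                [0, 0, 30],      # CV ~1.73, max 30 -> retained
                [4, 4, 9],       # max < 10 -> removed
                [0, 0, 0],       # undefined CV -> removed
            ]
        )
        kept, report = filter_features(table)
        assert kept.data.index.tolist() == ["f1"]
        assert report.n_input == 4
        assert report.n_pass_tpm == 2  # f0 and f1 reach 10 TPM
        assert report.n_pass_cv == 1
        # the retained profile's statistics, by hand
        profile = np.array([0.0, 0.0, 30.0])
        assert profile.std(ddof=1) / profile.mean() == pytest.approx(np.sqrt(3), rel=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.gamma(2.0, 10.0, (50, 8)))
        once, report_once = filter_features(table)
        twice, report_twice = filter_features(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert report_twice.n_input == report_twice.n_pass_cv == len(once.data)

    def test_report_counts_nested(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.gamma(1.0, 8.0, (100, 6)))
        filt = ExpressionFilter().fit(table)
        r = filt.report_
        assert r.n_pass_cv <= r.n_pass_tpm <= r.n_input


class TestAggregateGeneExpression:
    def test_sum_and_threshold(self):
        table = make_table([[12.0], [7.0], [30.0]], features=["p1", "p2", "p3"])
        out = aggregate_gene_expression(
            table, {"p1": "g1", "p2": "g1", "p3": "g2"}, min_tpm=20.0
        )
        # g1 = 12 + 7 = 19 < 20 -> excluded; g2 = 30 -> kept
        assert out.data.index.tolist() == ["g2"]

    def test_boundary_is_inclusive(self):
        table = make_table([[19.9], [20.0]], features=["p1", "p2"])
        out = aggregate_gene_expression(table, {"p1": "g1", "p2": "g2"})
        assert out.data.index.tolist() == ["g2"]

    def test_promoter_mapped_to_two_genes_rejected(self):
        table = make_table([[5.0]], features=["p1"])
        with pytest.raises(SchemaError, match="p1"):
            aggregate_gene_expression(table, [("p1", "g1"), ("p1", "g2")])

    def test_unmapped_promoters_ignored(self):
        table = make_table([[50.0], [60.0]], features=["p1", "px"])
        out = aggregate_gene_expression(table, {"p1": "g1"})
        assert out.data.index.tolist() == ["g1"]
        assert out.data.loc["g1"].iloc[0] == pytest.approx(50.0)
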