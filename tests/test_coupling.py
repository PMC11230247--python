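"""Patch coupling, GA binning, group t-tests, FDR and the age-mismatched
analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fetalfold.coupling import (
    CouplingError,
    StatConfig,
    age_mismatched_coupling,
    bh_fdr,
    bin_subjects,
    group_mean_depth,
    group_test,
    patch_coupling,
)
from fetalfold.metrics import VertexMetric
from fetalfold.surface import PatchSpec


class TestPatchCoupling:
    def test_perfect_anticorrelation(self, ico3, patches3, rng):
        metric = VertexMetric(rng.uniform(size=ico3.n_vertices))
        depth = VertexMetric(-metric.values)
        cm = patch_coupling(metric, depth, patches3, PatchSpec())
        np.testing.assert_allclose(cm.r, -1.0, atol=1e-12)
        np.testing.assert_allclose(cm.p, 0.0, atol=1e-12)

    def test_constant_metric_undefined(self, ico3, patches3, rng):
        metric = VertexMetric(np.full(ico3.n_vertices, 0.4))
        depth = VertexMetric(rng.uniform(size=ico3.n_vertices))
        cm = patch_coupling(metric, depth, patches3, PatchSpec())
        assert np.isnan(cm.r).all()
        assert np.isnan(cm.p).all()

    def test_matches_scipy_pearson_oracle(self, ico3, patches3, rng):
        metric = VertexMetric(rng.uniform(size=ico3.n_vertices))
        depth = VertexMetric(rng.uniform(size=ico3.n_vertices))
        cm = patch_coupling(metric, depth, patches3, PatchSpec())
        for c in range(0, ico3.n_vertices, 61):
            idx = patches3[c]
            r, p = stats.pearsonr(metric.values[idx], depth.values[idx])
            np.testing.assert_allclose(cm.r[c], r, atol=1e-12)
            np.testing.assert_allclose(cm.p[c], p, atol=1e-12)

    def test_missing_vertices_dropped_per_patch(self, ico3, patches3, rng):
        values = rng.uniform(size=ico3.n_vertices)
        mask = np.ones(ico3.n_vertices, bool)
        mask[patches3[0][:5]] = False  # knock out 5 members of patch 0
        metric = VertexMetric(values, mask)
        depth = VertexMetric(rng.uniform(size=ico3.n_vertices))
        cm = patch_coupling(metric, depth, patches3, PatchSpec())
        idx = patches3[0][mask[patches3[0]]]
        r, _ = stats.pearsonr(metric.values[idx], depth.values[idx])
        np.testing.assert_allclose(cm.r[0], r, atol=1e-12)
        assert cm.n[0] == len(idx)

    def test_min_valid_vertices_enforced(self, ico3, patches3, rng):
        values = rng.uniform(size=ico3.n_vertices)
        mask = np.ones(ico3.n_vertices, bool)
        mask[patches3[0][:-5]] = False  # leave only 5 valid in patch 0
        cm = patch_coupling(VertexMetric(values, mask),
                            VertexMetric(rng.uniform(size=ico3.n_vertices)),
                            patches3, PatchSpec(min_valid_vertices=10))
        assert np.isnan(cm.r[0])
        assert cm.n[0] == 0

    def test_template_mismatch_rejected(self, ico3, patches3):
        with pytest.raises(CouplingError):
            patch_coupling(VertexMetric(np.zeros(10)),
                           VertexMetric(np.zeros(ico3.n_vertices)),
                           patches3)


class TestBinSubjects:
    def manifest(self, gas):
        return pd.DataFrame({"subject_id": [f"s{i}" for i in range(len(gas))],
                             "ga_weeks": gas})

    def test_half_open_biweekly_bins(self):
        bins = bin_subjects(self.manifest([27.0, 26.0, 25.99, 24.0, 35.9]),
                            StatConfig())
        assert bins[27.0] == ["s0", "s1"]  # 26.0 falls in [26, 28)
        assert bins[25.0] == ["s2", "s3"]
        assert bins[35.0] == ["s4"]

    def test_out_of_range_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="outside configured bins"):
            bins = bin_subjects(self.manifest([23.0, 30.0]), StatConfig())
        assert sum(len(v) for v in bins.values()) == 1

    def test_partition_of_uniform_cohort(self, rng):
        gas = rng.uniform(24.0, 36.0, size=112)
        bins = bin_subjects(self.manifest(gas), StatConfig())
        assert sum(len(v) for v in bins.values()) == 112
        for center, members in bins.items():
            for sid in members:
                ga = gas[int(sid[1:])]
                assert center - 1 <= ga < center + 1

    def test_missing_ga_rejected(self):
        with pytest.raises(CouplingError):
            bin_subjects(self.manifest([26.0, np.nan]), StatConfig())


def _map(r):
    r = np.asarray(r, dtype=float)
    from fetalfold.coupling import CouplingMap

    return CouplingMap(r, np.full_like(r, 0.5), np.full(len(r), 20))


class TestGroupTest:
    def test_all_zero_r(self):
        res = group_test([_map([0.0]), _map([0.0]), _map([0.0])])
        assert res.t[0] == 0.0
        assert res.p[0] == 1.0

    def test_textbook_t_statistic(self):
        values = np.array([-0.5, -0.6, -0.7, -0.8])
        res = group_test([_map([v]) for v in values])
        expected_t = values.mean() / (values.std(ddof=1) / np.sqrt(4))
        expected_p = 2 * stats.t.sf(abs(expected_t), 3)
        np.testing.assert_allclose(res.t[0], expected_t, atol=1e-12)
        np.testing.assert_allclose(res.p[0], expected_p, atol=1e-12)
        np.testing.assert_allclose(res.mean_r[0], -0.65, atol=1e-12)

    def test_missing_subjects_reduce_n(self):
        res = group_test([_map([0.1, np.nan]), _map([0.2, 0.3]),
                          _map([0.3, 0.4])])
        assert res.n[0] == 3
        assert res.n[1] == 2

    def test_too_few_defined_is_missing(self):
        res = group_test([_map([np.nan]), _map([0.2]), _map([np.nan])],
                         StatConfig(min_subjects_per_bin=2))
        assert np.isnan(res.t[0]) and np.isnan(res.p[0])
        assert np.isnan(res.mean_r[0])

    def test_empty_bin_rejected(self):
        with pytest.raises(CouplingError):
            group_test([])

    def test_significant_mean_r_display_contract(self):
        res = group_test([_map([-0.9, 0.01]) for _ in range(6)])
        shown = res.significant_mean_r()
        assert np.isfinite(shown[res.mask]).all()
        assert np.isnan(shown[~res.mask]).all()


class TestBhFdr:
    def test_all_ones_empty(self):
        assert not bh_fdr(np.ones(10), 0.05).any()

    def test_single_test(self):
        assert bh_fdr(np.array([0.04]), 0.05).all()
        assert not bh_fdr(np.array([0.06]), 0.05).any()

    def test_missing_entries_stay_unselected(self):
        p = np.array([0.001, np.nan, 0.9])
        mask = bh_fdr(p, 0.05)
        assert mask[0] and not mask[1] and not mask[2]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_matches_stepup_definition_oracle(self, pvals):
        p = np.array(pvals)
        q = 0.05
        mask = bh_fdr(p, q)
        # direct implementation of the step-up definition
        order = np.argsort(p)
        m = len(p)
        threshold = -1.0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / m:
                threshold = p[idx]
        expected = p <= threshold if threshold >= 0 else np.zeros(m, bool)
        np.testing.assert_array_equal(mask, expected)


class TestGroupMeanDepth:
    def test_single_subject_identity(self, rng):
        d = VertexMetric(rng.uniform(size=50))
        np.testing.assert_array_equal(group_mean_depth([d]).values, d.values)

    def test_two_subject_mean(self, rng):
        d = rng.uniform(size=30)
        c = 4.0
        m = group_mean_depth([VertexMetric(d), VertexMetric(-d + 2 * c)])
        np.testing.assert_allclose(m.values, c, atol=1e-12)

    def test_matches_accumulation_oracle(self, rng):
        fields = [VertexMetric(rng.uniform(size=40)) for _ in range(7)]
        acc = np.zeros(40)
        for f in fields:  # independent accumulation
            acc += f.values
        np.testing.assert_allclose(group_mean_depth(fields).values, acc / 7,
                                   atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(CouplingError):
            group_mean_depth([])


class TestAgeMismatched:
    def test_degenerate_equality_reproduces_age_matched(self, ico3, patches3,
                                                        rng):
        depth = VertexMetric(rng.uniform(size=ico3.n_vertices))
        metric = VertexMetric(rng.uniform(size=ico3.n_vertices))
        matched = patch_coupling(metric, depth, patches3, PatchSpec())
        mismatched = age_mismatched_coupling(depth, metric, patches3,
                                             PatchSpec())
        np.testing.assert_array_equal(matched.r, mismatched.r)
        np.testing.assert_array_equal(matched.p, mismatched.p)

    def test_permutation_destroys_significance(self, ico3, patches3, rng):
        # planted effect is wiped out by permuting metric vertex labels
        depth = VertexMetric(rng.uniform(size=ico3.n_vertices))
        maps = []
        for _ in range(8):
            metric = depth.values * -0.5 + rng.normal(0, 0.1, ico3.n_vertices)
            perm = rng.permutation(ico3.n_vertices)
            maps.append(patch_coupling(VertexMetric(metric[perm]), depth,
                                       patches3, PatchSpec()))
        res = group_test(maps, StatConfig())
        tested = np.isfinite(res.p).sum()
        assert res.mask.sum() <= 0.05 * tested + 3 * np.sqrt(0.05 * tested)
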