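"""Preprocessing and circular binary segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ampliconscan import (
    CbsParams,
    cbs_segment,
    cohort_target_mad,
    filter_polymorphic,
    mad,
    max_t_arc,
    remove_outliers,
    rescale_mad,
    segment_cohort,
    simulate_cohort,
    SimConfig,
)
from ampliconscan.segmentation import make_profile


def brute_force_best_arc(x: np.ndarray, min_width: int = 2):
    """Independent O(n^2) scan: pooled-variance t over every circular arc."""
    n = len(x)
    best = (-1, -1, -1.0)
    for i in range(n - 1):
        for j in range(i + 1, n):
            m = j - i
            if m < min_width or n - m < min_width:
                continue
            arc = x[i + 1 : j + 1]
            comp = np.r_[x[j + 1 :], x[: i + 1]]
            v1 = arc.var(ddof=1) if m > 1 else 0.0
            v2 = comp.var(ddof=1) if n - m > 1 else 0.0
            vp = ((m - 1) * v1 + (n - m - 1) * v2) / (n - 2)
            d = arc.mean() - comp.mean()
            if vp > 0:
                t = abs(d) / np.sqrt(vp * (1 / m + 1 / (n - m)))
            else:
                t = np.inf if d != 0 else 0.0
            if t > best[2]:
                best = (i, j, t)
    return best


class TestMaxTArc:
    def test_zero_noise_step_boundary(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        i, j, t = max_t_arc(x)
        assert (i, j) == (19, 39)
        assert t == np.inf

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 80))
            x = rng.normal(0, 1, n)
            i, j, t = max_t_arc(x)
            oi, oj, ot = brute_force_best_arc(x)
            assert (i, j) == (oi, oj)
            assert t == pytest.approx(ot, rel=1e-9)

    def test_min_width_respected(self, rng):
        x = rng.normal(0, 1, 30)
        i, j, _ = max_t_arc(x, min_width=5)
        assert 5 <= j - i <= 25


class TestCbsSegment:
    def test_constant_input_single_segment(self, fast_cbs):
        segs = cbs_segment(np.full(20, 0.37), fast_cbs)
        assert len(segs) == 1
        assert segs[0].mean == pytest.approx(0.37)
        assert (segs[0].first, segs[0].last) == (0, 19)

    def test_zero_noise_step(self, fast_cbs):
        segs = cbs_segment(np.r_[np.zeros(20), np.ones(20)], fast_cbs)
        assert [(s.first, s.last) for s in segs] == [(0, 19), (20, 39)]
        assert [s.mean for s in segs] == [0.0, 1.0]

    def test_zero_noise_piecewise_exact_recovery(self, fast_cbs):
        x = np.r_[np.zeros(15), np.full(10, 0.8), np.zeros(15)]
        segs = cbs_segment(x, fast_cbs)
        assert [(s.first, s.last, s.mean) for s in segs] == [
            (0, 14, 0.0), (15, 24, 0.8), (25, 39, 0.0),
        ]

    def test_noisy_shift_recovers_boundaries_and_oracle_location(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 0.1, 100)
        x[40:60] += 0.8
        segs = cbs_segment(x, CbsParams(n_perm=2000, seed=5))
        assert len(segs) == 3
        assert abs(segs[0].last + 1 - 40) <= 2
        assert abs(segs[1].last + 1 - 60) <= 2
        i, j, _ = max_t_arc(x)
        oi, oj, _ = brute_force_best_arc(x)
        assert (i, j) == (oi, oj)

    def test_short_input_single_segment(self, fast_cbs):
        segs = cbs_segment(np.array([1.0, 2.0, 3.0]), CbsParams(min_width=2, n_perm=100))
        # n < 2*min_width -> no tested arc, single segment with the mean
        assert len(segs) == 1
        assert segs[0].mean == pytest.approx(2.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2, allow_nan=False, width=32), min_size=4, max_size=50))
    def test_mean_conservation_property(self, values):
        x = np.asarray(values, dtype=float)
        segs = cbs_segment(x, CbsParams(n_perm=100, seed=3))
        total = sum(s.n_probes * s.mean for s in segs)
        assert total == pytest.approx(x.sum(), abs=1e-9 * max(1.0, np.abs(x).sum()))
        # segments partition the sequence
        bounds = [(s.first, s.last) for s in segs]
        assert bounds[0][0] == 0 and bounds[-1][1] == len(x) - 1
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert c == b + 1

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.1, 60)
        x[20:35] += 1.0
        params = CbsParams(n_perm=2000, seed=7)
        fwd = cbs_segment(x, params)
        rev = cbs_segment(x[::-1].copy(), params)
        n = len(x)
        rev_mapped = sorted((n - 1 - s.last, n - 1 - s.first) for s in rev)
        assert sorted((s.first, s.last) for s in fwd) == rev_mapped

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 0.15, 80)
        x[20:30] += 0.45
        x[55:70] -= 0.35
        counts = [
            len(cbs_segment(x, CbsParams(alpha=a, n_perm=2000, seed=4)))
            for a in (0.001, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts)


class TestOutlierRemoval:
    def _profile(self, values, chrom="chr1"):
        n = len(values)
        clones = pd.DataFrame(
            {
                "clone_id": [f"c{i}" for i in range(n)],
                "chrom": chrom,
                "start": np.arange(n) * 100,
                "end": np.arange(n) * 100 + 80,
            }
        )
        df = clones.copy()
        df["s1"] = values
        return make_profile(df, "s1")

    def test_constant_sequence_no_flags(self):
        p = remove_outliers(self._profile([0.0] * 5), k=3)
        assert not p.excluded.any()

    def test_isolated_spike_flagged(self):
        p = remove_outliers(self._profile([0.0, 0.0, 5.0, 0.0, 0.0]), k=3)
        assert list(np.flatnonzero(p.excluded)) == [2]

    def test_chromosome_end_single_neighbour(self):
        # spike at the first clone only has one neighbour to jump from;
        # base values carry enough spread that the MAD is non-degenerate
        values = [5.0, 0.01, -0.02, 0.03, -0.01, 0.02, 0.0]
        p = remove_outliers(self._profile(values), k=3)
        assert p.excluded[0]
        assert not p.excluded[1:].any()

    def test_synthetic_spike_recovery(self):
        config = SimConfig(n_samples=2, n_clones=2000, seed=3, polymorphic_fraction=0.0)
        cohort = simulate_cohort(config)
        for sample in cohort.annotations.index:
            profile = remove_outliers(make_profile(cohort.clone_table, sample), k=3)
            planted = cohort.truth.outlier_mask[sample].to_numpy()
            flagged = profile.excluded
            recall = flagged[planted].mean() if planted.any() else 1.0
            fpr = flagged[~planted].mean()
            assert recall >= 0.9
            assert fpr <= 0.01

    def test_all_flagged_is_degenerate(self):
        profile = self._profile([0.0, 10.0, 0.0, 10.0])
        with pytest.raises(ValueError, match="degenerate"):
            # k=0 with alternating jumps flags everything
            remove_outliers(profile, k=0)


class TestRescaleMad:
    def _profile(self, values):
        return TestOutlierRemoval()._profile(values)

    def test_identity_when_mad_matches(self, rng):
        x = rng.normal(0, 0.2, 50)
        p = self._profile(x)
        out = rescale_mad(p, target_mad=mad(x))
        assert np.allclose(out.values, x)

    def test_single_sample_mode_unchanged(self, rng):
        x = rng.normal(0, 0.2, 50)
        p = self._profile(x)
        assert np.array_equal(rescale_mad(p, None).values, x)

    def test_two_sample_cohort_target(self, rng):
        base = rng.normal(0, 1, 200)
        p1 = self._profile(base * 0.10 / mad(base))  # sample MAD 0.10
        p2 = self._profile(base * 0.20 / mad(base))  # sample MAD 0.20
        out1 = rescale_mad(p1, 0.15)
        out2 = rescale_mad(p2, 0.15)
        assert np.allclose(out1.values, p1.values * 1.5)
        assert np.allclose(out2.values, p2.values * 0.75)
        assert mad(out1.values) == pytest.approx(0.15, rel=1e-9)
        assert mad(out2.values) == pytest.approx(0.15, rel=1e-9)
        assert cohort_target_mad([p1, p2]) == pytest.approx(0.15, rel=1e-9)

    def test_zero_mad_errors(self):
        with pytest.raises(ValueError, match="MAD"):
            rescale_mad(self._profile([1.0] * 10), 0.15)


class TestPolymorphicFilter:
    def test_empty_list_unchanged(self, small_cohort):
        out = filter_polymorphic(small_cohort.clone_table, [])
        pd.testing.assert_frame_equal(out, small_cohort.clone_table)

    def test_whole_chromosome_removed(self, small_cohort):
        table = small_cohort.clone_table
        chr2 = list(table.loc[table["chrom"] == "chr2", "clone_id"])
        out = filter_polymorphic(table, chr2)
        assert "chr2" not in set(out["chrom"])

    def test_unknown_clone_warns_and_is_ignored(self, small_cohort):
        with pytest.warns(UserWarning, match="not in table"):
            out = filter_polymorphic(small_cohort.clone_table, ["NOPE"])
        assert len(out) == len(small_cohort.clone_table)

    def test_synthetic_count_bookkeeping(self, small_cohort, small_config):
        out = filter_polymorphic(
            small_cohort.clone_table, small_cohort.truth.polymorphic_clones
        )
        expected = small_config.n_clones - round(
            small_config.polymorphic_fraction * small_config.n_clones
        )
        assert len(out) == expected


def test_segment_cohort_imputes_excluded_clones(fast_cbs):
    rng = np.random.default_rng(1)
    n = 60
    values = rng.normal(0, 0.05, n)
    values[20:40] += 1.0
    values[25] = 6.0  # isolated spike inside the elevated segment
    df = pd.DataFrame(
        {
            "clone_id": [f"c{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 800,
            "s1": values,
        }
    )
    smoothed, segments, profiles = segment_cohort(df, ["s1"], fast_cbs)
    assert profiles[0].excluded[25]
    assert profiles[0].imputed[25]
    # the spike inherits the surrounding segment's mean instead of its own value
    assert abs(smoothed["s1"].iloc[25] - 1.0) < 0.1
    assert segments["n_probes"].sum() == n - 1  # excluded clone not counted
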