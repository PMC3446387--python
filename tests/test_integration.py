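"""Detection filtering, gene-level copy number and overexpressed-when-amplified."""

import itertools

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from ampliconscan import (
    detection_filter,
    gene_cn,
    mann_whitney,
    overexpressed_when_amplified,
    pearson_cn_expression,
)


class TestDetectionFilter:
    def _matrices(self, n_detected, n_samples=48):
        detp = pd.DataFrame(
            [[0.001] * n_detected + [0.5] * (n_samples - n_detected)],
            index=["probe"], columns=[f"s{i}" for i in range(n_samples)],
        )
        expr = pd.DataFrame(
            np.zeros((1, n_samples)), index=["probe"], columns=detp.columns
        )
        return expr, detp

    def test_detected_everywhere_kept(self):
        expr, detp = self._matrices(48)
        assert len(detection_filter(expr, detp)) == 1

    def test_exactly_25_percent_excluded(self):
        # 12/48 = 25.0%: the rule is strictly greater than 25%
        expr, detp = self._matrices(12)
        assert len(detection_filter(expr, detp)) == 0

    def test_just_over_25_percent_kept(self):
        expr, detp = self._matrices(13)
        assert len(detection_filter(expr, detp)) == 1

    def test_dimension_mismatch_rejected(self):
        expr, detp = self._matrices(13)
        with pytest.raises(ValueError):
            detection_filter(expr.iloc[:, :10], detp)


def _smoothed_frame(chrom, starts, ends, values_per_sample):
    df = pd.DataFrame(
        {
            "clone_id": [f"c{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "end": ends,
        }
    )
    for name, vals in values_per_sample.items():
        df[name] = vals
    return df


class TestGeneCn:
    def test_median_of_overlapping_clones(self):
        smoothed = _smoothed_frame(
            "chr1", [0, 100, 200], [100, 200, 300], {"s1": [0.5, 0.6, 0.4]}
        )
        genes = pd.DataFrame({"symbol": ["g"], "chrom": ["chr1"], "start": [0], "end": [300]})
        vals, states = gene_cn(smoothed, genes)
        assert vals.loc["g", "s1"] == pytest.approx(0.5)
        assert states.loc["g", "s1"] == 2

    def test_single_clone_gene(self):
        smoothed = _smoothed_frame("chr1", [0, 100], [100, 200], {"s1": [0.9, 0.0]})
        genes = pd.DataFrame({"symbol": ["g"], "chrom": ["chr1"], "start": [10], "end": [50]})
        vals, _ = gene_cn(smoothed, genes)
        assert vals.loc["g", "s1"] == pytest.approx(0.9)

    def test_half_open_overlap_convention(self):
        smoothed = _smoothed_frame("chr1", [0, 100], [100, 200], {"s1": [1.0, 0.0]})
        # gene starting exactly at a clone's end does not overlap it
        genes = pd.DataFrame({"symbol": ["g"], "chrom": ["chr1"], "start": [100], "end": [150]})
        vals, _ = gene_cn(smoothed, genes)
        assert vals.loc["g", "s1"] == pytest.approx(0.0)

    def test_gene_without_clones_is_missing(self):
        smoothed = _smoothed_frame("chr1", [0], [100], {"s1": [1.0]})
        genes = pd.DataFrame({"symbol": ["g"], "chrom": ["chr2"], "start": [0], "end": [50]})
        vals, states = gene_cn(smoothed, genes)
        assert np.isnan(vals.loc["g", "s1"])
        assert np.isnan(states.loc["g", "s1"])

    def test_random_layout_matches_interval_tree_oracle(self, rng):
        n_clones, n_genes, n_samples = 300, 60, 4
        starts = np.sort(rng.integers(0, 1_000_000, n_clones))
        ends = starts + rng.integers(1, 5_000, n_clones)
        chroms = rng.choice(["chrA", "chrB"], n_clones)
        mat = rng.normal(0, 0.5, (n_clones, n_samples))
        smoothed = _smoothed_frame(
            chroms, starts, ends, {f"s{k}": mat[:, k] for k in range(n_samples)}
        )
        g_start = rng.integers(0, 1_000_000, n_genes)
        genes = pd.DataFrame(
            {
                "symbol": [f"g{i}" for i in range(n_genes)],
                "chrom": rng.choice(["chrA", "chrB"], n_genes),
                "start": g_start,
                "end": g_start + rng.integers(1, 20_000, n_genes),
            }
        )
        vals, _ = gene_cn(smoothed, genes)

        trees = {
            c: IntervalTree.from_tuples(
                (s, e, i) for i, (s, e) in enumerate(zip(starts, ends)) if chroms[i] == c
            )
            for c in ("chrA", "chrB")
        }
        for gi, g in genes.iterrows():
            hits = sorted(iv.data for iv in trees[g["chrom"]].overlap(g["start"], g["end"]))
            for k in range(n_samples):
                got = vals.loc[g["symbol"], f"s{k}"]
                if not hits:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(np.median(mat[hits, k]))


def mwu_enumeration_oracle(a, b):
    """Exact two-sided P by enumerating all group assignments."""
    pooled = np.r_[a, b]
    n1, n = len(a), len(pooled)

    def ustat(idx):
        x = pooled[list(idx)]
        rest = pooled[[i for i in range(n) if i not in idx]]
        return float(sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in rest))

    u_obs = ustat(tuple(range(n1)))
    us = [ustat(c) for c in itertools.combinations(range(n), n1)]
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


class TestMannWhitney:
    def test_textbook_separation(self):
        u, p = mann_whitney([10, 12, 14], [1, 2, 3])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_values_give_p_one(self):
        u, p = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 2), (5, 5), (8, 8), (1, 8)])
    def test_exact_path_matches_enumeration(self, n1, n2, rng):
        a = rng.normal(0.5, 1, n1)
        b = rng.normal(0, 1, n2)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mwu_enumeration_oracle(a, b), abs=1e-12)

    def test_large_groups_use_tie_corrected_normal(self, rng):
        a = np.round(rng.normal(0.2, 1, 30), 1)
        b = np.round(rng.normal(0, 1, 40), 1)  # rounding forces ties
        _, p = mann_whitney(a, b)
        assert 0.0 < p <= 1.0


class TestPearson:
    def test_affine_relation_is_one(self):
        x = np.arange(10, dtype=float)
        r, _ = pearson_cn_expression(x, 3 * x + 2)
        assert r == pytest.approx(1.0)

    def test_hand_computed_triple(self):
        r, _ = pearson_cn_expression([0, 1, 2], [0, 2, 1])
        assert r == pytest.approx(0.5)

    def test_null_simulation_small_r(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(100):
            r, _ = pearson_cn_expression(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
            hits += abs(r) < 0.1
        assert hits >= 99

    def test_zero_variance_is_missing(self):
        r, p = pearson_cn_expression([1, 1, 1], [0, 1, 2])
        assert np.isnan(r) and np.isnan(p)


class TestOverexpressedWhenAmplified:
    def _inputs(self, expr_amp, expr_not, n_amp=3, n_not=5):
        samples = [f"s{i}" for i in range(n_amp + n_not)]
        cn = pd.DataFrame(
            [[0.9] * n_amp + [0.0] * n_not], index=["g"], columns=samples
        )
        states = pd.DataFrame([[2] * n_amp + [0] * n_not], index=["g"], columns=samples)
        expr = pd.DataFrame([list(expr_amp) + list(expr_not)], index=["g"], columns=samples)
        return cn, states, expr

    def test_clear_overexpression_flagged(self):
        cn, states, expr = self._inputs([10, 12, 14], [1, 2, 3, 2, 1])
        res = overexpressed_when_amplified(cn, states, expr)
        row = res.loc["g"]
        assert row["overexpressed_when_amplified"]
        assert row["n_amplified"] == 3 and row["n_not_amplified"] == 5
        assert row["median_amplified"] > row["median_not_amplified"]

    def test_identical_distribution_not_flagged(self):
        cn, states, expr = self._inputs([1, 1, 1], [1, 1, 1, 1, 1])
        res = overexpressed_when_amplified(cn, states, expr)
        assert res.loc["g", "p_mwu"] == 1.0
        assert not res.loc["g", "overexpressed_when_amplified"]

    def test_underexpression_never_flagged(self):
        cn, states, expr = self._inputs([1, 2, 3], [10, 12, 14, 11, 13])
        res = overexpressed_when_amplified(cn, states, expr)
        assert res.loc["g", "p_mwu"] < 0.05
        assert not res.loc["g", "overexpressed_when_amplified"]

    def test_gene_without_amplified_samples_untested(self):
        cn, states, expr = self._inputs([1, 1, 1], [1, 1, 1, 1, 1])
        states.loc["g"] = 0
        res = overexpressed_when_amplified(cn, states, expr)
        assert not res.loc["g", "tested"]
        assert not res.loc["g", "overexpressed_when_amplified"]

    def test_driver_recovery_and_null_rate_on_truth_cn(self, small_cohort):
        """Using the noise-free true clone values as the smoothed matrix,
        planted drivers are flagged and planted nulls stay at the test's
        type-I level."""
        truth = small_cohort.truth
        smoothed = small_cohort.clone_table[["clone_id", "chrom", "start", "end"]].copy()
        for s in truth.clone_values.columns:
            smoothed[s] = truth.clone_values[s].to_numpy()
        expr = detection_filter(small_cohort.expression, small_cohort.detection_p)
        cn_vals, cn_states = gene_cn(smoothed, small_cohort.genes)
        res = overexpressed_when_amplified(cn_vals, cn_states, expr)
        drivers = set(truth.genes.loc[truth.genes["driver"], "symbol"])
        nulls = set(truth.genes.loc[~truth.genes["driver"], "symbol"])
        flagged = set(res.index[res["overexpressed_when_amplified"]])
        assert drivers <= flagged
        assert len(flagged & nulls) / len(nulls) <= 0.05


def test_power_at_unit_slope_is_reported_range(rng):
    """Simulated power of the amplified-vs-not test at slope 1.0 with 16 of
    313 samples amplified and unit expression noise."""
    hits = 0
    reps = 200
    for _ in range(reps):
        amplified = rng.normal(0.9, 1.0, 16)  # slope x ~0.9 log2 shift
        background = rng.normal(0.0, 1.0, 297)
        _, p = mann_whitney(amplified, background)
        hits += p < 0.05 and np.median(amplified) > np.median(background)
    power = hits / reps
    assert 0.5 < power < 1.0
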