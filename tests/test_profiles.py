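"""Composite profiles, heatmaps, factor integration and rank statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prowire as pw

from conftest import small_track


def anchors_df(positions, strand="+", chrom="c", ids=None):
    df = pd.DataFrame({"chrom": chrom, "pos": positions, "strand": strand})
    if ids is not None:
        df["id"] = ids
    return df


class TestCompositeProfile:
    def test_constant_track_degenerate_band(self):
        t = pw.SignalTrack({"c": 100_000})
        t.array("c", "+")[:] = 3.0
        prof = pw.composite_profile(t, anchors_df([10_000, 50_000]),
                                    bin_size=20, n_bins_flank=5)
        assert np.allclose(prof.mean, 60.0)
        assert np.allclose(prof.lo, 60.0) and np.allclose(prof.hi, 60.0)

    def test_single_anchor_band_collapses_to_estimate(self):
        t = small_track(length=100_000, seed=50)
        prof = pw.composite_profile(t, anchors_df([30_000]), bin_size=20,
                                    n_bins_flank=5)
        assert np.array_equal(prof.lo, prof.mean)
        assert np.array_equal(prof.hi, prof.mean)

    def test_band_is_ordered_and_brackets_mean_estimate(self):
        t = small_track(length=200_000, seed=51, lam=1.0)
        prof = pw.composite_profile(
            t, anchors_df(np.arange(20) * 5000 + 10_000), bin_size=20,
            n_bins_flank=10, n_boot=500, seed=2)
        assert np.all(prof.lo <= prof.hi)
        assert np.all(prof.lo <= prof.mean + 1e-9)
        assert np.all(prof.hi >= prof.mean - 1e-9)

    def test_deterministic_given_seed(self):
        t = small_track(length=100_000, seed=52)
        anchors = anchors_df(np.arange(10) * 5000 + 20_000)
        a = pw.composite_profile(t, anchors, seed=7, n_boot=200)
        b = pw.composite_profile(t, anchors, seed=7, n_boot=200)
        assert np.array_equal(a.lo, b.lo) and np.array_equal(a.hi, b.hi)

    def test_band_width_shrinks_with_anchor_count(self):
        t = small_track(length=2_000_000, seed=53, lam=1.0)
        widths = []
        for n in (10, 100, 1000):
            anchors = anchors_df(np.arange(n) * 1500 + 5000)
            prof = pw.composite_profile(t, anchors, bin_size=20,
                                        n_bins_flank=5, n_boot=200, seed=3)
            widths.append(np.median(prof.hi - prof.lo))
        assert widths[0] > widths[1] > widths[2]

    def test_empty_anchors_rejected(self):
        t = small_track(seed=54)
        with pytest.raises(ValueError):
            pw.composite_profile(t, anchors_df([]))


class TestScaledProfiles:
    def _prof(self, mean):
        arr = np.asarray(mean, dtype=float)
        return pw.CompositeProfile(20, -100, arr, arr * 0.9, arr * 1.1,
                                   10, "sense")

    def test_single_group_peak_becomes_one(self):
        out = pw.scaled_profiles({"a": self._prof([1, 4, 2])})
        assert out["a"].mean.max() == 1.0

    def test_shared_constant_across_groups(self):
        out = pw.scaled_profiles({"a": self._prof([2, 8, 4]),
                                  "b": self._prof([1, 4, 2])})
        assert out["a"].mean.max() == 1.0
        assert out["b"].mean.max() == 0.5

    def test_within_group_ratios_preserved_and_idempotent(self):
        profs = {"a": self._prof([2, 8, 4]), "b": self._prof([1, 4, 2])}
        once = pw.scaled_profiles(profs)
        twice = pw.scaled_profiles(once)
        assert np.allclose(once["a"].mean / once["a"].mean[0],
                           np.array([2, 8, 4]) / 2)
        for k in profs:
            assert np.array_equal(once[k].mean, twice[k].mean)


class TestHeatmap:
    def test_sort_by_distance_oracle(self):
        t = small_track(length=100_000, seed=55)
        anchors = anchors_df([10_000, 20_000, 30_000],
                             ids=["element1", "element2", "element3"])
        hm = pw.heatmap(t, anchors, bin_size=10, n_bins_flank=10,
                        sort_values=[30, 120, 80],
                        sort_key="intersummit_distance")
        assert hm.ids == ["element1", "element3", "element2"]

    def test_ties_break_deterministically_by_id(self):
        t = small_track(length=100_000, seed=56)
        anchors = anchors_df([10_000, 20_000, 30_000],
                             ids=["b", "a", "c"])
        hm = pw.heatmap(t, anchors, sort_values=[1.0, 1.0, 1.0],
                        n_bins_flank=5)
        assert hm.ids == ["a", "b", "c"]

    def test_rows_equal_query_bins(self):
        t = small_track(length=100_000, seed=57)
        anchors = anchors_df([10_000, 20_000], strand="-")
        hm = pw.heatmap(t, anchors, bin_size=10, n_bins_flank=8)
        for row, a in zip(hm.values, anchors.itertuples()):
            assert np.array_equal(
                row, pw.query_bins(t, "c", a.pos, "-", 10, 8))

    def test_strand_paired_matrix_interleaves(self):
        t = small_track(length=100_000, seed=58)
        anchors = anchors_df([10_000])
        M = pw.strand_paired_matrix(t, anchors, bin_size=4, n_bins_flank=3)
        sense = pw.query_bins(t, "c", 10_000, "+", 4, 3, "sense")
        anti = pw.query_bins(t, "c", 10_000, "+", 4, 3, "antisense")
        assert np.array_equal(M[0, 0::2], sense)
        assert np.array_equal(M[0, 1::2], anti)


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])


class TestCategorizeFactorSites:
    PROM = pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [1400]})
    DTRE = pd.DataFrame({"chrom": ["c"], "start": [1300], "end": [1800]})

    def test_promoter_precedence_on_double_overlap(self):
        peaks = peaks_df([("c", 1350, 1380, 1360)])
        out, _ = pw.categorize_factor_sites(peaks, self.PROM, self.DTRE)
        assert out["assigned_category"].iloc[0] == "promoter"
        out, _ = pw.categorize_factor_sites(peaks, self.PROM, self.DTRE,
                                            promoter_precedence=False)
        assert out["assigned_category"].iloc[0] == "dTRE"

    def test_single_nucleotide_overlap_counts(self):
        peaks = peaks_df([("c", 1799, 2100, 1950),     # 1 bp inside dTRE
                          ("c", 1800, 2100, 1950)])    # 0 bp overlap
        out, _ = pw.categorize_factor_sites(peaks, self.PROM, self.DTRE)
        assert out["assigned_category"].tolist() == ["dTRE",
                                                     "untranscribed"]

    def test_partition_and_counts(self):
        rng = np.random.default_rng(59)
        peaks = peaks_df([("c", int(s), int(s) + 50, int(s) + 25)
                          for s in rng.integers(0, 5000, 40)])
        out, counts = pw.categorize_factor_sites(peaks, self.PROM,
                                                 self.DTRE)
        assert counts.sum() == len(peaks)
        assert set(out["assigned_category"]) <= {"promoter", "dTRE",
                                                 "untranscribed"}


class TestGeneBinding:
    GENES = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"],
                          "strand": ["+"], "start": [10_000],
                          "end": [30_000]})
    QUANTS = pd.DataFrame({"gene_id": ["g"], "pause_offset": [30]})

    def _run(self, peak_start, peak_end, summit):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [peak_start],
                              "end": [peak_end], "summit": [summit]})
        return pw.gene_binding(peaks, self.GENES, self.QUANTS)

    def test_summit_at_pause_midpoint_distance_zero(self):
        out = self._run(10_000, 10_100, 10_055)   # pause mid = TSS+55
        assert bool(out["bound"].iloc[0])
        assert out["summit_to_pause"].iloc[0] == 0.0

    def test_peak_at_upstream_edge_is_bound_negative_distance(self):
        out = self._run(7_400, 7_600, 7_500)      # TSS-2500
        assert bool(out["bound"].iloc[0])
        assert out["summit_to_pause"].iloc[0] < 0

    def test_peak_beyond_window_not_bound(self):
        out = self._run(7_000, 7_400, 7_200)
        assert not bool(out["bound"].iloc[0])

    def test_matches_bruteforce_interval_test(self):
        rng = np.random.default_rng(60)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(30)],
            "chrom": "c",
            "strand": rng.choice(["+", "-"], 30),
            "start": rng.integers(5000, 400_000, 30)})
        genes["end"] = genes["start"] + rng.integers(2000, 20_000, 30)
        quants = pd.DataFrame({"gene_id": genes["gene_id"],
                               "pause_offset": 30})
        starts = rng.integers(0, 420_000, 50)
        peaks = pd.DataFrame({"chrom": "c", "start": starts,
                              "end": starts + 200,
                              "summit": starts + 100})
        out = pw.gene_binding(peaks, genes, quants).set_index("gene_id")
        for g in genes.itertuples():
            ws = g.start - 2500 if g.strand == "+" else g.start
            we = g.end if g.strand == "+" else g.end + 2500
            ref = any(min(we, e) > max(ws, s)
                      for s, e in zip(peaks["start"], peaks["end"]))
            assert bool(out.loc[g.gene_id, "bound"]) == ref


class TestConvertBindingScore:
    def test_endpoints(self):
        scores = pw.convert_binding_score([5.0, 2.0, 9.0])
        assert scores[np.argmax([5, 2, 9])] == 1000.0
        assert scores[np.argmin([5, 2, 9])] == 107.0

    def test_midpoint_affine(self):
        scores = pw.convert_binding_score([0.0, 5.0, 10.0])
        assert scores[1] == pytest.approx(553.5)

    def test_constant_input_maps_to_max(self):
        assert np.all(pw.convert_binding_score([3.0, 3.0]) == 1000.0)


class TestGroupStats:
    def test_perfect_monotone_rho_one(self):
        rho, p = pw.spearman_test([1, 2, 3, 4, 5, 6, 7],
                                  [2, 4, 9, 16, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert p <= 0.01

    def test_exact_small_n_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = pw.spearman_test(x, y)
        # independent enumeration of the permutation distribution
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(stats.spearmanr(x, y)[0])
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            hits += abs(stats.spearmanr(rx, perm)[0]) >= obs - 1e-12
        assert p == pytest.approx(hits / total)

    def test_identical_groups_u_test_not_significant(self):
        _, p = pw.mannwhitney_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p >= 0.99

    def test_group_stats_report_shape(self):
        rng = np.random.default_rng(61)
        vals = {"a": rng.normal(0, 1, 20), "b": rng.normal(2, 1, 20)}
        rep = pw.group_stats(vals, pairs={"a_vs_b": (vals["a"],
                                                     vals["b"])})
        assert set(rep["test"]) == {"spearman", "mannwhitneyu"}
        mw = rep[rep["test"] == "mannwhitneyu"].iloc[0]
        assert mw["p_value"] < 0.01
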