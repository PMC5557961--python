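"""Generator invariants: determinism, layout, noise model, DNase,
sequence composition and factor peaks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import prowire as pw
from prowire.synthetic import (InfeasiblePackingError, _rng, dnase_expectation,
                               markov_matrix, _stationary)

SMALL = dict(n_genes=30, n_dtres=10, n_untranscribed_sites=5,
             chrom_length=2_000_000)


def small_params(seed=0, **kw):
    d = dict(SMALL)
    d.update(kw)
    return pw.SimulationParams(seed=seed, **d)


class TestGenerateGenome:
    def test_counts_and_long_gene_invariant(self, sim_truth):
        assert len(sim_truth.genes) == 300
        assert (sim_truth.genes["length"] > 150_000).sum() >= 3
        assert (sim_truth.genes["length"] >= 500).all()

    def test_determinism_same_seed(self):
        p = small_params(seed=5)
        t1 = pw.generate_genome(p)
        t2 = pw.generate_genome(small_params(seed=5))
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(t1.dtres, t2.dtres)

    def test_track_determinism_byte_identical(self):
        p = small_params(seed=6)
        t = pw.generate_genome(p)
        a = pw.simulate_tracks(t, p, "HS", 1)
        b = pw.simulate_tracks(t, p, "HS", 1)
        for s in "+-":
            assert np.array_equal(a.array(p.chrom, s), b.array(p.chrom, s))

    def test_class_counts_recomputable_from_seeded_draw(self):
        p = small_params(seed=7, n_genes=50, frac_up=0.2, frac_down=0.4,
                         frac_unexpressed=0.1)
        truth = pw.generate_genome(p)
        rng = _rng(p, 0)
        # replay the layout RNG up to the class draw
        rng.uniform(size=p.n_genes)
        long_idx = rng.choice(p.n_genes, p.n_long_genes, replace=False)
        rng.integers(p.long_length_range[0], p.long_length_range[1],
                     p.n_long_genes)
        rng.integers(p.dtre_width_range[0], p.dtre_width_range[1] + 1,
                     p.n_dtres)
        rng.integers(300, 601, p.n_untranscribed_sites)
        n_spec = p.n_genes + p.n_dtres + p.n_untranscribed_sites
        rng.permutation(n_spec)
        rng.integers(1000, 4001, n_spec)
        rng.choice(["+", "-"], p.n_genes)
        cls = rng.choice(["Up", "Down", "UnExp", "UnCh"], p.n_genes,
                         p=[0.2, 0.4, 0.1, 0.3])
        cls[np.isin(np.arange(p.n_genes), long_idx)
            & (cls == "UnExp")] = "UnCh"
        expected = pd.Series(cls).value_counts().to_dict()
        got = truth.genes["cls"].value_counts().to_dict()
        assert got == expected

    def test_classes_partition_elements(self, sim_truth):
        assert sim_truth.genes["cls"].isin(
            ["Up", "Down", "UnCh", "UnExp"]).all()
        assert sim_truth.dtres["cls"].isin(
            ["up", "down", "unchanged"]).all()

    def test_dtres_do_not_overlap_tsss(self, sim_truth):
        tss = np.where(sim_truth.genes["strand"] == "+",
                       sim_truth.genes["start"], sim_truth.genes["end"] - 1)
        for d in sim_truth.dtres.itertuples():
            assert not np.any((tss >= d.start) & (tss < d.end))

    def test_genes_nonoverlapping(self, sim_truth):
        g = sim_truth.genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_infeasible_packing_raises(self):
        with pytest.raises(InfeasiblePackingError):
            pw.generate_genome(small_params(chrom_length=900_000,
                                            n_genes=100))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pw.SimulationParams(frac_up=0.8, frac_down=0.5).validate()
        with pytest.raises(ValueError):
            pw.SimulationParams(elongation_rate=1e6,
                                chrom_length=10_000).validate()


class TestSimulateTracks:
    def test_unchanged_gene_body_equal_between_conditions(self):
        """Monte-Carlo: UnCh mean body density NHS vs HS within 3 SE."""
        p = small_params(seed=8, frac_up=0, frac_down=0,
                         frac_unexpressed=0, nb_dispersion=0.01)
        truth = pw.generate_genome(p)
        genes = pw.filter_genes(truth.gene_annotation())
        diffs = []
        nhs = pw.simulate_tracks(truth, p, "NHS", 0)
        hs = pw.simulate_tracks(truth, p, "HS", 0)
        qn = pw.quantify_genes(nhs, genes)["body_rpk"]
        qh = pw.quantify_genes(hs, genes)["body_rpk"]
        rel = (qh - qn) / qn.mean()
        se = rel.std(ddof=1) / np.sqrt(len(rel))
        assert abs(rel.mean()) < 3 * se + 1e-3

    def test_down_gene_expectation_untouched_beyond_wave_front(self,
                                                               sim_truth):
        """Wave front (60 kb) < +100 kb, so >150 kb Down genes keep their
        NHS expectation on [+100 kb, polyA-500)."""
        nhs = pw.expected_tracks(sim_truth, "NHS")
        hs = pw.expected_tracks(sim_truth, "HS")
        long_down = sim_truth.genes[
            (sim_truth.genes["length"] > 150_000)]
        assert len(long_down)
        for g in long_down.itertuples():
            s, e = pw.rel_to_genomic(
                g.start if g.strand == "+" else g.end - 1, g.strand,
                100_000, g.length - 500)
            for strand in "+-":
                assert np.array_equal(nhs[strand][s:e], hs[strand][s:e])

    def test_poisson_limit_of_dispersion(self):
        """nb_dispersion -> 0 gives variance/mean ~= 1 per base."""
        p = small_params(seed=9, nb_dispersion=0.0)
        truth = pw.generate_genome(p)
        tr = pw.simulate_tracks(truth, p, "NHS", 0)
        g = truth.genes[truth.genes["cls"] != "UnExp"].iloc[0]
        body = tr.array(p.chrom, g.strand)[g.start + 500:g.end - 500]
        ratio = body.var() / body.mean()
        assert 0.8 < ratio < 1.25

    def test_count_conservation_within_nb_error(self):
        """Total counts match total expectation within 4 SE."""
        p = small_params(seed=10)
        truth = pw.generate_genome(p)
        exp = pw.expected_tracks(truth, "NHS")
        total_exp = exp["+"].sum() + exp["-"].sum() \
            + 2 * p.background_rate * p.chrom_length
        tr = pw.simulate_tracks(truth, p, "NHS", 0)
        # variance: per-block gamma variance + Poisson
        from prowire.synthetic import GAMMA_BLOCK, _element_spans
        summed = exp["+"] + exp["-"]
        per_block = [summed[max(b, 0):min(b + GAMMA_BLOCK, e)].sum()
                     for s, e in _element_spans(truth)
                     for b in range(s, e, GAMMA_BLOCK)]
        var = total_exp + p.nb_dispersion * np.sum(np.square(per_block))
        assert abs(tr.total() - total_exp) < 4 * np.sqrt(var)

    def test_hs_depth_factor_scales_reference_sums(self):
        p = small_params(seed=11, hs_depth_factor=2.0)
        truth = pw.generate_genome(p)
        genes = pw.filter_genes(truth.gene_annotation())
        regions = pw.reference_regions(genes)
        nhs = pw.simulate_tracks(truth, p, "NHS", 0)
        hs = pw.simulate_tracks(truth, p, "HS", 0)
        r = sum(pw.region_sum(hs, x, "both") for x in regions) \
            / sum(pw.region_sum(nhs, x, "both") for x in regions)
        assert abs(r - 2.0) < 0.1


def _bare_truth(params, genes=None, dtres=None):
    cols_g = ["gene_id", "chrom", "strand", "start", "end", "length", "cls",
              "nhs_body_density", "hs_body_density", "pause_enrich",
              "pause_offset", "hs_pause_offset", "pause_factor",
              "div_offset", "div_scale"]
    cols_d = ["dtre_id", "chrom", "start", "end", "cls", "center",
              "distance", "plus_summit", "minus_summit", "plus_density",
              "minus_density", "hs_factor", "paused"]
    return pw.SyntheticTruth(
        params=params,
        genes=pd.DataFrame(genes or [], columns=cols_g),
        dtres=pd.DataFrame(dtres or [], columns=cols_d),
        untranscribed=pd.DataFrame([], columns=["site_id", "chrom", "start",
                                                "end"]),
        candidates=pd.DataFrame([], columns=["chrom", "start", "end",
                                             "score", "kind", "element_id"]))


class TestSimulateDnase:
    def test_zero_noise_output_equals_expectation(self):
        p = small_params(seed=12, dnase_noise_sd=0.0)
        truth = pw.generate_genome(p)
        tr = pw.simulate_tracks(truth, p, "NHS", 0)
        dnase = pw.simulate_dnase(truth, p, tr)
        exp = dnase_expectation(truth, p, tr)
        got = dnase.array(p.chrom, ".")
        assert np.corrcoef(exp, got)[0, 1] > 0.999999
        assert np.allclose(got, np.clip(exp, 0, None))

    def test_symmetric_dtre_apex_at_midpoint(self):
        """A dTRE with equal strand intensities has its smoothed DNase
        apex within +-25 bp of the inter-summit midpoint."""
        p = pw.SimulationParams(chrom_length=20_000, dnase_noise_sd=0.0)
        center = 10_000
        d = 150
        dtre = dict(dtre_id="d0", chrom=p.chrom, start=center - 150,
                    end=center + 150, cls="unchanged", center=center,
                    distance=d, plus_summit=center + d // 2,
                    minus_summit=center - d // 2, plus_density=1000.0,
                    minus_density=1000.0, hs_factor=1.0, paused=False)
        truth = _bare_truth(p, dtres=[dtre])
        tr = pw.SignalTrack({p.chrom: p.chrom_length})
        half = p.pause_width // 2
        tr.array(p.chrom, "+")[center + d // 2 - half:
                               center + d // 2 + half] = 1.0
        tr.array(p.chrom, "-")[center - d // 2 - half:
                               center - d // 2 + half] = 1.0
        exp = dnase_expectation(truth, p, tr)
        assert abs(int(np.argmax(exp)) - center) <= 25

    def test_untranscribed_sites_have_zero_expectation(self, sim_truth,
                                                       sim_params,
                                                       pooled_nhs):
        exp = dnase_expectation(sim_truth, sim_params, pooled_nhs)
        pad = 3 * int(sim_params.dnase_bandwidth)
        for u in sim_truth.untranscribed.itertuples():
            mid = (u.start + u.end) // 2
            # element midpoints are far from any initiation signal
            assert exp[mid] < 1e-6


class TestSequences:
    def test_markov_matrix_has_requested_stationary_gc_and_cpg(self):
        gc, cpg = 0.6, 0.08
        M = markov_matrix(gc, cpg)
        pi = _stationary(gc)
        assert np.allclose(M.sum(axis=1), 1.0)
        assert np.allclose(pi @ M, pi)           # stationarity
        assert np.isclose(pi[1] * M[1, 2], cpg)  # CpG flux

    def test_promoter_windows_hit_target_gc(self, sim_truth, sim_params,
                                            sim_seqs):
        seq = sim_seqs[sim_params.chrom]
        hits = 0
        genes = sim_truth.genes.head(60)
        for g in genes.itertuples():
            a = g.start if g.strand == "+" else g.end - 1
            win = seq[a - 500:a + 500]
            gc = (win.count("G") + win.count("C")) / len(win)
            hits += 0.55 <= gc <= 0.65
        assert hits / len(genes) >= 0.95

    def test_gc_one_gives_pure_gc_sequence(self):
        M = markov_matrix(0.9999, 0.25)
        pi = _stationary(0.9999)
        rng = np.random.default_rng(0)
        from prowire.synthetic import _sample_chain
        codes = _sample_chain(M, pi, 500, rng)
        assert np.isin(codes, [1, 2]).mean() > 0.999

    def test_promoter_cpg_exceeds_dtre_cpg(self, sim_truth, sim_params,
                                           sim_seqs):
        seq = sim_seqs[sim_params.chrom]

        def cpg_at(pos):
            win = seq[pos - 500:pos + 500]
            return win.count("CG") / (len(win) - 1)

        prom = np.mean([cpg_at(g.start if g.strand == "+" else g.end - 1)
                        for g in sim_truth.genes.head(50).itertuples()])
        dtre = np.mean([cpg_at(d.center)
                        for d in sim_truth.dtres.itertuples()])
        assert prom > dtre

    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"cX": "ACGT" * 30}
        path = tmp_path / "g.fa"
        pw.synthetic.write_fasta(seqs, str(path), width=50)
        from pyfaidx import Fasta
        fa = Fasta(str(path))
        assert str(fa["cX"][:]) == seqs["cX"]


class TestFactorPeaks:
    def test_pure_promoter_mix_summits_in_promoter_windows(self, sim_truth,
                                                           sim_params):
        peaks = pw.simulate_factor_peaks(sim_truth, sim_params, n=50,
                                         mix=(1.0, 0.0, 0.0))
        genes = sim_truth.genes.set_index("gene_id")
        for pk in peaks.itertuples():
            g = genes.loc[pk.target]
            off = (pk.summit - g.start if g.strand == "+"
                   else g.end - 1 - pk.summit)
            assert -300 <= off <= 50

    def test_zero_jitter_dtre_summit_at_midpoint(self, sim_truth,
                                                 sim_params):
        peaks = pw.simulate_factor_peaks(sim_truth, sim_params, n=40,
                                         mix=(0.0, 1.0, 0.0), jitter=0)
        dt = sim_truth.dtres.set_index("dtre_id")
        for pk in peaks.itertuples():
            assert pk.summit == int(dt.loc[pk.target, "center"])

    def test_category_counts_recomputable_from_seeded_draw(self, sim_truth):
        p = dataclasses.replace(sim_truth.params, seed=3)
        peaks = pw.simulate_factor_peaks(sim_truth, p, n=100,
                                         mix=(0.31, 0.29, 0.40))
        rng = _rng(p, 5)
        cats = rng.choice(["promoter", "dtre", "untranscribed"], 100,
                          p=[0.31, 0.29, 0.40])
        assert (peaks["category"].value_counts().to_dict()
                == pd.Series(cats).value_counts().to_dict())
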