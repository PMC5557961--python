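"""Synthetic genome, nascent-transcription tracks and companion data.

Generates a toy genome whose statistical structure matches what the analysis
modules assume about a 30-minute heat-shock PRO-seq experiment:

* genes with divergent initiation: a promoter-proximal pause peak 20-60 bp
  downstream of the TSS on the coding strand, a shorter unstable divergent
  peak 110-250 bp upstream on the antisense strand, and uniform gene-body
  signal out to the polyA site;
* distal transcribed regulatory elements (dTREs) with two short unstable
  divergent transcripts and no overlap with annotated TSSs;
* a heat-shock response: pause accumulation plus a receding wave of
  elongating polymerase on downregulated genes and an advancing wave on
  upregulated genes, both bounded by elongation_rate x hs_duration, so the
  3' ends of long (>150 kb) genes are untouched and remain valid
  normalization references;
* negative-binomial count noise via a Gamma-Poisson mixture: one gamma
  multiplier per 1-kb block of an element footprint and per replicate,
  shared across the two treatments of a replicate (a paired design: each
  replicate culture is split into control and heat shock), so short
  elements feel the full dispersion while long reference regions stay
  depth-limited;
* an unstranded DNaseI hypersensitivity track that is a Gaussian-smoothed
  function of initiation-proximal PRO-seq signal plus i.i.d. noise, peaking
  between the divergently oriented pause summits;
* genome sequence with class-dependent GC and CpG composition (first-order
  Markov chains at promoters and dTREs, uniform-GC background);
* transcription-factor peak calls at promoters, dTREs and untranscribed
  loci;
* broad candidate TRE intervals with scores, standing in for the output of
  an upstream broad-region TRE detector (score >= 0.7 at expressed
  promoters and dTREs, sub-threshold scores at decoy sites).

Everything is deterministic given (params, seed): each product draws from
its own child RNG spawned from the seed.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .tracks import (GenomicInterval, SignalTrack, rel_to_genomic,
                     write_bedgraph, write_bed6, write_narrowpeak)

CONDITIONS = ("NHS", "HS")
GENE_CLASSES = ("Up", "Down", "UnCh", "UnExp")
DTRE_CLASSES = ("up", "down", "unchanged")
_EDGE_MARGIN = 3000


class InfeasiblePackingError(ValueError):
    """Requested elements cannot fit on the chromosome."""


@dataclass
class SimulationParams:
    """All tunable knobs of the simulator. Defaults are the standard study
    conditions exercised by the test-suite and acceptance checks."""

    n_genes: int = 300
    n_dtres: int = 80
    n_untranscribed_sites: int = 40
    chrom_length: int = 6_000_000
    chrom: str = "chrS"
    n_replicates: int = 2

    elongation_rate: float = 2000.0      # bp per minute
    hs_duration: float = 30.0            # minutes
    pause_position_range: Tuple[int, int] = (20, 60)   # window start, bp from TSS
    pause_width: int = 40                # bp
    divergent_offset_range: Tuple[int, int] = (110, 250)  # bp upstream of TSS
    divergent_scale_range: Tuple[float, float] = (0.2, 0.6)

    gene_length_range: Tuple[int, int] = (2_000, 15_000)
    n_long_genes: int = 4
    long_length_range: Tuple[int, int] = (160_000, 220_000)
    body_density_range: Tuple[float, float] = (30.0, 300.0)   # expected RPK
    pause_enrichment_range: Tuple[float, float] = (8.0, 40.0)

    nb_dispersion: float = 0.05
    background_rate: float = 1e-4        # expected reads per base off-element

    frac_up: float = 0.15
    frac_down: float = 0.40
    frac_unexpressed: float = 0.10
    fc_up: float = 3.0
    fc_down: float = 0.3
    hs_pause_gain: float = 2.0           # pause accumulation on Down genes
    hs_pause_shift: int = 10             # pause tightening toward TSS, bp
    hs_depth_factor: float = 1.0         # global scale injected into HS tracks

    dtre_width_range: Tuple[int, int] = (200, 400)
    intersummit_range: Tuple[int, int] = (60, 200)
    dtre_density_range: Tuple[float, float] = (300.0, 3000.0)  # RPK at summit
    dtre_tail_length: int = 150
    dtre_tail_scale: float = 0.15
    dtre_frac_up: float = 0.3
    dtre_frac_down: float = 0.2
    dtre_fc_up: float = 3.0
    dtre_fc_down: float = 0.3
    dtre_paused_frac: float = 0.0        # paused-but-unreleased dTRE profiles

    dnase_bandwidth: float = 150.0       # Gaussian smoothing sd, bp
    dnase_noise_sd: float = 0.05         # signal units
    dnase_gain: float = 100.0            # arbitrary-unit scale of the track

    gc_promoter: float = 0.60
    gc_dtre: float = 0.45
    gc_background: float = 0.41
    cpg_promoter: float = 0.08
    cpg_dtre: float = 0.02
    seq_window: int = 700                # class-sequence half-width around site

    n_factor_peaks: int = 120
    factor_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3)  # prom, dtre, untx
    factor_jitter: int = 25
    factor_halfwidth: int = 150

    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_dtres", "n_untranscribed_sites",
                     "chrom_length", "n_replicates", "n_factor_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_up", "frac_down", "frac_unexpressed",
                     "dtre_frac_up", "dtre_frac_down", "dtre_paused_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_up + self.frac_down + self.frac_unexpressed > 1.0:
            raise ValueError("gene class fractions exceed 1")
        if self.dtre_frac_up + self.dtre_frac_down > 1.0:
            raise ValueError("dTRE class fractions exceed 1")
        if self.elongation_rate * self.hs_duration >= self.chrom_length:
            raise ValueError("wave front exceeds chromosome length")
        if self.gene_length_range[0] < 500:
            raise ValueError("genes must be at least 500 bp")
        if self.long_length_range[0] <= 150_000:
            raise ValueError("long genes must exceed 150 kb")
        if not 0 < sum(self.factor_mix) <= 1.0 + 1e-9:
            raise ValueError("factor_mix must sum to 1")

    @property
    def wave_front(self) -> int:
        """Distance travelled by the elongation wave during heat shock."""
        return int(self.elongation_rate * self.hs_duration)

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {self.chrom: self.chrom_length}


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator: element coordinates, classes,
    expression levels and heat-shock effects."""

    params: SimulationParams
    genes: pd.DataFrame
    dtres: pd.DataFrame
    untranscribed: pd.DataFrame
    candidates: pd.DataFrame            # broad candidate TREs with scores
    factor_peaks: Optional[pd.DataFrame] = None

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return self.params.chrom_sizes

    def gene_annotation(self) -> pd.DataFrame:
        """Annotation table in the shape the quantification modules read."""
        g = self.genes
        return pd.DataFrame({
            "gene_id": g["gene_id"], "chrom": g["chrom"],
            "strand": g["strand"], "start": g["start"], "end": g["end"],
        })

    def true_dnase_peaks(self) -> pd.DataFrame:
        """True DNaseI apex per transcribed element: the argmax of the
        noise-free DNaseI expectation (smoothed expected initiation
        signal) within the element's initiation span.  It lies between
        the divergent pause summits, pulled toward the stronger one."""
        p = self.params
        exp = expected_tracks(self, "NHS")
        summed = exp["+"] + exp["-"]
        summed[~_initiation_mask(self)] = 0.0
        smooth = gaussian_filter1d(summed, p.dnase_bandwidth,
                                   mode="constant")
        pad = int(p.dnase_bandwidth)
        floor = 0.002 * float(smooth.max())   # ignore numerical ripples
        rows = []

        def maxima(s, e, kind, eid):
            seg = smooth[s:e]
            idx = np.flatnonzero((seg[1:-1] > seg[:-2])
                                 & (seg[1:-1] > seg[2:])
                                 & (seg[1:-1] >= floor)) + 1
            for i in idx:
                rows.append((p.chrom, s + int(i), kind, eid))

        for g in self.genes.itertuples():
            if g.cls == "UnExp":
                continue
            lo = _frame_point(g, -(g.div_offset + p.pause_width))
            hi = _frame_point(g, g.pause_offset + p.pause_width)
            maxima(min(lo, hi) - pad, max(lo, hi) + pad,
                   "promoter", g.gene_id)
        for d in self.dtres.itertuples():
            maxima(d.minus_summit - pad, d.plus_summit + pad,
                   "dtre", d.dtre_id)
        return pd.DataFrame(rows, columns=["chrom", "pos", "kind",
                                           "element_id"])


def _frame_point(gene, rel: int) -> int:
    """Genomic base at frame position ``rel`` of a gene-like record."""
    anchor = gene.start if gene.strand == "+" else gene.end - 1
    return anchor + rel if gene.strand == "+" else anchor - rel


def _rng(params: SimulationParams, *tag: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) & 0x7FFFFFFF, *tag])


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def generate_genome(params: SimulationParams) -> SyntheticTruth:
    """Lay out genes, dTREs and untranscribed sites on one chromosome, draw
    their classes and expression levels, and emit candidate broad TREs."""
    params.validate()
    rng = _rng(params, 0)

    n_long = params.n_long_genes
    if n_long < 3:
        raise ValueError("need at least 3 genes > 150 kb for normalization")
    lengths = np.exp(rng.uniform(np.log(params.gene_length_range[0]),
                                 np.log(params.gene_length_range[1]),
                                 params.n_genes)).astype(int)
    long_idx = rng.choice(params.n_genes, n_long, replace=False)
    lengths[long_idx] = rng.integers(params.long_length_range[0],
                                     params.long_length_range[1],
                                     n_long)

    dtre_widths = rng.integers(params.dtre_width_range[0],
                               params.dtre_width_range[1] + 1, params.n_dtres)
    untx_widths = rng.integers(300, 601, params.n_untranscribed_sites)

    specs = ([("gene", i, int(lengths[i])) for i in range(params.n_genes)]
             + [("dtre", i, int(dtre_widths[i])) for i in range(params.n_dtres)]
             + [("untx", i, int(untx_widths[i])) for i in
                range(params.n_untranscribed_sites)])
    order = rng.permutation(len(specs))
    gaps = rng.integers(1000, 4001, len(specs))
    need = 2 * _EDGE_MARGIN + int(sum(s[2] for s in specs)) + int(gaps.sum())
    if need > params.chrom_length:
        raise InfeasiblePackingError(
            f"elements need ~{need} bp but chrom_length is "
            f"{params.chrom_length}")

    placements: Dict[Tuple[str, int], Tuple[int, int]] = {}
    pos = _EDGE_MARGIN
    for k, oi in enumerate(order):
        kind, idx, width = specs[oi]
        pos += int(gaps[k])
        placements[(kind, idx)] = (pos, pos + width)
        pos += width

    # genes ------------------------------------------------------------------
    strands = rng.choice(["+", "-"], params.n_genes)
    probs = [params.frac_up, params.frac_down, params.frac_unexpressed]
    cls = rng.choice(["Up", "Down", "UnExp", "UnCh"], params.n_genes,
                     p=probs + [1.0 - sum(probs)])
    # long genes must have reference counts: never unexpressed
    cls[np.isin(np.arange(params.n_genes), long_idx) & (cls == "UnExp")] = "UnCh"

    body = np.exp(rng.uniform(np.log(params.body_density_range[0]),
                              np.log(params.body_density_range[1]),
                              params.n_genes))
    enrich = np.exp(rng.uniform(np.log(params.pause_enrichment_range[0]),
                                np.log(params.pause_enrichment_range[1]),
                                params.n_genes))
    pause_off = rng.integers(params.pause_position_range[0],
                             params.pause_position_range[1] + 1,
                             params.n_genes)
    div_off = rng.integers(params.divergent_offset_range[0],
                           params.divergent_offset_range[1] + 1,
                           params.n_genes)
    div_scale = rng.uniform(params.divergent_scale_range[0],
                            params.divergent_scale_range[1], params.n_genes)

    body_factor = {"Up": params.fc_up, "Down": params.fc_down,
                   "UnCh": 1.0, "UnExp": 1.0}
    pause_factor = {"Up": params.fc_up, "Down": params.hs_pause_gain,
                    "UnCh": 1.0, "UnExp": 1.0}
    gene_rows = []
    for i in range(params.n_genes):
        start, end = placements[("gene", i)]
        c = str(cls[i])
        dens = 0.0 if c == "UnExp" else float(body[i])
        hs_po = int(pause_off[i])
        if c == "Down":
            hs_po = max(hs_po - params.hs_pause_shift, 5)
        gene_rows.append(dict(
            gene_id=f"g{i:04d}", chrom=params.chrom, strand=str(strands[i]),
            start=start, end=end, length=end - start, cls=c,
            nhs_body_density=dens,
            hs_body_density=dens * body_factor[c],
            pause_enrich=float(enrich[i]),
            pause_offset=int(pause_off[i]), hs_pause_offset=hs_po,
            pause_factor=pause_factor[c],
            div_offset=int(div_off[i]), div_scale=float(div_scale[i]),
        ))
    genes = pd.DataFrame(gene_rows)
    if (genes["length"] > 150_000).sum() < 3:
        raise InfeasiblePackingError("fewer than 3 genes exceed 150 kb")

    # dTREs --------------------------------------------------------------
    dprobs = [params.dtre_frac_up, params.dtre_frac_down]
    dcls = rng.choice(["up", "down", "unchanged"], params.n_dtres,
                      p=dprobs + [1.0 - sum(dprobs)])
    dist = rng.integers(params.intersummit_range[0],
                        params.intersummit_range[1] + 1, params.n_dtres)
    ddens = np.exp(rng.uniform(np.log(params.dtre_density_range[0]),
                               np.log(params.dtre_density_range[1]),
                               (params.n_dtres, 2)))
    dfac = {"up": params.dtre_fc_up, "down": params.dtre_fc_down,
            "unchanged": 1.0}
    paused = rng.random(params.n_dtres) < params.dtre_paused_frac
    dtre_rows = []
    for i in range(params.n_dtres):
        start, end = placements[("dtre", i)]
        center = (start + end) // 2
        d = int(dist[i])
        dtre_rows.append(dict(
            dtre_id=f"d{i:03d}", chrom=params.chrom, start=start, end=end,
            cls=str(dcls[i]), center=center, distance=d,
            plus_summit=center + d // 2, minus_summit=center - (d - d // 2),
            plus_density=float(ddens[i, 0]), minus_density=float(ddens[i, 1]),
            hs_factor=dfac[str(dcls[i])], paused=bool(paused[i]),
        ))
    dtres = pd.DataFrame(dtre_rows)

    untx = pd.DataFrame(
        [dict(site_id=f"u{i:03d}", chrom=params.chrom,
              start=placements[("untx", i)][0],
              end=placements[("untx", i)][1])
         for i in range(params.n_untranscribed_sites)])

    candidates = _candidate_regions(params, genes, dtres, untx, rng)
    return SyntheticTruth(params=params, genes=genes, dtres=dtres,
                          untranscribed=untx, candidates=candidates)


def _candidate_regions(params, genes, dtres, untx, rng) -> pd.DataFrame:
    """Broad candidate TREs with scores, emulating an upstream detector:
    expressed promoters and dTREs score >= 0.7, decoys below."""
    rows = []
    for g in genes.itertuples():
        lo = _frame_point(g, -(g.div_offset + params.pause_width + 100))
        hi = _frame_point(g, g.pause_offset + params.pause_width + 100)
        start, end = min(lo, hi), max(lo, hi) + 1
        start -= int(rng.integers(0, 101))
        end += int(rng.integers(0, 101))
        expressed = g.cls != "UnExp"
        score = (rng.uniform(0.75, 1.0) if expressed
                 else rng.uniform(0.2, 0.6))
        rows.append((g.chrom, start, end, float(score), "promoter", g.gene_id))
    for d in dtres.itertuples():
        start = d.start - int(rng.integers(0, 101))
        end = d.end + int(rng.integers(0, 101))
        rows.append((d.chrom, start, end, float(rng.uniform(0.7, 1.0)),
                     "dtre", d.dtre_id))
    for u in untx.itertuples():
        rows.append((u.chrom, u.start, u.end, float(rng.uniform(0.3, 0.69)),
                     "decoy", u.site_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score",
                                       "kind", "element_id"])


# ---------------------------------------------------------------------------
# expected signal and count noise
# ---------------------------------------------------------------------------

def expected_tracks(truth: SyntheticTruth, condition: str
                    ) -> Dict[str, np.ndarray]:
    """Per-base expected PRO-seq signal for one condition, by strand.

    Does not include the global ``hs_depth_factor`` or background."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    p = truth.params
    n = p.chrom_length
    exp = {"+": np.zeros(n), "-": np.zeros(n)}
    hs = condition == "HS"
    front = p.wave_front

    def add(strand, gstart, gend, value):
        exp[strand][max(gstart, 0):min(gend, n)] += value

    for g in truth.genes.itertuples():
        if g.cls == "UnExp":
            continue
        sense, anti = (g.strand, "-" if g.strand == "+" else "+")
        anchor = g.start if g.strand == "+" else g.end - 1
        per_base = g.nhs_body_density / 1000.0
        pause_dens = per_base * g.pause_enrich
        po = g.hs_pause_offset if hs else g.pause_offset
        pf = g.pause_factor if hs else 1.0
        # pause peak
        s, e = rel_to_genomic(anchor, g.strand, po, po + p.pause_width)
        add(sense, s, e, pause_dens * pf)
        # proximal transit between pause and +500
        s, e = rel_to_genomic(anchor, g.strand, po + p.pause_width, 500)
        add(sense, s, e, per_base)
        # gene body, split at the wave front under heat shock
        L = g.length
        if L > 500:
            cut = min(front, L) if hs else L
            if cut > 500:
                s, e = rel_to_genomic(anchor, g.strand, 500, cut)
                add(sense, s, e, per_base * (
                    g.hs_body_density / max(g.nhs_body_density, 1e-300)
                    if hs else 1.0))
            if hs and L > cut:
                s, e = rel_to_genomic(anchor, g.strand, cut, L)
                add(sense, s, e, per_base)
        # divergent upstream peak on the antisense strand
        s, e = rel_to_genomic(anchor, g.strand, -(g.div_offset + p.pause_width),
                              -g.div_offset)
        add(anti, s, e, pause_dens * g.div_scale * pf)

    half = p.pause_width // 2
    for d in truth.dtres.itertuples():
        f = d.hs_factor if hs else 1.0
        plus = d.plus_density / 1000.0 * f
        minus = d.minus_density / 1000.0 * f
        add("+", d.plus_summit - half, d.plus_summit + half, plus)
        add("-", d.minus_summit - half, d.minus_summit + half, minus)
        if not d.paused:
            add("+", d.plus_summit + half,
                d.plus_summit + half + p.dtre_tail_length,
                plus * p.dtre_tail_scale)
            add("-", d.minus_summit - half - p.dtre_tail_length,
                d.minus_summit - half, minus * p.dtre_tail_scale)
    return exp


def _element_spans(truth: SyntheticTruth) -> List[Tuple[int, int]]:
    """Genomic footprint of every element, for gamma-multiplier sharing."""
    p = truth.params
    spans = []
    for g in truth.genes.itertuples():
        lo = _frame_point(g, -(g.div_offset + p.pause_width))
        hi = _frame_point(g, g.length - 1)
        spans.append((min(lo, hi), max(lo, hi) + 1))
    for d in truth.dtres.itertuples():
        spans.append((d.start - p.dtre_tail_length - p.pause_width,
                      d.end + p.dtre_tail_length + p.pause_width))
    return spans


GAMMA_BLOCK = 1000   # bp: granularity of the Gamma overdispersion field


def _gammas(truth: SyntheticTruth) -> np.ndarray:
    """Gamma(1/a, a) multipliers (mean 1) per replicate and per 1-kb block
    of every element footprint, shared between the two conditions of the
    same replicate (paired design: one culture split into NHS and HS).

    Short elements (dTREs, initiation regions) span a single block and so
    feel the full dispersion; long gene bodies average over many blocks,
    which keeps the >150 kb reference regions depth-limited as the
    normalization premise requires."""
    p = truth.params
    spans = _element_spans(truth)
    n_blocks = sum(-(-(e - s) // GAMMA_BLOCK) for s, e in spans)
    if p.nb_dispersion <= 0:
        return np.ones((n_blocks, p.n_replicates))
    shape = 1.0 / p.nb_dispersion
    return _rng(p, 1).gamma(shape, p.nb_dispersion,
                            size=(n_blocks, p.n_replicates))


def simulate_tracks(truth: SyntheticTruth, params: SimulationParams,
                    condition: str, replicate: int) -> SignalTrack:
    """Realize one replicate of one condition as integer counts.

    Counts are Poisson draws around the per-base expectation times the
    block's replicate gamma multiplier (negative binomial marginally)
    plus a uniform low background; HS tracks are additionally scaled by
    ``hs_depth_factor`` (sequencing-depth injection)."""
    if replicate < 0 or replicate >= params.n_replicates:
        raise ValueError("replicate index out of range")
    exp = expected_tracks(truth, condition)
    gam = _gammas(truth)
    spans = _element_spans(truth)
    cond_idx = CONDITIONS.index(condition)
    rng = _rng(params, 2, cond_idx, replicate)
    scale = params.hs_depth_factor if condition == "HS" else 1.0

    track = SignalTrack(params.chrom_sizes, stranded=True, dtype=np.int64,
                        metadata=dict(condition=condition,
                                      replicate=replicate, norm_factor=None))
    for strand in ("+", "-"):
        lam = exp[strand].copy()
        block = 0
        for (s, t) in spans:
            for bs in range(s, t, GAMMA_BLOCK):
                g = gam[block, replicate]
                if g != 1.0:
                    lam[max(bs, 0):min(bs + GAMMA_BLOCK, t)] *= g
                block += 1
        lam = lam * scale + params.background_rate
        track.set_array(params.chrom, strand, rng.poisson(lam))
    return track


def simulate_experiment(truth: SyntheticTruth, params: SimulationParams
                        ) -> Dict[Tuple[str, int], SignalTrack]:
    """All condition x replicate tracks of the experiment."""
    return {(c, r): simulate_tracks(truth, params, c, r)
            for c in CONDITIONS for r in range(params.n_replicates)}


# ---------------------------------------------------------------------------
# DNaseI hypersensitivity
# ---------------------------------------------------------------------------

def _initiation_mask(truth: SyntheticTruth) -> np.ndarray:
    """Boolean mask of initiation-proximal bases (between and including the
    divergent pause windows of each transcribed element)."""
    p = truth.params
    mask = np.zeros(p.chrom_length, dtype=bool)
    for g in truth.genes.itertuples():
        if g.cls == "UnExp":
            continue
        lo = _frame_point(g, -(g.div_offset + p.pause_width))
        hi = _frame_point(g, g.pause_offset + p.pause_width)
        mask[min(lo, hi):max(lo, hi) + 1] = True
    half = p.pause_width // 2
    for d in truth.dtres.itertuples():
        mask[d.minus_summit - half:d.plus_summit + half] = True
    return mask


def simulate_dnase(truth: SyntheticTruth, params: SimulationParams,
                   proseq: SignalTrack) -> SignalTrack:
    """Unstranded DNaseI track: Gaussian-smoothed (sd ``dnase_bandwidth``)
    initiation-proximal summed-strand PRO-seq signal, times ``dnase_gain``,
    plus i.i.d. Gaussian noise of sd ``dnase_noise_sd``, clipped at zero."""
    chrom = params.chrom
    summed = (np.asarray(proseq.array(chrom, "+"), dtype=float)
              + np.asarray(proseq.array(chrom, "-"), dtype=float))
    summed[~_initiation_mask(truth)] = 0.0
    expect = gaussian_filter1d(summed, params.dnase_bandwidth,
                               mode="constant") * params.dnase_gain
    if params.dnase_noise_sd > 0:
        expect = expect + _rng(params, 3).normal(
            0.0, params.dnase_noise_sd, params.chrom_length)
    track = SignalTrack(params.chrom_sizes, stranded=False,
                        metadata=dict(kind="dnase"))
    track.set_array(chrom, ".", np.clip(expect, 0.0, None))
    return track


def dnase_expectation(truth: SyntheticTruth, params: SimulationParams,
                      proseq: SignalTrack) -> np.ndarray:
    """Noise-free DNaseI expectation for the given PRO-seq input."""
    chrom = params.chrom
    summed = (np.asarray(proseq.array(chrom, "+"), dtype=float)
              + np.asarray(proseq.array(chrom, "-"), dtype=float))
    summed[~_initiation_mask(truth)] = 0.0
    return gaussian_filter1d(summed, params.dnase_bandwidth,
                             mode="constant") * params.dnase_gain


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _stationary(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def markov_matrix(gc: float, cpg_rate: float) -> np.ndarray:
    """First-order transition matrix with exact stationary GC fraction and
    stationary CpG dinucleotide rate ``cpg_rate`` = pi_C * P(G|C).

    P(G|C) is set from the target rate; P(G|other) compensates so the flux
    into G keeps the stationary distribution unchanged; the remaining mass
    of each row is spread over A, C, T in stationary proportions."""
    pi = _stationary(gc)
    pi_a, pi_c, pi_g, pi_t = pi
    if not 0 < cpg_rate <= pi_g:
        raise ValueError("cpg rate must be in (0, pi_G]")
    q = cpg_rate / pi_c          # P(G | C)
    p = (pi_g - pi_c * q) / (1 - pi_c)   # P(G | not C)
    M = np.zeros((4, 4))
    rest = pi.copy()
    rest[2] = 0.0
    rest = rest / rest.sum()
    for s in range(4):
        pg = q if s == 1 else p
        M[s, 2] = pg
        M[s, [0, 1, 3]] = (1 - pg) * rest[[0, 1, 3]]
    return M


def _sample_chain(M: np.ndarray, pi: np.ndarray, length: int,
                  rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(M, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    out[0] = np.searchsorted(np.cumsum(pi), u[0])
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    return out


def simulate_sequences(truth: SyntheticTruth, params: SimulationParams
                       ) -> Dict[str, str]:
    """Genome sequence: i.i.d. background at ``gc_background``; first-order
    Markov windows (half-width ``seq_window``) with class GC/CpG composition
    around each promoter TSS and dTRE center."""
    rng = _rng(params, 4)
    n = params.chrom_length
    pi_bg = _stationary(params.gc_background)
    codes = rng.choice(4, size=n, p=pi_bg).astype(np.int8)

    jobs = []
    for g in truth.genes.itertuples():
        anchor = g.start if g.strand == "+" else g.end - 1
        jobs.append((anchor, params.gc_promoter, params.cpg_promoter))
    for d in truth.dtres.itertuples():
        jobs.append((d.center, params.gc_dtre, params.cpg_dtre))
    w = params.seq_window
    for anchor, gc, cpg in jobs:
        M = markov_matrix(gc, cpg)
        pi = _stationary(gc)
        s = max(anchor - w, 0)
        e = min(anchor + w, n)
        codes[s:e] = _sample_chain(M, pi, e - s, rng)
    return {params.chrom: "".join(_BASES[codes])}


def write_fasta(seqs: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# factor peaks
# ---------------------------------------------------------------------------

def simulate_factor_peaks(truth: SyntheticTruth, params: SimulationParams,
                          n: Optional[int] = None,
                          mix: Optional[Sequence[float]] = None,
                          jitter: Optional[int] = None) -> pd.DataFrame:
    """Place transcription-factor peaks on promoters (summit within
    -300..+50 of the TSS), dTREs (summit at the element midpoint +- jitter)
    and untranscribed sites, recording the true category."""
    n = params.n_factor_peaks if n is None else n
    mix = params.factor_mix if mix is None else tuple(mix)
    jitter = params.factor_jitter if jitter is None else jitter
    rng = _rng(params, 5)
    cats = rng.choice(["promoter", "dtre", "untranscribed"], n, p=list(mix))

    expressed = truth.genes[truth.genes["cls"] != "UnExp"].reset_index(drop=True)
    rows = []
    for i, cat in enumerate(cats):
        if cat == "promoter":
            g = expressed.iloc[int(rng.integers(len(expressed)))]
            off = int(rng.integers(-300, 51))
            summit = (g.start + off) if g.strand == "+" else (g.end - 1 - off)
            target = g.gene_id
        elif cat == "dtre":
            d = truth.dtres.iloc[int(rng.integers(len(truth.dtres)))]
            summit = int(d.center) + (int(rng.integers(-jitter, jitter + 1))
                                      if jitter > 0 else 0)
            target = d.dtre_id
        else:
            u = truth.untranscribed.iloc[
                int(rng.integers(len(truth.untranscribed)))]
            summit = (int(u.start) + int(u.end)) // 2
            target = u.site_id
        raw = float(rng.lognormal(3.0, 0.6))
        rows.append(dict(
            chrom=params.chrom,
            start=max(summit - params.factor_halfwidth, 0),
            end=min(summit + params.factor_halfwidth, params.chrom_length),
            name=f"p{i:03d}", summit=summit, raw_intensity=raw,
            category=str(cat), target=target))
    peaks = pd.DataFrame(rows)
    truth.factor_peaks = peaks
    return peaks


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_simulation(outdir: str, truth: SyntheticTruth,
                     params: SimulationParams) -> None:
    """Write the full simulated experiment as plain-text files: per-strand
    bedGraphs, DNase bedGraph, gene TSV, BED6 elements, narrowPeak factor
    peaks, FASTA sequence and the truth tables."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for c, size in params.chrom_sizes.items():
            fh.write(f"{c}\t{size}\n")
    tracks = simulate_experiment(truth, params)
    for (cond, rep), tr in tracks.items():
        for strand, tag in (("+", "plus"), ("-", "minus")):
            write_bedgraph(tr, os.path.join(
                outdir, f"proseq_{cond}_rep{rep + 1}_{tag}.bedGraph"), strand)
    pooled = tracks[("NHS", 0)].copy()
    for r in range(1, params.n_replicates):
        for strand in ("+", "-"):
            pooled.array(params.chrom, strand)[:] += \
                tracks[("NHS", r)].array(params.chrom, strand)
    dnase = simulate_dnase(truth, params, pooled)
    write_bedgraph(dnase, os.path.join(outdir, "dnase.bedGraph"), ".")
    truth.gene_annotation().to_csv(os.path.join(outdir, "genes.tsv"),
                                   sep="\t", index=False)
    write_bed6(truth.dtres.assign(name=truth.dtres["dtre_id"], strand="."),
               os.path.join(outdir, "dtres.bed"))
    write_bed6(truth.untranscribed.assign(
        name=truth.untranscribed["site_id"], strand="."),
        os.path.join(outdir, "untranscribed.bed"))
    write_bed6(truth.candidates.assign(name=truth.candidates["element_id"],
                                       strand="."),
               os.path.join(outdir, "candidates.bed"))
    peaks = simulate_factor_peaks(truth, params)
    write_narrowpeak(peaks.assign(signal=peaks["raw_intensity"]),
                     os.path.join(outdir, "factor_peaks.narrowPeak"))
    write_fasta(simulate_sequences(truth, params),
                os.path.join(outdir, "genome.fa"))
    truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t",
                       index=False)
    truth.dtres.to_csv(os.path.join(outdir, "truth_dtres.tsv"), sep="\t",
                       index=False)
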