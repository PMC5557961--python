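"""End-to-end composition helpers tying the analysis stages together.

These functions chain the module APIs the way the full analysis runs:
pool replicates, count gene bodies / dTRE strands for the NB test, map
candidate-TRE scores to TSSs, and run the gene and dTRE response-class
analyses from raw tracks to classified tables.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .differential import classify_dtres, classify_genes, nb_test
from .gene_quant import (body_interval, filter_genes, flag_unexpressed,
                         quantify_genes, tss)
from .normalization import fit_scale_factors, reference_regions
from .tracks import GenomicInterval, SignalTrack, region_sum


def pool_tracks(tracks: Mapping[Tuple[str, int], SignalTrack],
                condition: str) -> SignalTrack:
    """Sum the replicate tracks of one condition."""
    reps = sorted(r for (c, r) in tracks if c == condition)
    if not reps:
        raise ValueError(f"no tracks for condition {condition!r}")
    out = tracks[(condition, reps[0])].copy()
    for r in reps[1:]:
        t = tracks[(condition, r)]
        for chrom in out.chrom_sizes:
            for strand in out.strands:
                out.array(chrom, strand)[:] += t.array(chrom, strand)
    return out


def gene_body_counts(tracks: Mapping[Tuple[str, int], SignalTrack],
                     genes: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Raw sense-strand gene-body counts per (condition, replicate).

    Returns {condition: DataFrame genes x replicates}; genes with an empty
    body region get zero counts."""
    conditions = sorted({c for c, _ in tracks})
    out = {}
    for cond in conditions:
        reps = sorted(r for (c, r) in tracks if c == cond)
        cols = {}
        for r in reps:
            track = tracks[(cond, r)]
            vals = []
            for g in genes.itertuples():
                body = body_interval(g)
                vals.append(region_sum(track, body, "sense")
                            if body is not None else 0.0)
            cols[f"rep{r}"] = np.asarray(vals)
        out[cond] = pd.DataFrame(cols, index=genes["gene_id"])
    return out


def dtre_strand_counts(tracks: Mapping[Tuple[str, int], SignalTrack],
                       dtres: pd.DataFrame) -> Dict[Tuple[str, str],
                                                    pd.DataFrame]:
    """Raw counts per strand over the full dTRE length, per condition."""
    conditions = sorted({c for c, _ in tracks})
    ids = dtres["dtre_id"] if "dtre_id" in dtres.columns else dtres.index
    out = {}
    for cond in conditions:
        reps = sorted(r for (c, r) in tracks if c == cond)
        for strand in ("+", "-"):
            cols = {}
            for r in reps:
                track = tracks[(cond, r)]
                cols[f"rep{r}"] = np.asarray([
                    region_sum(track, GenomicInterval(d.chrom, d.start,
                                                      d.end, strand),
                               "sense")
                    for d in dtres.itertuples()])
            out[(cond, strand)] = pd.DataFrame(cols, index=ids)
    return out


def dreg_scores_at_tss(candidates: pd.DataFrame, genes: pd.DataFrame,
                       flank: int = 200) -> Dict[str, float]:
    """Best candidate-TRE score overlapping TSS +- flank, per gene."""
    scores: Dict[str, float] = {}
    for g in genes.itertuples():
        t = tss(g)
        hit = candidates[(candidates["chrom"] == g.chrom)
                         & (candidates["start"] < t + flank)
                         & (candidates["end"] > t - flank)]
        if len(hit):
            scores[g.gene_id] = float(hit["score"].max())
    return scores


def fit_normalization(tracks: Mapping[Tuple[str, int], SignalTrack],
                      genes: pd.DataFrame,
                      baseline: Tuple[str, int] = ("NHS", 0)):
    """Per-(condition, replicate) scale factors from long-gene references."""
    regions = reference_regions(genes)
    named = {f"{c}_rep{r}": t for (c, r), t in tracks.items()}
    return fit_scale_factors(named, regions,
                             baseline=f"{baseline[0]}_rep{baseline[1]}")


def run_gene_analysis(tracks: Mapping[Tuple[str, int], SignalTrack],
                      annotation: pd.DataFrame, candidates: pd.DataFrame,
                      baseline: Tuple[str, int] = ("NHS", 0)
                      ) -> Dict[str, object]:
    """Raw tracks -> filtered genes, quantifications, normalization,
    NB test and response classes."""
    genes = filter_genes(annotation)
    norm = fit_normalization(tracks, genes, baseline)
    pooled = {c: pool_tracks(tracks, c) for c in ("NHS", "HS")}
    quants = {c: quantify_genes(pooled[c], genes, c) for c in pooled}
    counts = gene_body_counts(tracks, genes)
    reps_nhs = sorted(r for (c, r) in tracks if c == "NHS")
    reps_hs = sorted(r for (c, r) in tracks if c == "HS")
    sf_nhs = [norm.factors[f"NHS_rep{r}"] for r in reps_nhs]
    sf_hs = [norm.factors[f"HS_rep{r}"] for r in reps_hs]
    test = nb_test(counts["NHS"].to_numpy(), counts["HS"].to_numpy(),
                   sf_nhs, sf_hs)
    test.index = genes["gene_id"]
    unexp = flag_unexpressed(quants)
    scores = dreg_scores_at_tss(candidates, genes)
    classified = classify_genes(test, unexp, scores)
    return dict(genes=genes, normalization=norm, quants=quants,
                counts=counts, classified=classified)


def run_dtre_analysis(tracks: Mapping[Tuple[str, int], SignalTrack],
                      dtres: pd.DataFrame, norm) -> pd.DataFrame:
    """Strand-specific dTRE NB tests and up/down/unchanged classes."""
    counts = dtre_strand_counts(tracks, dtres)
    reps_nhs = sorted(r for (c, r) in tracks if c == "NHS")
    reps_hs = sorted(r for (c, r) in tracks if c == "HS")
    sf_nhs = [norm.factors[f"NHS_rep{r}"] for r in reps_nhs]
    sf_hs = [norm.factors[f"HS_rep{r}"] for r in reps_hs]
    calls = {}
    for strand in ("+", "-"):
        t = nb_test(counts[("NHS", strand)].to_numpy(),
                    counts[("HS", strand)].to_numpy(), sf_nhs, sf_hs)
        t.index = counts[("NHS", strand)].index
        calls[strand] = t
    return classify_dtres(calls["+"], calls["-"])
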