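"""Per-gene, strand-specific quantification of pausing and transcription.

For each gene, in its own 5'->3' frame (position 0 on the TSS base):

* the promoter-proximal pause is the 50-nt window with the highest coding-
  strand read count in the region -100..+400 from the TSS, reported as RPK;
* divergent initiation is the analogous 50-nt maximum on the antisense
  strand over -800..+100;
* gene-body transcription is the average coding-strand density (RPK) from
  +500 of the TSS to -500 of the polyA site;
* the pausing index is pause-window RPK divided by body RPK (both already
  length-normalized), defined only when the body density is positive.

Genes are filtered to a non-redundant list of genes of at least 500 nt:
among entries sharing a TSS (chrom, strand, position) only the longest is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .tracks import (GenomicInterval, SignalTrack, max_window, region_rpk,
                     rel_to_genomic)

PAUSE_SEARCH = (-100, 400)       # frame range scanned for the sense pause
DIVERGENT_SEARCH = (-800, 100)   # frame range scanned on the antisense strand
PAUSE_WINDOW = 50                # nt
BODY_MARGIN = 500                # nt trimmed at both gene ends


@dataclass(frozen=True)
class PauseCall:
    gene_id: str
    window: GenomicInterval
    rpk: float
    offset: int      # frame position of the window's 5'-most base


@dataclass
class GeneQuant:
    gene_id: str
    pause: PauseCall
    divergent: PauseCall
    body_rpk: Optional[float]       # None when the body region is empty
    pausing_index: Optional[float]  # None when body undefined or zero
    condition: str = ""


class AnnotationError(ValueError):
    pass


def read_gene_table(path: str) -> pd.DataFrame:
    """Read a gene TSV (gene_id, chrom, strand, start, end; BED-convention
    half-open coordinates). Raises with the offending line number on
    malformed records."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "start", "end"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"gene table must have columns {sorted(required)}")
    for i, row in enumerate(df.itertuples(), start=2):
        if row.strand not in ("+", "-") or row.end <= row.start or row.start < 0:
            raise AnnotationError(f"malformed gene record at line {i}")
    return df


def tss(gene) -> int:
    """Genomic base of the TSS (frame position 0)."""
    return gene.start if gene.strand == "+" else gene.end - 1


def filter_genes(annotation: pd.DataFrame, min_length: int = 500
                 ) -> pd.DataFrame:
    """Non-redundant gene list: drop genes shorter than ``min_length`` and,
    among genes sharing a TSS, keep the longest (first id on ties)."""
    df = annotation.copy()
    df["length"] = df["end"] - df["start"]
    df = df[df["length"] >= min_length]
    df["_tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df = df.sort_values(["length", "gene_id"],
                        ascending=[False, True], kind="mergesort")
    df = df.drop_duplicates(subset=["chrom", "strand", "_tss"], keep="first")
    return (df.drop(columns=["_tss"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def gene_frame_interval(gene, rel_start: int, rel_end: int) -> GenomicInterval:
    """Genomic interval of a frame range of a gene, carrying the gene strand."""
    s, e = rel_to_genomic(tss(gene), gene.strand, rel_start, rel_end)
    return GenomicInterval(gene.chrom, s, e, gene.strand)


def body_interval(gene) -> Optional[GenomicInterval]:
    length = gene.end - gene.start
    if length <= 2 * BODY_MARGIN:
        return None
    return gene_frame_interval(gene, BODY_MARGIN, length - BODY_MARGIN)


def _scan(track: SignalTrack, gene, search: Tuple[int, int], mode: str,
          step: int) -> PauseCall:
    region = gene_frame_interval(gene, search[0], search[1])
    win, rpk = max_window(track, region, PAUSE_WINDOW, strand_mode=mode,
                          step=step)
    if gene.strand == "+":
        offset = win.start - tss(gene)
    else:
        offset = tss(gene) - (win.end - 1)
    return PauseCall(gene.gene_id, win, rpk, int(offset))


def quantify_gene(track: SignalTrack, gene, condition: str = "",
                  pause_scan_step: int = 1) -> GeneQuant:
    """Pause, divergent and body quantification of one gene."""
    pause = _scan(track, gene, PAUSE_SEARCH, "sense", pause_scan_step)
    div = _scan(track, gene, DIVERGENT_SEARCH, "antisense", pause_scan_step)
    body = body_interval(gene)
    body_rpk = region_rpk(track, body, "sense") if body is not None else None
    pi = None
    if body_rpk is not None and body_rpk > 0:
        pi = pause.rpk / body_rpk
    return GeneQuant(gene.gene_id, pause, div, body_rpk, pi, condition)


def quantify_genes(track: SignalTrack, genes: pd.DataFrame,
                   condition: str = "", pause_scan_step: int = 1
                   ) -> pd.DataFrame:
    """Quantify every gene; one row per gene with all GeneQuant fields."""
    rows = []
    for gene in genes.itertuples():
        q = quantify_gene(track, gene, condition, pause_scan_step)
        rows.append(dict(
            gene_id=q.gene_id, condition=condition,
            pause_rpk=q.pause.rpk, pause_offset=q.pause.offset,
            pause_start=q.pause.window.start, pause_end=q.pause.window.end,
            divergent_rpk=q.divergent.rpk, divergent_offset=q.divergent.offset,
            body_rpk=np.nan if q.body_rpk is None else q.body_rpk,
            pausing_index=np.nan if q.pausing_index is None else q.pausing_index,
        ))
    return pd.DataFrame(rows)


def flag_unexpressed(quants_by_condition: Dict[str, pd.DataFrame],
                     min_body_rpk: float = 0.5,
                     min_pause_rpk: float = 2.0) -> pd.Series:
    """UnExp flag per gene: body RPK and pause RPK strictly below their
    thresholds in every condition."""
    flags = None
    for q in quants_by_condition.values():
        body = q["body_rpk"].fillna(0.0)
        f = (body < min_body_rpk) & (q["pause_rpk"] < min_pause_rpk)
        f.index = q["gene_id"]
        flags = f if flags is None else (flags & f)
    flags.name = "unexpressed"
    return flags
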