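"""Cross-sample normalization against the 3' ends of long genes.

A 30-minute stress changes initiation and pause release, but polymerase
that had already entered productive elongation keeps moving at ~2 kb/min,
so regions more than ~60 kb into a gene body are untouched by the
treatment.  The 3' regions (+100 kb from the TSS to -0.5 kb from the polyA
site) of genes longer than 150 kb therefore act as internal references:
any between-sample difference there reflects sequencing depth, not
biology.  Scale factors equalize the reference read sums to the baseline
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd

from .gene_quant import gene_frame_interval
from .tracks import GenomicInterval, SignalTrack, region_sum

MIN_LONG_LENGTH = 150_000     # strict >, bp
REF_START = 100_000           # frame offset of reference start
REF_END_MARGIN = 500          # bp trimmed before the polyA site


@dataclass
class NormalizationResult:
    regions: List[GenomicInterval]
    factors: Dict[str, float]
    reference_sums: Dict[str, float]
    baseline: str
    method: str = "ratio_of_sums"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": list(self.factors),
            "reference_sum": [self.reference_sums[s] for s in self.factors],
            "factor": [self.factors[s] for s in self.factors],
        })


def reference_regions(genes: pd.DataFrame) -> List[GenomicInterval]:
    """[TSS+100 kb, polyA-0.5 kb) of every gene strictly longer than 150 kb."""
    regions = []
    for gene in genes.itertuples():
        length = gene.end - gene.start
        if length > MIN_LONG_LENGTH:
            regions.append(gene_frame_interval(
                gene, REF_START, length - REF_END_MARGIN))
    if not regions:
        raise ValueError("no genes > 150 kb: normalization impossible")
    return regions


def _ref_sum(track: SignalTrack, regions: List[GenomicInterval]) -> float:
    # both strands summed: 3' gene bodies are dominated by sense signal
    return sum(region_sum(track, r, "both") for r in regions)


def fit_scale_factors(tracks: Mapping[str, SignalTrack],
                      regions: List[GenomicInterval], baseline: str,
                      method: str = "ratio_of_sums") -> NormalizationResult:
    """Per-sample factors that equalize reference-region read sums to the
    baseline sample (factor 1 for the baseline).

    ``ratio_of_sums`` (default): factor_s = sum_ref(baseline) / sum_ref(s).
    ``median_of_ratios``: median over regions of the per-region count ratio.
    """
    if baseline not in tracks:
        raise ValueError(f"baseline sample {baseline!r} not among tracks")
    if not regions:
        raise ValueError("no reference regions")
    sums = {name: _ref_sum(t, regions) for name, t in tracks.items()}
    if any(s <= 0 for s in sums.values()):
        bad = [n for n, s in sums.items() if s <= 0]
        raise ValueError(f"zero reference counts in sample(s) {bad}")
    if method == "ratio_of_sums":
        factors = {name: sums[baseline] / s for name, s in sums.items()}
    elif method == "median_of_ratios":
        base_per_region = np.array(
            [region_sum(tracks[baseline], r, "both") for r in regions])
        factors = {}
        for name, t in tracks.items():
            per_region = np.array([region_sum(t, r, "both") for r in regions])
            ok = (per_region > 0) & (base_per_region > 0)
            if not ok.any():
                raise ValueError(f"zero reference counts in sample {name!r}")
            factors[name] = float(np.median(base_per_region[ok]
                                            / per_region[ok]))
        factors[baseline] = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return NormalizationResult(regions=regions, factors=factors,
                               reference_sums=sums, baseline=baseline,
                               method=method)


def apply_scale(track: SignalTrack, factor: float) -> SignalTrack:
    """Multiply every value by ``factor``; refuses double application."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if track.metadata.get("norm_factor") is not None:
        raise ValueError("track already normalized; refusing to scale again")
    out = SignalTrack(track.chrom_sizes, track.stranded,
                      metadata=dict(track.metadata))
    for chrom in track.chrom_sizes:
        for strand in track.strands:
            out.array(chrom, strand)[:] = (
                np.asarray(track.array(chrom, strand), dtype=float) * factor)
    out.metadata["norm_factor"] = float(factor)
    return out
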