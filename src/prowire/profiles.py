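"""Composite profiles, heatmaps and transcription-factor integration.

Composite (meta-)profiles average binned signal over a set of anchors
(TSSs, pause sites, element centers), mirrored for minus-strand anchors so
every row runs 5'->3'.  Uncertainty is a bootstrap over anchors: anchors
are resampled with replacement and the 12.5th-87.5th percentile of the
resampled per-bin means forms a nominal 75% band.  Group-scaled profiles
divide every group of a factor by the single highest bin across the
groups, so the maximum over all groups is exactly 1.

Factor-binding integration follows fixed interval rules: a peak is a
promoter site if it overlaps any promoter TRE by at least one nucleotide,
else a dTRE site by the same rule, else untranscribed; gene-level binding
uses the window from 2.5 kb upstream of the TSS to the polyA site; raw
binding intensities are mapped affinely onto the 107-1000 score range used
for public peak tracks.  Group comparisons use Spearman rank correlation
and the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import GenomicInterval, SignalTrack, query_bins, query_rel_bins

SCORE_MIN, SCORE_MAX = 107.0, 1000.0
BOOT_LO, BOOT_HI = 12.5, 87.5          # percentile band of the bootstrap
GENE_WINDOW_UPSTREAM = 2500            # bp upstream of the TSS


# ---------------------------------------------------------------------------
# composite profiles
# ---------------------------------------------------------------------------

@dataclass
class CompositeProfile:
    bin_size: int
    rel_start: int                     # frame position of the first bin
    mean: np.ndarray
    lo: np.ndarray                     # 12.5th percentile of bootstrap means
    hi: np.ndarray                     # 87.5th percentile
    n_anchors: int
    strand_mode: str
    anchor_description: str = ""


def anchor_matrix(track: SignalTrack, anchors: pd.DataFrame, bin_size: int,
                  n_bins_flank: int, strand_mode: str = "sense"
                  ) -> np.ndarray:
    """Per-anchor bin vectors (rows 5'->3' of each anchor's frame).

    ``anchors`` needs columns chrom, pos, strand."""
    return np.vstack([
        query_bins(track, a.chrom, int(a.pos), a.strand, bin_size,
                   n_bins_flank, strand_mode)
        for a in anchors.itertuples()])


def composite_profile(track: SignalTrack, anchors: pd.DataFrame,
                      bin_size: int = 20, n_bins_flank: int = 25,
                      strand_mode: str = "sense", n_boot: int = 1000,
                      seed: int = 0, description: str = ""
                      ) -> CompositeProfile:
    """Anchor-averaged binned signal with a bootstrap 12.5-87.5% band."""
    if len(anchors) == 0:
        raise ValueError("no anchors")
    M = anchor_matrix(track, anchors, bin_size, n_bins_flank, strand_mode)
    mean = M.mean(axis=0)
    if len(M) == 1:
        lo = hi = mean.copy()
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(M), size=(n_boot, len(M)))
        boot_means = M[idx].mean(axis=1)       # (n_boot, n_bins)
        lo = np.percentile(boot_means, BOOT_LO, axis=0)
        hi = np.percentile(boot_means, BOOT_HI, axis=0)
    return CompositeProfile(bin_size=bin_size,
                            rel_start=-n_bins_flank * bin_size,
                            mean=mean, lo=lo, hi=hi, n_anchors=len(M),
                            strand_mode=strand_mode,
                            anchor_description=description)


def scaled_profiles(profiles: Mapping[str, CompositeProfile]
                    ) -> Dict[str, CompositeProfile]:
    """Scale a factor's per-group profiles by the single highest mean bin
    across all groups; the global maximum becomes exactly 1. Idempotent."""
    peak = max(float(p.mean.max()) for p in profiles.values())
    if peak <= 0:
        raise ValueError("profiles have no positive signal")
    out = {}
    for name, p in profiles.items():
        out[name] = CompositeProfile(
            bin_size=p.bin_size, rel_start=p.rel_start,
            mean=p.mean / peak, lo=p.lo / peak, hi=p.hi / peak,
            n_anchors=p.n_anchors, strand_mode=p.strand_mode,
            anchor_description=p.anchor_description)
    return out


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------

@dataclass
class HeatmapMatrix:
    values: np.ndarray           # (n_elements, n_bins) or paired-strand
    ids: List[str]               # row order after sorting
    sort_key: str
    bin_size: int
    rel_start: int


def heatmap(track: SignalTrack, anchors: pd.DataFrame, bin_size: int = 10,
            n_bins_flank: int = 100, strand_mode: str = "sense",
            sort_values: Optional[Sequence[float]] = None,
            sort_key: str = "") -> HeatmapMatrix:
    """Row-per-element binned matrix, rows sorted ascending by
    ``sort_values`` (ties by element id; ids from an ``id`` column or the
    row number)."""
    M = anchor_matrix(track, anchors, bin_size, n_bins_flank, strand_mode)
    ids = (anchors["id"].astype(str).tolist() if "id" in anchors.columns
           else [str(i) for i in range(len(anchors))])
    if sort_values is None:
        order = np.arange(len(M))
    else:
        key = np.asarray(sort_values, dtype=float)
        order = np.lexsort((np.asarray(ids, dtype=object), key))
    return HeatmapMatrix(values=M[order],
                         ids=[ids[i] for i in order],
                         sort_key=sort_key, bin_size=bin_size,
                         rel_start=-n_bins_flank * bin_size)


def strand_paired_matrix(track: SignalTrack, anchors: pd.DataFrame,
                         bin_size: int = 4, n_bins_flank: int = 100
                         ) -> np.ndarray:
    """Strand-paired binning (ChIP-nexus style): per anchor, sense and
    antisense bin vectors interleaved column-wise as (sense_0, anti_0,
    sense_1, anti_1, ...)."""
    S = anchor_matrix(track, anchors, bin_size, n_bins_flank, "sense")
    A = anchor_matrix(track, anchors, bin_size, n_bins_flank, "antisense")
    out = np.empty((S.shape[0], 2 * S.shape[1]))
    out[:, 0::2] = S
    out[:, 1::2] = A
    return out


# ---------------------------------------------------------------------------
# factor-site integration
# ---------------------------------------------------------------------------

def _overlaps_any(start: int, end: int, intervals: np.ndarray) -> bool:
    """>= 1 bp overlap with any (start, end) row of a sorted interval array."""
    if len(intervals) == 0:
        return False
    i = np.searchsorted(intervals[:, 0], end)
    return bool((intervals[:i, 1] > start).any())


def categorize_factor_sites(peaks: pd.DataFrame, promoters: pd.DataFrame,
                            dtres: pd.DataFrame,
                            promoter_precedence: bool = True
                            ) -> Tuple[pd.DataFrame, pd.Series]:
    """Assign each factor peak to promoter / dTRE / untranscribed by >= 1 nt
    interval overlap; peaks hitting both take the promoter label by default
    (``promoter_precedence=False`` inverts). Returns the labeled peaks and
    the category counts."""
    def by_chrom(df):
        return {c: np.array(sorted(
            zip(df.loc[df["chrom"] == c, "start"],
                df.loc[df["chrom"] == c, "end"]))).reshape(-1, 2)
            for c in df["chrom"].unique()}

    prom = by_chrom(promoters)
    dt = by_chrom(dtres)
    first, second, lbl1, lbl2 = (
        (prom, dt, "promoter", "dTRE") if promoter_precedence
        else (dt, prom, "dTRE", "promoter"))
    cats = []
    for p in peaks.itertuples():
        if _overlaps_any(p.start, p.end, first.get(p.chrom, np.empty((0, 2)))):
            cats.append(lbl1)
        elif _overlaps_any(p.start, p.end,
                           second.get(p.chrom, np.empty((0, 2)))):
            cats.append(lbl2)
        else:
            cats.append("untranscribed")
    out = peaks.copy()
    out["assigned_category"] = cats
    counts = out["assigned_category"].value_counts()
    return out, counts


def gene_binding(peaks: pd.DataFrame, genes: pd.DataFrame,
                 quants: pd.DataFrame,
                 upstream: int = GENE_WINDOW_UPSTREAM) -> pd.DataFrame:
    """Per-gene factor binding over [TSS - 2500, polyA) in the gene frame.

    A gene is bound iff any peak interval overlaps that window; for bound
    genes the signed frame distance from the nearest peak summit to the
    sense pause-window midpoint is reported (negative = upstream)."""
    q = quants.set_index("gene_id")
    rows = []
    for g in genes.itertuples():
        if g.strand == "+":
            ws, we = g.start - upstream, g.end
        else:
            ws, we = g.start, g.end + upstream
        hit = peaks[(peaks["chrom"] == g.chrom) & (peaks["start"] < we)
                    & (peaks["end"] > ws)]
        bound = len(hit) > 0
        dist = np.nan
        if bound:
            tss = g.start if g.strand == "+" else g.end - 1
            pause_mid = (q.loc[g.gene_id, "pause_offset"]
                         + 25 if g.gene_id in q.index else 25)
            summits = hit["summit"].to_numpy()
            frame = (summits - tss) if g.strand == "+" else (tss - summits)
            d = frame - pause_mid
            dist = float(d[np.argmin(np.abs(d))])
        rows.append(dict(gene_id=g.gene_id, bound=bound,
                         summit_to_pause=dist))
    return pd.DataFrame(rows)


def convert_binding_score(raw: Sequence[float]) -> np.ndarray:
    """Affine min-max map of raw intensities onto [107, 1000]."""
    x = np.asarray(raw, dtype=float)
    if len(x) == 0:
        raise ValueError("no intensities")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.full(len(x), SCORE_MAX)
    return SCORE_MIN + (x - lo) * (SCORE_MAX - SCORE_MIN) / (hi - lo)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def spearman_test(x: Sequence[float], y: Sequence[float],
                  exact_max_n: int = 8) -> Tuple[float, float]:
    """Spearman rho with two-sided p: exact permutation enumeration for
    n <= exact_max_n, t approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need paired samples, n >= 3")
    rho, p = stats.spearmanr(x, y)
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = stats.spearmanr(rx, ry[list(perm)])[0]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def mannwhitney_test(a: Sequence[float], b: Sequence[float]
                     ) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def group_stats(values: Mapping[str, Sequence[float]],
                pairs: Optional[Mapping[str, Tuple[Sequence[float],
                                                   Sequence[float]]]] = None
                ) -> pd.DataFrame:
    """Rank-based report: Spearman rho/p for each named (x, y) pairing and
    Mann-Whitney U/p for each unordered pair of named groups."""
    rows = []
    if pairs:
        for name, (x, y) in pairs.items():
            rho, p = spearman_test(x, y)
            rows.append(dict(test="spearman", comparison=name,
                             statistic=rho, p_value=p))
    names = list(values)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, p = mannwhitney_test(values[names[i]], values[names[j]])
            rows.append(dict(test="mannwhitneyu",
                             comparison=f"{names[i]} vs {names[j]}",
                             statistic=u, p_value=p))
    return pd.DataFrame(rows)
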