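"""Strand-specific base-resolution signal tracks and exact region queries.

Nascent-transcription assays such as PRO-seq record the 3' end of each
nascent RNA, giving per-base, strand-specific counts of transcriptionally
engaged polymerase.  This module holds those counts in dense per-chromosome
arrays and provides the coordinate conventions used throughout the package:

* all genomic intervals are 0-based, half-open (BED convention);
* element-relative ("frame") coordinates put position 0 on the TSS base and
  run 5'->3' of the element, so for a minus-strand element relative position
  ``r`` maps to genomic base ``anchor - r`` and the sense strand is the
  minus strand;
* queries are exact sums of per-base values — no interpolation, no silent
  truncation at chromosome ends.

All bases are treated as mappable, so "per kb mappable DNA" densities are
plain per-kb densities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
UNSTRANDED = "."


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def rel_to_genomic(anchor: int, anchor_strand: str, rel_start: int, rel_end: int
                   ) -> Tuple[int, int]:
    """Map a half-open relative range [rel_start, rel_end) in an element's
    5'->3' frame (0 = anchor base) to a half-open genomic range.

    On the minus strand relative base ``r`` is genomic base ``anchor - r``,
    so the range mirrors to ``[anchor - rel_end + 1, anchor - rel_start + 1)``.
    """
    if rel_end <= rel_start:
        raise ValueError("empty relative range")
    if anchor_strand == "-":
        return anchor - rel_end + 1, anchor - rel_start + 1
    return anchor + rel_start, anchor + rel_end


# ---------------------------------------------------------------------------
# the track container
# ---------------------------------------------------------------------------

class SignalTrack:
    """Dense per-chromosome, per-strand non-negative signal.

    Raw tracks hold integer counts; normalized tracks hold non-negative
    reals and record the scale factor applied in ``metadata['norm_factor']``.
    Unstranded tracks (e.g. DNaseI hypersensitivity) use the single strand
    key ``'.'``.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], stranded: bool = True,
                 dtype=np.float64, metadata: Optional[dict] = None):
        self.chrom_sizes = dict(chrom_sizes)
        self.stranded = stranded
        self.metadata: dict = dict(metadata or {})
        keys = STRANDS if stranded else (UNSTRANDED,)
        self._arr: Dict[str, Dict[str, np.ndarray]] = {
            c: {s: np.zeros(n, dtype=dtype) for s in keys}
            for c, n in self.chrom_sizes.items()
        }

    # -- access -------------------------------------------------------------

    def array(self, chrom: str, strand: str = UNSTRANDED) -> np.ndarray:
        if not self.stranded:
            strand = UNSTRANDED
        return self._arr[chrom][strand]

    def set_array(self, chrom: str, strand: str, values: np.ndarray) -> None:
        arr = self.array(chrom, strand)
        if len(values) != len(arr):
            raise ValueError("length mismatch with chromosome size")
        if np.any(np.asarray(values) < 0):
            raise ValueError("signal values must be non-negative")
        key = UNSTRANDED if not self.stranded else strand
        self._arr[chrom][key] = np.asarray(values)

    @property
    def strands(self) -> Tuple[str, ...]:
        return STRANDS if self.stranded else (UNSTRANDED,)

    def total(self) -> float:
        return float(sum(a.sum() for c in self._arr.values() for a in c.values()))

    def copy(self) -> "SignalTrack":
        t = SignalTrack(self.chrom_sizes, self.stranded,
                        metadata=dict(self.metadata))
        for c in self._arr:
            for s in self._arr[c]:
                t._arr[c][s] = self._arr[c][s].copy()
        return t

    # -- strand selection in an element frame --------------------------------

    def _select(self, chrom: str, frame_strand: str, mode: str) -> np.ndarray:
        """Per-base values on the strand selected relative to a frame."""
        if not self.stranded:
            return self._arr[chrom][UNSTRANDED]
        if mode == "both":
            return self._arr[chrom]["+"] + self._arr[chrom]["-"]
        if mode == "unstranded":
            return self._arr[chrom]["+"] + self._arr[chrom]["-"]
        if frame_strand not in STRANDS:
            if mode in ("sense", "antisense"):
                raise ValueError("sense/antisense need a stranded frame")
        sense = frame_strand
        anti = "-" if frame_strand == "+" else "+"
        if mode == "sense":
            return self._arr[chrom][sense]
        if mode == "antisense":
            return self._arr[chrom][anti]
        raise ValueError(f"unknown strand mode {mode!r}")


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def _check_range(track: SignalTrack, chrom: str, start: int, end: int) -> None:
    n = track.chrom_sizes[chrom]
    if start < 0 or end > n:
        raise ValueError(
            f"range {chrom}:{start}-{end} off chromosome (size {n})"
        )


def query_rel_bins(track: SignalTrack, chrom: str, anchor: int,
                   anchor_strand: str, rel_start: int, bin_size: int,
                   n_bins: int, strand_mode: str = "sense") -> np.ndarray:
    """Exact bin sums over ``n_bins`` consecutive bins of ``bin_size`` bp
    starting at frame position ``rel_start``, ordered 5'->3' of the frame."""
    if bin_size <= 0 or n_bins <= 0:
        raise ValueError("bin_size and n_bins must be positive")
    gstart, gend = rel_to_genomic(anchor, anchor_strand, rel_start,
                                  rel_start + bin_size * n_bins)
    _check_range(track, chrom, gstart, gend)
    vals = track._select(chrom, anchor_strand, strand_mode)[gstart:gend]
    binned = vals.reshape(n_bins, bin_size).sum(axis=1)
    if anchor_strand == "-":
        binned = binned[::-1]
    return binned


def query_bins(track: SignalTrack, chrom: str, anchor: int, anchor_strand: str,
               bin_size: int, n_bins_flank: int, strand_mode: str = "sense"
               ) -> np.ndarray:
    """Bin sums flanking an anchor: 2*n_bins_flank bins covering frame
    positions [-n_bins_flank*bin_size, +n_bins_flank*bin_size)."""
    return query_rel_bins(track, chrom, anchor, anchor_strand,
                          -n_bins_flank * bin_size, bin_size,
                          2 * n_bins_flank, strand_mode)


def region_sum(track: SignalTrack, interval: GenomicInterval,
               strand_mode: str = "sense") -> float:
    _check_range(track, interval.chrom, interval.start, interval.end)
    vals = track._select(interval.chrom, interval.strand, strand_mode)
    return float(vals[interval.start:interval.end].sum())


def region_rpk(track: SignalTrack, interval: GenomicInterval,
               strand_mode: str = "sense") -> float:
    """Reads per kb: 1000 x (strand-selected counts in interval) / length."""
    if interval.length <= 0:
        raise ValueError("zero-length interval")
    return 1000.0 * region_sum(track, interval, strand_mode) / interval.length


def max_window(track: SignalTrack, search: GenomicInterval, window: int,
               strand_mode: str = "sense", step: int = 1
               ) -> Tuple[GenomicInterval, float]:
    """Highest-count window of ``window`` bp among all ``step``-bp-spaced
    placements fully inside ``search``.

    Ties are broken toward the most upstream placement in the element's
    5'->3' frame (leftmost for a plus frame, rightmost for a minus frame).
    Returns the winning window as a genomic interval (carrying the frame
    strand) and its RPK.
    """
    if window > search.length:
        raise ValueError("window longer than search region")
    if step <= 0:
        raise ValueError("step must be positive")
    _check_range(track, search.chrom, search.start, search.end)
    vals = track._select(search.chrom, search.strand, strand_mode)
    seg = vals[search.start:search.end]
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    starts = np.arange(0, search.length - window + 1, step)
    sums = cs[starts + window] - cs[starts]
    if search.strand == "-":
        # most upstream in frame = rightmost genomic placement
        idx = len(sums) - 1 - int(np.argmax(sums[::-1]))
    else:
        idx = int(np.argmax(sums))
    s = search.start + int(starts[idx])
    win = GenomicInterval(search.chrom, s, s + window, search.strand)
    return win, 1000.0 * float(sums[idx]) / window


# ---------------------------------------------------------------------------
# bedGraph / bigWig / interval file I/O
# ---------------------------------------------------------------------------

def _runs(arr: np.ndarray) -> Iterable[Tuple[int, int, float]]:
    """Yield (start, end, value) runs of constant value, skipping zeros."""
    n = len(arr)
    if n == 0:
        return
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    bounds = np.concatenate([[0], change, [n]])
    for i in range(len(bounds) - 1):
        s, e = int(bounds[i]), int(bounds[i + 1])
        v = arr[s]
        if v != 0:
            yield s, e, float(v)


def write_bedgraph(track: SignalTrack, path: str, strand: str = UNSTRANDED,
                   negative_minus: bool = False) -> None:
    """Write one strand of a track as 4-column bedGraph (zero runs omitted).

    ``negative_minus`` emits minus-strand magnitudes with a negative sign,
    a common dialect for run-on data.
    """
    sign = -1.0 if (negative_minus and strand == "-") else 1.0
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            arr = track.array(chrom, strand)
            for s, e, v in _runs(arr):
                v = sign * v
                if float(v).is_integer():
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6f}\n")


def read_bedgraph_into(track: SignalTrack, path: str, strand: str = UNSTRANDED
                       ) -> None:
    """Read a 4-column bedGraph into one strand of an existing track.

    Values are stored as magnitudes; negative values (minus-strand dialect)
    are accepted and folded to positive.
    """
    arr = {c: track.array(c, strand) for c in track.chrom_sizes}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            arr[chrom][int(s):int(e)] = abs(float(v))


def read_track(chrom_sizes: Mapping[str, int], plus_path: str,
               minus_path: str, metadata: Optional[dict] = None) -> SignalTrack:
    """Build a stranded SignalTrack from a pair of bedGraph files."""
    t = SignalTrack(chrom_sizes, stranded=True, metadata=metadata)
    read_bedgraph_into(t, plus_path, "+")
    read_bedgraph_into(t, minus_path, "-")
    return t


def write_bigwig(track: SignalTrack, path: str, strand: str = UNSTRANDED) -> None:
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(path, "w")
    bw.addHeader(list(track.chrom_sizes.items()))
    for chrom in track.chrom_sizes:
        arr = track.array(chrom, strand)
        starts, ends, vals = [], [], []
        for s, e, v in _runs(arr):
            starts.append(s)
            ends.append(e)
            vals.append(v)
        if starts:
            bw.addEntries([chrom] * len(starts), starts, ends=ends,
                          values=vals)
    bw.close()


def read_bigwig_into(track: SignalTrack, path: str, strand: str = UNSTRANDED
                     ) -> None:
    import pyBigWig

    bw = pyBigWig.open(path)
    for chrom in track.chrom_sizes:
        if chrom not in bw.chroms():
            continue
        vals = np.nan_to_num(
            np.asarray(bw.values(chrom, 0, track.chrom_sizes[chrom])))
        track.array(chrom, strand)[:] = np.abs(vals)
    bw.close()


def read_chrom_sizes(path: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, n = line.split()[:2]
                out[c] = int(n)
    return out


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3/BED6/narrowPeak into a DataFrame (columns named for the
    fields present; narrowPeak summit offset becomes an absolute `summit`)."""
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signal", "pvalue", "qvalue", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if "peak" in df.columns:
        df["summit"] = df["start"] + df["peak"]
    return df


def write_bed6(df: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    for c, default in (("name", "."), ("score", 0), ("strand", ".")):
        if c not in out.columns:
            out[c] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def write_narrowpeak(df: pd.DataFrame, path: str) -> None:
    """Write peaks with absolute `summit` column as 10-column narrowPeak."""
    out = df.copy()
    for c, default in (("name", "."), ("score", 0), ("strand", "."),
                       ("signal", 0.0), ("pvalue", -1.0), ("qvalue", -1.0)):
        if c not in out.columns:
            out[c] = default
    out["peak"] = out["summit"] - out["start"]
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signal", "pvalue", "qvalue", "peak"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)
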