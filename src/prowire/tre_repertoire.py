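"""Promoter vs dTRE classification and cross-condition repertoires.

Refined TREs are separated into promoters (at least one stable transcript)
and dTREs (unstable divergent transcripts in both directions) with a
Gaussian-kernel SVM on two feature families:

* the strand-specific PRO-seq shape around the element center, summarized
  as log1p read counts in fixed non-overlapping windows;
* sequence composition: GC fraction and CpG dinucleotide rate in a single
  window centered on the element (promoters sit in CpG-rich islands).

Feature geometry (number of windows, window size, CpG/GC window) is tuned
by five-fold cross-validated AUC — first the number of 50-bp windows, then
the window size at fixed genomic span — and every SVM fit tunes (gamma, C)
by an internal ten-fold cross-validation.  The decision boundary (score 0)
separates the classes; scores are emitted so users can re-threshold.

dTRE-classified elements that fall on an annotated TSS are relabeled
``excluded_tss`` and are not treated as distal elements.  dTREs are
quantified per strand over their full length (RPK plus the position of the
highest 50-nt window), and repertoires from two conditions are compared
with a 50%-overlap criterion and greedy one-to-one best-overlap matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     cross_val_score, train_test_split)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dreg_hd import HDFeatureSpec, extract_features
from .tracks import GenomicInterval, SignalTrack, max_window, region_rpk

PROMOTER, DTRE, EXCLUDED = "promoter", "dTRE", "excluded_tss"
QUANT_WINDOW = 50   # nt, per-strand maximum window inside a dTRE


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def tre_features(proseq: SignalTrack, chrom: str, center: int,
                 window_size: int = 50, n_windows: int = 10) -> np.ndarray:
    """Per-strand log1p window counts centered on a TRE (2*n_windows+1
    windows of window_size bp per strand)."""
    spec = HDFeatureSpec(window_size=window_size, n_windows=n_windows)
    return extract_features(proseq, chrom, center, spec)


def cpg_gc_features(sequence: str, center: int, window: int = 500
                    ) -> Tuple[float, float]:
    """(GC fraction, CpG dinucleotide rate) of the window centered on the
    element. CpG rate = CpG count / (window length - 1)."""
    start = max(center - window // 2, 0)
    seq = sequence[start:start + window].upper()
    if len(seq) < 2:
        raise ValueError("window too short for CpG counting")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    cpg = seq.count("CG") / (len(seq) - 1)
    return gc, cpg


def _proseq_matrix(proseq, sites, window_size, n_windows):
    return np.vstack([tre_features(proseq, s.chrom, int(s.pos),
                                   window_size, n_windows)
                      for s in sites.itertuples()])


def _cpg_matrix(seqs, sites, window):
    return np.array([cpg_gc_features(seqs[s.chrom], int(s.pos), window)
                     for s in sites.itertuples()])


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

@dataclass
class TREClassifierModel:
    pipeline: Pipeline            # combined features
    window_size: int
    n_windows: int
    cpg_window: int
    gamma: float | str
    C: float
    auc_proseq: float
    auc_cpg_gc: float
    auc_combined: float

    def features(self, proseq: SignalTrack, seqs: Dict[str, str],
                 sites: pd.DataFrame) -> np.ndarray:
        X1 = _proseq_matrix(proseq, sites, self.window_size, self.n_windows)
        X2 = _cpg_matrix(seqs, sites, self.cpg_window)
        return np.hstack([X1, X2])

    def score(self, proseq, seqs, sites: pd.DataFrame) -> np.ndarray:
        """Signed margin; positive = promoter-like."""
        return self.pipeline.decision_function(
            self.features(proseq, seqs, sites))


def _svm(gamma="scale", C=1.0) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(kernel="rbf", gamma=gamma, C=C))])


def _tuned_svm(seed: int, inner_folds: int = 10) -> GridSearchCV:
    grid = {"svm__gamma": ["scale", 0.01, 0.1], "svm__C": [1.0, 10.0]}
    cv = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
    return GridSearchCV(_svm(), grid, scoring="roc_auc", cv=cv)


def _cv_auc(X: np.ndarray, y: np.ndarray, seed: int, outer_folds: int = 5,
            inner_folds: int = 10) -> float:
    """Nested CV: outer 5-fold AUC of an SVM whose (gamma, C) are tuned by
    an internal 10-fold CV."""
    outer = StratifiedKFold(outer_folds, shuffle=True, random_state=seed)
    est = _tuned_svm(seed, inner_folds)
    scores = cross_val_score(est, X, y, scoring="roc_auc", cv=outer)
    return float(np.mean(scores))


def train_tre_classifier(sites: pd.DataFrame, proseq: SignalTrack,
                         seqs: Dict[str, str], seed: int = 0,
                         n_windows_grid: Sequence[int] = (2, 5, 10),
                         window_size_grid: Sequence[int] = (20, 50, 100),
                         cpg_window_grid: Sequence[int] = (200, 500, 1000),
                         holdout_fraction: float = 0.25
                         ) -> TREClassifierModel:
    """Two-stage tuning and final combined model.

    ``sites`` needs columns chrom, pos, label (label in {promoter, dTRE}).
    Stage 1 fixes 50-bp windows and picks the number of windows by 5-fold
    CV AUC; stage 2 re-tunes the window size at (approximately) fixed
    genomic span; the CpG/GC window is tuned likewise.  The final SVM is
    trained on the concatenated features with internal 10-fold CV for
    (gamma, C); held-out AUCs are reported for each component and the
    combination.
    """
    labels = sites["label"].to_numpy()
    classes = set(labels)
    if classes != {PROMOTER, DTRE}:
        raise ValueError("need both promoter and dTRE training labels")
    y = (labels == PROMOTER).astype(int)

    # stage 1: number of 50-bp windows
    best_n, best_auc = None, -np.inf
    for n in n_windows_grid:
        auc = _cv_auc(_proseq_matrix(proseq, sites, 50, n), y, seed)
        if auc > best_auc:
            best_n, best_auc = n, auc
    span = 50 * (2 * best_n + 1)

    # stage 2: window size at fixed span
    best_w, best_auc = None, -np.inf
    for w in window_size_grid:
        n = max(int(round((span / w - 1) / 2)), 1)
        auc = _cv_auc(_proseq_matrix(proseq, sites, w, n), y, seed)
        if auc > best_auc:
            best_w, best_auc = w, auc
    best_nw = max(int(round((span / best_w - 1) / 2)), 1)

    # CpG/GC window
    best_cpgw, best_auc = None, -np.inf
    for w in cpg_window_grid:
        auc = _cv_auc(_cpg_matrix(seqs, sites, w), y, seed)
        if auc > best_auc:
            best_cpgw, best_auc = w, auc

    X_pro = _proseq_matrix(proseq, sites, best_w, best_nw)
    X_cpg = _cpg_matrix(seqs, sites, best_cpgw)
    X = np.hstack([X_pro, X_cpg])
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=holdout_fraction, stratify=y,
        random_state=seed)

    def _holdout_auc(M):
        est = _tuned_svm(seed)
        est.fit(M[idx_train], y[idx_train])
        return float(roc_auc_score(
            y[idx_test], est.decision_function(M[idx_test]))), est

    auc_pro, _ = _holdout_auc(X_pro)
    auc_cpg, _ = _holdout_auc(X_cpg)
    auc_comb, est = _holdout_auc(X)

    final = _tuned_svm(seed)
    final.fit(X, y)
    params = final.best_params_
    return TREClassifierModel(
        pipeline=final.best_estimator_, window_size=best_w,
        n_windows=best_nw, cpg_window=best_cpgw,
        gamma=params["svm__gamma"], C=params["svm__C"],
        auc_proseq=auc_pro, auc_cpg_gc=auc_cpg, auc_combined=auc_comb)


def classify_tres(model: TREClassifierModel, elements: pd.DataFrame,
                  proseq: SignalTrack, seqs: Dict[str, str],
                  annotation: pd.DataFrame) -> pd.DataFrame:
    """Classify refined elements; any dTRE-scored element that overlaps an
    annotated TSS is relabeled excluded_tss.

    ``elements`` needs chrom, start, end and a center column ``pos``."""
    out = elements.copy()
    out["score"] = model.score(proseq, seqs, out)
    out["cls"] = np.where(out["score"] > 0, PROMOTER, DTRE)
    tss_pos = np.where(annotation["strand"] == "+", annotation["start"],
                       annotation["end"] - 1)
    tss_by_chrom: Dict[str, np.ndarray] = {
        c: np.sort(tss_pos[(annotation["chrom"] == c).to_numpy()])
        for c in annotation["chrom"].unique()}
    relabel = []
    for e in out.itertuples():
        hit = False
        pos = tss_by_chrom.get(e.chrom)
        if pos is not None and e.cls == DTRE:
            i = np.searchsorted(pos, e.start)
            hit = i < len(pos) and pos[i] < e.end
        relabel.append(EXCLUDED if hit else e.cls)
    out["cls"] = relabel
    return out


# ---------------------------------------------------------------------------
# dTRE quantification
# ---------------------------------------------------------------------------

@dataclass
class DTREQuant:
    dtre_id: str
    plus_rpk: float
    minus_rpk: float
    plus_window: GenomicInterval
    minus_window: GenomicInterval
    plus_summit: int
    minus_summit: int
    distance: int
    condition: str = ""


def quantify_dtre(proseq: SignalTrack, dtre, condition: str = ""
                  ) -> DTREQuant:
    """Per-strand RPK over the full element and the position of the highest
    50-nt window on each strand; ties go to the most 5' placement in each
    strand's own orientation. Summits are window midpoints."""
    plus_region = GenomicInterval(dtre.chrom, dtre.start, dtre.end, "+")
    minus_region = GenomicInterval(dtre.chrom, dtre.start, dtre.end, "-")
    plus_rpk = region_rpk(proseq, plus_region, "sense")
    minus_rpk = region_rpk(proseq, minus_region, "sense")
    pwin, _ = max_window(proseq, plus_region, QUANT_WINDOW, "sense")
    mwin, _ = max_window(proseq, minus_region, QUANT_WINDOW, "sense")
    ps, ms = pwin.midpoint, mwin.midpoint
    name = getattr(dtre, "dtre_id", getattr(dtre, "name", ""))
    return DTREQuant(dtre_id=str(name), plus_rpk=plus_rpk,
                     minus_rpk=minus_rpk, plus_window=pwin,
                     minus_window=mwin, plus_summit=ps, minus_summit=ms,
                     distance=abs(ps - ms), condition=condition)


def quantify_dtres(proseq: SignalTrack, dtres: pd.DataFrame,
                   condition: str = "") -> pd.DataFrame:
    rows = []
    for d in dtres.itertuples():
        q = quantify_dtre(proseq, d, condition)
        rows.append(dict(dtre_id=q.dtre_id, condition=condition,
                         plus_rpk=q.plus_rpk, minus_rpk=q.minus_rpk,
                         plus_summit=q.plus_summit,
                         minus_summit=q.minus_summit,
                         distance=q.distance))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repertoire comparison
# ---------------------------------------------------------------------------

@dataclass
class RepertoireComparison:
    shared: List[Tuple[int, int]]    # (index in A, index in B)
    a_only: List[int]
    b_only: List[int]
    criterion: str = "overlap >= 0.5 x len(A element), greedy best-overlap"


def compare_repertoires(dtres_a: pd.DataFrame, dtres_b: pd.DataFrame,
                        min_fraction: float = 0.5,
                        reciprocal: bool = False) -> RepertoireComparison:
    """Partition two dTRE repertoires (e.g. NHS vs HS) into shared /
    A-only / B-only.

    An A element is shareable with a B element when their overlap is at
    least ``min_fraction`` of the A element's length (of both lengths if
    ``reciprocal``). Matching is greedy by decreasing overlap, each element
    used at most once, so the three sets partition the union."""
    pairs = []
    for i, a in enumerate(dtres_a.itertuples()):
        for j, b in enumerate(dtres_b.itertuples()):
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov <= 0:
                continue
            ok = ov >= min_fraction * (a.end - a.start)
            if reciprocal:
                ok = ok and ov >= min_fraction * (b.end - b.start)
            if ok:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b = set(), set()
    shared = []
    for ov, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        shared.append((i, j))
        used_a.add(i)
        used_b.add(j)
    a_only = [i for i in range(len(dtres_a)) if i not in used_a]
    b_only = [j for j in range(len(dtres_b)) if j not in used_b]
    crit = (f"overlap >= {min_fraction} x len(A element)"
            + (", reciprocal" if reciprocal else "")
            + ", greedy best-overlap")
    return RepertoireComparison(shared=shared, a_only=a_only, b_only=b_only,
                                criterion=crit)
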