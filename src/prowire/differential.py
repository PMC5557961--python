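"""Negative-binomial differential test and response-class assignment.

Raw replicate counts (gene bodies, or dTRE strands over the full element)
are compared between control (NHS) and heat shock (HS) with a Wald test on
a negative-binomial model.  Size factors from the long-gene normalization
carry sequencing depth, so the test sees raw counts, as is standard for NB
models.

Dispersion is estimated per feature by method of moments across replicates
and then moderated toward the across-feature median with a fixed prior
weight.  With two replicates per condition the raw per-feature estimate is
extremely noisy — roughly half of genuinely overdispersed features would
get a near-zero estimate and wildly anti-conservative p-values — while the
median over thousands of features is stable; blending the two (information
sharing in the spirit of DESeq2/limma, without a fitted mean-dispersion
trend) keeps the test calibrated at the stringent thresholds used for
class calls.

Classes follow fixed raw-p cutoffs: genes need p <= 0.001, fold change
>= 1.25 and a candidate TRE score >= 0.7 at the TSS (otherwise Filtered);
dTREs are up/down when either strand passes p <= 0.05 and FC >= 1.25, and
"discordant" when both strands pass in opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
DISPERSION_PRIOR_WEIGHT = 24.0  # pseudo-replicates of the pooled estimate

GENE_P_MAX = 0.001
GENE_MIN_FC = 1.25
MIN_DREG_SCORE = 0.7
DTRE_P_MAX = 0.05
DTRE_MIN_FC = 1.25


def nb_test(counts_nhs: np.ndarray, counts_hs: np.ndarray,
            size_factors_nhs: Sequence[float],
            size_factors_hs: Sequence[float]) -> pd.DataFrame:
    """Vectorized NB Wald test, one row per feature.

    ``counts_*`` are (n_features, n_replicates) integer arrays. Size
    factors are the multipliers that put each sample on the baseline scale
    (counts are multiplied by them). Returns log2 fold change (HS/NHS, with
    a 0.5 pseudocount on scaled means), two-sided p, base mean, the
    moderated dispersion, and an ``all_zero`` flag (p = 1 there).
    """
    y0 = np.atleast_2d(np.asarray(counts_nhs, dtype=float))
    y1 = np.atleast_2d(np.asarray(counts_hs, dtype=float))
    if y0.shape[1] < 2 or y1.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    sf0 = np.asarray(size_factors_nhs, dtype=float)
    sf1 = np.asarray(size_factors_hs, dtype=float)
    q0 = y0 * sf0           # scaled counts
    q1 = y1 * sf1
    m0 = q0.mean(axis=1)
    m1 = q1.mean(axis=1)
    v0 = q0.var(axis=1, ddof=1)
    v1 = q1.var(axis=1, ddof=1)

    # method-of-moments dispersion per feature, averaged over conditions;
    # E[m^2] = mu^2 + Var/r, so m^2 - s^2/r debiases the denominator
    r0, r1 = y0.shape[1], y1.shape[1]
    d0 = m0 ** 2 - v0 / r0
    d1 = m1 ** 2 - v1 / r1
    with np.errstate(divide="ignore", invalid="ignore"):
        a0 = np.where(d0 > 0, (v0 - m0) / np.where(d0 > 0, d0, 1.0), np.nan)
        a1 = np.where(d1 > 0, (v1 - m1) / np.where(d1 > 0, d1, 1.0), np.nan)
    stacked = np.stack([a0, a1])
    valid = np.isfinite(stacked)
    raw = (np.where(valid, stacked, 0.0).sum(axis=0)
           / np.maximum(valid.sum(axis=0), 1))
    raw = np.clip(raw, 0.0, None)
    # pooled moment estimator: solve sum(s^2 - m) = alpha * sum(mu^2) over
    # all features and both conditions (stable and nearly unbiased where
    # the per-feature estimate is wildly noisy)
    num = np.nansum(v0 - m0) + np.nansum(v1 - m1)
    den = np.nansum(np.clip(d0, 0, None)) + np.nansum(np.clip(d1, 0, None))
    pooled = float(np.clip(num / den, 0.0, None)) if den > 0 else 0.0
    n_resid = (r0 - 1) + (r1 - 1)
    disp = ((n_resid * raw + DISPERSION_PRIOR_WEIGHT * pooled)
            / (n_resid + DISPERSION_PRIOR_WEIGHT))
    # per-feature evidence can only raise the dispersion above the pooled
    # value: with few replicates a low raw estimate is noise, and letting
    # it pull below the pool de-calibrates the extreme tail
    disp = np.maximum(np.maximum(disp, pooled), DISPERSION_FLOOR)

    # Wald statistic on the log ratio of scaled means (delta method);
    # Var(q_ij) = sf_j * mu + alpha * mu^2 on the baseline scale
    mu0 = np.maximum(m0, 1e-8)[:, None]
    mu1 = np.maximum(m1, 1e-8)[:, None]
    var_m0 = (sf0[None, :] * mu0 + disp[:, None] * mu0 ** 2).sum(axis=1) \
        / y0.shape[1] ** 2
    var_m1 = (sf1[None, :] * mu1 + disp[:, None] * mu1 ** 2).sum(axis=1) \
        / y1.shape[1] ** 2
    log_ratio = np.log(m1 + 0.5) - np.log(m0 + 0.5)
    se = np.sqrt(var_m0 / (m0 + 0.5) ** 2 + var_m1 / (m1 + 0.5) ** 2)
    z = np.where(se > 0, log_ratio / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (y0.sum(axis=1) + y1.sum(axis=1)) == 0
    p = np.where(all_zero, 1.0, p)
    lfc = np.where(all_zero, 0.0, log_ratio / np.log(2.0))
    return pd.DataFrame({
        "base_mean": (m0 + m1) / 2.0,
        "log2FC": lfc,
        "p_value": p,
        "dispersion": disp,
        "all_zero": all_zero,
    })


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, not used for classes)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _passes(p: float, lfc: float, p_max: float, min_fc: float,
            direction: int) -> bool:
    # min_fc applies to the fold-change magnitude in either direction
    return (p <= p_max and 2.0 ** abs(lfc) >= min_fc
            and (lfc > 0 if direction > 0 else lfc < 0))


def classify_genes(calls: pd.DataFrame, unexpressed: pd.Series,
                   dreg_scores: Mapping[str, float],
                   p_max: float = GENE_P_MAX, min_fc: float = GENE_MIN_FC,
                   min_dreg: float = MIN_DREG_SCORE) -> pd.DataFrame:
    """Assign Up / Down / UnCh / UnExp / Filtered to each tested gene.

    ``calls`` must be indexed by gene_id (or carry a gene_id column) with
    log2FC and p_value; ``dreg_scores`` maps gene_id to the best candidate
    TRE score at the TSS (absent = no TRE)."""
    df = calls.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    missing = unexpressed.index.difference(df.index)
    if len(missing):
        raise ValueError(f"missing differential call for genes {list(missing)[:5]}")
    classes = []
    for gid, row in df.iterrows():
        if bool(unexpressed.get(gid, False)):
            classes.append("UnExp")
            continue
        score = dreg_scores.get(gid)
        if score is None or score < min_dreg:
            classes.append("Filtered")
            continue
        if _passes(row["p_value"], row["log2FC"], p_max, min_fc, +1):
            classes.append("Up")
        elif _passes(row["p_value"], row["log2FC"], p_max, min_fc, -1):
            classes.append("Down")
        else:
            classes.append("UnCh")
    df["cls"] = classes
    df["dreg_score_at_tss"] = [dreg_scores.get(g, np.nan) for g in df.index]
    df["padj"] = bh_adjust(df["p_value"].to_numpy())
    return df


def classify_dtres(plus_calls: pd.DataFrame, minus_calls: pd.DataFrame,
                   p_max: float = DTRE_P_MAX, min_fc: float = DTRE_MIN_FC
                   ) -> pd.DataFrame:
    """Per-dTRE class from the two strand-specific tests.

    up/down when either strand passes in that direction; both directions
    significant -> "discordant" (reported, excluded from up/down sets)."""
    if not plus_calls.index.equals(minus_calls.index):
        raise ValueError("strand call tables must share the same index")
    classes = []
    for dtre_id in plus_calls.index:
        pr = plus_calls.loc[dtre_id]
        mr = minus_calls.loc[dtre_id]
        up = (_passes(pr["p_value"], pr["log2FC"], p_max, min_fc, +1)
              or _passes(mr["p_value"], mr["log2FC"], p_max, min_fc, +1))
        down = (_passes(pr["p_value"], pr["log2FC"], p_max, min_fc, -1)
                or _passes(mr["p_value"], mr["log2FC"], p_max, min_fc, -1))
        if up and down:
            classes.append("discordant")
        elif up:
            classes.append("up")
        elif down:
            classes.append("down")
        else:
            classes.append("unchanged")
    return pd.DataFrame({
        "cls": classes,
        "plus_log2FC": plus_calls["log2FC"],
        "plus_p": plus_calls["p_value"],
        "minus_log2FC": minus_calls["log2FC"],
        "minus_p": minus_calls["p_value"],
    }, index=plus_calls.index)


def assign_gene_groups(classified: pd.DataFrame,
                       nhs_quant: pd.DataFrame, hs_quant: pd.DataFrame
                       ) -> pd.DataFrame:
    """Gene groups used for promoter-architecture profiling.

    highly_up: Up with log2FC > 2 and body RPK gain (HS-NHS) > 200;
    moderately_up: the remaining Up genes; highly_transcribed: NHS body
    RPK > 500; all_transcribed: everything not UnExp."""
    nhs = nhs_quant.set_index("gene_id")["body_rpk"]
    hs = hs_quant.set_index("gene_id")["body_rpk"]
    out = classified.copy()
    delta = (hs - nhs).reindex(out.index).fillna(0.0)
    up = out["cls"] == "Up"
    out["highly_up"] = up & (out["log2FC"] > 2.0) & (delta > 200.0)
    out["moderately_up"] = up & ~out["highly_up"]
    out["highly_transcribed"] = nhs.reindex(out.index).fillna(0.0) > 500.0
    out["all_transcribed"] = out["cls"] != "UnExp"
    out["delta_rpk"] = delta
    return out
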