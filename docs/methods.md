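# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and quantification conventions

All intervals are 0-based half-open (BED). Each gene defines a frame with
position 0 on the TSS base, running 5'→3'; on the minus strand, relative
position *r* is genomic base `anchor − r`, and the sense/antisense strands
swap. Signal densities are RPK (reads per kb of region); every base is
treated as mappable, so region length is the denominator.

The pause call scans all 1-bp-step placements of a 50-nt window inside the
frame range −100..+400 (antisense divergent call: −800..+100) and keeps the
placement with the highest count. The half-open reading of the range gives
451 (resp. 851) placements. Ties are broken toward the most upstream
placement in the element's frame, which makes the "pause tightening toward
the TSS" readout well-defined; the scan step is configurable
(`pause_scan_step`, default 1). The gene body is +500..polyA−500, so genes
of ≤ 1000 nt have an undefined body and pausing index: they are emitted
with explicit missing values rather than dropped.

The pausing index is pause-window RPK divided by body RPK. Both terms are
length-normalized, so the index is dimensionless and equals 1 for a
uniformly covered gene. It is undefined (missing) when the body RPK is 0.

Gene filtering keeps genes ≥ 500 nt; among entries sharing a (chrom,
strand, TSS) the longest survives, ties by lexicographically first id.

`flag_unexpressed` uses body RPK < 0.5 and pause RPK < 2 in *every*
condition (strict inequalities). Both thresholds are configuration values.
Note that the pause term is a maximum over ~450 windows, so a handful of
background reads near the TSS can exceed 2 RPK; such genes fall through to
the `Filtered` class instead (their candidate-TRE score is below 0.7), and
the class partition is unaffected.

## Normalization

Reference regions are +100 kb..polyA−0.5 kb of genes strictly longer than
150 kb. During a 30-minute treatment, polymerase released before the
treatment has travelled at most elongation_rate × 30 min ≈ 60 kb, so these
regions are transcriptionally inert to the stimulus and differences there
measure sequencing depth. Both strands are summed (3' gene bodies are
overwhelmingly sense signal, so this choice is insensitive). The default
estimator is the ratio of total reference counts to the baseline sample; a
median-of-ratios alternative is available behind a flag. Factors are
fitted per replicate (a flag pools them), the baseline has factor 1 by
construction, and double application of a factor to a track is refused.

## Differential test and response classes

Raw counts (gene bodies on the sense strand; dTREs per strand over the
full element) enter a negative-binomial Wald test; size factors from the
normalization carry depth, as is standard for NB models — testing RPK
would destroy the count distribution.

Dispersion: a per-feature method-of-moments estimate across replicates is
computed per condition with a debiased denominator (E[m²] = μ² + Var/r)
and averaged; a single pooled moment estimate solves
Σ(s² − m) = α·Σμ̂² over all features and conditions. The working
dispersion blends the two with a prior weight of 24 pseudo-replicates and
is floored at the pooled value: with two replicates per condition the
per-feature estimate is so noisy that letting it pull *below* the pool
de-calibrates the extreme tail (p ≤ 0.001) where the class thresholds
operate, while genuine over-dispersion evidence can still raise it. This
is information sharing in the spirit of DESeq2/limma but without a fitted
mean–dispersion trend; the package is self-contained and the analysis
uses the test only at fixed thresholds. On a 5,000-feature null
simulation (dispersion 0.05, 2+2 replicates) the empirical type-I error
is within the nominal level at both 0.001 and 0.05, and 3-fold changes at
mean 200 are detected in ≈ 92% of features (`scripts/acceptance.py`
recomputes both).

The Wald statistic is the log ratio of size-factor-scaled condition means
(0.5 pseudocount) over a delta-method standard error; all-zero features
report p = 1, log2FC = 0, and a flag. A Benjamini–Hochberg column is
emitted for reference but classes use the fixed raw-p thresholds: genes
Up/Down at p ≤ 0.001 and fold-change magnitude ≥ 1.25 with the matching
sign, and only if a candidate TRE of score ≥ 0.7 overlaps TSS ± 200 bp
(otherwise `Filtered`); unexpressed flags take precedence. dTREs use
p ≤ 0.05 and FC ≥ 1.25 on either strand; strands significant in opposite
directions give `discordant`, reported but excluded from the up/down sets
rather than resolved by guesswork. Gene groups: `highly_up` = Up with
log2FC > 2 and ΔRPK > 200; `moderately_up` = remaining Up;
`highly_transcribed` = NHS body RPK > 500 (strict); `all_transcribed` =
not UnExp.

## DNaseI imputation and peak refinement

Features at a position are log1p window counts: 2·n+1 windows of
`window_size` bp per strand (defaults 50 bp, n = 10, ≈ 1 kb of context),
ordered left-to-right. The ε-SVR (RBF kernel) is trained on random
positions inside candidate regions extended 200 bp; targets are log1p
DNaseI values (flag to disable). Hyperparameters (γ, C, ε) come from a
small log-spaced grid scored by Pearson r on a holdout split; the winner
is refit on all sites and records its holdout r. Predictions are clipped
to the training-target range — an RBF regression extrapolating far from
its support can otherwise explode through the log back-transform.

Imputation evaluates the model every `step` bp (default 10) across each
candidate ± 200 bp. Peak calling fits a smoothing cubic spline (penalty
λ; λ = 0 selects smoothness by generalized cross-validation), evaluates
it at 1-bp resolution, takes strict local maxima with spline value ≥ τ,
merges apexes closer than 150 bp keeping the higher, and reports each
peak as the maximal run where the spline stays ≥ max(τ, half the apex).

The operating point (λ, τ) is grid-optimized against known DNaseI peaks:
sensitivity = fraction of true peaks with a called apex within 150 bp,
FDR = fraction of called apexes with no true peak within 150 bp; the
selected point maximizes sensitivity subject to FDR ≤ 0.10 (ties: lower
FDR, then smaller λ and τ). The λ grid spans 1e4–1e8 (the scale at which
a 10-bp-step profile over a few hundred points moves from wiggly to
single-peaked); the default τ grid spans fixed fractions of the global
profile maximum, because imputed profiles are mostly near-zero background
and absolute quantiles are uninformative. The 150-bp matching radius and
the 0.10 FDR cap are configuration values.

## Promoter/dTRE classification and repertoires

Two feature families describe each element center: per-strand log1p
window counts (promoters show a dominant stable-direction tail, dTREs two
short symmetric ones) and (GC fraction, CpG rate) in one window
(promoters sit in CpG-rich, GC-high islands). Tuning is two-stage: with
50-bp windows fixed, the window count is chosen by 5-fold
cross-validated AUC; the window size is then re-tuned at approximately
fixed genomic span; the CpG/GC window likewise. Every SVM fit selects
(γ, C) by internal 10-fold cross-validation. The final classifier trains
on the concatenated features; held-out AUCs are reported for each
component and the combination. The decision threshold is the SVM margin
at 0, with raw scores emitted for re-thresholding. dTRE-classified
elements overlapping an annotated TSS are relabeled `excluded_tss` and
never treated as distal elements.

dTRE quantification is per strand over the full element: RPK plus the
highest 50-nt window, ties to the most 5' placement in that strand's own
orientation; summits are window midpoints and the inter-summit distance
is their absolute difference (used as the heatmap sort key and the
element center for display).

Repertoire comparison uses a single-sided 50% criterion — the overlap
must reach half of the *query* element's length (boundary inclusive); a
`--reciprocal` flag demands both. Matching is greedy by decreasing
overlap with each element used once, so shared/A-only/B-only partition
the union (an intersection tool reporting all pairs does not give a
partition). The separate ≥ 1-nucleotide criterion used for factor-site
categorization is never conflated with this one.

## Profiles and factor integration

Composite profiles average per-anchor bin vectors (default 20-bp bins),
mirrored for minus-strand anchors. The uncertainty band resamples
*anchors* with replacement (the between-element interval is what a
per-group band means) and takes the 12.5th–87.5th percentiles of the
resampled means — a nominal 75% band whose empirical coverage on i.i.d.
synthetic anchors is ≈ 73%. Group scaling divides all of a factor's
profiles by the single highest mean bin across groups (global max = 1,
idempotent, within-group ratios preserved). Heatmaps use 10-bp bins by
default and a 4-bp strand-paired mode that interleaves sense/antisense
columns. Factor sites are categorized with ≥ 1 nt overlap, promoters
taking precedence over dTREs on double overlap (promoters are the
stricter annotation; a flag inverts). Gene binding uses TSS−2500..polyA
in the gene frame; the reported distance is from the nearest peak summit
to the sense pause-window midpoint, negative upstream. Binding scores are
an affine min–max map onto [107, 1000] (a stand-in for the public-track
score transform, whose exact form is not recoverable); degenerate
constant input maps to 1000. Spearman p-values are exact by permutation
enumeration for n ≤ 8 and use the t approximation above (full
enumeration beyond that is infeasible and the approximation is accurate);
Mann–Whitney U uses the exact small-sample distribution where tie-free.

## The synthetic genome

The generator lays out non-overlapping genes (log-uniform 2–15 kb plus
four forced 160–220 kb genes so the normalization premise is testable),
dTREs (200–400 bp) and untranscribed sites on one 6-Mb chromosome with
1–4 kb gaps, then draws classes (15% Up, 40% Down, 10% UnExp by default —
heat shock represses far more genes than it induces; long genes are never
UnExp so reference counts exist), expression (body 30–300 RPK,
pause enrichment 8–40×), pause offsets (+20..+60), divergent offsets
(110–250 bp upstream at 0.2–0.6× pause intensity), and dTRE geometry
(inter-summit distance 60–200 bp, summit windows 300–3000 RPK per strand,
short 150-bp unstable tails).

Heat shock multiplies Up-gene bodies by 3 and Down-gene bodies by 0.3 —
but only out to the wave front, elongation_rate × hs_duration = 60 kb,
modeled as a hard front (no rate is implied by the data; 2 kb/min is the
standard polymerase speed and both are configurable). Down genes also
gain pause density (×2) and their pause window shifts 10 bp toward the
TSS; beyond the front, and everywhere on unchanged genes, HS expectation
equals NHS exactly, which is what makes long-gene 3' ends valid
references. An optional global `hs_depth_factor` injects a
sequencing-depth difference for normalization-recovery experiments.

Counts are Gamma–Poisson: one Gamma(1/α, α) multiplier (mean 1,
dispersion α = 0.05) per replicate and per 1-kb block of an element
footprint, shared between the two conditions of the same replicate — a
paired design, as when one culture is split into control and treatment.
Block granularity matters: short elements (pause regions, dTREs) feel the
full dispersion across replicates, while 100-kb reference regions average
over ~100 blocks and stay depth-limited, so normalization factors are
recoverable to well under 2%. A uniform 1e-4 reads/base background is
added everywhere. With whole-element sharing instead, the handful of
long reference genes would carry ~10–15% biological noise between
samples and no depth estimator could meet that precision — a property of
the design, not of the estimator.

The DNaseI track is Gaussian-kernel smoothing (sd 150 bp) of the
initiation-proximal summed-strand PRO-seq signal (the divergent window
through the pause window of each transcribed element), scaled by an
arbitrary gain, plus i.i.d. Gaussian noise, clipped at zero. Its
noise-free local maxima are the ground-truth peaks for tuning: at
promoters the apex lies between the divergent summits but pulled toward
the (stronger) sense pause, so the naive inter-summit midpoint is not
the truth.

Sequence: i.i.d. background at GC 0.41; around promoters and dTREs
(± 700 bp) a first-order Markov chain with exact stationary GC and CpG
rate (promoters 0.60/0.08, dTREs 0.45/0.02), constructed by flux
balance so the stationary composition is exact. Factor peaks are placed
on promoters (summit −300..+50 of the TSS), dTRE midpoints (± 25 bp
jitter) and untranscribed sites in a configurable mix, with lognormal
raw intensities. Candidate broad TREs emulate an upstream detector:
scores ≥ 0.7 at expressed promoters and dTREs, sub-threshold scores at
unexpressed promoters and decoy sites.

Everything is deterministic given (params, seed); each product draws
from its own child RNG so adding one output never perturbs another.
The fraction of dTREs with paused-but-unreleased profiles is exposed as
a parameter (default 0) without any claim about its real-data value.

## What the simulator does not emulate — and what passing means

No mappability gaps, no multi-chromosome structure, no overlapping or
nested genes, no internal TSSs or run-through transcription (the very
artifacts the candidate-TRE filter guards against in real data), no
sequence motifs (category labels stand in for motif presence), no
read-level errors or alignment, and dispersion is homogeneous rather
than mean-dependent. Passing tests therefore demonstrates that the
implementations are correct and that the statistical machinery is
calibrated under the stated model — near-perfect classifier AUCs, for
instance, reflect cleanly separable synthetic classes, not expected
real-data performance, where the corresponding published-scale analyses
report AUCs near 0.9 and peak-calling sensitivity near 80% at 10% FDR.

## Problem sizes

Defaults were chosen so a full desk-scale run is comfortable on one CPU:
300 genes (≥ 100 downregulated for wave statistics), 80 dTREs, a 6-Mb
chromosome, 2 conditions × 2 replicates, 5,000-feature null calibration,
500 × 300-bootstrap coverage simulations. All sizes are parameters.
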