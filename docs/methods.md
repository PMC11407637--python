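# Methods

This note records the models, conventions, parameter defaults, and design
choices behind `ribostop`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and region geometry

All coordinates are 0-based, half-open, in transcript space. `cds_start` is
the A of the annotated AUG; `cds_end` is the exclusive end of the last sense
codon, so the stop codon occupies `[cds_end, cds_end+3)` and belongs to the
3′-UTR. The region partition tiles each transcript exactly once:

- 5′-UTR, then a start window of the AUG plus 3 flanking nt each side
  (9 nt when both flanks exist; truncated at transcript edges),
- CDS body, then a stop window of the stop codon plus 3 flanking nt each
  side,
- the figure-style extension (from the end of the stop window to the end of
  the readthrough extension), and the distal 3′-UTR.

Two extension conventions coexist deliberately. `rt_extension` runs from
the canonical stop codon (inclusive) to the next in-frame stop codon
(exclusive) and is the readthrough statistic's region — a P-site on the
stop codon is a ribosome that decoded the stop with a near-cognate tRNA, so
including it is mechanistically coherent. `fig4_extension` starts only
after the stop window, so region-occupancy percentages don't double-count
the stop codon. The 3-nt flanks absorbed into the start/stop windows are
likewise kept out of the CDS body so the six regions stay disjoint
(window priority).

Transcripts whose 3′-UTR contains no downstream in-frame stop get an
extension truncated to the last complete codon and an `open_extension`
flag; readthrough analysis excludes them by default because their extension
length is ill-defined.

The gene-overlap filter removes both members of any same-strand gene pair
whose genomic spans overlap by ≥ 18 nt (strict "< 18 nt" retention);
opposite strands are ignored and isoforms of one gene are never compared.

## P-sites, frames, metagene

Footprints of 20–23 nt and 27–32 nt are retained (configurable). The P-site
position is the read 5′ end plus a per-read-length offset from a
calibration table; when no table is supplied, offsets are estimated as the
modal distance from read 5′ ends to annotated start codons among reads
spanning them (≥ 200 reads per length; shorter-supported lengths inherit
the nearest length's offset). Frame is `(psite − cds_start) mod 3`;
footprints spanning region boundaries are assigned by P-site alone.

Metagene distances: from the start anchor, the AUG's first nt is 0; from
the stop anchor, the last sense nt is 0, so the stop codon occupies
distances 1–3 and "distance > 0" is exactly the 3′-UTR. Windows default to
−25…+80 nt around each anchor; profiles are normalized by the summed count
over both windows (jointly summing to 1). Pooling replicates before
normalization equals count-weighted combination of per-replicate profiles.

## Readthrough efficiency

For each mRNA and strain (replicates pooled),

RE = (frame-0 extension count / extension length) /
     (frame-0 CDS count / CDS length),

with the first 15 nt of the CDS excluded *from both the count and the
length*, so numerator and denominator are densities over identical support
(the wording "length of CDS" is ambiguous; consistency of support decides).
RE is reported only when CDS RPKM > 0.2 and extension RPKM > 0.1 (strict);
"detectable" is operationalized as exactly these filters. Library size for
RPKM is the total P-site-assigned, length-filtered footprint count of the
library — the most self-contained definition. RE = 0 is a valid value
(detectable mRNA, zero frame-0 extension count); undetectable mRNAs get NaN,
never 0.

Strain comparisons use two-sided Wilcoxon rank-sum tests over all strain
pairs with BH adjustment; strains with < 3 detectable mRNAs are skipped.
RE-vs-3′-UTR-length associations are Spearman correlations computed on all
detectable mRNAs and within each stop-codon stratum, with stratum sizes and
a low-n flag below 10.

## Translation efficiency and the NB test

CDS counting for TE keeps P-sites with `cds_start+15 ≤ pos < cds_end−3`
(initiation ramp and terminating ribosome excluded). Libraries are
normalized by median-of-ratios size factors against a geometric-mean
pseudo-reference, ribo and RNA layers separately. Note the factors are
relative: per-library depth changes with geometric mean 1 leave normalized
counts unchanged, while a uniform rescale of all libraries moves the
normalized scale, not the factors.

The differential test is deliberately generic rather than a re-implementation
of any published tool. Counts are modeled NB with per-gene dispersion α
(Var = μ + αμ²). α is estimated by pooled within-condition method of
moments, then shrunk 50/50 in log space toward a log-linear trend of
dispersion on mean. The test statistic is the log2 ratio of normalized
condition means over its delta-method standard error,
Var(log q̂) = Σⱼ (q/sⱼ + αq²) / (n q)², referred to a t distribution with
residual df (n−2) plus a prior df of 2 crediting the trend information —
the moderated-t logic; a plain normal reference is anticonservative at 3
replicates and the bare residual-df t is far too conservative. A 0.5
pseudocount (on the normalized scale) keeps zero-mean genes finite.
Contracts asserted in tests: type-I error at or below nominal on NB null
data (20 seeds) and ≥ 80% power on 4-fold changes at mean count 200;
directions and calls cross-checked against an independent NB framework on
injected changes.

Differential TE is the assay × strain interaction: log2fc_te =
log2fc_ribo − log2fc_rna, variance the sum of the layer variances, df the
sum of the layer dfs. Classes use adjusted p < 0.01 (RNA/ribo), < 0.05
(TE), < 0.015 (protein log2FC tables consumed externally), regardless of
fold-change magnitude. An optional independent-filtering stand-in (mean
count threshold maximizing rejections) is off by default so gene sets are
deterministic.

For one-sample "fold change vs zero" figure statistics the package exposes
the one-sample Wilcoxon signed-rank test (`signed_rank_vs_zero`) alongside
the two-sample rank-sum; reports should state which was used.

## Sequence features

- **uORFs**: every AUG starting in the 5′-UTR opens one; reading in its
  frame, a first stop ending at or before `cds_start` makes it *upstream*,
  otherwise (including no stop before the transcript end) *overlapping*.
  No minimum length.
- **poly(A)**: the stated rule ("at least 10 consecutive adenines…
  allowing at most 2 other nucleotides in the 10-A window") is internally
  contradictory; it is operationalized as *a 10-nt window containing ≥ 8 A*.
  For the 5′-UTR the scanned region extends through the first A of the main
  AUG (only up to that A).
- **oligo(U)**: an exact run of ≥ 7 U, no mismatches.
- **tAI**: W_i = Σ_j (1−s_ij)·tGCN_j over the Watson-Crick decoder and one
  wobble decoder per codon (G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68 —
  shipped as an editable TSV); w = W/max W; zero weights replaced by the
  geometric mean of nonzero weights. Codon optimality is the geometric mean
  of w over all CDS codons (stop excluded). tRNA gene copy numbers are user
  input; the bundled `tgcn_synthetic_yeastlike.tsv` is a synthetic table
  with yeast-like sparsity and copy-number range, for tests and simulations
  only — substitute a real copy-number table for biological work.
- **Stop context**: stop codon = positions +1+2+3, first 3′-UTR nt = +4;
  the record carries +4…+9, the last sense (P-site) codon, 3′-UTR and
  extension lengths. Missing positions on short UTRs are flagged, not
  fabricated.
- **Out-of-frame QC**: fraction of non-frame-0 P-sites in the last 30 nt of
  the CDS (≥ 30 footprints there for the correlation analysis; CDS
  RPKM > 0.2 and 3′-UTR RPKM > 0.1 throughout), the presence of +1/+2-frame
  stop triplets in the CDS, and their association with 3′-UTR footprint
  density (Spearman; rank-sum by flag).

## Random-forest importance

25 models per strain: 5-fold CV repeated 5 times, folds stratified by
response quantile (the stratification choice is ours; it stabilizes fold
difficulty for a skewed response). Each model: 100 trees, mtry = ⌊√p⌋,
seeds derived deterministically from a master seed. Categorical features
are one-hot encoded internally; importance permutes all member columns
jointly and is reported per original feature. Single-level features are
dropped with a warning.

%IncMSE is computed per tree on its out-of-bag samples — OOB membership is
reconstructed from each tree's recorded bootstrap seed — as
100·(MSE_permuted − MSE)/MSE, averaged over trees. Empirical p-values
refit the forest on permuted responses (the full null pipeline, so fitting
variability is in the null): p = (1 + #{null ≥ observed}) / (1 + n_perm).
The headline scheme uses 1,000 permutations; tests and the acceptance
script run 20–60 because the permutation count only sets p-value
resolution, which must merely sit below the 0.05 threshold (n_perm < 20 is
refused). A feature is *overall significant* at p < 0.05 in ≥ 15 of 25
models; with fewer models the rule rescales proportionally and is flagged
non-standard. NRMSE = held-out RMSE / range of the observed response.
Negative controls — a uniform random number and a 4-level random factor —
are appended to every feature table and are expected never to reach overall
significance.

## Synthetic data generator

The generator emulates the assumed study design: 3 strains × 3 replicates;
footprints CDS-dominant with frame-0 fidelity f = 0.95 (off-frame reads
jittered ±1 nt); per-transcript readthrough rates ρ log-normal
(log₁₀ mean −1.7, sd 0.35 → median ≈ 2%), scaled per strain (default
mutant ×3, capped at 0.9); extension frame-0 density = CDS frame-0
density × ρ, distal 3′-UTR density = × ρ² (double readthrough, no extra
free parameter); uniform background at 5×10⁻⁴ reads/nt; RNA counts NB with
dispersion 0.05 (a typical replicate-level value for yeast count data);
read lengths drawn over the admitted set with a mode at 28 nt and offsets
in the calibration-table shape (28-mer offset 12). Transcript geometry is
yeast-like: 24–60 nt 5′-UTRs, 80–250 codon CDSs, extensions of 2–12 codons,
30–150 nt distal 3′-UTRs. Feature-planting probabilities (uORFs ~23%,
tracts ~8–10%) give informative but unsaturated feature tables. Sequences
are rejection-sampled so every planted feature — and no accidental one —
is re-detected by the scanners, and no in-frame stop precedes the planted
extension-terminating stop. All randomness flows from one master seed;
fixtures on disk carry a manifest with the config hash and seed.

Because extension occupancy is density-proportional by construction, the
true ρ and the readthrough-efficiency statistic are estimands of each
other; parameter-recovery tests therefore measure estimator noise and
filter-induced selection, not model misfit. Real libraries additionally
contain rRNA contamination, cloning biases, codon-level pausing,
UTR-annotation errors and mapping artifacts that the generator does not
emulate — passing tests demonstrate correctness of the accounting and
calibration of the statistics under the stated model, not robustness to
those artifacts.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen so each check is decisive at
desk scale: recovery fixtures use deep coverage (≈ 20,000–30,000 CDS reads
per transcript) because at routine depth the extension of a ρ ≈ 0.5–2%
mRNA receives < 1 read and the detectability filter then selects upward
fluctuations — the same selection bias is visible in the shallow-coverage
strain contrast, where the detectable-set median ratio underestimates the
planted ×3. Null calibrations run 10–20 seeds at 800–2,000 genes. TE
recovery error at 3 replicates is dominated by the NB dispersion, not
depth; at α = 0.05 the interaction's standard error is ≈ 0.35 log2 units,
putting the median absolute error near 0.2.

Ties in rank statistics use average ranks; the rank-sum test is exact for
min(n) ≤ 8 without ties, else normal with tie and continuity corrections.
Spearman p-values are exact-permutation for n ≤ 8 (the threshold is an
argument), t-approximate above. BH adjustment is the standard step-up with
ties preserved. χ² tests with any expected count < 1 fall back to Fisher
for 2×2 tables. Welch is the default t-test; the pooled variant is a flag.
Degenerate inputs (all-tied samples, zero rank variance, all-zero genes,
empty regions) return flagged results or are excluded — never silent zeros.

## Known limitations

- Genome-space alignment, splice graphs, and UTR annotation inference are
  out of scope; inputs are transcript-space alignments and an annotation
  with UTR lengths.
- The NB test is calibrated but not bit-compatible with published
  differential-expression tools; do not expect identical gene lists.
- The readthrough statistic cannot distinguish genuine readthrough from
  frame-0 3′-UTR footprints of other origins; the frame-0 restriction
  reduces but does not remove this contamination (quantified in tests via
  the frame-0 vs all-frame bias comparison).
- Permutation importance at reduced n_perm has coarse p resolution; near
  the 0.05 threshold the ≥ 15/25 rule is the stabilizing element.
- The bundled tRNA copy-number table is synthetic; codon-optimality values
  from it are only meaningful relative to each other within simulations.
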