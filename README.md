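# ribostop

Frame-resolved ribosome-profiling analysis of **stop-codon readthrough**,
translation efficiency, and the mRNA features that predict readthrough.

When a ribosome reaches a stop codon, release factors usually terminate
translation — but occasionally a near-cognate tRNA decodes the stop instead
and elongation continues in frame into the 3′-UTR, until the next in-frame
stop codon. `ribostop` quantifies this *readthrough* transcriptome-wide from
ribosome footprint data, and is aimed at groups studying translation
termination, nonsense-mediated decay, or 3′-UTR regulation in yeast-like
transcriptomes.

## What it computes

**Region partition.** Each mRNA is tiled into 5′-UTR, a 9-nt start window
(AUG ± 3 nt), CDS body, a 9-nt stop window, the *extension* (stop codon
inclusive, to the next in-frame stop codon exclusive — the region a
readthrough ribosome traverses), and the *distal 3′-UTR* beyond it. The stop
codon is counted as part of the 3′-UTR, so "CDS" always means the sense
codons only.

**Readthrough efficiency.** Footprints are filtered to 20–23 nt and 27–32 nt,
assigned P-sites via a per-read-length offset table, and given a reading
frame `(psite − cds_start) mod 3`. Per mRNA,

```
RE = (frame-0 count in extension / extension length)
     ─────────────────────────────────────────────────
     (frame-0 count in CDS      / CDS length)
```

with the first 15 nt of the CDS excluded from count and length, reported
only for mRNAs with CDS RPKM > 0.2 and extension RPKM > 0.1. Strain
distributions are compared with two-sided Wilcoxon rank-sum tests
(Benjamini–Hochberg adjusted), and RE is correlated with 3′-UTR length
overall and per stop codon (Spearman).

**Translation efficiency.** TE = CDS footprint density / mRNA abundance on
median-of-ratios-normalized counts, excluding P-sites in UTRs and in the
first 15 / last 3 nt of the CDS. Differential abundance and differential TE
use a generic negative-binomial Wald test (method-of-moments dispersions
shrunk to a mean–dispersion trend); genes are classed Up/Down/Unchanged at
adjusted p < 0.01 (RNA) and < 0.05 (TE).

**mRNA features.** uORFs (AUG-initiated, upstream vs overlapping), poly(A)
tracts (≥ 8 A in a 10-nt window, the A of the main AUG included), oligo(U)
runs (≥ 7 U), codon optimality as the geometric mean of tAI weights (from
tRNA gene copy numbers with wobble-pairing penalties), stop codon and its
+4…+9 context, P-site codon, and out-of-frame QC quantities.

**Feature importance.** Readthrough efficiency is regressed on the feature
table with random forests under 5-fold cross-validation repeated 5 times
(25 models, 100 trees, mtry = √p). Importance is %IncMSE on per-tree
out-of-bag samples; empirical p-values come from response-permutation
refits, and a feature is significant when p < 0.05 in ≥ 15 of 25 models.
Model quality is NRMSE (held-out RMSE / response range). Random continuous
and categorical columns serve as negative controls.

**Synthetic data.** `ribostop.synthetic` generates transcriptomes with
planted, re-detectable features, frame-0-biased footprints whose extension
occupancy is proportional to a known per-transcript readthrough rate ρ
(distal 3′-UTR at ρ², i.e. double readthrough), and NB-distributed RNA
counts — so every stage of the pipeline is testable against ground truth.

## Worked example

```python
import numpy as np
from ribostop import annotation, psite, readthrough, synthetic

cfg = synthetic.SimConfig(
    n_transcripts=100,
    seed=7,
    strains=(
        synthetic.StrainConfig("wt"),
        synthetic.StrainConfig("mutant", rt_multiplier=3.0),
    ),
)
transcripts, truth = synthetic.simulate_transcriptome(cfg)
footprints = synthetic.simulate_footprints(transcripts, truth, cfg)

partitions = {tid: annotation.partition_regions(tr) for tid, tr in transcripts.items()}
kept = psite.filter_read_lengths(footprints)
psites = psite.assign_psites(
    kept, psite.PsiteOffsetTable(dict(cfg.offsets)), transcripts, partitions
)
print(f"frame-0 share in CDS body: {psite.frame0_share(psites, 'cds_body'):.3f}")

pooled = readthrough.pool_libraries(psites, synthetic.strain_of_library(cfg))
rt = readthrough.readthrough_table(pooled, partitions, groupby="strain")
det = rt[rt["detectable"]]
for strain, grp in det.groupby("strain"):
    print(f"{strain}: median readthrough efficiency = "
          f"{grp['readthrough_efficiency'].median():.4f} (n={len(grp)})")

comp = readthrough.compare_strain_distributions(rt)
row = comp.iloc[0]
print(f"{row['strain_a']} vs {row['strain_b']}: rank-sum padj = {row['padj']:.2e}")
```

Output:

```
frame-0 share in CDS body: 0.949
mutant: median readthrough efficiency = 0.0919 (n=81)
wt: median readthrough efficiency = 0.0408 (n=52)
mutant vs wt: rank-sum padj = 6.86e-06
```

The simulated frame fidelity is 0.95 and the mutant's readthrough rate is
tripled; the pipeline recovers the 95% frame-0 share, a ~2–3× shift in the
median efficiency (attenuated slightly by the detectability filter on the
lower-coverage wild type), and calls the strain difference highly
significant.

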