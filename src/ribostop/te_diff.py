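"""Translation-efficiency (TE) quantification and generic negative-binomial
differential testing.

TE is ribosome-footprint density over the CDS normalized to mRNA abundance:
``TE = ribo_norm / rna_norm`` on median-of-ratios-normalized counts. CDS
footprint counting excludes P-sites in the UTRs and in the first 15 nt and
last 3 nt of the CDS (initiation ramp and termination pause).

The differential machinery is deliberately generic: NB counts with per-gene
dispersions estimated by method of moments and shrunk toward a log-linear
mean-dispersion trend, Wald tests on log2 fold changes of normalized means,
and Benjamini-Hochberg adjustment. It is calibrated (type-I error at or
below nominal on NB null data) rather than bit-compatible with any published
tool. TE changes are tested as the ribo/rna interaction: the difference of
the ribo-layer and rna-layer log2 fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ribostop.annotation import RegionPartition
from ribostop.stats import bh_adjust

#: classification thresholds on adjusted p-values, per analysis layer
PADJ_THRESHOLDS = {"rna": 0.01, "ribo": 0.01, "te": 0.05, "protein": 0.015}

CDS_HEAD_TRIM = 15
CDS_TAIL_TRIM = 3

#: extra Wald df credited for the trend component of the shrunk dispersion
DISPERSION_PRIOR_DF = 2


@dataclass
class CountMatrix:
    """Gene x library integer counts with library metadata."""

    counts: pd.DataFrame  # genes x libraries
    strain: Mapping[str, str]  # library -> condition label
    assay: str = "ribo"
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [c for c in self.counts.columns if c not in self.strain]
        if missing:
            raise KeyError(f"libraries without a strain label: {missing}")

    def normalized(self) -> pd.DataFrame:
        sf = self.size_factors if self.size_factors is not None else size_factors(self.counts)
        return self.counts / sf


def cds_counts_for_te(
    psites: pd.DataFrame, partitions: Mapping[str, RegionPartition]
) -> pd.DataFrame:
    """Per-gene CDS footprint counts for TE analysis.

    Keeps P-sites with ``cds_start + 15 <= pos < cds_end - 3`` only; UTR
    footprints and the initiation/termination windows are discarded. Returns
    a genes x libraries count frame (all partitioned transcripts, zero-filled).
    """
    df = psites[psites["transcript_id"].isin(partitions.keys())]
    lo = df["transcript_id"].map(lambda t: partitions[t].cds_start + CDS_HEAD_TRIM)
    hi = df["transcript_id"].map(lambda t: partitions[t].cds_end - CDS_TAIL_TRIM)
    keep = (df["psite_pos"] >= lo) & (df["psite_pos"] < hi)
    kept = df.loc[keep]
    mat = (
        kept.groupby(["transcript_id", "library_id"])["count"]
        .sum()
        .unstack(fill_value=0)
    )
    libs = sorted(psites["library_id"].unique())
    mat = mat.reindex(index=sorted(partitions.keys()), columns=libs, fill_value=0)
    return mat.fillna(0).astype(int)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean pseudo-reference.

    Only genes with nonzero counts in every library enter the reference; a
    matrix with no such gene is an error (use a pseudo-reference upstream).
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all libraries; median-of-ratios "
            "is undefined (consider filtering or a pseudo-reference)"
        )
    ref = np.exp(np.log(arr[all_nonzero]).mean(axis=1))
    ratios = arr[all_nonzero] / ref[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _dispersions(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion: within-group method of moments, shrunk 50/50
    (log scale) toward a log-linear mean-dispersion trend."""
    n_genes = norm.shape[0]
    mu = norm.mean(axis=1)
    # pooled within-group variance (residual df across groups)
    ss = np.zeros(n_genes)
    df_tot = 0
    for idx in groups:
        sub = norm[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df_tot += len(idx) - 1
    var = ss / max(df_tot, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (var - mu) / mu**2
    mom = np.where(np.isfinite(mom), mom, 0.0)
    mom_floor = np.maximum(mom, 1e-8)

    ok = (mu > 0) & (mom > 1e-6)
    if ok.sum() >= 10:
        x = np.log(mu[ok])
        y = np.log(mom_floor[ok])
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(divide="ignore"):
            trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-8)))
    else:
        trend = np.full(n_genes, np.exp(np.log(mom_floor[ok]).mean()) if ok.any() else 0.1)
    disp = np.exp(0.5 * np.log(mom_floor) + 0.5 * np.log(np.maximum(trend, 1e-8)))
    return np.clip(disp, 1e-8, 10.0)


def _wald_lfc(
    counts: pd.DataFrame,
    sf: pd.Series,
    cond_a: list[str],
    cond_b: list[str],
    disp: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald-type test of log2(mean_b / mean_a) on normalized NB counts.

    Var(log q_hat_c) is the delta-method variance of the mean of normalized
    counts: sum_j (mu_ij + a mu_ij^2) / s_j^2 / (n q)^2 with mu_ij = s_j q.
    The statistic is referred to a t distribution with residual degrees of
    freedom (n_a + n_b - 2) plus a prior df of 2 crediting the information
    the mean-dispersion trend contributes to the shrunk dispersion (limma's
    moderated-t logic). A plain normal reference is anticonservative at the
    3-replicate design; the plain residual-df t is far too conservative.
    """
    norm = (counts / sf).to_numpy(dtype=float)
    cols = list(counts.columns)
    ia = [cols.index(c) for c in cond_a]
    ib = [cols.index(c) for c in cond_b]
    if disp is None:
        disp = _dispersions(norm, [np.array(ia), np.array(ib)])
    sfv = sf.to_numpy(dtype=float)

    qa = norm[:, ia].mean(axis=1)
    qb = norm[:, ib].mean(axis=1)
    qa_s = qa + pseudocount / sfv[ia].mean()
    qb_s = qb + pseudocount / sfv[ib].mean()
    lfc = np.log2(qb_s / qa_s)

    def var_log_q(q: np.ndarray, idx: list[int]) -> np.ndarray:
        s = sfv[idx]
        n = len(idx)
        qs = np.maximum(q, pseudocount / s.mean())
        # sum over libraries of Var(K_ij / s_j) = (s_j q + a s_j^2 q^2)/s_j^2
        v = (qs[:, None] / s[None, :] + disp[:, None] * qs[:, None] ** 2).sum(axis=1)
        return v / (n * qs) ** 2

    var_log = var_log_q(qa, ia) + var_log_q(qb, ib)
    se_lfc = np.sqrt(var_log) / np.log(2)
    z = np.where(se_lfc > 0, lfc / se_lfc, 0.0)
    dof = max(len(ia) + len(ib) - 2, 1) + DISPERSION_PRIOR_DF
    pvalue = 2 * sps.t.sf(np.abs(z), dof)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "se": se_lfc,
            "stat": z,
            "pvalue": pvalue,
            "dof": dof,
            "dispersion": disp,
        },
        index=counts.index,
    )


def nb_differential(
    cm: CountMatrix,
    contrast: tuple[str, str],
    independent_filtering: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Generic NB differential test between two conditions.

    ``contrast = (reference, treatment)``; ``log2fc`` is treatment over
    reference. All-zero genes are excluded (no p-value). With
    ``independent_filtering=True``, a mean-normalized-count threshold chosen
    to maximize BH rejections at ``alpha`` masks low-count genes before
    adjustment (their padj is NaN); default off for deterministic gene sets.
    Single-replicate conditions fall back to pooled dispersion across all
    libraries with a prominent warning.
    """
    ref, trt = contrast
    libs_a = [l for l in cm.counts.columns if cm.strain[l] == ref]
    libs_b = [l for l in cm.counts.columns if cm.strain[l] == trt]
    if not libs_a or not libs_b:
        raise ValueError(f"contrast {contrast}: condition with no libraries")
    sub = cm.counts[libs_a + libs_b]
    nonzero = sub.sum(axis=1) > 0
    sub = sub.loc[nonzero]
    sf = (cm.size_factors.loc[libs_a + libs_b]
          if cm.size_factors is not None else size_factors(sub))

    if min(len(libs_a), len(libs_b)) < 2:
        warnings.warn(
            "a condition has a single replicate; dispersion pooled across ALL "
            "libraries — interpret p-values with caution"
        )
        norm = (sub / sf).to_numpy(dtype=float)
        disp = _dispersions(norm, [np.arange(norm.shape[1])])
        res = _wald_lfc(sub, sf, libs_a, libs_b, disp=disp)
    else:
        res = _wald_lfc(sub, sf, libs_a, libs_b)

    if independent_filtering:
        res["padj"] = _independent_filter_padj(res, alpha)
    else:
        res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def _independent_filter_padj(res: pd.DataFrame, alpha: float) -> np.ndarray:
    """Mean-count threshold grid search maximizing BH rejections at alpha."""
    base = res["base_mean"].to_numpy()
    p = res["pvalue"].to_numpy()
    qs = np.quantile(base, np.linspace(0, 0.95, 20))
    best_padj, best_rej = None, -1
    for thr in qs:
        keep = base >= thr
        if keep.sum() == 0:
            continue
        padj = np.full(p.size, np.nan)
        padj[keep] = bh_adjust(p[keep])
        rej = int((padj[keep] < alpha).sum())
        if rej > best_rej:
            best_rej, best_padj = rej, padj
    return best_padj


def te_differential(
    ribo: CountMatrix,
    rna: CountMatrix,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Differential translation efficiency between two strains.

    ``log2fc_te = log2((ribo_trt/rna_trt) / (ribo_ref/rna_ref))`` on
    normalized means — the assay x strain interaction. Its Wald variance is
    the sum of the four layer variances (layers are independent libraries).
    Genes present in only one layer are dropped. Classes at padj < 0.05.
    """
    shared = ribo.counts.index.intersection(rna.counts.index)
    dropped = len(ribo.counts.index.union(rna.counts.index)) - len(shared)
    if dropped:
        warnings.warn(f"{dropped} genes present in only one layer; dropped")

    ribo_res = nb_differential(
        CountMatrix(ribo.counts.loc[shared], ribo.strain, "ribo"), contrast
    )
    rna_res = nb_differential(
        CountMatrix(rna.counts.loc[shared], rna.strain, "rna"), contrast
    )
    idx = ribo_res.index.intersection(rna_res.index)
    r, m = ribo_res.loc[idx], rna_res.loc[idx]

    lfc_te = r["log2fc"] - m["log2fc"]
    se = np.sqrt(r["se"] ** 2 + m["se"] ** 2)
    z = np.where(se > 0, lfc_te / se, 0.0)
    dof = int(r["dof"].iloc[0] + m["dof"].iloc[0])
    pvalue = 2 * sps.t.sf(np.abs(z), dof)
    out = pd.DataFrame(
        {
            "log2fc_ribo": r["log2fc"],
            "log2fc_rna": m["log2fc"],
            "log2fc_te": lfc_te,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
        },
        index=idx,
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["te_class"] = classify(out["log2fc_te"], out["padj"], layer="te")
    return out


def te_values(ribo: CountMatrix, rna: CountMatrix) -> pd.DataFrame:
    """Per-gene TE (ribo_norm / rna_norm mean) per condition."""
    shared = ribo.counts.index.intersection(rna.counts.index)
    rn = ribo.normalized().loc[shared]
    mn = rna.normalized().loc[shared]
    conds = sorted(set(ribo.strain.values()))
    cols = {}
    for c in conds:
        rl = [l for l in rn.columns if ribo.strain[l] == c]
        ml = [l for l in mn.columns if rna.strain[l] == c]
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[f"te_{c}"] = rn[rl].mean(axis=1) / mn[ml].mean(axis=1)
    return pd.DataFrame(cols)


def classify(
    log2fc: Sequence[float], padj: Sequence[float], layer: str = "te",
    threshold: float | None = None,
) -> pd.Series:
    """Up/Down/Unchanged classes from adjusted p and fold-change sign.

    Thresholds follow the per-layer convention (RNA/ribo 0.01, TE 0.05,
    protein 0.015), regardless of fold-change magnitude.
    """
    thr = threshold if threshold is not None else PADJ_THRESHOLDS[layer]
    lfc = np.asarray(log2fc, dtype=float)
    pa = np.asarray(padj, dtype=float)
    cls = np.where(
        (pa < thr) & np.isfinite(pa),
        np.where(lfc > 0, "Up", "Down"),
        "Unchanged",
    )
    idx = log2fc.index if isinstance(log2fc, pd.Series) else None
    return pd.Series(cls, index=idx, name="class")


def classify_and_correlate(
    layers: Mapping[str, pd.DataFrame], min_shared: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-layer Up/Down/Unchanged classes and pairwise Spearman correlations
    of log2 fold changes across omics layers.

    ``layers`` maps layer name (a key of PADJ_THRESHOLDS) to a gene-indexed
    frame with ``log2fc`` and ``padj``; the protein layer is typically an
    external table. Pairs sharing fewer than ``min_shared`` genes are
    skipped.
    """
    from ribostop.stats import spearman

    classes = {}
    for name, df in layers.items():
        classes[name] = classify(df["log2fc"], df["padj"], layer=name)
    class_table = pd.DataFrame(classes)

    names = sorted(layers)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = layers[a].index.intersection(layers[b].index)
            va = layers[a].loc[shared, "log2fc"]
            vb = layers[b].loc[shared, "log2fc"]
            ok = va.notna() & vb.notna()
            if ok.sum() < min_shared:
                warnings.warn(f"{a} vs {b}: only {int(ok.sum())} shared genes; skipped")
                continue
            res = spearman(va[ok], vb[ok])
            rows.append({"layer_a": a, "layer_b": b, "rho": res.statistic,
                         "pvalue": res.pvalue, "n": int(ok.sum())})
    return class_table, pd.DataFrame(rows)
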