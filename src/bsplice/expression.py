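"""Normalization, differential expression, gene-set summaries, enrichment, PCA.

Differential expression uses a Welch t test per gene on log2(normalized
count + 1) -- a deliberately transparent substitute for a negative-binomial
GLM -- with the study's gates: Benjamini-Hochberg adjusted p < 0.001 and
|log2FC| > 0.5. Normalization is median-of-ratios; GO-style enrichment is a
one-sided hypergeometric test over flat gene sets with BH correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormalizationError


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean 1.

    Ratios are taken to the per-gene geometric mean over genes with
    all-positive counts; the factor vector is rescaled to geometric mean 1
    so a single sample gets factor exactly 1.
    """
    x = counts.counts.to_numpy(dtype=float)
    if x.size == 0 or not x.any():
        raise NormalizationError("cannot normalize an all-zero count matrix")
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise NormalizationError("no gene with positive counts in every sample")
    logx = np.log(x[allpos])
    log_gm = logx.mean(axis=1, keepdims=True)
    log_factors = np.median(logx - log_gm, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean -> 1
    return pd.Series(np.exp(log_factors), index=counts.sample_ids, name="size_factor")


def normalized_log2(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size factor + pseudocount), the scale all tests use."""
    sf = size_factors(counts)
    return np.log2(counts.counts / sf.to_numpy()[None, :] + pseudocount)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _welch_log2(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t on two log-scale matrices. Returns (mb - ma, p)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = mb - ma
    se2 = va / na + vb / nb
    p = np.ones_like(diff)
    nz = se2 > 0
    t = diff[nz] / np.sqrt(se2[nz])
    df = se2[nz] ** 2 / (
        (va[nz] / na) ** 2 / (na - 1) + (vb[nz] / nb) ** 2 / (nb - 1)
    )
    p[nz] = 2.0 * stats.t.sf(np.abs(t), df)
    return diff, p


def de_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.001,
    lfc_cut: float = 0.5,
) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    log2FC is the difference of group means of log2(normalized + 1), group B
    over group A. Genes with zero variance in both groups get p = 1. Returns
    a DataFrame with log2fc, pvalue, padj and status in {up, down, ns}.
    """
    sa = counts.samples_of(group_a)
    sb = counts.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("differential testing needs >= 2 replicates per group")
    log2 = normalized_log2(counts)
    diff, p = _welch_log2(log2[sa].to_numpy(), log2[sb].to_numpy())
    padj = bh_adjust(p)
    status = np.where(
        (padj < alpha) & (diff > lfc_cut),
        "up",
        np.where((padj < alpha) & (diff < -lfc_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": diff, "pvalue": p, "padj": padj, "status": status},
        index=counts.gene_ids,
    )


def geneset_direction_summary(
    de: pd.DataFrame, geneset: set[str]
) -> tuple[int, int, int]:
    """(n_up, n_down, n_in_set) for a gene set within a DE result.

    Mirrors directional statements of the form "88 of 410 mRNA-processing
    genes upregulated in MBC vs 36 in PC".
    """
    members = de.index.intersection(list(geneset))
    sub = de.loc[members, "status"]
    return int((sub == "up").sum()), int((sub == "down").sum()), len(members)


def go_enrichment(
    hits: set[str],
    universe: set[str],
    genesets: dict[str, set[str]],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``hits`` within flat gene sets.

    Per set: upper-tail probability of drawing at least the observed overlap
    when sampling ``len(hits)`` genes from the universe; BH across sets.
    Rows with fdr < ``fdr_cut`` carry ``reportable = True``.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for set_id, genes in genesets.items():
        in_univ = genes & universe
        k = len(in_univ & hits)
        n = len(in_univ)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append(
            {
                "geneset_id": set_id,
                "overlap": k,
                "set_size": n,
                "universe_size": M,
                "hits": N,
                "pvalue": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("geneset_id")
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
        out["reportable"] = out["fdr"] < fdr_cut
    return out


def pca_projection(counts: CountMatrix, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of samples on log2(normalized + 1).

    Genes are centered, not scaled. Component variances are non-increasing
    by construction of the SVD.
    """
    if len(counts.sample_ids) < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > len(counts.sample_ids):
        raise ValueError(
            f"cannot extract {n_components} components from "
            f"{len(counts.sample_ids)} samples"
        )
    x = normalized_log2(counts).to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    df = pd.DataFrame(
        scores,
        index=counts.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    df.attrs["explained_variance"] = pca.explained_variance_.tolist()
    return df


def sample_correlation(counts: CountMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples on the log scale (helper)."""
    return normalized_log2(counts).corr(method="pearson")
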