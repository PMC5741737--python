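"""Cross-analysis correspondence, signature overlap and sample-structure QC.

These summaries situate the keratinocyte results against the matched
whole-skin analysis and external expression signatures, and characterise
the sample-level structure of a paired cohort: samples cluster by subject
before tissue or status, so subject-residualised expression is needed to
see the disease signal, and per-gene likelihood-ratio attribution
quantifies which design factor dominates each gene's variation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import CountMatrix, DEResult, ExpressionMatrix
from .de import effective_library_sizes, estimate_dispersions
from .nbglm import drop_aliased_columns, fit_nb_glm


def fc_correspondence(
    de_a: DEResult, de_b: DEResult, sig_fdr: float = 0.10, discord_fc: float = 1.5
) -> tuple[pd.DataFrame, float]:
    """Per-gene fold-change correspondence between two analyses.

    Returns the (logFC_a, logFC_b) table over the genes detected in both
    analyses, with a Spearman rank correlation, and flags discordant genes:
    significant in analysis A (FDR < 0.10, |FC| beyond ``discord_fc``) with
    an opposite-sign or near-zero change in analysis B.
    """
    shared = de_a.detected_genes.intersection(de_b.detected_genes)
    shared = shared[
        de_a.table.loc[shared, "pvalue"].notna() & de_b.table.loc[shared, "pvalue"].notna()
    ]
    if len(shared) < 10:
        raise ValueError("fewer than 10 genes detected in both analyses")
    ta, tb = de_a.table.loc[shared], de_b.table.loc[shared]
    rs = float(stats.spearmanr(ta["logFC"], tb["logFC"]).statistic)
    lfc_cut = np.log2(discord_fc)
    sig_a = (ta["fdr"] < sig_fdr) & (ta["logFC"].abs() > lfc_cut)
    discordant = sig_a & (np.sign(tb["logFC"]) != np.sign(ta["logFC"]))
    table = pd.DataFrame(
        {"logFC_a": ta["logFC"], "logFC_b": tb["logFC"], "sig_a": sig_a, "discordant": discordant}
    )
    return table, rs


def signature_overlap(signature: pd.DataFrame, de: DEResult) -> dict:
    """Direction of an external signature's genes in a comparison.

    For the signature's resolvable genes, reports the fraction with FC
    below 1 (decreased) and above 1, with a two-sided sign test against
    0.5.  Needs at least 5 resolvable genes.
    """
    genes = [g for g in signature["gene"] if g in de.table.index]
    if len(genes) < 5:
        raise ValueError("fewer than 5 signature genes resolvable against the DE table")
    fc = de.table.loc[genes, "FC"]
    n_down = int((fc < 1.0).sum())
    n_up = int((fc > 1.0).sum())
    p = float(stats.binomtest(n_down, n_down + n_up, 0.5, alternative="two-sided").pvalue)
    return {
        "n_resolved": len(genes),
        "down_fraction": n_down / len(genes),
        "up_fraction": n_up / len(genes),
        "sign_test_p": p,
    }


def cumulative_overlap(ranking: list[str], query: set[str]) -> pd.DataFrame:
    """Cumulative overlap of a query gene set along a ranked gene list."""
    query = set(query)
    hits = np.fromiter((g in query for g in ranking), dtype=int, count=len(ranking))
    return pd.DataFrame(
        {"rank": np.arange(1, len(ranking) + 1), "cumulative_overlap": np.cumsum(hits)}
    )


def _log2p1(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + 1.0)


def sample_structure(expr: ExpressionMatrix | pd.DataFrame, meta: pd.DataFrame) -> dict:
    """Sample clustering, PCA and subject-residualised clustering.

    Expression is log2(x+1)-transformed; constant genes are dropped with a
    warning.  Samples are clustered by average linkage on the correlation
    distance 1 - Spearman r; PCA runs on gene-standardised log expression;
    the residualised matrix subtracts each gene's per-subject mean, so its
    subject means are zero and the disease signal becomes visible.

    Returns dict with: log_expr, distance (condensed), linkage, pcs,
    residualized, linkage_residualized, distance_residualized.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    logx = _log2p1(values)
    const = logx.std(axis=1) < 1e-12
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant genes")
        logx = logx.loc[~const]

    def spearman_linkage(mat: pd.DataFrame):
        rho = stats.spearmanr(mat.to_numpy(), axis=0).statistic
        rho = np.atleast_2d(rho)
        dist = 1.0 - rho
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        return condensed, linkage(condensed, method="average")

    dist, lk = spearman_linkage(logx)

    zs = (logx.sub(logx.mean(axis=1), axis=0)).div(logx.std(axis=1, ddof=0), axis=0)
    x = zs.to_numpy().T  # samples x genes
    xc = x - x.mean(axis=0, keepdims=True)
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(5, xc.shape[0])
    pcs = pd.DataFrame(xc @ vt[:k].T, index=logx.columns, columns=[f"PC{i+1}" for i in range(k)])

    subj = meta.loc[logx.columns, "subject"]
    resid = logx.copy()
    for s, cols in logx.columns.to_series().groupby(subj.values).groups.items():
        cols = list(cols)
        resid[cols] = logx[cols].sub(logx[cols].mean(axis=1), axis=0)
    dist_r, lk_r = spearman_linkage(resid.loc[resid.std(axis=1) > 1e-12])

    return {
        "log_expr": logx,
        "distance": dist,
        "linkage": lk,
        "pcs": pcs,
        "residualized": resid,
        "distance_residualized": dist_r,
        "linkage_residualized": lk_r,
    }


def nearest_sample(distance_condensed: np.ndarray, samples: pd.Index) -> pd.Series:
    """Each sample's nearest neighbour under a condensed distance matrix."""
    d = squareform(distance_condensed)
    np.fill_diagonal(d, np.inf)
    return pd.Series(samples[np.argmin(d, axis=1)], index=samples)


def factor_attribution(
    cm: CountMatrix, dispersion: float | pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene dominant design factor by NB-GLM deviance attribution.

    For each of subject, tissue and status, the factor's contribution is
    the likelihood-ratio deviance gained when it is added last to a model
    already containing the other two (aliased columns are dropped, so the
    partially confounded subject/status factors contribute only their
    estimable spans).  The dominant factor is the one with the largest
    deviance gain per estimable degree of freedom -- without the per-df
    scaling a many-level factor like subject would win on noise alone.
    Genes with a non-converged full fit are flagged NaN.
    """
    meta = cm.meta
    parts = {
        "subject": pd.get_dummies(meta["subject"], drop_first=True).to_numpy(dtype=float),
        "tissue": pd.get_dummies(meta["tissue"], drop_first=True).to_numpy(dtype=float),
        "status": pd.get_dummies(meta["status"], drop_first=True).to_numpy(dtype=float),
    }
    intercept = np.ones((len(meta), 1))
    offset = np.log(effective_library_sizes(cm).to_numpy())
    y = cm.counts.to_numpy(dtype=float)

    X_full = drop_aliased_columns(np.column_stack([intercept] + list(parts.values())))
    if dispersion is None:
        phi = estimate_dispersions(cm, X_full, offset=offset)["phi"].to_numpy()
    elif np.isscalar(dispersion):
        phi = np.full(y.shape[0], float(dispersion))
    else:
        phi = dispersion.loc[cm.genes].to_numpy()

    _, _, ll_full, conv = fit_nb_glm(y, X_full, offset, phi)
    out, dfs = {}, {}
    for name in parts:
        others = [v for k, v in parts.items() if k != name]
        X_red = drop_aliased_columns(np.column_stack([intercept] + others))
        _, _, ll_red, _ = fit_nb_glm(y, X_red, offset, phi)
        out[name] = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        dfs[name] = max(X_full.shape[1] - X_red.shape[1], 1)
    dev = pd.DataFrame(out, index=cm.genes)
    per_df = dev / pd.Series(dfs)
    dominant = per_df.idxmax(axis=1)
    dominant[~conv] = np.nan
    dev["dominant"] = dominant
    dev["converged"] = conv
    return dev
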