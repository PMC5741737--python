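"""Co-expression module construction and differentially expressed modules.

Modules are built on an independent reference expression matrix: genes are
row-centred, samples standardised, then clustered by average-linkage
hierarchical clustering on Euclidean distances; the dendrogram is cut to a
target cluster count and clusters below the 25-gene minimum are merged into
the cluster with the nearest centroid.  A module is summarised by its
centroid (per-sample mean), its medoid (member with minimal summed distance
to the rest) and its 25 centroid-nearest representative genes.

A differentially expressed module (DEM) is one whose 25 representatives
have log fold changes (from the uninvolved-vs-normal keratinocyte
comparison) shifted relative to all other clustered genes (two-sided
Wilcoxon rank-sum, BH across modules, FDR < 0.05); subsampling to 25
representatives equalises statistical power across module sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, ModuleSet
from .de import bh_adjust

MIN_MODULE_SIZE = 25
N_REPRESENTATIVES = 25
DEM_FDR_CUT = 0.05


def standardize_reference(ref: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Row-centre each gene, then standardise each sample to mean 0, var 1."""
    values = ref.values if isinstance(ref, ExpressionMatrix) else ref
    if values.shape[1] < 2:
        raise ValueError("need at least 2 reference samples")
    x = values.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=0, ddof=0)
    if (sd < 1e-12).any():
        raise ValueError("constant sample column after gene centring")
    x = (x - x.mean(axis=0, keepdims=True)) / sd
    return pd.DataFrame(x, index=values.index, columns=values.columns)


def build_modules(
    standardized: pd.DataFrame,
    min_size: int = MIN_MODULE_SIZE,
    n_clusters: int | None = None,
) -> ModuleSet:
    """Average-linkage Euclidean clustering with small-cluster merging.

    The dendrogram is cut into ``n_clusters`` groups; the default
    deliberately over-segments (one cluster per ~10 genes) because the
    nearest-centroid merge pass reassembles over-split modules while
    absorbing outlier singletons; a cut near the expected module count
    instead wastes branches on outliers and under-segments the rest.
    Every emitted module has at least ``min_size`` members.
    """
    genes = standardized.index
    if len(genes) < min_size:
        raise ValueError(f"need at least {min_size} genes to build modules")
    if n_clusters is None:
        n_clusters = max(len(genes) // 10, 2)
    Z = linkage(standardized.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")

    x = standardized.to_numpy()
    clusters = {c: list(np.flatnonzero(labels == c)) for c in np.unique(labels)}
    centroids = {c: x[idx].mean(axis=0) for c, idx in clusters.items()}
    while True:
        small = sorted((len(v), c) for c, v in clusters.items() if len(v) < min_size)
        if not small or len(clusters) == 1:
            break
        _, c = small[0]
        others = [k for k in clusters if k != c]
        d = [float(np.linalg.norm(centroids[c] - centroids[k])) for k in others]
        tgt = others[int(np.argmin(d))]
        clusters[tgt].extend(clusters.pop(c))
        centroids.pop(c)
        centroids[tgt] = x[clusters[tgt]].mean(axis=0)

    assignment = pd.Series(-1, index=genes, dtype=int)
    cent_rows, reps, medoids = {}, {}, {}
    for new_id, c in enumerate(sorted(clusters, key=lambda k: min(clusters[k]))):
        idx = clusters[c]
        assignment.iloc[idx] = new_id
        members = list(genes[idx])
        centroid, rep, medoid = module_centroid_and_representatives(members, standardized)
        cent_rows[new_id] = centroid
        reps[new_id] = rep
        medoids[new_id] = medoid
    centroids_df = pd.DataFrame.from_dict(cent_rows, orient="index")
    centroids_df.columns = standardized.columns
    return ModuleSet(
        assignment=assignment, centroids=centroids_df, representatives=reps, medoids=medoids
    )


def module_centroid_and_representatives(
    members: list[str], standardized: pd.DataFrame, n_rep: int = N_REPRESENTATIVES
) -> tuple[np.ndarray, list[str], str]:
    """(centroid, centroid-nearest representatives, medoid) of a module.

    Representatives are the ``n_rep`` members closest to the centroid in
    Euclidean distance (all members if the module has exactly ``n_rep``);
    distance ties break lexicographically by gene id, as does the medoid.
    """
    sub = standardized.loc[members]
    x = sub.to_numpy()
    centroid = x.mean(axis=0)
    d_cent = np.linalg.norm(x - centroid, axis=1)
    order = sorted(range(len(members)), key=lambda i: (d_cent[i], members[i]))
    rep = [members[i] for i in order[: min(n_rep, len(members))]]
    from scipy.spatial.distance import squareform

    pair = squareform(pdist(x, metric="euclidean"))
    total = pair.sum(axis=1)
    medoid = members[min(range(len(members)), key=lambda i: (total[i], members[i]))]
    return centroid, rep, medoid


def label_module(members: list[str], annotation: pd.DataFrame, medoid: str | None = None) -> str:
    """Label = "<member with most GO terms>-<module size>", ties lexicographic.

    Falls back to the medoid gene id when no GO counts are available.
    """
    if "go_n" not in annotation.columns or not set(members) & set(annotation.index):
        head = medoid if medoid is not None else sorted(members)[0]
        return f"{head}-{len(members)}"
    go = annotation.reindex(members)["go_n"].fillna(-1)
    best = min(members, key=lambda g: (-go[g], g))
    return f"{best}-{len(members)}"


def label_modules(modules: ModuleSet, annotation: pd.DataFrame) -> ModuleSet:
    for m in modules.module_ids:
        modules.labels[m] = label_module(modules.members(m), annotation, modules.medoids.get(m))
    return modules


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray, exact_max: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most ``exact_max``
    observations and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size <= exact_max and y.size <= exact_max and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def dem_test(
    modules: ModuleSet,
    logfc: pd.Series,
    fdr_cut: float = DEM_FDR_CUT,
    min_representatives: int = 10,
) -> pd.DataFrame:
    """Identify differentially expressed modules from per-gene log FCs.

    For each module, the log2 FCs of its representative genes are compared
    to the log2 FCs of all other clustered genes (two-sided Wilcoxon
    rank-sum); p-values are BH-adjusted across modules and direction
    (increased/decreased) is the sign of the representatives' median FC at
    FDR < ``fdr_cut``.  Representatives without an FC are dropped; a module
    retaining fewer than ``min_representatives`` is skipped with a warning.
    """
    clustered = modules.assignment.index[modules.assignment >= 0]
    fc = logfc.reindex(clustered)
    rows = []
    for m in modules.module_ids:
        reps = modules.representatives[m]
        rep_fc = fc.reindex(reps).dropna()
        if len(rep_fc) < min_representatives:
            warnings.warn(f"module {m}: only {len(rep_fc)} representatives with FC; skipped")
            rows.append((m, np.nan, np.nan, len(rep_fc)))
            continue
        members = set(modules.members(m))
        bg = fc[~fc.index.isin(members)].dropna()
        p = wilcoxon_rank_sum(rep_fc.to_numpy(), bg.to_numpy())
        rows.append((m, float(rep_fc.median()), p, len(rep_fc)))
    res = pd.DataFrame(rows, columns=["module", "median_fc", "pvalue", "n_rep"]).set_index("module")
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res["direction"] = "none"
    sig = res["fdr"] < fdr_cut
    res.loc[sig & (res["median_fc"] < 0), "direction"] = "decreased"
    res.loc[sig & (res["median_fc"] > 0), "direction"] = "increased"
    res["label"] = [modules.labels.get(m, str(m)) for m in res.index]
    return res


def dem_summaries(
    dems: pd.DataFrame,
    modules: ModuleSet,
    standardized: pd.DataFrame,
    down_degs: list[str],
    top_n: int = 20,
) -> dict:
    """Medoid-level summaries of the DEM analysis.

    Returns a dict with: ``medoid_linkage`` (average-linkage Euclidean
    linkage matrix over module medoid profiles), ``medoid_pcs`` (first two
    principal-component coordinates per module), ``medoid_spearman``
    (Spearman correlation matrix among the top-``top_n`` DEM medoids) and
    ``cumulative_down`` (cumulative fraction of the supplied decreased DEGs
    accounted for by modules ranked by their decreased-DEG count).
    """
    mids = modules.module_ids
    med_genes = [modules.medoids[m] for m in mids]
    M = standardized.loc[med_genes].to_numpy()

    med_linkage = linkage(M, method="average", metric="euclidean") if len(mids) > 1 else None

    Mc = M - M.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Mc, full_matrices=False)
    pcs = pd.DataFrame(Mc @ vt[:2].T, index=mids, columns=["PC1", "PC2"])

    ranked = dems.dropna(subset=["pvalue"]).sort_values("pvalue").index
    top = list(ranked[:top_n])
    if len(top) >= 2:
        sp = stats.spearmanr(standardized.loc[[modules.medoids[m] for m in top]].to_numpy(), axis=1)
        corr = np.atleast_2d(sp.statistic)
        if corr.shape == (1, 1) and len(top) == 2:  # scipy collapses the 2-row case
            r = float(corr[0, 0])
            corr = np.array([[1.0, r], [r, 1.0]])
        med_spear = pd.DataFrame(corr, index=top, columns=top)
    else:
        med_spear = pd.DataFrame(np.ones((len(top), len(top))), index=top, columns=top)

    down = set(down_degs)
    counts = {m: len(down & set(modules.members(m))) for m in mids}
    order = sorted(mids, key=lambda m: (-counts[m], m))
    cum, acc = [], 0
    denom = max(len(down), 1)
    for m in order:
        acc += counts[m]
        cum.append((m, modules.labels.get(m, str(m)), counts[m], acc / denom))
    cumulative = pd.DataFrame(cum, columns=["module", "label", "n_down_degs", "cumulative_fraction"])
    return {
        "medoid_linkage": med_linkage,
        "medoid_pcs": pcs,
        "medoid_spearman": med_spear,
        "cumulative_down": cumulative,
    }
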