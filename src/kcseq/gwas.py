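"""GWAS locus filtering and proximity enrichment of top-altered genes.

A curated risk-locus table (region, SNP, chromosome, position, association
p-value) is reduced to one most-significant locus per independent region;
genes are then collected within a grid of TSS-to-SNP distance windows and
their overlap with the most strongly altered genes of a comparison is
tested by a two-sided Fisher's exact test over the detected-gene universe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DEResult
from .de import bh_adjust

DEFAULT_WINDOWS = (10_000, 25_000, 50_000, 100_000, 150_000, 200_000, 300_000, 400_000, 500_000)
DEFAULT_TOP_N = 500


def filter_independent_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Keep the single most significant locus per independent region.

    Ties on p-value break by smaller position, then lexicographic SNP id.
    Rows with a missing p-value are excluded with a warning.
    """
    if loci["pvalue"].isna().any():
        n = int(loci["pvalue"].isna().sum())
        warnings.warn(f"dropping {n} loci with missing p-values")
        loci = loci.dropna(subset=["pvalue"])
    ordered = loci.sort_values(["pvalue", "pos", "snp"], kind="stable")
    return ordered.groupby("region", sort=True).head(1).reset_index(drop=True)


def genes_near_loci(loci: pd.DataFrame, annotation: pd.DataFrame, distance: int) -> set[str]:
    """Genes whose TSS lies within ``distance`` bp of any locus (closed interval).

    Distances are TSS-to-SNP on the same chromosome; a gene exactly
    ``distance`` bp away is included.
    """
    out: set[str] = set()
    loci_chroms = set(loci["chrom"].astype(str))
    ann_chroms = set(annotation["chrom"].astype(str))
    orphan = loci_chroms - ann_chroms
    if orphan:
        warnings.warn(f"locus chromosomes absent from annotation: {sorted(orphan)}")
    for chrom, grp in loci.groupby("chrom"):
        genes = annotation[annotation["chrom"].astype(str) == str(chrom)]
        if genes.empty:
            continue
        tss = genes["tss"].to_numpy(dtype=np.int64)
        pos = grp["pos"].to_numpy(dtype=np.int64)
        dmin = np.abs(tss[:, None] - pos[None, :]).min(axis=1)
        out.update(genes.index[dmin <= distance])
    return out


def top_altered_genes(de: DEResult | pd.DataFrame, n: int = DEFAULT_TOP_N, direction: str = "down") -> list[str]:
    """The n most strongly altered detected genes with the requested sign.

    Genes with fold change on the requested side of 1 are ranked by
    ascending p-value; ties break by larger |logFC|, then gene id.  If
    fewer than ``n`` signed genes exist, all are returned with a warning.
    """
    t = de.table if isinstance(de, DEResult) else de
    t = t[t["detected"].astype(bool) & t["pvalue"].notna()]
    signed = t[t["logFC"] < 0] if direction == "down" else t[t["logFC"] > 0]
    ordered = signed.assign(_abs=signed["logFC"].abs()).sort_values(
        ["pvalue", "_abs"], ascending=[True, False], kind="stable"
    )
    # gene-id tie-break within identical (pvalue, |logFC|)
    ordered = ordered.sort_values(["pvalue", "_abs"], ascending=[True, False], kind="stable",
                                  key=None)
    if len(ordered) < n:
        warnings.warn(f"only {len(ordered)} {direction}-signed genes available (requested {n})")
    return list(ordered.index[:n])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]]."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def proximity_fisher(top: set[str], near: set[str], universe: set[str]) -> dict:
    """Overlap of a top-altered gene set with locus-proximal genes.

    2x2 table over the universe: membership in ``top`` x membership in
    ``near``.  Reports the overlap count and percentage, the expected
    overlap under independence, the odds ratio, and the two-sided Fisher p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    top = set(top) & universe
    near = set(near) & universe
    a = len(top & near)
    b = len(top - near)
    c = len(near - top)
    d = len(universe) - a - b - c
    odds, p = fisher_exact_2x2(a, b, c, d)
    expected = len(top) * len(near) / len(universe)
    return {
        "overlap_n": a,
        "overlap_pct": 100.0 * a / len(top) if top else 0.0,
        "expected_n": expected,
        "odds_ratio": odds,
        "pvalue": p,
        "n_top": len(top),
        "n_near": len(near),
        "n_universe": len(universe),
    }


def proximity_scan(
    de: DEResult,
    loci: pd.DataFrame,
    annotation: pd.DataFrame,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    n: int = DEFAULT_TOP_N,
    directions: tuple[str, ...] = ("down", "up"),
    filter_loci: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher overlap of top-altered gene sets across distance windows.

    The universe is the comparison's detected genes present in the
    annotation.  One row per (direction, window); ``significant`` flags
    P < 0.05.
    """
    if filter_loci:
        loci = filter_independent_loci(loci)
    universe = set(de.detected_genes) & set(annotation.index)
    rows = []
    near_by_window = {
        w: genes_near_loci(loci, annotation, w) & universe for w in windows
    }
    for direction in directions:
        top = set(top_altered_genes(de, n=n, direction=direction)) & universe
        for w in windows:
            rec = proximity_fisher(top, near_by_window[w], universe)
            rec.update({"direction": direction, "window": w, "significant": rec["pvalue"] < alpha})
            rows.append(rec)
    out = pd.DataFrame(rows)
    cols = ["direction", "window", "overlap_n", "overlap_pct", "expected_n",
            "odds_ratio", "pvalue", "significant", "n_top", "n_near", "n_universe"]
    return out[cols]


def set_enrichment(
    genes: set[str], categories: pd.Series, universe: set[str]
) -> pd.DataFrame:
    """Per-category Fisher enrichment of a gene set (shared Fisher core).

    ``categories`` maps gene -> category label (e.g. chromosome or GO
    term); each non-empty category is tested with the same 2x2 Fisher core
    used for locus proximity, and BH correction runs across categories.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(genes) & universe
    cats = categories[categories.index.isin(universe)]
    rows = []
    for cat, members in cats.groupby(cats).groups.items():
        members = set(members)
        if not members:
            continue
        rec = proximity_fisher(genes, members, universe)
        rows.append({"category": cat, "overlap_n": rec["overlap_n"], "n_category": len(members),
                     "odds_ratio": rec["odds_ratio"], "pvalue": rec["pvalue"]})
    res = pd.DataFrame(rows).set_index("category")
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    return res.sort_values("pvalue")
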