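"""Lightweight data containers shared across the pipeline.

The pipeline operates on gene-level count matrices from a paired design:
subjects contribute keratinocyte (KC) and whole-skin samples, each labelled
with disease status PP (lesional), PN (uninvolved) or NN (normal control).
Containers are thin wrappers around pandas objects; all heavy lifting lives
in the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("KC", "skin")
STATUSES = ("PP", "PN", "NN")
COMPARISONS = ("PP_vs_PN", "PP_vs_NN", "PN_vs_NN")


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus per-sample metadata.

    ``meta`` is indexed by sample id and must carry columns
    ``subject``, ``tissue`` (KC/skin) and ``status`` (PP/PN/NN).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        for col in ("subject", "tissue", "status"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        self.meta = self.meta.loc[self.counts.columns]
        bad_t = set(self.meta["tissue"]) - set(TISSUES)
        bad_s = set(self.meta["status"]) - set(STATUSES)
        if bad_t:
            raise ValueError(f"unknown tissue labels: {sorted(bad_t)}")
        if bad_s:
            raise ValueError(f"unknown status labels: {sorted(bad_s)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Raw library size per sample (column sum of counts)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = pd.Index(samples)
        return CountMatrix(self.counts[samples], self.meta.loc[samples].copy())

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[pd.Index(genes)], self.meta.copy())

    def check_pairing(self, tissue: str | None = None) -> None:
        """Require that every PP sample's subject also contributes a PN sample."""
        meta = self.meta if tissue is None else self.meta[self.meta["tissue"] == tissue]
        pp_subj = set(meta.loc[meta["status"] == "PP", "subject"])
        pn_subj = set(meta.loc[meta["status"] == "PN", "subject"])
        orphan = pp_subj - pn_subj
        if orphan:
            raise ValueError(f"PP samples without a paired PN sample for subjects {sorted(orphan)}")


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values (cpm or FPKM).

    Optional confidence-bound matrices accompany the point values; where
    present they must bracket them.
    """

    values: pd.DataFrame
    ci_lower: pd.DataFrame | None = None
    ci_upper: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        for ci, side in ((self.ci_lower, "lower"), (self.ci_upper, "upper")):
            if ci is not None and ci.shape != self.values.shape:
                raise ValueError(f"ci_{side} shape mismatch")
        if self.ci_lower is not None:
            if (self.ci_lower.to_numpy() > self.values.to_numpy() + 1e-9).any():
                raise ValueError("ci_lower exceeds values")
        if self.ci_upper is not None:
            if (self.ci_upper.to_numpy() < self.values.to_numpy() - 1e-9).any():
                raise ValueError("ci_upper below values")


@dataclass
class DEResult:
    """Per-gene differential expression results for one comparison.

    ``table`` is indexed by gene with columns: logFC (log2), FC (linear),
    lrt, pvalue, fdr, detected, call (up/down/none), mean_expr_g1,
    mean_expr_g2, converged.
    """

    table: pd.DataFrame
    comparison: str
    tissue: str
    group1: str = ""
    group2: str = ""

    def degs(self, direction: str | None = None) -> pd.Index:
        t = self.table
        mask = t["call"] != "none"
        if direction is not None:
            mask = t["call"] == direction
        return t.index[mask]

    @property
    def detected_genes(self) -> pd.Index:
        return self.table.index[self.table["detected"].astype(bool)]


@dataclass
class ModuleSet:
    """Disjoint gene modules built on a reference expression matrix.

    ``assignment`` maps gene -> module id; per-module centroids are vectors
    over the reference samples; ``representatives`` holds the 25 genes
    nearest each centroid; ``medoids`` the member with minimal summed
    distance to the rest.
    """

    assignment: pd.Series
    centroids: pd.DataFrame
    representatives: dict[int, list[str]] = field(default_factory=dict)
    medoids: dict[int, str] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.centroids.index)

    def members(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()
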