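"""Promoter extraction, PWM scanning and motif enrichment testing.

A 5500 bp TSS-proximal region (5000 bp upstream, 500 bp downstream of the
TSS, strand-oriented) is scanned on both strands with log2-odds position
weight matrix scores; per-gene hit counts then enter a semiparametric
additive logistic model of DEG-set membership with a smooth GC-content
covariate, and Benjamini-Hochberg correction is applied across the motif
panel.  Enriched motifs are intersected with the differential expression
of their cognate transcription factors and with open-chromatin intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DEResult
from .de import bh_adjust

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

UPSTREAM = 5000
DOWNSTREAM = 500
REGION_LENGTH = UPSTREAM + DOWNSTREAM


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    n = len(s)
    return (s.count("G") + s.count("C")) / n if n else 0.0


@dataclass
class PWM:
    """Column-stochastic position probability matrix with TF annotation."""

    id: str
    matrix: np.ndarray  # (4, width) probabilities
    tf_genes: tuple[str, ...] = ()
    tf_class: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"PWM {self.id}: need a 4 x width matrix with width >= 4")
        colsum = self.matrix.sum(axis=0)
        if np.abs(colsum - 1.0).max() > 1e-6:
            raise ValueError(f"PWM {self.id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        bg = np.asarray(background, dtype=float)
        if (bg <= 0).any():
            raise ValueError("background frequencies must be positive (apply a pseudocount)")
        return np.log2(self.matrix / bg[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.matrix[::-1, ::-1], self.tf_genes, self.tf_class)


def pwm_from_counts(mid: str, counts: np.ndarray, pseudocount: float = 0.5, **kw) -> PWM:
    counts = np.asarray(counts, dtype=float) + pseudocount
    return PWM(mid, counts / counts.sum(axis=0), **kw)


def pwm_from_consensus(mid: str, consensus: str, p_match: float = 0.94, **kw) -> PWM:
    w = len(consensus)
    mat = np.full((4, w), (1.0 - p_match) / 3.0)
    for j, b in enumerate(consensus.upper()):
        mat[_CODE[b], j] = p_match
    return PWM(mid, mat, **kw)


def read_jaspar(path, pseudocount: float = 0.5) -> list[PWM]:
    """Parse a JASPAR-format PFM file into probability PWMs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            out.append(pwm_from_counts(m.matrix_id or m.name, counts, pseudocount))
    return out


def read_meme(path) -> list[PWM]:
    """Parse a MEME minimal-format motif file."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "minimal"):
            prob = np.array([[m.pwm[b][j] for j in range(m.length)] for b in BASES])
            prob = prob + 1e-9
            prob /= prob.sum(axis=0)
            out.append(PWM(m.name, prob))
    return out


def synthetic_motif_panel(
    n_motifs: int,
    tf_genes: list[str] | None = None,
    seed: int = 0,
    width_range: tuple[int, int] = (6, 10),
    include_ap1: bool = True,
) -> list[PWM]:
    """A panel of random sharp PWMs, optionally led by the canonical AP-1 site.

    AP-1 (Jun/Fos) binds 5'-TGACTCA-3', which is the reverse complement of
    TGAGTCA, so the panel's first motif detects both orientations.
    """
    rng = np.random.default_rng(seed)
    panel: list[PWM] = []
    if include_ap1 and n_motifs > 0:
        panel.append(pwm_from_consensus("AP1_TGACTCA", "TGACTCA", tf_class="bZIP"))
    while len(panel) < n_motifs:
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        cons = "".join(BASES[i] for i in rng.integers(0, 4, size=w))
        panel.append(pwm_from_consensus(f"M{len(panel):04d}_{cons}", cons))
    if tf_genes:
        for i, p in enumerate(panel):
            p.tf_genes = (tf_genes[i % len(tf_genes)],)
    return panel


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoters(
    annotation: pd.DataFrame,
    genome: dict[str, str],
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
) -> pd.DataFrame:
    """Strand-oriented TSS-proximal regions from a genome.

    Coordinates are 0-based half-open.  A plus-strand gene with TSS t gets
    genomic span [t - upstream, t + downstream); a minus-strand gene gets
    the reverse complement of [t - downstream, t + upstream), so both read
    5'->3' relative to the gene.  Regions truncated at a contig edge are
    flagged.

    Returns a frame indexed by gene: sequence, gc, chrom, start, end,
    strand, truncated.
    """
    rows = {}
    for gene, row in annotation.iterrows():
        chrom = str(row["chrom"])
        if chrom not in genome:
            warnings.warn(f"chromosome {chrom} absent from genome; skipping {gene}")
            continue
        contig = genome[chrom]
        tss = int(row["tss"])
        strand = str(row["strand"])
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        truncated = start < 0 or end > len(contig)
        s, e = max(start, 0), min(end, len(contig))
        seq = contig[s:e].upper()
        if strand != "+":
            seq = revcomp(seq)
        rows[gene] = {
            "sequence": seq,
            "gc": gc_fraction(seq),
            "chrom": chrom,
            "start": s,
            "end": e,
            "strand": strand,
            "truncated": truncated,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# scanning


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Sum of per-position log-odds over every window; N bases score 0."""
    w = lod.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    lod5 = np.vstack([lod, np.zeros(w)])  # row 4 = N
    scores = np.zeros(n_win)
    for j in range(w):
        scores += lod5[codes[j : j + n_win], j]
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    threshold: float | None = None,
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Both-strand log2-odds scan of one sequence.

    A hit is any window whose score meets or exceeds the threshold
    (default: ``threshold_frac`` of the maximal achievable score).
    Overlapping hits are all retained.  Minus-strand hit offsets refer to
    the window start on the scanned sequence.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    lod = pwm.log_odds(bg)
    if threshold is None:
        threshold = threshold_frac * lod.max(axis=0).sum()
    codes = encode(sequence)
    recs = []
    for strand, mat in (("+", lod), ("-", pwm.reverse_complement().log_odds(bg))):
        scores = _window_scores(codes, mat)
        for off in np.flatnonzero(scores >= threshold):
            recs.append((int(off), strand, float(scores[off])))
    return pd.DataFrame(recs, columns=["offset", "strand", "score"]).sort_values(
        ["offset", "strand"], ignore_index=True
    )


def count_hits(
    promoters: pd.DataFrame,
    panel: list[PWM],
    background: np.ndarray | None = None,
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Genes x motifs hit-count matrix over a promoter set (both strands)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    coded = [encode(s) for s in promoters["sequence"]]
    out = np.zeros((len(coded), len(panel)), dtype=int)
    for k, pwm in enumerate(panel):
        lod = pwm.log_odds(bg)
        rc = pwm.reverse_complement().log_odds(bg)
        thr = threshold_frac * lod.max(axis=0).sum()
        for i, codes in enumerate(coded):
            out[i, k] = int((_window_scores(codes, lod) >= thr).sum()) + int(
                (_window_scores(codes, rc) >= thr).sum()
            )
    return pd.DataFrame(out, index=promoters.index, columns=[p.id for p in panel])


# ---------------------------------------------------------------------------
# enrichment model


def _spline_basis(x: np.ndarray, df: int = 8, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis (centred, no intercept column)."""
    from scipy.interpolate import BSpline

    x = np.asarray(x, dtype=float)
    n_inner = max(df - degree, 0)
    qs = np.linspace(0, 1, n_inner + 2)[1:-1]
    inner = np.quantile(x, qs) if n_inner else np.empty(0)
    lo, hi = x.min() - 1e-9, x.max() + 1e-9
    knots = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    design = np.empty((x.size, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        design[:, j] = BSpline(knots, c, degree, extrapolate=True)(x)
    design = design[:, 1:]  # drop one column: intercept handled separately
    return design - design.mean(axis=0)


def _logistic_fit(y: np.ndarray, X: np.ndarray, ridge: float = 0.0, max_iter: int = 100):
    """IRLS logistic fit; returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    pen = np.eye(p) * ridge
    pen[0, 0] = 0.0
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = X.T @ (X * w[:, None]) + pen
        g = X.T @ (y - mu) - pen @ beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-10)
    H = X.T @ (X * w[:, None]) + pen
    cov = np.linalg.pinv(H)
    return beta, cov, converged


def gam_motif_test(
    membership: pd.Series,
    hits: pd.DataFrame,
    gc: pd.Series,
    region_length: pd.Series | None = None,
    spline_df: int = 8,
    fdr_cut: float = 0.10,
) -> pd.DataFrame:
    """Semiparametric additive logistic test of motif enrichment.

    For each motif, DEG-set membership (1 = DEG, 0 = background) is
    regressed on the per-gene hit count plus a cubic regression-spline
    smooth of promoter GC fraction (and of region length when it varies);
    the enrichment p-value is a two-sided Wald test of the hit-count
    coefficient.  BH correction runs across the whole motif panel.  Fits
    that fail (e.g. complete separation) fall back to a ridge-penalised
    fit and are flagged.
    """
    genes = hits.index
    y = membership.loc[genes].astype(float).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 genes in the DEG set and 2 in the background")
    covs = [np.ones(len(genes))]
    gc_arr = gc.loc[genes].to_numpy(dtype=float)
    if np.ptp(gc_arr) > 1e-9:
        covs.append(_spline_basis(gc_arr, df=spline_df))
    if region_length is not None:
        rl = region_length.loc[genes].to_numpy(dtype=float)
        if np.ptp(rl) > 1e-9:
            covs.append(_spline_basis(rl, df=min(spline_df, 4)))
    base = np.column_stack([c if c.ndim == 2 else c[:, None] for c in covs])

    rows = []
    for mid in hits.columns:
        h = hits[mid].to_numpy(dtype=float)
        if np.ptp(h) < 1e-12:
            rows.append((mid, 0.0, np.nan, h[y == 1].sum(), h[y == 0].sum(), False))
            continue
        X = np.column_stack([base[:, :1], h, base[:, 1:]])
        beta, cov, ok = _logistic_fit(y, X, ridge=1e-8)
        flagged = False
        se = np.sqrt(max(cov[1, 1], 0.0))
        if not ok or not np.isfinite(se) or se > 1e3:
            beta, cov, ok = _logistic_fit(y, X, ridge=1.0)
            se = np.sqrt(max(cov[1, 1], 0.0))
            flagged = True
        z = beta[1] / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((mid, float(beta[1]), float(p), h[y == 1].sum(), h[y == 0].sum(), flagged))
    res = pd.DataFrame(
        rows, columns=["motif", "coef", "pvalue", "n_hits_deg", "n_hits_bg", "flagged"]
    ).set_index("motif")
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res["enriched"] = (res["coef"] > 0) & (res["fdr"] < fdr_cut)
    return res


def intersect_tf_expression(
    enrichment: pd.DataFrame,
    panel: list[PWM],
    de: DEResult,
    fdr_cut: float = 0.10,
    fc_down: float = 0.50,
) -> pd.DataFrame:
    """Flag motifs whose cognate TF is itself a decreased DEG.

    ``tf_decreased`` is true iff any TF gene mapped to the motif has
    FDR < 0.10 and FC < 0.50 in the supplied comparison (any-rule for
    multi-TF motifs).  Unmapped motifs are flagged false.
    """
    by_id = {p.id: p for p in panel}
    t = de.table
    down = set(t.index[(t["fdr"] < fdr_cut) & (t["FC"] < fc_down)])
    out = enrichment.copy()
    flags, tf_lists = [], []
    for mid in out.index:
        pwm = by_id.get(mid)
        genes = pwm.tf_genes if pwm is not None else ()
        if not genes:
            warnings.warn(f"motif {mid} has no TF mapping; tf_decreased set to False")
        flags.append(any(g in down for g in genes))
        tf_lists.append(",".join(genes))
    out["tf_genes"] = tf_lists
    out["tf_decreased"] = flags
    return out


def summarize_motif_classes(enrichment: pd.DataFrame, panel: list[PWM]) -> pd.DataFrame:
    """Fraction of significant motifs per TF class (pure group-by)."""
    cls = {p.id: (p.tf_class or "unknown") for p in panel}
    df = enrichment.assign(tf_class=[cls.get(m, "unknown") for m in enrichment.index])
    grp = df.groupby("tf_class")["enriched"].agg(["sum", "count"])
    grp["fraction_of_significant"] = grp["sum"] / max(int(df["enriched"].sum()), 1)
    return grp.rename(columns={"sum": "n_enriched", "count": "n_motifs"})


# ---------------------------------------------------------------------------
# open chromatin


def hits_to_genomic(hits: pd.DataFrame, promoter_row: pd.Series, width: int) -> pd.DataFrame:
    """Map promoter-offset hits back to genomic half-open intervals."""
    start, end, strand = int(promoter_row["start"]), int(promoter_row["end"]), promoter_row["strand"]
    if strand == "+":
        gs = start + hits["offset"].to_numpy()
    else:
        gs = end - hits["offset"].to_numpy() - width
    out = hits.copy()
    out["chrom"] = promoter_row["chrom"]
    out["gstart"] = gs
    out["gend"] = gs + width
    return out


def open_chromatin_overlap(hits: pd.DataFrame, bed: pd.DataFrame) -> pd.DataFrame:
    """Annotate genomic hits with open-chromatin overlap (>= 1 bp, half-open).

    The BED intervals need not be sorted; they are merged internally.
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in bed.groupby("chrom"):
        iv = grp.sort_values(["start", "end"]).to_numpy()[:, 1:3].astype(int)
        starts, ends = [], []
        for s, e in iv:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[str(chrom)] = (np.array(starts), np.array(ends))
    flags = np.zeros(len(hits), dtype=bool)
    for i, (_, row) in enumerate(hits.iterrows()):
        ch = merged.get(str(row["chrom"]))
        if ch is None:
            continue
        starts, ends = ch
        j = np.searchsorted(starts, row["gend"], side="left") - 1
        flags[i] = j >= 0 and ends[j] > row["gstart"]
    out = hits.copy()
    out["open_chromatin"] = flags
    return out
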