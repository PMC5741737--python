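"""Detection filtering, TMM normalisation and NB-GLM differential expression.

The workflow mirrors standard count-based RNA-seq practice: genes pass a
detection filter (cpm > 0.25 with a strictly positive lower FPKM confidence
bound in at least 2 of the 8 samples of a comparison), library scaling uses
the weighted trimmed mean of M-values (TMM), per-gene NB dispersions are
estimated by Cox-Reid adjusted profile likelihood with shrinkage toward the
common value, and each comparison is tested by a likelihood-ratio test of
the group coefficient in a log-linear NB model.  The lesional-vs-uninvolved
(PP vs PN) comparison adds the patient factor to exploit sample pairing.

DEGs are called at FDR < 0.10 with fold change > 2.0 or < 0.50 (strict
inequalities).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COMPARISONS, CountMatrix, DEResult, ExpressionMatrix
from .nbglm import cox_reid_apl, fit_nb_glm

DEFAULT_CPM_THRESHOLD = 0.25
DEFAULT_MIN_DETECTED_SAMPLES = 2
DEFAULT_FDR_CUT = 0.10
DEFAULT_FC_UP = 2.0
DEFAULT_FC_DOWN = 0.50

_PHI_GRID = np.concatenate([[1e-6], np.logspace(-4, np.log10(4.0), 24)])


# ---------------------------------------------------------------------------
# expression units


def compute_cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million mapped reads; library size = raw column sum."""
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = cm.samples[lib <= 0]
        raise ValueError(f"zero library size for samples {list(bad)}")
    vals = cm.counts.to_numpy(dtype=float) * 1e6 / lib
    return ExpressionMatrix(pd.DataFrame(vals, index=cm.genes, columns=cm.samples))


def compute_fpkm_with_ci(
    cm: CountMatrix, lengths: pd.Series, alpha: float = 0.05
) -> ExpressionMatrix:
    """FPKM with exact Poisson (Garwood) confidence intervals on the count.

    FPKM = count * 1e9 / (length * library size).  The interval treats the
    raw count as a Poisson observation: lower = chi2(alpha/2, 2k)/2 (zero
    for k = 0), upper = chi2(1-alpha/2, 2k+2)/2, both scaled into FPKM
    units.  A zero count therefore has a lower bound of exactly 0, so the
    downstream "CI lower bound > 0" detection clause fails for it.
    """
    missing = cm.genes.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for genes: {list(missing[:5])}")
    length = lengths.loc[cm.genes].to_numpy(dtype=float)
    if (length < 1).any():
        raise ValueError("gene lengths must be >= 1")
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    k = cm.counts.to_numpy(dtype=float)
    scale = 1e9 / (length[:, None] * lib[None, :])
    lower_k = np.where(k > 0, stats.chi2.ppf(alpha / 2.0, 2.0 * k) / 2.0, 0.0)
    upper_k = stats.chi2.ppf(1.0 - alpha / 2.0, 2.0 * (k + 1.0)) / 2.0
    mk = lambda a: pd.DataFrame(a, index=cm.genes, columns=cm.samples)
    return ExpressionMatrix(mk(k * scale), ci_lower=mk(lower_k * scale), ci_upper=mk(upper_k * scale))


# ---------------------------------------------------------------------------
# comparison bookkeeping


def comparison_groups(comparison: str) -> tuple[str, str]:
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {COMPARISONS}, got {comparison!r}")
    g1, g2 = comparison.split("_vs_")
    return g1, g2


def comparison_samples(
    meta: pd.DataFrame, comparison: str, tissue: str
) -> tuple[pd.Index, pd.Index]:
    """Sample ids of the two groups of a comparison within one tissue."""
    g1, g2 = comparison_groups(comparison)
    sel = meta["tissue"] == tissue
    s1 = meta.index[sel & (meta["status"] == g1)]
    s2 = meta.index[sel & (meta["status"] == g2)]
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError(f"no samples for {comparison} in tissue {tissue}")
    return s1, s2


def detect_genes(
    cm: CountMatrix,
    fpkm: ExpressionMatrix,
    comparison: str,
    tissue: str,
    cpm_threshold: float = DEFAULT_CPM_THRESHOLD,
    min_samples: int = DEFAULT_MIN_DETECTED_SAMPLES,
) -> pd.Index:
    """Genes with detectable expression in >= 2 samples of the comparison.

    Detectable in a sample means cpm strictly greater than 0.25 AND the
    lower limit of the FPKM 95% confidence interval strictly greater than
    zero.  Both clauses are strict, so cpm exactly at the threshold or a
    zero count never counts as detected.
    """
    if fpkm.ci_lower is None:
        raise ValueError("fpkm must carry confidence bounds (use compute_fpkm_with_ci)")
    s1, s2 = comparison_samples(cm.meta, comparison, tissue)
    samples = s1.append(s2)
    cpm = compute_cpm(cm).values[samples]
    low = fpkm.ci_lower[samples]
    ok = (cpm.to_numpy() > cpm_threshold) & (low.to_numpy() > 0.0)
    keep = ok.sum(axis=1) >= min_samples
    return cm.genes[keep]


# ---------------------------------------------------------------------------
# TMM normalisation


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.max(np.abs(m)) < 1e-10:
        return 1.0
    n = m.size
    # drop the floor(n*trim) smallest and largest by M, likewise by A
    def trimmed(v: np.ndarray, trim: float) -> np.ndarray:
        k = int(np.floor(v.size * trim))
        order = np.argsort(v, kind="stable")
        mask = np.zeros(v.size, dtype=bool)
        mask[order[k : v.size - k]] = True
        return mask

    sel = trimmed(m, trim_m) & trimmed(a, trim_a)
    if sel.sum() == 0:
        return 1.0
    # asymptotic (delta-method) inverse variance of M as weights
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return float(2.0 ** f)


def tmm_factors(
    cm: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean across samples.  Genes with a zero count in either
    the sample or the reference are excluded from each pairwise fit.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("cannot TMM-normalise a sample with all-zero counts")
    q75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = x[:, ref_idx]
    factors = np.array(
        [_tmm_pair_factor(x[:, j], ref, trim_m, trim_a) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_library_sizes(cm: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(cm)
    return cm.library_sizes.astype(float) * factors.loc[cm.samples]


# ---------------------------------------------------------------------------
# dispersion estimation


def _design_matrix(meta: pd.DataFrame, comparison: str, tissue: str, paired: bool):
    """Full/reduced designs for a two-group comparison within one tissue."""
    s1, s2 = comparison_samples(meta, comparison, tissue)
    samples = s1.append(s2)
    sub = meta.loc[samples]
    group = (sub["status"] == comparison_groups(comparison)[0]).to_numpy(dtype=float)
    cols = [np.ones(len(samples))]
    if paired:
        subj = pd.get_dummies(sub["subject"], drop_first=True)
        cols.extend(subj.to_numpy(dtype=float).T)
    X_reduced = np.column_stack(cols)
    X_full = np.column_stack(cols + [group])
    return samples, X_full, X_reduced


def estimate_dispersions(
    cm: CountMatrix,
    design: np.ndarray,
    prior_df: float = 10.0,
    offset: np.ndarray | None = None,
    grid: np.ndarray = _PHI_GRID,
) -> pd.DataFrame:
    """Cox-Reid adjusted-profile-likelihood NB dispersions with shrinkage.

    The adjusted profile likelihood of each gene is evaluated on a log-
    spaced phi grid; the per-gene maximiser is shrunk toward the common
    (all-gene) maximiser by adding ``prior_df / residual_df`` times the
    mean APL curve before taking the argmax, a weighted-likelihood
    empirical Bayes scheme.  ``prior_df = inf`` returns the common value
    for every gene.

    Returns a frame with columns ``phi`` (shrunk), ``phi_raw`` and
    ``phi_common`` (same value in every row).
    """
    y = cm.counts.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    S, p = X.shape
    if y.shape[1] != S:
        raise ValueError("design rows must match samples")
    resid_df = S - p
    if resid_df < 1:
        raise ValueError("non-estimable design: residual degrees of freedom < 1")
    if offset is None:
        offset = np.log(effective_library_sizes(cm).to_numpy())
    apl = np.stack([cox_reid_apl(y, X, offset, phi) for phi in grid], axis=1)  # (G, K)

    def argmax_interp(curve: np.ndarray) -> float:
        """Grid argmax refined by a parabola in log-phi."""
        k = int(np.argmax(curve))
        if k == 0 or k == len(grid) - 1:
            return float(grid[k])
        lg = np.log(grid[k - 1 : k + 2])
        v = curve[k - 1 : k + 2]
        denom = (v[0] - 2 * v[1] + v[2])
        if denom >= -1e-12:
            return float(grid[k])
        shift = 0.5 * (v[0] - v[2]) / denom
        return float(np.exp(lg[1] + shift * (lg[1] - lg[0])))

    mean_apl = apl.mean(axis=0)
    phi_common = argmax_interp(mean_apl)
    phi_raw = np.apply_along_axis(argmax_interp, 1, apl)
    if np.isinf(prior_df):
        phi_shrunk = np.full(y.shape[0], phi_common)
    else:
        w0 = prior_df / resid_df
        shrunk_curves = apl + w0 * mean_apl[None, :]
        phi_shrunk = np.apply_along_axis(argmax_interp, 1, shrunk_curves)
    return pd.DataFrame(
        {"phi": phi_shrunk, "phi_raw": phi_raw, "phi_common": phi_common},
        index=cm.genes,
    )


# ---------------------------------------------------------------------------
# likelihood ratio tests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, order preserved.

    NaN entries (untested genes) are ignored and returned as NaN; they do
    not contribute to the denominator m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def nb_glm_lrt(
    cm: CountMatrix,
    dispersions: pd.Series | pd.DataFrame,
    comparison: str,
    tissue: str,
    factors: pd.Series | None = None,
    fpkm: ExpressionMatrix | None = None,
) -> DEResult:
    """Likelihood-ratio test of the group effect, per gene.

    The full model regresses log mean on the group indicator (group 1 of
    the comparison vs group 2) with log effective library sizes as offsets;
    for PP_vs_PN the patient factor is added to both models so the test is
    paired.  The statistic is 2*(l_full - l_reduced) on 1 df; logFC is the
    group coefficient in log2 units.  Genes whose full fit fails to
    converge get NaN p-values and are excluded from the BH denominator.
    """
    g1, g2 = comparison_groups(comparison)
    paired = comparison == "PP_vs_PN"
    if paired:
        cm.check_pairing(tissue)
    samples, X_full, X_red = _design_matrix(cm.meta, comparison, tissue, paired)
    sub = cm.subset_samples(samples)
    if factors is None:
        factors = tmm_factors(sub)
    offset = np.log(sub.library_sizes.to_numpy(dtype=float) * factors.loc[samples].to_numpy())
    y = sub.counts.to_numpy(dtype=float)
    if isinstance(dispersions, pd.DataFrame):
        phi = dispersions["phi"].loc[sub.genes].to_numpy()
    else:
        phi = dispersions.loc[sub.genes].to_numpy()

    beta_f, _, ll_f, conv_f = fit_nb_glm(y, X_full, offset, phi)
    _, _, ll_r, conv_r = fit_nb_glm(y, X_red, offset, phi)
    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)
    converged = conv_f & conv_r
    pvals = np.where(converged, pvals, np.nan)
    logfc = beta_f[:, -1] / np.log(2.0)
    fc = 2.0 ** logfc

    if fpkm is not None:
        e1 = fpkm.values.loc[sub.genes, cm.meta.index[(cm.meta["tissue"] == tissue) & (cm.meta["status"] == g1)]].mean(axis=1)
        e2 = fpkm.values.loc[sub.genes, cm.meta.index[(cm.meta["tissue"] == tissue) & (cm.meta["status"] == g2)]].mean(axis=1)
    else:
        cpm = compute_cpm(sub).values
        s1, s2 = comparison_samples(cm.meta, comparison, tissue)
        e1, e2 = cpm[s1].mean(axis=1), cpm[s2].mean(axis=1)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "FC": fc,
            "lrt": lrt,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
            "detected": True,
            "call": "none",
            "mean_expr_g1": np.asarray(e1, dtype=float),
            "mean_expr_g2": np.asarray(e2, dtype=float),
            "converged": converged,
        },
        index=sub.genes,
    )
    if (~converged).any():
        warnings.warn(f"{(~converged).sum()} gene fits did not converge; p set to NaN")
    return DEResult(table=table, comparison=comparison, tissue=tissue, group1=g1, group2=g2)


def call_degs(
    de: DEResult,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
) -> DEResult:
    """Assign up/down DEG calls at FDR < 0.10 with FC > 2.0 or FC < 0.50.

    All inequalities are strict; a gene at FDR exactly 0.10 or FC exactly
    2.0 is not called.
    """
    t = de.table
    sig = t["detected"].astype(bool) & (t["fdr"] < fdr_cut)
    call = np.where(sig & (t["FC"] > fc_up), "up", np.where(sig & (t["FC"] < fc_down), "down", "none"))
    de.table = t.assign(call=call)
    return de


def run_de(
    cm: CountMatrix,
    lengths: pd.Series,
    comparison: str,
    tissue: str,
    prior_df: float = 10.0,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
) -> DEResult:
    """Full single-comparison pipeline: detect, normalise, test, call DEGs."""
    s1, s2 = comparison_samples(cm.meta, comparison, tissue)
    sub = cm.subset_samples(s1.append(s2))
    fpkm = compute_fpkm_with_ci(sub, lengths)
    detected = detect_genes(sub, fpkm, comparison, tissue)
    if len(detected) == 0:
        raise ValueError("no genes pass the detection filter")
    dsub = sub.subset_genes(detected)
    factors = tmm_factors(dsub)
    paired = comparison == "PP_vs_PN"
    _, X_full, _ = _design_matrix(dsub.meta, comparison, tissue, paired)
    offset = np.log(dsub.library_sizes.to_numpy(dtype=float) * factors.to_numpy())
    disp = estimate_dispersions(dsub, X_full, prior_df=prior_df, offset=offset)
    fpkm_det = ExpressionMatrix(
        fpkm.values.loc[detected], fpkm.ci_lower.loc[detected], fpkm.ci_upper.loc[detected]
    )
    de = nb_glm_lrt(dsub, disp, comparison, tissue, factors=factors, fpkm=fpkm_det)
    return call_degs(de, fdr_cut=fdr_cut, fc_up=fc_up, fc_down=fc_down)
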