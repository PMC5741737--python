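"""Unit and property tests for detection, normalisation and NB-GLM testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kcseq.containers import DEResult
from kcseq.de import (
    bh_adjust,
    call_degs,
    compute_cpm,
    compute_fpkm_with_ci,
    detect_genes,
    estimate_dispersions,
    nb_glm_lrt,
    tmm_factors,
    _design_matrix,
)
from kcseq.nbglm import fit_nb_glm
from kcseq.simulate import SimConfig, simulate_counts

from conftest import toy_count_matrix


# ---------------------------------------------------------------------------
# cpm / FPKM


def test_cpm_hand_values():
    # column sums: 1e6, 2e7 -> cpm of gene 1 is 10 and 0.25
    counts = np.array([[10, 5], [999_990, 19_999_995], [0, 0]])
    cm = toy_count_matrix(counts, statuses=["PP", "NN"])
    cpm = compute_cpm(cm).values
    assert cpm.iloc[0, 0] == pytest.approx(10.0)
    assert cpm.iloc[0, 1] == pytest.approx(0.25)
    assert cpm.iloc[2, 0] == 0.0


def test_cpm_zero_library_errors():
    cm = toy_count_matrix(np.array([[0, 5], [0, 5]]), statuses=["PP", "NN"])
    with pytest.raises(ValueError, match="library"):
        compute_cpm(cm)


def test_fpkm_hand_value_and_poisson_ci():
    # library size (column sum) is exactly 1e7 via the filler gene
    counts = np.array([[100], [1], [0], [10_000_000 - 101]])
    cm = toy_count_matrix(counts, statuses=["PP"])
    lengths = pd.Series([1000, 500, 800, 1000], index=cm.genes)
    fpkm = compute_fpkm_with_ci(cm, lengths)
    # count 100, length 1000, library 1e7 -> FPKM 10
    assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)
    # zero count: lower bound exactly 0; any count >= 1: strictly positive
    assert fpkm.ci_lower.iloc[2, 0] == 0.0
    assert fpkm.ci_lower.iloc[0, 0] > 0.0
    assert fpkm.ci_lower.iloc[1, 0] > 0.0
    # Garwood interval brackets the point estimate
    assert (fpkm.ci_lower.to_numpy() <= fpkm.values.to_numpy() + 1e-12).all()
    assert (fpkm.ci_upper.to_numpy() >= fpkm.values.to_numpy() - 1e-12).all()


# ---------------------------------------------------------------------------
# detection rule


def _detection_fixture():
    """10 scored genes + filler; 8 samples with library size exactly 4e6.

    At library 4e6: count 1 = cpm 0.25 (boundary, strict > fails),
    count 2 = cpm 0.5 (passes both clauses).
    """
    lib = 4_000_000
    rows = {
        "g1": [2] * 8,               # detected everywhere
        "g2": [2, 2, 0, 0, 0, 0, 0, 0],  # exactly 2 samples -> detected
        "g3": [50] * 8,              # strongly detected
        "g4": [0, 0, 0, 2, 2, 2, 0, 0],  # 3 samples -> detected
        "g5": [2, 0, 2, 0, 2, 0, 2, 0],  # 4 samples -> detected
        "g6": [100, 3, 0, 0, 0, 0, 0, 3],  # 3 samples -> detected
        "g7": [1] * 8,               # cpm exactly 0.25 everywhere -> NOT detected
        "g8": [2, 0, 0, 0, 0, 0, 0, 0],  # only 1 qualifying sample -> NOT detected
        "g9": [0] * 8,               # never seen -> NOT detected
        "g10": [1, 1, 1, 1, 1, 1, 1, 2],  # one qualifying sample only -> NOT detected
    }
    mat = np.array(list(rows.values()))
    filler = lib - mat.sum(axis=0)
    counts = np.vstack([mat, filler])
    cm = toy_count_matrix(
        counts,
        statuses=["PP"] * 4 + ["NN"] * 4,
        subjects=[f"u{i}" for i in range(8)],
    )
    expected = {"g1", "g2", "g3", "g4", "g5", "g6"}
    return cm, expected


def test_detection_rule_hand_fixture():
    cm, expected = _detection_fixture()
    lengths = pd.Series(1000, index=cm.genes)
    fpkm = compute_fpkm_with_ci(cm, lengths)
    detected = set(detect_genes(cm, fpkm, "PP_vs_NN", "KC")) - {"g11"}
    assert detected == expected


# ---------------------------------------------------------------------------
# TMM


def _tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Independent brute-force TMM: explicit sort-based trimming."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    q75 = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = []
    for j in range(x.shape[1]):
        obs, refc = x[:, j], x[:, ref]
        keep = (obs > 0) & (refc > 0)
        po, pr = obs[keep] / lib[j], refc[keep] / lib[ref]
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        if np.max(np.abs(m)) < 1e-10:
            factors.append(1.0)
            continue
        n = len(m)
        km, ka = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
        m_sorted = np.argsort(m, kind="stable")
        a_sorted = np.argsort(a, kind="stable")
        keep_m = set(m_sorted[km : n - km])
        keep_a = set(a_sorted[ka : n - ka])
        sel = sorted(keep_m & keep_a)
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (lib[ref] - refc[keep]) / (
            lib[ref] * refc[keep]
        )
        f = sum(m[i] / w[i] for i in sel) / sum(1.0 / w[i] for i in sel)
        factors.append(2.0 ** f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_identical_columns_unity():
    counts = pd.DataFrame(np.tile(np.arange(1, 21)[:, None], (1, 2)) * 10)
    f = tmm_factors(counts)
    assert np.allclose(f, 1.0)


def test_tmm_pure_depth_difference_absorbed():
    col = np.arange(1, 21) * 7
    counts = pd.DataFrame({"a": col, "b": 2 * col})
    f = tmm_factors(counts)
    assert np.allclose(f, 1.0, atol=1e-12)


def test_tmm_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    base = rng.integers(50, 5000, size=20).astype(float)
    colb = base.copy()
    colb[3] *= 9.0  # discordant genes
    colb[11] *= 0.1
    counts = pd.DataFrame({"a": base, "b": np.round(colb * 1.7)})
    got = tmm_factors(counts).to_numpy()
    want = _tmm_oracle(counts)
    assert np.allclose(got, want, atol=1e-10)


def test_tmm_all_zero_column_errors():
    counts = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
    with pytest.raises(ValueError):
        tmm_factors(counts)


def test_tmm_scale_invariance_of_normalized_cpm():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(10, 2000, size=(200, 4)).astype(float))
    f1 = tmm_factors(counts)
    norm1 = counts / (counts.sum(axis=0) * f1)
    scaled = counts.copy()
    scaled[2] = scaled[2] * 5  # uniform depth change in one sample
    f2 = tmm_factors(scaled)
    norm2 = scaled / (scaled.sum(axis=0) * f2)
    # invariance is approximate: if the rescaled sample is the TMM reference,
    # the inverse-variance weights shift slightly
    assert np.allclose(f1, f2, rtol=0.05)
    assert np.allclose(norm1, norm2, rtol=0.05)


# ---------------------------------------------------------------------------
# BH


def test_bh_hand_computation():
    got = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_matches_statsmodels_and_properties():
    rng = np.random.default_rng(5)
    p = rng.uniform(0, 1, 200)
    got = bh_adjust(p)
    from statsmodels.stats.multitest import multipletests

    want = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(got, want, atol=1e-12)
    assert (got >= p - 1e-15).all() and (got <= 1.0).all()
    # permutation equivariance
    perm = rng.permutation(200)
    assert np.allclose(bh_adjust(p[perm]), got[perm])


def test_bh_nan_excluded_from_denominator():
    p = np.array([0.01, np.nan, 0.02])
    got = bh_adjust(p)
    assert np.isnan(got[1])
    assert got[0] == pytest.approx(0.02)  # m = 2, not 3


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# DEG calling


def test_call_degs_enumerated_fixture():
    table = pd.DataFrame(
        {
            "logFC": np.log2([3.0, 0.4, 3.0, 0.4, 1.5, 0.5]),
            "FC": [3.0, 0.4, 3.0, 0.4, 1.5, 0.5],
            "pvalue": [0.001] * 6,
            "fdr": [0.05, 0.05, 0.10, 0.20, 0.05, 0.05],
            "detected": [True] * 6,
            "call": ["none"] * 6,
        },
        index=[f"g{i}" for i in range(6)],
    )
    de = DEResult(table=table, comparison="PN_vs_NN", tissue="KC")
    got = call_degs(de).table["call"].tolist()
    # g0 up; g1 down; g2 FDR exactly 0.10 -> none; g3 FDR too high -> none;
    # g4 FC 1.5 below cut -> none; g5 FC exactly 0.50 -> none (strict)
    assert got == ["up", "down", "none", "none", "none", "none"]


# ---------------------------------------------------------------------------
# dispersions


def test_dispersion_poisson_limit(null_cfg):
    cfg = null_cfg.with_(seed=12, dispersion=0.0, n_genes=600)
    cm, _ = simulate_counts(cfg)
    sub = cm.subset_samples(
        cm.meta.index[(cm.meta.tissue == "KC") & (cm.meta.status.isin(["PN", "NN"]))]
    )
    _, Xf, _ = _design_matrix(sub.meta, "PN_vs_NN", "KC", False)
    disp = estimate_dispersions(sub, Xf, prior_df=0.0)
    mu = sub.counts.mean(axis=1)
    assert disp["phi_raw"][mu >= 100].median() < 0.01


def test_dispersion_recovery(null_cfg):
    cfg = null_cfg.with_(seed=9, dispersion=0.2, n_genes=600)
    cm, _ = simulate_counts(cfg)
    sub = cm.subset_samples(
        cm.meta.index[(cm.meta.tissue == "KC") & (cm.meta.status.isin(["PN", "NN"]))]
    )
    _, Xf, _ = _design_matrix(sub.meta, "PN_vs_NN", "KC", False)
    disp = estimate_dispersions(sub, Xf, prior_df=0.0)
    assert 0.1 <= disp["phi_raw"].median() <= 0.3


def test_dispersion_infinite_prior_gives_common(null_counts):
    sub = null_counts.subset_samples(
        null_counts.meta.index[
            (null_counts.meta.tissue == "KC") & (null_counts.meta.status.isin(["PN", "NN"]))
        ]
    ).subset_genes(null_counts.genes[:100])
    _, Xf, _ = _design_matrix(sub.meta, "PN_vs_NN", "KC", False)
    disp = estimate_dispersions(sub, Xf, prior_df=np.inf)
    assert np.allclose(disp["phi"], disp["phi_common"].iloc[0])


# ---------------------------------------------------------------------------
# NB GLM LRT


def test_lrt_matches_poisson_deviance_in_small_phi_limit():
    """With phi -> 0 the NB LRT equals the Poisson GLM likelihood-ratio test."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    counts = rng.poisson(200, size=(30, 8))
    cm = toy_count_matrix(
        counts, statuses=["PN"] * 4 + ["NN"] * 4, subjects=[f"u{i}" for i in range(8)]
    )
    factors = pd.Series(1.0, index=cm.samples)
    disp = pd.Series(1e-10, index=cm.genes)
    de = nb_glm_lrt(cm, disp, "PN_vs_NN", "KC", factors=factors)
    _, X_full, X_red = _design_matrix(cm.meta, "PN_vs_NN", "KC", False)
    offset = np.log(cm.library_sizes.to_numpy(dtype=float))
    for i in range(5):
        y = counts[i]
        llf = sm.GLM(y, X_full, family=sm.families.Poisson(), offset=offset).fit().llf
        llr = sm.GLM(y, X_red, family=sm.families.Poisson(), offset=offset).fit().llf
        assert de.table["lrt"].iloc[i] == pytest.approx(2 * (llf - llr), abs=1e-4)


def test_paired_design_has_patient_columns():
    cfg = SimConfig(n_genes=50, seed=1, n_modules=0)
    cm, _ = simulate_counts(cfg)
    samples, X_full, X_red = _design_matrix(cm.meta, "PP_vs_PN", "KC", True)
    # intercept + 3 patient dummies + group
    assert X_full.shape == (8, 5)
    assert X_red.shape == (8, 4)


def test_pairing_enforced():
    counts = np.ones((5, 4), dtype=int) * 100
    cm = toy_count_matrix(
        counts, statuses=["PP", "PP", "PN", "NN"], subjects=["a", "b", "a", "c"]
    )
    with pytest.raises(ValueError, match="paired"):
        cm.check_pairing("KC")


def test_nb_glm_recovers_planted_logfc():
    rng = np.random.default_rng(8)
    mu = np.full(8, 400.0)
    mu[:4] *= 4.0  # logFC = 2 for group 1 (PN)
    counts = rng.poisson(np.tile(mu, (40, 1)))
    # filler gene keeps all library sizes equal so the offset is constant
    filler = 1_000_000 - counts.sum(axis=0)
    counts = np.vstack([counts, filler])
    cm = toy_count_matrix(
        counts, statuses=["PN"] * 4 + ["NN"] * 4, subjects=[f"u{i}" for i in range(8)]
    )
    de = nb_glm_lrt(cm, pd.Series(1e-8, index=cm.genes), "PN_vs_NN", "KC",
                    factors=pd.Series(1.0, index=cm.samples))
    assert de.table["logFC"].iloc[:40].mean() == pytest.approx(2.0, abs=0.1)
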