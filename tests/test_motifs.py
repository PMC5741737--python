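"""Tests for promoter extraction, PWM scanning and motif enrichment."""

import numpy as np
import pandas as pd
import pytest

from kcseq.containers import DEResult
from kcseq.motifs import (
    PWM,
    extract_promoters,
    gam_motif_test,
    gc_fraction,
    hits_to_genomic,
    intersect_tf_expression,
    open_chromatin_overlap,
    pwm_from_consensus,
    read_jaspar,
    read_meme,
    revcomp,
    scan_pwm,
    summarize_motif_classes,
    synthetic_motif_panel,
)
from kcseq.simulate import SimConfig, simulate_annotation, simulate_genome, simulate_promoters_and_motifs


# ---------------------------------------------------------------------------
# PWM parsing and validity


JASPAR_TEXT = """>MA0000.1 TEST1
A [ 10  0  0 10 ]
C [  0 10  0  0 ]
G [  0  0 10  0 ]
T [  0  0  0  0 ]
>MA0001.1 TEST2
A [ 5 5 0 0 5 ]
C [ 0 0 5 5 0 ]
G [ 5 5 5 5 0 ]
T [ 0 0 0 1 5 ]
"""

MEME_TEXT = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M1 test
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
 0.80 0.10 0.05 0.05
 0.05 0.80 0.10 0.05
 0.05 0.10 0.80 0.05
 0.10 0.05 0.05 0.80
"""


def test_read_jaspar_columns_stochastic(tmp_path):
    p = tmp_path / "m.jaspar"
    p.write_text(JASPAR_TEXT)
    pwms = read_jaspar(p)
    assert len(pwms) == 2
    for pwm in pwms:
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)
    assert pwms[0].width == 4
    assert pwms[0].consensus == "ACGA"


def test_read_meme_minimal(tmp_path):
    p = tmp_path / "m.meme"
    p.write_text(MEME_TEXT)
    pwms = read_meme(p)
    assert len(pwms) == 1 and pwms[0].width == 4
    assert pwms[0].consensus == "ACGT"


def test_pwm_validation():
    with pytest.raises(ValueError, match="width"):
        PWM("x", np.full((4, 3), 0.25))
    with pytest.raises(ValueError, match="sum"):
        PWM("x", np.full((4, 6), 0.3))


# ---------------------------------------------------------------------------
# promoter extraction


def test_plus_strand_span_arithmetic():
    genome = {"chr1": "A" * 20_000}
    ann = pd.DataFrame({"chrom": ["chr1"], "tss": [10_000], "strand": ["+"],
                        "length": [500]}, index=["g"])
    prom = extract_promoters(ann, genome)
    assert prom.loc["g", "start"] == 5000 and prom.loc["g", "end"] == 10_500
    assert len(prom.loc["g", "sequence"]) == 5500
    assert not prom.loc["g", "truncated"]


def test_minus_strand_reverse_complement():
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
    genome = {"chr1": seq}
    ann = pd.DataFrame({"chrom": ["chr1"], "tss": [9000], "strand": ["-"],
                        "length": [500]}, index=["g"])
    prom = extract_promoters(ann, genome)
    span = seq[9000 - 500 : 9000 + 5000]
    assert prom.loc["g", "sequence"] == revcomp(span).upper()


def test_truncation_flagged_near_contig_edge():
    genome = {"chr1": "A" * 6000}
    ann = pd.DataFrame({"chrom": ["chr1"], "tss": [3000], "strand": ["+"],
                        "length": [500]}, index=["g"])
    prom = extract_promoters(ann, genome)
    assert prom.loc["g", "truncated"]
    assert len(prom.loc["g", "sequence"]) == 3500


def test_planted_marker_found_after_genome_roundtrip():
    """Promoters pasted into a synthetic genome are recovered exactly."""
    cfg = SimConfig(n_genes=30, seed=17, n_modules=0, n_chroms=3, gene_spacing=15_000)
    ann = simulate_annotation(cfg)
    pwm = pwm_from_consensus("MK", "TGACTCA")
    prom, truth = simulate_promoters_and_motifs(
        cfg, ann, [pwm], target_genes=list(ann.index), plant_frac_target=1.0
    )
    genome = simulate_genome(cfg, ann, prom)
    extracted = extract_promoters(ann, genome)
    assert (extracted.loc[prom.index, "sequence"] == prom["sequence"]).all()
    # marker 7-mer planted 5000 bp upstream of the TSS appears at offset 0
    g = prom.index[0]
    seq = prom.loc[g, "sequence"]
    marked = "TGACTCA" + seq[7:]
    assert extract_promoters(
        ann.loc[[g]], {ann.loc[g, "chrom"]: _paste(genome[ann.loc[g, "chrom"]], ann.loc[g], marked)}
    ).loc[g, "sequence"].startswith("TGACTCA")


def _paste(contig, row, oriented_seq):
    if row["strand"] == "+":
        start = int(row["tss"]) - 5000
        ins = oriented_seq
    else:
        start = int(row["tss"]) - 500
        ins = revcomp(oriented_seq)
    return contig[:start] + ins + contig[start + len(ins):]


# ---------------------------------------------------------------------------
# scanning


def test_consensus_scores_maximally_at_plant_site():
    pwm = pwm_from_consensus("M", "ACGTACGT")
    seq = "T" * 100 + "ACGTACGT" + "T" * 100
    hits = scan_pwm(seq, pwm, threshold_frac=1.0)
    plus = hits[hits["strand"] == "+"]
    assert plus["offset"].tolist() == [100]
    assert plus["score"].iloc[0] == pytest.approx(pwm.log_odds(np.full(4, 0.25)).max(axis=0).sum())


def test_ap1_motif_detected_on_minus_strand():
    """TGAGTCA is the reverse complement of the AP-1 site TGACTCA."""
    pwm = pwm_from_consensus("AP1", "TGACTCA")
    seq = "C" * 60 + "TGAGTCA" + "C" * 60
    hits = scan_pwm(seq, pwm, threshold_frac=1.0)
    assert (hits["strand"] == "-").any()
    assert hits.loc[hits["strand"] == "-", "offset"].tolist() == [60]


def test_strand_symmetry():
    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    pwm = pwm_from_consensus("M", "GATTACA", p_match=0.85)
    h_fwd = scan_pwm(seq, pwm, threshold_frac=0.7)
    h_rev = scan_pwm(revcomp(seq), pwm, threshold_frac=0.7)
    L, w = len(seq), pwm.width
    mirrored = sorted(
        (L - w - off, {"+": "-", "-": "+"}[s], round(sc, 9))
        for off, s, sc in h_rev.itertuples(index=False)
    )
    got = sorted((off, s, round(sc, 9)) for off, s, sc in h_fwd.itertuples(index=False))
    assert got == mirrored


def test_threshold_monotonicity():
    rng = np.random.default_rng(6)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    pwm = pwm_from_consensus("M", "TGACTCA", p_match=0.8)
    prev = None
    for frac in (0.5, 0.7, 0.9, 1.0):
        hits = scan_pwm(seq, pwm, threshold_frac=frac)
        cur = set(zip(hits["offset"], hits["strand"]))
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_degenerate_background_rejected():
    pwm = pwm_from_consensus("M", "ACGTAA")
    with pytest.raises(ValueError, match="pseudocount|positive"):
        scan_pwm("ACGT" * 30, pwm, background=np.array([0.5, 0.5, 0.0, 0.0]))


# ---------------------------------------------------------------------------
# enrichment model


def _planted_hit_scenario(rng, n_deg=100, n_bg=900, gc_bias=False, plant=True):
    genes = [f"g{i:04d}" for i in range(n_deg + n_bg)]
    membership = pd.Series([True] * n_deg + [False] * n_bg, index=genes)
    gc = pd.Series(rng.uniform(0.35, 0.65, len(genes)), index=genes)
    if gc_bias:
        gc[membership] += 0.08
    base_rate = 0.5 + (4.0 * (gc - gc.min()).to_numpy() if gc_bias else 0.0)
    hits = rng.poisson(base_rate, size=len(genes))
    if plant:
        hits = hits + np.where(membership, rng.binomial(1, 0.5, len(genes)),
                               rng.binomial(1, 0.05, len(genes)))
    return membership, pd.DataFrame({"M0": hits}, index=genes), gc


def test_gam_recovers_planted_enrichment():
    rng = np.random.default_rng(3)
    membership, hits, gc = _planted_hit_scenario(rng)
    res = gam_motif_test(membership, hits, gc)
    assert res.loc["M0", "coef"] > 0
    assert res.loc["M0", "pvalue"] < 1e-4


def test_gam_requires_two_genes_per_class():
    rng = np.random.default_rng(4)
    membership, hits, gc = _planted_hit_scenario(rng, n_deg=1, n_bg=50)
    with pytest.raises(ValueError):
        gam_motif_test(membership, hits, gc)


def test_gam_flags_separation_fallback():
    genes = [f"g{i}" for i in range(40)]
    membership = pd.Series([True] * 20 + [False] * 20, index=genes)
    hits = pd.DataFrame({"M0": [5] * 20 + [0] * 20}, index=genes)  # separating
    gc = pd.Series(np.linspace(0.4, 0.6, 40), index=genes)
    res = gam_motif_test(membership, hits, gc)
    assert bool(res.loc["M0", "flagged"])
    assert np.isfinite(res.loc["M0", "pvalue"])


def test_constant_hit_column_gets_nan_p():
    genes = [f"g{i}" for i in range(30)]
    membership = pd.Series([True] * 10 + [False] * 20, index=genes)
    hits = pd.DataFrame({"M0": [2] * 30}, index=genes)
    gc = pd.Series(np.linspace(0.4, 0.6, 30), index=genes)
    res = gam_motif_test(membership, hits, gc)
    assert np.isnan(res.loc["M0", "pvalue"])


# ---------------------------------------------------------------------------
# TF intersection and class summary


def _enrichment_and_panel():
    panel = [
        pwm_from_consensus("M_down", "TGACTCA", tf_class="bZIP"),
        pwm_from_consensus("M_null", "CCCGGGA", tf_class="ZF"),
        pwm_from_consensus("M_multi", "TTTACGA", tf_class="bZIP"),
    ]
    panel[0].tf_genes = ("TF1",)
    panel[1].tf_genes = ("TF2",)
    panel[2].tf_genes = ("TF2", "TF1")
    enr = pd.DataFrame(
        {"coef": [1.0, 0.5, 0.2], "pvalue": [1e-5, 0.2, 0.01],
         "fdr": [3e-5, 0.2, 0.015], "enriched": [True, False, True]},
        index=["M_down", "M_null", "M_multi"],
    )
    table = pd.DataFrame(
        {"FC": [0.3, 1.2], "logFC": np.log2([0.3, 1.2]), "fdr": [0.01, 0.01],
         "pvalue": [0.001, 0.01], "detected": [True, True], "call": ["down", "none"]},
        index=["TF1", "TF2"],
    )
    de = DEResult(table=table, comparison="PN_vs_NN", tissue="KC")
    return enr, panel, de


def test_tf_intersection_any_rule():
    enr, panel, de = _enrichment_and_panel()
    out = intersect_tf_expression(enr, panel, de)
    assert bool(out.loc["M_down", "tf_decreased"])       # mapped to a down TF
    assert not bool(out.loc["M_null", "tf_decreased"])   # mapped to a null TF
    assert bool(out.loc["M_multi", "tf_decreased"])      # any-rule over multiple TFs


def test_motif_class_summary_groupby():
    enr, panel, _ = _enrichment_and_panel()
    grp = summarize_motif_classes(enr, panel)
    assert grp.loc["bZIP", "n_enriched"] == 2
    assert grp.loc["ZF", "n_enriched"] == 0
    assert grp.loc["bZIP", "fraction_of_significant"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# open chromatin


def _hits_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "gstart", "gend"])


def test_open_chromatin_one_bp_overlap():
    bed = pd.DataFrame({"chrom": ["chr1"], "start": [106], "end": [200]})
    hits = _hits_df([("chr1", 100, 107)])
    assert open_chromatin_overlap(hits, bed)["open_chromatin"].iloc[0]


def test_open_chromatin_half_open_no_touch():
    bed = pd.DataFrame({"chrom": ["chr1"], "start": [107], "end": [200]})
    hits = _hits_df([("chr1", 100, 107)])
    assert not open_chromatin_overlap(hits, bed)["open_chromatin"].iloc[0]


def test_open_chromatin_matches_brute_force():
    rng = np.random.default_rng(8)
    bed = pd.DataFrame(
        {"chrom": rng.choice(["chr1", "chr2"], 20),
         "start": rng.integers(0, 5000, 20)}
    )
    bed["end"] = bed["start"] + rng.integers(1, 400, 20)
    hits = _hits_df(
        [(c, s, s + 7) for c, s in zip(rng.choice(["chr1", "chr2"], 50),
                                       rng.integers(0, 5400, 50))]
    )
    got = open_chromatin_overlap(hits, bed)["open_chromatin"].to_numpy()
    brute = np.array(
        [
            any(
                (b.chrom == h.chrom) and (h.gstart < b.end) and (b.start < h.gend)
                for b in bed.itertuples()
            )
            for h in hits.itertuples()
        ]
    )
    assert (got == brute).all()


def test_hits_to_genomic_roundtrip_contains_plant():
    prow = pd.Series({"chrom": "chr1", "start": 4000, "end": 9500, "strand": "+"})
    hits = pd.DataFrame({"offset": [120], "strand": ["+"], "score": [10.0]})
    out = hits_to_genomic(hits, prow, width=7)
    assert out["gstart"].iloc[0] == 4120 and out["gend"].iloc[0] == 4127
    prow_m = pd.Series({"chrom": "chr1", "start": 4000, "end": 9500, "strand": "-"})
    out_m = hits_to_genomic(hits, prow_m, width=7)
    assert out_m["gend"].iloc[0] == 9500 - 120
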