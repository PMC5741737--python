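"""Promoter motif enrichment with a planted AP-1 site.

Generates 5500 bp TSS-proximal promoter sequences (5000 up / 500 down of
the TSS) with the AP-1 consensus TGACTCA planted in half of a 200-gene
"DEG" set versus 5% of the background, scans a small PWM panel on both
strands, and fits the semiparametric logistic enrichment model with a
smooth GC covariate.  The TF-expression intersection and open-chromatin
overlap steps are shown on the enriched motif.
"""

import pandas as pd

from kcseq.motifs import (
    count_hits,
    gam_motif_test,
    hits_to_genomic,
    intersect_tf_expression,
    open_chromatin_overlap,
    scan_pwm,
    synthetic_motif_panel,
)
from kcseq.de import run_de
from kcseq.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_counts,
    simulate_open_chromatin,
    simulate_promoters_and_motifs,
)

cfg = SimConfig(n_genes=2200, seed=5, n_modules=30)
ann = simulate_annotation(cfg)
cm, truth_deg = simulate_counts(cfg)
panel = synthetic_motif_panel(12, seed=2, tf_genes=list(ann.index[:12]))
target = list(ann.index[:200])
prom, truth = simulate_promoters_and_motifs(
    cfg, ann, panel, target_genes=target, plant_frac_target=0.5, plant_frac_background=0.05
)
print(f"{len(prom)} promoters, {len(truth.motif_plants)} planted AP-1 sites")

hits = count_hits(prom, panel)
membership = pd.Series(False, index=prom.index)
membership[target] = True
enr = gam_motif_test(membership, hits, prom["gc"])
print(enr.sort_values("pvalue")[["coef", "pvalue", "fdr", "enriched"]].head(5).to_string())

de = run_de(cm, ann["length"], "PN_vs_NN", "KC")
# map the AP-1 motif to a disease-repressed TF gene, as for FOSL2/JUNB
panel[0].tf_genes = (str(de.degs("down")[0]),)
enr = intersect_tf_expression(enr, panel, de)
top = enr.sort_values("pvalue").iloc[0]
print(f"\ntop motif: {enr['pvalue'].idxmin()}  coef={top['coef']:.3f}  "
      f"fdr={top['fdr']:.2e}  tf_decreased={top['tf_decreased']}")

# map one promoter's hits to genomic coordinates and overlap open chromatin
gene = truth.motif_plants["gene"].iloc[0]
prow = pd.Series({"chrom": ann.loc[gene, "chrom"],
                  "start": int(ann.loc[gene, "tss"]) - 5000,
                  "end": int(ann.loc[gene, "tss"]) + 500,
                  "strand": ann.loc[gene, "strand"]})
ghits = hits_to_genomic(scan_pwm(prom.loc[gene, "sequence"], panel[0]), prow, panel[0].width)
import pandas as _pd

bed = _pd.concat(
    [simulate_open_chromatin(cfg, ann, [gene]),
     _pd.DataFrame({"chrom": [prow["chrom"]],
                    "start": [int(ghits["gstart"].iloc[0]) - 50],
                    "end": [int(ghits["gstart"].iloc[0]) + 50]})]
)
print("\nhits for", gene, "vs open-chromatin intervals at its promoter:")
print(open_chromatin_overlap(ghits, bed).to_string(index=False))
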