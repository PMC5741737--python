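"""Differential expression on a synthetic paired keratinocyte/skin cohort.

Simulates the default 24-sample study design (4 patients x PP/PN + 4
controls x NN, each profiled as cultured keratinocytes and whole skin),
runs the three comparisons in both tissues, and prints DEG counts.  The
planted scenario repressed ~5% of genes in patient keratinocytes, so the
KC comparisons should report far more decreased DEGs than the skin ones.
"""

import pandas as pd

from kcseq.de import run_de
from kcseq.simulate import SimConfig, simulate_annotation, simulate_counts

cfg = SimConfig(seed=1)
cm, truth = simulate_counts(cfg)
ann = simulate_annotation(cfg)

print(f"cohort: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples")
print(f"planted DEGs: {truth.true_deg.groupby(['tissue', 'direction']).size().to_dict()}")
print()
rows = []
for tissue in ("KC", "skin"):
    for comparison in ("PP_vs_PN", "PP_vs_NN", "PN_vs_NN"):
        de = run_de(cm, ann["length"], comparison, tissue)
        rows.append(
            {
                "tissue": tissue,
                "comparison": comparison,
                "detected": len(de.detected_genes),
                "up": len(de.degs("up")),
                "down": len(de.degs("down")),
            }
        )
print(pd.DataFrame(rows).to_string(index=False))
print()
print("Each row: genes passing the detection filter (cpm > 0.25, FPKM CI > 0")
print("in >= 2 of 8 samples) and DEGs at FDR < 0.10 with FC > 2.0 or < 0.50.")
print("The KC comparisons recover many more decreased genes than whole skin,")
print("matching the planted asymmetry.")
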