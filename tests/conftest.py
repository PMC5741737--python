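import numpy as np
import pandas as pd
import pytest

from kcseq.containers import CountMatrix
from kcseq.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def null_cfg() -> SimConfig:
    """All-null cohort: no planted effects, no subject variation, phi=0.1."""
    return SimConfig(
        n_genes=2000,
        seed=7,
        subject_sd=0.0,
        tissue_sd=0.0,
        frac_deg_kc_down=0.0,
        frac_deg_kc_up=0.0,
        frac_deg_skin_down=0.0,
        frac_deg_skin_up=0.0,
        frac_silent=0.0,
        dispersion=0.1,
        n_modules=40,
    )


@pytest.fixture(scope="session")
def null_counts(null_cfg):
    cm, _ = simulate_counts(null_cfg)
    return cm


@pytest.fixture(scope="session")
def unit_lengths(null_counts) -> pd.Series:
    return pd.Series(1000, index=null_counts.genes)


def toy_count_matrix(counts: np.ndarray, statuses, tissues=None, subjects=None) -> CountMatrix:
    """Small CountMatrix helper: columns named s1.. with given labels."""
    counts = np.asarray(counts)
    n_s = counts.shape[1]
    samples = [f"s{i+1}" for i in range(n_s)]
    meta = pd.DataFrame(
        {
            "subject": subjects or [f"u{i+1}" for i in range(n_s)],
            "tissue": tissues or ["KC"] * n_s,
            "status": statuses,
        },
        index=pd.Index(samples, name="sample"),
    )
    genes = pd.Index([f"g{i+1}" for i in range(counts.shape[0])], name="gene")
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)
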