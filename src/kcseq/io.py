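"""Readers and writers for the plain-text formats the pipeline consumes.

Everything is tab-delimited UTF-8 with a single header line, except FASTA
(via Biopython), BED (3+ columns, no header) and the JASPAR/MEME motif
formats (via Bio.motifs).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, ExpressionMatrix


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_matrix(values: pd.DataFrame, path, index_label: str = "gene") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(em: ExpressionMatrix, path) -> None:
    write_matrix(em.values, path)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    required = {"chrom", "tss", "strand", "length"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation lacks columns {sorted(missing)}")
    return ann


def write_loci(loci: pd.DataFrame, path) -> None:
    loci.to_csv(path, sep="\t", index=False)


def read_loci(path) -> pd.DataFrame:
    loci = pd.read_csv(path, sep="\t")
    required = {"region", "snp", "chrom", "pos", "pvalue"}
    missing = required - set(loci.columns)
    if missing:
        raise ValueError(f"locus table lacks columns {sorted(missing)}")
    return loci


def write_fasta(sequences: dict[str, str] | pd.Series, path) -> None:
    records = [
        SeqRecord(Seq(str(seq)), id=str(name), description="")
        for name, seq in (sequences.items() if hasattr(sequences, "items") else sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path) -> pd.DataFrame:
    """BED intervals (0-based half-open); only the first three columns are used."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end"]
    bed["start"] = bed["start"].astype(int)
    bed["end"] = bed["end"].astype(int)
    return bed


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_json_table(obj, path) -> None:
    import json

    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
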