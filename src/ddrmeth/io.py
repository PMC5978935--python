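"""Plain-text (TSV) readers and writers for matrices and annotation tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import validate_annotation


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a samples x probes (or samples x genes) matrix as TSV."""
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(ann: pd.DataFrame, path) -> None:
    """BED-like TSV: chrom, 1-based position, probe_id, then context columns."""
    out = ann.reset_index()[
        ["chrom", "pos", "probe_id", "gene", "tss_distance", "region_class",
         "snp_flag", "sex_chrom", "ddr_flag"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene": str})
    ann["gene"] = ann["gene"].fillna("")
    ann = ann.set_index("probe_id")
    return validate_annotation(ann)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
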