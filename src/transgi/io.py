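"""Readers and writers for the plain-text formats used by the pipeline."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "read_bed",
    "read_dosages_vcf",
    "write_stage_tsv",
    "JsonlLogger",
]

_FLOAT_FMT = "%.10g"


def read_matrix_tsv(path: str, index_col: str = "sample") -> pd.DataFrame:
    """Read a samples x features TSV matrix."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_bed(path: str, names: tuple[str, ...] = ("chrom", "start", "end", "name")) -> pd.DataFrame:
    """Read a headerless BED-like TSV, tolerating extra columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_dosages_vcf(path: str) -> pd.DataFrame:
    """Read a VCF with a DS FORMAT field into a samples x SNPs dosage matrix."""
    from cyvcf2 import VCF  # optional dependency; plain TSV is the default path

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            continue
        cols[var.ID] = np.asarray(ds, dtype=float).reshape(-1)
    return pd.DataFrame(cols, index=samples)


def write_stage_tsv(df: pd.DataFrame, path: str, meta: str, index: bool = False) -> None:
    """Write a stage output TSV with a single '#'-prefixed metadata line."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT)


class JsonlLogger:
    """Append-only JSON-lines run log (no timestamps: reruns must be
    byte-identical)."""

    def __init__(self, path: str):
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        self.path = path
        with open(self.path, "w"):
            pass

    def log(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
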