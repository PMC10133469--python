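"""Readers and writers for the plain-text interchange formats.

counts.tsv        samples x genera integer table, first column ``sample_id``
taxonomy.tsv      columns ``genus``, ``domain`` (Archaea|Bacteria|unclassified),
                  ``phylum``
phenotypes.csv    one row per sample: diet, breed, chamber, week,
                  body_weight_kg, dmi_kg_d, ch4_g_d, ch4_yield_g_kg_dmi
truth.json        ground-truth effect records from the simulator
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "read_counts",
    "read_taxonomy",
    "read_phenotypes",
    "read_truth",
    "write_clr",
    "read_clr",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genus count table (samples x genera, integer)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if (df.values < 0).any():
        raise ValidationError(f"negative counts in {path}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"duplicate sample or genus ids in {path}")
    return df.astype("int64")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"genus", "domain", "phylum"} - set(df.columns)
    if missing:
        raise ValidationError(f"taxonomy file {path} lacks columns {sorted(missing)}")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"phenotype file {path} lacks a sample_id column")
    if df.isna().any().any():
        raise ValidationError(f"phenotype file {path} has missing values")
    return df


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_clr(clr: pd.DataFrame, path: str | Path) -> None:
    """Write a clr matrix as TSV, same orientation as the count table."""
    clr.to_csv(path, sep="\t")


def read_clr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
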