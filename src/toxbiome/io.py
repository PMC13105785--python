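"""TSV/JSON readers and writers for the pipeline's file dialects.

Conventions: metadata and labs are plain TSVs with one row per record;
feature tables are stored features-as-rows x samples-as-columns (the usual
abundance-table orientation) but handled samples x features in memory; LD
matrices are square TSVs with SNP ids as both row and column labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV into a samples x features frame."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x features frame as a features x samples TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.T.to_csv(path, sep="\t", index_label="feature")


def read_metadata(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col:
        df = df.set_index(index_col)
        df.index = df.index.astype(str)
    return df


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ld_matrix(ld: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ld.to_csv(path, sep="\t", index_label="snp")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
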