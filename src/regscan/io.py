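"""Readers and writers for the plain-text formats the pipeline exchanges.

Cohort expression matrices and bin-count matrices travel as TSV, region sets
as BED, chromatin loops as BEDPE, gene sets as GMT, and simulation truth as
JSON. All writers use a fixed float format so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# expression matrices (genes x samples)

def write_expression_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a genes × samples matrix; index = gene IDs, columns = sample IDs."""
    matrix.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df


# ---------------------------------------------------------------------------
# bin-count matrices (BED-style coordinate columns + one column per sample)

def write_bin_counts_tsv(
    path: str | Path, chrom: str, starts: np.ndarray, ends: np.ndarray, counts: pd.DataFrame
) -> None:
    out = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    out = pd.concat([out, counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_bin_counts_tsv(path: str | Path) -> tuple[str, np.ndarray, np.ndarray, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: expected a single chromosome, found {list(chroms)}")
    counts = df.drop(columns=["chrom", "start", "end"])
    return str(chroms[0]), df["start"].to_numpy(), df["end"].to_numpy(), counts


# ---------------------------------------------------------------------------
# BED / BEDPE

def write_bed(path: str | Path, records: pd.DataFrame) -> None:
    """Write BED; expects columns chrom,start,end and optionally name,score,..."""
    records.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FORMAT)


def read_bed(path: str | Path, n_cols: int | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    extra = [f"extra{i}" for i in range(max(0, df.shape[1] - len(names)))]
    df.columns = (names + extra)[: df.shape[1]]
    if n_cols is not None and df.shape[1] < n_cols:
        raise ValueError(f"{path}: expected ≥{n_cols} BED columns, found {df.shape[1]}")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED records with start >= end")
    return df


def write_bedpe(path: str | Path, loops: pd.DataFrame) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    loops[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs ≥6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if (df["start1"] >= df["end1"]).any() or (df["start2"] >= df["end2"]).any():
        raise ValueError(f"{path}: BEDPE anchors with start >= end")
    return df


# ---------------------------------------------------------------------------
# GMT gene sets

def write_gmt(path: str | Path, sets: Mapping[str, Iterable[str]], description: str = "regscan") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line with fewer than 3 fields")
            sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# JSON helpers (truth files, manifests)

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
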