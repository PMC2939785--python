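"""Readers and writers for the plain-text dialects used across the pipeline.

Matrix files are UTF-8 TSV: header row of sample ids, first column the
feature id, numeric cells.  An *empty* cell is the sentinel for an
undetected qPCR reaction (missing in memory, ``NaN``); undetected is never
encoded as a pseudo-Ct such as 40.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SAMPLE_COLUMNS = [
    "subtype",
    "t_status",
    "n_status",
    "m_status",
    "stage",
    "grade",
    "er",
    "her2",
    "age",
]

SURVIVAL_COLUMNS = ["sample_id", "dataset_id", "endpoint", "time", "event"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix; NaN serializes to an empty cell."""
    df.to_csv(path, sep="\t", na_rep="")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation table (one row per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_target_db(path: str | Path) -> dict[str, set[str]]:
    """Read a flat miRNA -> predicted-target mapping (columns mirna_id, gene_symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["mirna_id", "gene_symbol"]:
        raise ValueError(f"expected columns mirna_id, gene_symbol in {path}")
    mapping: dict[str, set[str]] = {}
    for mirna, gene in zip(df["mirna_id"], df["gene_symbol"]):
        mapping.setdefault(mirna, set()).add(gene)
    return mapping


def write_target_db(mapping: dict[str, set[str]], path: str | Path) -> None:
    rows = [(m, g) for m in sorted(mapping) for g in sorted(mapping[m])]
    pd.DataFrame(rows, columns=["mirna_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, then one gene per field."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table missing columns {missing}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
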