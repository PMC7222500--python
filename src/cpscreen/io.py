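"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-separated text: expression matrices and label tables as
TSV, ranked signatures as RNK (gene, score), gene-set libraries as GMT
(name, description, members...), plus the interaction and exposure tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its column or shape contract."""


# ---------------------------------------------------------------- matrices

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV matrix (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expected at least one sample column")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample_id / group TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df.set_index("sample_id")["group"]


def write_labels(labels: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    s = pd.Series(labels, name="group")
    s.rename_axis("sample_id").to_csv(path, sep="\t", lineterminator="\n")


def read_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def write_mapping(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------- RNK / GMT

def read_rnk(path: str | Path) -> List[Tuple[str, float]]:
    """Read a ranked gene list (gene_id TAB score, descending score)."""
    entries: List[Tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed RNK line {line!r}")
            entries.append((parts[0], float(parts[1])))
    return entries


def write_rnk(entries: Iterable[Tuple[str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, score in entries:
            fh.write(f"{gene}\t{score:.10g}\n")


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Read a GMT gene-set library; returns name -> member list (ordered)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line needs name, description, members")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = descriptions.get(name, "na") if descriptions else "na"
            members = "\t".join(sets[name])
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------- tables

INTERACTION_COLUMNS = [
    "chemical_id",
    "chemical_name",
    "gene_id",
    "organism",
    "action",
    "target_type",
    "pubmed_ids",
]


def read_interactions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in INTERACTION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=INTERACTION_COLUMNS,
              lineterminator="\n")


def read_exposure(path: str | Path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("chemical_id", "exposure"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    bad = set(df["exposure"]) - {"high", "medium", "low"}
    if bad:
        raise FormatError(f"{path}: invalid exposure labels {sorted(bad)}")
    return dict(zip(df["chemical_id"], df["exposure"]))


def write_exposure(exposure: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"chemical_id": list(exposure), "exposure": list(exposure.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
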