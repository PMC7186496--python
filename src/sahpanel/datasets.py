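"""Expression-matrix container and plain-text I/O.

The package works on gene x sample matrices in two dialects:

``"log"``
    Log2-scale intensities (microarray-style, or log-CPM after
    :func:`sahpanel.diffexpr.transform_counts`).
``"counts"``
    Nonnegative integer read counts (RNA-seq-style).

All files are uncompressed, tab-separated UTF-8 text so that fixtures and
pipeline artifacts stay human-readable and diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DIALECTS = ("log", "counts")

METADATA_COLUMNS = ("sample_id", "group", "time", "treatment")


@dataclasses.dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene (or probe) id, columns by sample id.
    metadata : pandas.DataFrame
        One row per sample; columns ``sample_id``, ``group``, ``time``,
        ``treatment``. ``sample_id`` must match the matrix columns.
    dialect : str
        ``"log"`` or ``"counts"``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    dialect: str = "log"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"dialect must be one of {DIALECTS}, got {self.dialect!r}")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata is missing columns: {missing}")
        meta_ids = list(self.metadata["sample_id"])
        mat_ids = list(self.values.columns)
        if sorted(meta_ids) != sorted(mat_ids):
            raise ValueError(
                "sample ids in metadata do not match matrix columns: "
                f"{sorted(set(mat_ids) ^ set(meta_ids))}"
            )
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> sample ids, in metadata order."""
        out: dict[str, list[str]] = {}
        for sid, grp in zip(self.metadata["sample_id"], self.metadata["group"]):
            out.setdefault(grp, []).append(sid)
        return out

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.groups().get(group)
        if not sel:
            raise KeyError(f"group {group!r} not present in metadata")
        return sel

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        keep = [g for g in gene_ids if g in self.values.index]
        return ExpressionDataset(self.values.loc[keep], self.metadata.copy(), self.dialect)


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix with a leading ``gene_id`` column."""
    frame = dataset.values.copy()
    frame.insert(0, "gene_id", frame.index)
    frame.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path, metadata: pd.DataFrame, dialect: str = "log") -> ExpressionDataset:
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {frame.columns[0]!r}")
    frame = frame.set_index("gene_id")
    frame.index.name = None
    return ExpressionDataset(frame, metadata, dialect)


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.loc[:, list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    return meta


def write_gmt(gene_sets: Mapping[str, set[str] | list[str]], path: str | Path, description: str = "na") -> None:
    """Write gene sets in the 3+-column GMT format (name, description, members)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in gene_sets:
            members = sorted(gene_sets[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >=3 tab-separated fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_annotation_tsv(mapping: pd.DataFrame, path: str | Path) -> None:
    """Probe -> gene annotation map, columns ``probe_id``, ``gene_id``."""
    mapping.loc[:, ["probe_id", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    mapping = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in mapping.columns:
            raise ValueError(f"{path}: annotation map missing column {col!r}")
    return mapping


def map_probes_to_genes(probe_ids, annotation: pd.DataFrame) -> list[str]:
    """Translate probe ids to gene ids, dropping unmapped probes and duplicates.

    Order follows the first occurrence of each mapped gene.
    """
    lookup = dict(zip(annotation["probe_id"], annotation["gene_id"]))
    seen: set[str] = set()
    out: list[str] = []
    for pid in probe_ids:
        gid = lookup.get(pid)
        if gid is None or gid in seen or (isinstance(gid, float) and np.isnan(gid)):
            continue
        seen.add(gid)
        out.append(gid)
    return out
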