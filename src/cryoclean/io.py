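"""Readers and writers for every external format the pipeline touches.

Tabular artifacts (OTU table, sample sheet, taxonomy, distance matrix) are
plain TSV with a header; trees are newick handled by scikit-bio. Every reader
validates against the type invariants in :mod:`cryoclean.model` and every
writer emits files its reader re-ingests identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .model import (
    RANKS,
    UNCLASSIFIED,
    FormatError,
    OtuTable,
    SampleSheet,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "read_distance_matrix",
    "write_distance_matrix",
]

log = logging.getLogger("cryoclean")

DIALECTS = ("tsv_samples_as_rows", "tsv_samples_as_cols")

#: lineage prefixes in the rank-prefixed dialect ("k__Bacteria;p__...;g__...").
_PREFIXES = {"k": "domain", "d": "domain", "p": "phylum", "c": "class",
             "o": "order", "f": "family", "g": "genus"}
_RANK_TO_PREFIX = {"domain": "k", "phylum": "p", "class": "c", "order": "o",
                   "family": "f", "genus": "g"}

_ORGANELLE_MARKERS = ("mitochondri", "chloroplast")


def read_otu_table(path, dialect: str = "tsv_samples_as_rows") -> OtuTable:
    """Read an OTU count table from TSV in either orientation.

    The internal canonical orientation is samples-as-rows; reading the same
    table in both dialects yields identical objects.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse OTU table {path}: {exc}") from exc
    if dialect == "tsv_samples_as_cols":
        df = df.T
    values = np.empty(df.shape, dtype=np.int64)
    for i, (sid, row) in enumerate(df.iterrows()):
        for j, (oid, cell) in enumerate(row.items()):
            try:
                v = int(cell)
                if float(cell) != v:
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at sample {sid!r}, OTU {oid!r}"
                ) from None
            values[i, j] = v
    return OtuTable(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_otu_table(table: OtuTable, path, dialect: str = "tsv_samples_as_rows") -> None:
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = table.to_dataframe()
    if dialect == "tsv_samples_as_cols":
        df = df.T
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"could not parse sample sheet {path}: {exc}") from exc
    for col in SampleSheet.REQUIRED:
        if col not in df.columns:
            raise FormatError(f"sample sheet {path} is missing column {col!r}")
    df["qpcr_copies_per_ul"] = pd.to_numeric(df["qpcr_copies_per_ul"], errors="coerce")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


def _parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a rank-prefixed lineage string into a rank -> name mapping."""
    out = {r: "" for r in RANKS}
    for part in str(lineage).split(";"):
        part = part.strip()
        if not part:
            continue
        if len(part) >= 3 and part[1:3] == "__" and part[0].lower() in _PREFIXES:
            rank = _PREFIXES[part[0].lower()]
            out[rank] = part[3:].strip()
        # unprefixed fragments are ignored rather than guessed at
    return out


def read_taxonomy(path, confidence_threshold: float = 0.80) -> TaxonomyTable:
    """Read OTU -> lineage assignments, masking low-confidence ranks.

    Ranks whose confidence is strictly below ``confidence_threshold`` are
    replaced by ``unclassified`` (a confidence exactly at the threshold is
    retained). With the usual single per-assignment confidence the mask
    applies to the whole lineage; a ``confidences`` column of per-rank
    ``;``-separated values masks rank by rank. Lineages naming mitochondria
    or chloroplasts (case-insensitive substring match) are flagged as
    organellar.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"could not parse taxonomy {path}: {exc}") from exc
    for col in ("otu_id", "lineage", "confidence"):
        if col not in df.columns:
            raise FormatError(f"taxonomy {path} is missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        lineage = str(row["lineage"])
        ranks = _parse_lineage(lineage)
        conf = float(row["confidence"])
        if not 0.0 <= conf <= 1.0:
            raise ValidationError(
                f"confidence {conf} outside [0, 1] for OTU {row['otu_id']!r}"
            )
        per_rank = None
        if "confidences" in df.columns and pd.notna(row.get("confidences")) \
                and str(row.get("confidences")).strip():
            vals = [float(v) for v in str(row["confidences"]).split(";")]
            if len(vals) != len(RANKS):
                raise FormatError(
                    f"expected {len(RANKS)} per-rank confidences for OTU "
                    f"{row['otu_id']!r}, got {len(vals)}"
                )
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValidationError(
                    f"per-rank confidence outside [0, 1] for OTU {row['otu_id']!r}"
                )
            per_rank = dict(zip(RANKS, vals))
        masked = {}
        for r in RANKS:
            c = per_rank[r] if per_rank is not None else conf
            name = ranks[r]
            if not name:
                masked[r] = ""  # rank absent from the lineage string
            elif c < confidence_threshold:
                masked[r] = UNCLASSIFIED  # strict <: exactly-at-threshold kept
            else:
                masked[r] = name
        low = lineage.lower()
        organelle = any(m in low for m in _ORGANELLE_MARKERS)
        records.append({"otu_id": str(row["otu_id"]), "lineage": lineage,
                        "confidence": conf, "is_organelle": organelle, **masked})
    out = pd.DataFrame.from_records(records)
    return TaxonomyTable(out)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    """Write the post-masking taxonomy; re-reading reproduces the ranks.

    The lineage is re-serialised from the masked ranks so that a round trip
    through :func:`read_taxonomy` (at any threshold <= the original) is the
    identity.
    """
    df = tax.df.copy()
    df["lineage"] = [
        ";".join(f"{_RANK_TO_PREFIX[r]}__{df.loc[o, r]}" for r in RANKS)
        for o in df.index
    ]
    cols = ["otu_id", "lineage", "confidence", "is_organelle", *RANKS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_newick(path) -> skbio.TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"could not parse newick {path}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} in {path}"
            )
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        log.warning("newick %s: %d missing branch length(s) treated as 0",
                    path, n_missing)
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return skbio.DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))
    except Exception as exc:
        raise ValidationError(f"invalid distance matrix {path}: {exc}") from exc


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t")
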