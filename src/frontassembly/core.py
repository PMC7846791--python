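"""Core data model and file formats.

The central object is the :class:`OtuTable`: a samples x OTUs matrix of read
counts with per-sample metadata (season, station, depth, size fraction,
replicate) and an OTU -> taxonomic-reference map through which trait
annotations are propagated.  Trees are scikit-bio ``TreeNode`` objects over
OTU tips; symmetric distance carriers are scikit-bio ``DistanceMatrix``
objects (cophenetic, Bray-Curtis, Gower) or labelled square DataFrames where
entries may be negative (βNTI) or signed (Raup-Crick).

All tabular formats are plain text: TSV for counts and matrices, CSV for
metadata/traits/environment, Newick for trees, JSON for nested results.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("frontassembly")

SEASONS = ("March", "July", "September")
STATIONS = ("O1", "O2", "F", "C1", "C2")  # ocean -> coast
DEPTHS = ("surface", "DCM")
SIZE_FRACTIONS = ("micro", "nano", "pico")  # >10 um, 10-3 um, 3-0.2 um
METADATA_FIELDS = ("season", "station", "depth", "size_fraction", "replicate")

_VOCAB = {
    "season": SEASONS,
    "station": STATIONS,
    "depth": DEPTHS,
    "size_fraction": SIZE_FRACTIONS,
}

NUMERIC_TRAITS = ("SizeMin", "SizeMax")
CATEGORICAL_TRAITS = (
    "Cell Cover",
    "Cell Shape",
    "Cell Symmetry",
    "Cell Polarity",
    "Ingestion method",
    "Symbiosis type",
)
BINARY_TRAITS = ("Presence of Spicule", "Coloniality", "Motility", "Resting Stage")
TRAIT_COLUMNS = NUMERIC_TRAITS + CATEGORICAL_TRAITS + BINARY_TRAITS
PHOTOTROPH_COLUMN = "obligate_phototroph"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_metadata(metadata: pd.DataFrame) -> None:
    if metadata.index.has_duplicates:
        dups = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample_id(s): {dups}")
    for col, vocab in _VOCAB.items():
        if col in metadata.columns:
            bad = set(metadata[col].dropna().astype(str)) - set(vocab)
            if bad:
                raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
    if "replicate" in metadata.columns:
        reps = pd.to_numeric(metadata["replicate"], errors="raise")
        if (reps < 1).any():
            raise ValidationError("replicate must be >= 1")


def _coerce_counts(counts: pd.DataFrame) -> pd.DataFrame:
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("counts contain non-finite values")
        rounded = np.rint(arr)
        if np.max(np.abs(arr - rounded), initial=0.0) > 1e-9:
            raise ValidationError("counts must be integral (within 1e-9)")
        arr = rounded.astype(np.int64)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    return pd.DataFrame(arr.astype(np.int64), index=counts.index, columns=counts.columns)


@dataclass
class OtuTable:
    """Samples x OTUs read-count matrix with metadata and taxref map.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and OTU ids as columns.
    metadata
        DataFrame indexed by sample id; columns are a subset of
        ``METADATA_FIELDS`` (fields may be absent after merging).
    taxref
        Series mapping each OTU id to a taxonomic-reference string
        (``"unknown"`` when unannotated).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxref: pd.Series = None

    def __post_init__(self) -> None:
        self.counts = _coerce_counts(self.counts)
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate sample ids in counts")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate OTU ids in counts")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValidationError(
                f"samples missing from metadata: {sorted(missing.tolist())}"
            )
        self.metadata = self.metadata.loc[self.counts.index]
        _check_metadata(self.metadata)
        empty = self.counts.columns[self.counts.sum(axis=0) == 0]
        if len(empty):
            logger.warning("dropping %d all-zero OTU column(s)", len(empty))
            self.counts = self.counts.drop(columns=empty)
        if self.taxref is None:
            self.taxref = pd.Series("unknown", index=self.counts.columns)
        else:
            self.taxref = self.taxref.reindex(self.counts.columns).fillna("unknown")
        self.taxref = self.taxref.astype(str)

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def presence(self) -> pd.DataFrame:
        """Boolean samples x OTUs presence matrix."""
        return self.counts > 0

    def subset_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        return OtuTable(self.counts[keep], self.metadata.copy(), self.taxref[keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


def read_otu_table(path, metadata_path, taxref_path=None) -> OtuTable:
    """Read a count TSV plus a sample-metadata CSV into an :class:`OtuTable`.

    Orientation is auto-detected: if the row index matches the metadata
    sample ids the table is samples x OTUs, if the columns match it is
    transposed.  A header sentinel of ``sample_id`` / ``otu_id`` in the
    top-left cell takes precedence.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        raw = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"malformed numeric cell in {path}: {exc}") from exc
    metadata = pd.read_csv(metadata_path, index_col="sample_id")
    sentinel = str(raw.index.name or "").strip().lower()
    sample_set = set(metadata.index.astype(str))
    if sentinel == "sample_id" or set(raw.index.astype(str)) <= sample_set:
        counts = raw
    elif sentinel == "otu_id" or set(raw.columns.astype(str)) <= sample_set:
        counts = raw.T
    else:
        missing = sorted(set(raw.index.astype(str)) - sample_set)[:5]
        raise ValidationError(
            f"samples missing from metadata (first few): {missing}"
        )
    taxref = None
    if taxref_path is not None:
        tr = pd.read_csv(taxref_path, index_col=0)
        taxref = tr.iloc[:, 0]
    return OtuTable(counts, metadata, taxref)


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree, validating tips and branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"duplicate tip label(s): {dup}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            label = node.name or f"internal node above {{{','.join(t.name for t in node.tips()) or node.name}}}"
            raise ValidationError(f"missing branch length on edge to {label}")
        if node.length < 0:
            raise ValidationError(f"negative branch length on edge to {node.name}")
    return tree


def merge_samples(table: OtuTable, keys: Sequence[str]) -> OtuTable:
    """Sum counts over the metadata fields in ``keys``.

    Samples sharing every *retained* (non-key) field are collapsed into one
    sample whose id is the ``"|"``-joined retained field values, in the fixed
    metadata-field order.  Total read count is conserved.
    """
    keys = list(keys)
    if not keys:
        raise ValidationError("merge_samples requires at least one key")
    bad = set(keys) - set(METADATA_FIELDS)
    if bad:
        raise ValidationError(f"unknown merge key(s): {sorted(bad)}")
    retained = [f for f in METADATA_FIELDS if f in table.metadata.columns and f not in keys]
    if retained:
        group_vals = table.metadata[retained].astype(str)
        new_ids = group_vals.apply("|".join, axis=1)
    else:
        new_ids = pd.Series("all", index=table.metadata.index)
    counts = table.counts.groupby(new_ids, sort=True).sum()
    meta = table.metadata[retained].astype(str).groupby(new_ids, sort=True).first()
    meta.index.name = "sample_id"
    return OtuTable(counts, meta, table.taxref)


# -- traits and environment ------------------------------------------------

def read_trait_table(path) -> pd.DataFrame:
    """Read a trait CSV (rows = taxonomic references, empty cell = missing)."""
    traits = pd.read_csv(path, index_col=0)
    if traits.index.has_duplicates:
        raise ValidationError("duplicate rows in trait table")
    if PHOTOTROPH_COLUMN in traits.columns:
        traits[PHOTOTROPH_COLUMN] = traits[PHOTOTROPH_COLUMN].astype(bool)
    both = traits[["SizeMin", "SizeMax"]].dropna() if {"SizeMin", "SizeMax"} <= set(traits.columns) else pd.DataFrame()
    if len(both) and (both["SizeMin"] > both["SizeMax"] + 1e-12).any():
        raise ValidationError("SizeMin > SizeMax in trait table")
    return traits


def read_env_table(path) -> pd.DataFrame:
    env = pd.read_csv(path, index_col="sample_id")
    num = env.select_dtypes("number")
    conc = [c for c in num.columns if c.lower() not in ("temperature",)]
    if (num[conc] < 0).any().any():
        raise ValidationError("negative concentration in environment table")
    return env


# -- distance matrices -----------------------------------------------------

def write_distance_matrix(dm, path) -> None:
    if isinstance(dm, DistanceMatrix):
        df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    else:
        df = dm
    df.to_csv(path, sep="\t", index_label="id")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index.astype(str)))


def write_results(obj, path) -> None:
    """Write any result object to its canonical text format.

    TSV for tables/matrices, JSON for mappings, edge-list TSV for networks.
    Output is bit-stable given fixed inputs.
    """
    path = Path(path)
    if isinstance(obj, DistanceMatrix):
        write_distance_matrix(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep="\t")
    elif isinstance(obj, Mapping):
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, TreeNode):
        obj.write(str(path), format="newick")
    elif isinstance(obj, (list, tuple)) and obj and hasattr(obj[0], "process"):
        from .assembly import results_to_frame

        results_to_frame(list(obj)).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"no writer for {type(obj).__name__}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, tuple)):
        return sorted(o) if isinstance(o, set) else list(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def write_otu_table(table: OtuTable, counts_path, metadata_path, taxref_path=None) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(metadata_path, index_label="sample_id")
    if taxref_path is not None:
        table.taxref.rename("taxref").to_csv(taxref_path, index_label="otu_id")
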