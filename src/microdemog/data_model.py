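"""Core data types for microbiota survey analysis and their on-disk formats.

The pipeline's central objects are a sample x OTU count table, a rooted
phylogeny over the OTUs, a taxonomy map, per-sample covariate metadata, and
pairwise sample distance matrices.  File formats are deliberately plain:
classic (TSV) OTU tables, Newick trees, and headered TSV for metadata,
taxonomy and distance matrices.  All readers validate on load; writers emit
a fixed dialect so that write -> read round-trips are exact.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("microdemog")

__all__ = [
    "FormatError",
    "ValidationError",
    "CountTable",
    "PhyloTree",
    "TaxonomyMap",
    "SampleMetadata",
    "DistanceMatrix",
    "FieldSpec",
    "DEFAULT_METADATA_SCHEMA",
    "read_count_table",
    "read_newick",
    "read_metadata",
    "read_taxonomy",
    "align",
    "AlignedData",
]


class FormatError(ValueError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(ValueError):
    """Parsed data violated a structural invariant."""


# ---------------------------------------------------------------------------
# CountTable


class CountTable:
    """Sample x OTU matrix of non-negative integer read counts.

    Internally always samples-as-rows.  ``data`` is a pandas DataFrame with
    unique sample ids as index and unique OTU ids as columns.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValidationError("count table has no samples or no OTUs")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        arr = data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count table contains non-numeric cells")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {data.index[i]!r}, OTU {data.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count at sample {data.index[i]!r}, OTU {data.columns[j]!r}"
            )
        zero_rows = arr.sum(axis=1) == 0
        if zero_rows.any():
            raise ValidationError(
                f"all-zero sample rows: {data.index[zero_rows].tolist()}"
            )
        self.data = data.astype(np.int64)

    # -- accessors ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def proportions(self) -> pd.DataFrame:
        d = self.depths().astype(float)
        return self.data.div(d, axis=0)

    def select_samples(self, ids) -> "CountTable":
        return CountTable(self.data.loc[list(ids)])

    def __eq__(self, other):
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self):
        return f"CountTable({self.n_samples} samples x {self.n_otus} OTUs)"

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path, orientation: str = "otus") -> None:
        """Write a classic TSV OTU table (default: OTUs as rows, '#OTU ID' header)."""
        if orientation == "otus":
            out = self.data.T
            out.index.name = "#OTU ID"
        elif orientation == "samples":
            out = self.data.copy()
            out.index.name = "#SampleID"
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        out.to_csv(path, sep="\t")


def read_count_table(path, orientation: str = "otus") -> CountTable:
    """Read a classic TSV OTU table.

    ``orientation`` names what the *rows* of the file are: ``"otus"``
    (classic BIOM-style table, the default) or ``"samples"``.  The returned
    table is always samples-as-rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None, header=0)
    except pd.errors.EmptyDataError:
        raise FormatError("no samples: count table file is empty") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError("no samples: count table has no data rows/columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    if orientation == "otus":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountTable(df)


# ---------------------------------------------------------------------------
# PhyloTree


class PhyloTree:
    """Rooted phylogenetic tree whose tips are OTU identifiers.

    Thin wrapper around a :class:`dendropy.Tree` adding validation (unique
    tips, non-negative branch lengths) and the edge arrays used by UniFrac.
    """

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
            elif edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        if n_missing:
            logger.warning("%d branch lengths absent; defaulted to 0", n_missing)
        self._tree = tree
        self._edge_cache: dict[tuple, tuple] = {}

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise FormatError(f"Newick parse error: {exc}") from exc
        return cls(tree)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def n_edges(self) -> int:
        """Number of edges below the root (the root's own edge is ignored)."""
        return sum(1 for e in self._tree.preorder_edge_iter()
                   if e.head_node is not self._tree.seed_node)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", unquoted_underscores=True,
            suppress_rooting=True,
        ).strip()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def prune_to(self, labels) -> "PhyloTree":
        """Return a copy restricted to the given tip labels."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)[:5]} ...")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        return PhyloTree(tree)

    def edge_arrays(self, otu_order) -> tuple[np.ndarray, np.ndarray]:
        """Branch lengths and tip membership for every edge below the root.

        Returns ``(lengths, membership)`` where ``lengths`` has shape (E,)
        and ``membership`` is a boolean (E, n_otus) matrix: membership[e, i]
        is True iff OTU ``otu_order[i]`` is a descendant tip of edge ``e``.
        Every OTU in ``otu_order`` must be a tip of the tree.
        """
        key = tuple(otu_order)
        if key in self._edge_cache:
            return self._edge_cache[key]
        idx = {label: i for i, label in enumerate(key)}
        missing = set(self.tip_labels) - set(key)
        extra = set(key) - set(self.tip_labels)
        if extra:
            raise ValidationError(f"OTUs absent from tree: {sorted(extra)[:5]} ...")
        if missing:
            raise ValidationError(
                "tree has tips not in the requested OTU order; prune first"
            )
        lengths, rows = [], []
        node_sets: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            mask = np.zeros(len(key), dtype=bool)
            if node.is_leaf():
                mask[idx[node.taxon.label]] = True
            else:
                for child in node.child_nodes():
                    mask |= node_sets.pop(id(child))
            node_sets[id(node)] = mask
            if node is not self._tree.seed_node:
                lengths.append(node.edge.length or 0.0)
                rows.append(mask)
        result = (np.asarray(lengths, dtype=float), np.asarray(rows))
        self._edge_cache[key] = result
        return result


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# SampleMetadata


@dataclass(frozen=True)
class FieldSpec:
    """Schema entry for one metadata column."""

    kind: str  # "continuous" | "categorical" | "label"
    levels: dict[str, str] = field(default_factory=dict)  # synonym -> canonical


#: Default cohort schema: age (years), sex, race, BMI (kg/m^2), alcohol and
#: tobacco use, and the sequencing batch label.
DEFAULT_METADATA_SCHEMA: dict[str, FieldSpec] = {
    "age": FieldSpec("continuous"),
    "sex": FieldSpec("categorical", {"f": "F", "female": "F", "m": "M", "male": "M"}),
    "race": FieldSpec(
        "categorical",
        {"w": "white", "white": "white", "nw": "non-white",
         "non-white": "non-white", "nonwhite": "non-white"},
    ),
    "bmi": FieldSpec("continuous"),
    "alcohol": FieldSpec("categorical", {"y": "Y", "yes": "Y", "n": "N", "no": "N"}),
    "tobacco": FieldSpec("categorical", {"y": "Y", "yes": "Y", "n": "N", "no": "N"}),
    "batch": FieldSpec("label"),
}

_MISSING = {"", "na", "nan", "none", "null", "."}


class SampleMetadata:
    """Typed per-sample covariates indexed by sample id.

    Missing values are held as NaN/None; analyses drop incomplete samples
    per covariate (complete-case analysis).
    """

    def __init__(self, data: pd.DataFrame, schema: dict[str, FieldSpec] | None = None):
        schema = schema or DEFAULT_METADATA_SCHEMA
        if data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        for name, spec in schema.items():
            if name not in data.columns:
                raise ValidationError(f"missing required metadata column {name!r}")
            if spec.kind == "continuous":
                vals = data[name].to_numpy(dtype=float)
                if np.isinf(vals).any():
                    raise ValidationError(f"non-finite value in column {name!r}")
        if "batch" in data.columns and data["batch"].nunique() < 1:
            raise ValidationError("batch must have at least one level")
        self.data = data
        self.schema = schema

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __getitem__(self, column: str) -> pd.Series:
        return self.data[column]

    def select_samples(self, ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(ids)], self.schema)

    def __eq__(self, other):
        return isinstance(other, SampleMetadata) and self.data.equals(other.data)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def _canonical(value, column: str, spec: FieldSpec):
    if spec.kind == "continuous":
        s = str(value).strip()
        if s.lower() in _MISSING:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise FormatError(f"unparseable numeric {value!r} in column {column!r}") from None
    s = str(value).strip()
    if s.lower() in _MISSING:
        return None
    if spec.kind == "label":
        return s
    canon = spec.levels.get(s.lower())
    if canon is None:
        if s in spec.levels.values():
            return s
        raise FormatError(f"unknown level {value!r} for column {column!r}")
    return canon


def read_metadata(path, schema: dict[str, FieldSpec] | None = None) -> SampleMetadata:
    """Read a TSV of per-sample covariates (first column = sample id)."""
    schema = schema or DEFAULT_METADATA_SCHEMA
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    cols = {}
    for name, spec in schema.items():
        if name not in raw.columns:
            raise ValidationError(f"missing required metadata column {name!r}")
        cols[name] = [_canonical(v, name, spec) for v in raw[name]]
    df = pd.DataFrame(cols, index=raw.index)
    return SampleMetadata(df, schema)


# ---------------------------------------------------------------------------
# TaxonomyMap


class TaxonomyMap:
    """OTU id -> (phylum, family, genus); missing ranks are 'unclassified'."""

    UNCLASSIFIED = "unclassified"
    RANKS = ("phylum", "family", "genus")

    def __init__(self, mapping: dict[str, tuple[str, str, str]]):
        if not mapping:
            raise ValidationError("empty taxonomy")
        self.mapping = {
            str(k): tuple(v if v else self.UNCLASSIFIED for v in vals)
            for k, vals in mapping.items()
        }

    def lineage(self, otu_id: str) -> tuple[str, str, str]:
        return self.mapping.get(
            otu_id, (self.UNCLASSIFIED, self.UNCLASSIFIED, self.UNCLASSIFIED)
        )

    def __len__(self):
        return len(self.mapping)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame.from_dict(self.mapping, orient="index", columns=self.RANKS)
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.columns = [c.lower() for c in df.columns]
    for rank in TaxonomyMap.RANKS:
        if rank not in df.columns:
            raise FormatError(f"taxonomy file missing column {rank!r}")
    return TaxonomyMap(
        {str(i): (r["phylum"], r["family"], r["genus"]) for i, r in df.iterrows()}
    )


# ---------------------------------------------------------------------------
# DistanceMatrix


class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    def __init__(self, sample_ids, values: np.ndarray):
        ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample ids in distance matrix")
        if values.shape != (len(ids), len(ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite distances")
        if np.any(values < -1e-12):
            raise ValidationError("negative distances")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal not zero")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self.sample_ids = ids
        self.values = values

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        ii = [pos[str(s)] for s in ids]
        return DistanceMatrix([self.sample_ids[i] for i in ii],
                              self.values[np.ix_(ii, ii)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise FormatError("distance matrix row/column ids differ")
        return cls(list(df.index), df.to_numpy())


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class AlignedData:
    table: CountTable
    metadata: SampleMetadata
    tree: PhyloTree | None
    dropped_samples: list[str]
    otus_missing_from_tree: list[str]


def align(table: CountTable, meta: SampleMetadata,
          tree: PhyloTree | None = None) -> AlignedData:
    """Restrict table and metadata to their common samples (table order).

    Tips present in the tree but absent from the table are pruned away
    (unrepresented lineages carry no branch mass); table OTUs missing from
    the tree are reported and left in place — β-diversity raises on them
    unless explicitly told to prune.
    """
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not common:
        raise ValidationError("no samples shared between count table and metadata")
    dropped = sorted(
        (set(table.sample_ids) | set(meta.sample_ids)) - set(common)
    )
    if dropped:
        logger.info("align: dropped %d unmatched samples: %s", len(dropped), dropped[:5])
    table2 = table.select_samples(common) if common != table.sample_ids else table
    meta2 = meta.select_samples(common) if common != meta.sample_ids else meta
    missing_otus: list[str] = []
    tree2 = tree
    if tree is not None:
        tips = set(tree.tip_labels)
        missing_otus = [o for o in table2.otu_ids if o not in tips]
        shared_tips = [o for o in table2.otu_ids if o in tips]
        if not shared_tips:
            raise ValidationError("no OTUs shared between count table and tree")
        if set(tree.tip_labels) != set(shared_tips):
            tree2 = tree.prune_to(shared_tips)
        if missing_otus:
            logger.warning("align: %d table OTUs absent from tree", len(missing_otus))
    return AlignedData(table2, meta2, tree2, dropped, missing_otus)
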