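"""Reading, validation and cross-referencing of OTU tables, trees and metadata.

File contracts
--------------
* OTU table: tab-separated, first column taxon ids, header row sample ids
  (``orientation="taxa_as_rows"``, the common OTU-table dialect) or the
  transpose (``orientation="samples_as_rows"``).
* Tree: rooted Newick with branch lengths; parsed into a scikit-bio
  :class:`~skbio.TreeNode`.
* Metadata: tab-separated with mandatory columns ``sample_id``,
  ``elevation``, ``layer``, ``latitude``, ``longitude``; every remaining
  numeric column is treated as an environmental variable.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

LAYERS = ("surface", "middle", "deep")

METADATA_REQUIRED = ("sample_id", "elevation", "layer", "latitude", "longitude")


class ValidationError(ValueError):
    """An input violated a structural invariant (duplicates, negatives, ...)."""


class CountTable:
    """Non-negative integer taxa x samples count matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are taxa, columns are samples, cells are read counts.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        vals = data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("non-numeric cell in count table")
        if np.isnan(vals.astype(float)).any():
            raise ValidationError("missing value in count table")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at taxon {data.index[i]!r}, sample {data.columns[j]!r}"
            )
        if not np.allclose(vals, np.round(vals.astype(float))):
            i, j = np.argwhere(~np.isclose(vals.astype(float), np.round(vals.astype(float))))[0]
            raise ValidationError(
                f"non-integer count at taxon {data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self.data = data.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def matrix(self) -> np.ndarray:
        """Counts as a samples x taxa integer array (one row per sample)."""
        return self.data.to_numpy().T

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.data.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise ValidationError(f"zero-total sample(s): {list(zero.index)}")
        return self.data / totals

    def presence(self) -> np.ndarray:
        """Boolean samples x taxa presence matrix."""
        return self.matrix() > 0

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.data.sum(axis=1) > 0
        return CountTable(self.data.loc[keep])

    def sort(self) -> "CountTable":
        return CountTable(self.data.sort_index(axis=0).sort_index(axis=1))

    def write(self, path, orientation: str = "taxa_as_rows") -> None:
        df = self.data if orientation == "taxa_as_rows" else self.data.T
        label = "taxon_id" if orientation == "taxa_as_rows" else "sample_id"
        df.to_csv(path, sep="\t", index_label=label)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.n_taxa} taxa x {self.n_samples} samples)"


def read_count_table(path, orientation: str = "taxa_as_rows") -> CountTable:
    """Read a tab-separated OTU count table.

    ``orientation="taxa_as_rows"`` (default) expects taxa down the first
    column and samples across the header; ``"samples_as_rows"`` reads the
    transpose.
    """
    if orientation not in ("taxa_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        kind = "sample" if orientation == "taxa_as_rows" else "taxon"
        raise ValidationError(f"duplicate {kind} ids in header: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric cell in column {col!r}, row(s) {list(bad.index)[:3]}"
            )
    if orientation == "samples_as_rows":
        df = df.T
    return CountTable(df)


def read_tree(path, default_branch_length: float = 0.0) -> TreeNode:
    """Read a rooted Newick tree and validate it for phylogenetic metrics.

    Missing branch lengths are replaced by ``default_branch_length`` with a
    warning; negative lengths and duplicate tip labels are rejected.
    """
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree, default_branch_length=default_branch_length)


def validate_tree(tree: TreeNode, default_branch_length: float = 0.0) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if any(name is None for name in tips):
        raise ValidationError("tree has unlabeled tips")
    if len(set(tips)) != len(tips):
        seen, dupes = set(), []
        for name in tips:
            if name in seen:
                dupes.append(name)
            seen.add(name)
        raise ValidationError(f"duplicate tip labels: {sorted(set(dupes))}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = default_branch_length
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if n_missing:
        warnings.warn(
            f"{n_missing} branch length(s) missing; set to {default_branch_length}",
            stacklevel=2,
        )
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata; returns a frame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_layer = set(df["layer"]) - set(LAYERS)
    if bad_layer:
        raise ValidationError(
            f"unknown layer value(s) {sorted(bad_layer)}; expected one of {LAYERS}"
        )
    return df.set_index("sample_id")


def env_columns(meta: pd.DataFrame) -> list[str]:
    """Numeric metadata columns other than the design columns."""
    skip = {"elevation", "latitude", "longitude", "layer"}
    return [
        c
        for c in meta.columns
        if c not in skip and np.issubdtype(meta[c].dtype, np.number)
    ]


def align_inputs(
    table: CountTable,
    tree: TreeNode | None = None,
    meta: pd.DataFrame | None = None,
):
    """Restrict table/tree/metadata to their shared taxa and samples.

    Taxa are restricted to the intersection of the table and the tree tip
    set (ITS OTU tables routinely exceed the tree, so extra table taxa are
    dropped with a logged count, and extra tree tips are sheared off).
    Samples are restricted to the intersection with the metadata index.
    All orderings are lexicographic so outputs are byte-stable; the
    operation is idempotent.

    Returns ``(table, tree, meta)``; tree/meta are None if not supplied.
    """
    taxa = set(table.taxon_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        shared = sorted(taxa & tips)
        if not shared:
            raise ValidationError("table taxa and tree tips are disjoint")
        dropped = len(taxa) - len(shared)
        if dropped:
            logger.info("align_inputs: dropped %d table taxa absent from tree", dropped)
        if len(shared) < len(tips):
            tree = tree.shear(shared)
            tree.prune()
            tree = validate_tree(tree)
        taxa = set(shared)

    samples = set(table.sample_ids)
    if meta is not None:
        shared_s = sorted(samples & set(meta.index.astype(str)))
        if not shared_s:
            raise ValidationError("table samples and metadata samples are disjoint")
        dropped_s = len(samples) - len(shared_s)
        if dropped_s:
            logger.info(
                "align_inputs: dropped %d table samples absent from metadata", dropped_s
            )
        meta = meta.loc[shared_s]
        samples = set(shared_s)

    data = table.data.loc[sorted(taxa), sorted(samples)]
    return CountTable(data), tree, meta
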