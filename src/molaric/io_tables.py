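"""Reading and validation of measurement tables, coordinates, and Newick trees.

The package consumes three kinds of external input: a CSV of crown
diameters (one row per group x jaw x tooth, mesiodistal and buccolingual
diameters in mm), an optional CSV of geographic coordinates for
population-level analyses, and a rooted Newick tree with branch lengths
for phylogenetic analyses.  All readers validate against the domain
invariants and raise :class:`FormatError` / :class:`ValidationError`
with row-level context.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

JAWS = ("lower", "upper")
TEETH = ("M1", "M2", "M3")
GROUP_TYPES = ("species", "population")


class FormatError(ValueError):
    """Structural problem with an input file (missing column, bad Newick)."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. non-positive diameter)."""


@dataclass(frozen=True)
class ToothMeasurement:
    """Crown diameters of one tooth for one group (species or population).

    Attributes
    ----------
    group_id : str
        Species or population identifier; must match tree tip labels for
        phylogenetic analyses (after optional aliasing).
    group_type : str
        ``"species"`` or ``"population"``.
    jaw : str
        ``"lower"`` (mandible) or ``"upper"`` (maxilla).
    tooth : str
        ``"M1"``, ``"M2"`` or ``"M3"``.
    md, bl : float
        Mesiodistal and buccolingual crown diameters in mm; both > 0.
    n : int or None
        Number of specimens behind the (mean) diameters, when known.
    """

    group_id: str
    jaw: str
    tooth: str
    md: float
    bl: float
    group_type: str = "species"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.jaw not in JAWS:
            raise ValidationError(f"jaw must be one of {JAWS}, got {self.jaw!r}")
        if self.tooth not in TEETH:
            raise ValidationError(f"tooth must be one of {TEETH}, got {self.tooth!r}")
        if self.group_type not in GROUP_TYPES:
            raise ValidationError(
                f"group_type must be one of {GROUP_TYPES}, got {self.group_type!r}"
            )
        if not (self.md > 0 and self.bl > 0):
            raise ValidationError(
                f"diameters must be positive: md={self.md}, bl={self.bl}"
            )
        if self.n is not None and self.n < 1:
            raise ValidationError(f"specimen count must be >= 1, got {self.n}")


@dataclass(frozen=True)
class GeoLocation:
    """Geographic location of a population (decimal degrees)."""

    group_id: str
    lat: float
    lon: float
    continent: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude out of range: {self.lon}")


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` exposing the operations the
    comparative analyses need: tip labels, node depths, most-recent-common-
    ancestor depths, pruning, and Newick round-trip.  Branch lengths may be
    in any consistent unit; ultrametricity is not required.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is not None and not np.isfinite(edge.length):
                raise FormatError("non-finite branch length in tree")
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length: {edge.length}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls, source: str, missing_length: str = "error"
    ) -> "PhyloTree":
        """Parse a Newick string.

        Parameters
        ----------
        missing_length : {"error", "one"}
            What to do when an edge (other than the root edge) has no
            branch length: raise, or assign 1.0.
        """
        try:
            tree = dendropy.Tree.get(
                data=source,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"Newick parse error: {exc}") from exc
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            if node.edge.length is None:
                if missing_length == "one":
                    node.edge.length = 1.0
                else:
                    raise FormatError(
                        "edge without branch length (set missing_length='one' "
                        "to assign 1.0)"
                    )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    # -- basic structure ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _nodes(self) -> list:
        return list(self._tree.preorder_node_iter())

    def node_ids(self) -> list[str]:
        """Stable identifiers: tip label for leaves, ``nodeK`` (preorder
        index) for unlabeled internal nodes."""
        out = []
        for i, node in enumerate(self._nodes()):
            if node.is_leaf():
                out.append(node.taxon.label)
            elif node.taxon is not None and node.taxon.label:
                out.append(node.taxon.label)
            elif node.label:
                out.append(node.label)
            else:
                out.append(f"node{i}")
        return out

    def depths(self) -> dict[int, float]:
        """Root-to-node path length for every node, keyed by ``id(node)``."""
        depth: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depth[id(node)] = 0.0
            else:
                depth[id(node)] = depth[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
        return depth

    def mrca_depth_matrix(
        self, labels: Sequence[str] | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Shared root-to-MRCA path length for every pair of tips.

        This is the Brownian-motion trait covariance structure up to a
        rate constant: diagonal entries are root-to-tip distances.
        """
        if labels is None:
            labels = self.tip_labels
        depth = self.depths()
        leaves = {
            leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()
        }
        missing = [l for l in labels if l not in leaves]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        # ancestor chains (node itself first), depths along them
        chains: dict[str, list[int]] = {}
        for lab in labels:
            chain = []
            node = leaves[lab]
            while node is not None:
                chain.append(id(node))
                node = node.parent_node
            chains[lab] = chain
        n = len(labels)
        C = np.zeros((n, n))
        for i, li in enumerate(labels):
            anc_i = set(chains[li])
            C[i, i] = depth[chains[li][0]]
            for j in range(i + 1, n):
                shared = next(a for a in chains[labels[j]] if a in anc_i)
                C[i, j] = C[j, i] = depth[shared]
        return list(labels), C

    def tip_distance_matrix(
        self, labels: Sequence[str] | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between tips."""
        labels, C = self.mrca_depth_matrix(labels)
        d = np.diag(C)
        return labels, d[:, None] + d[None, :] - 2 * C

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        keep = set(keep)
        present = keep & set(self.tip_labels)
        if not present:
            raise ValidationError(
                f"no overlap between tree tips {sorted(self.tip_labels)} "
                f"and requested labels {sorted(keep)}"
            )
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(present))
        return PhyloTree(clone)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


# ---------------------------------------------------------------------------
# CSV readers / writers


REQUIRED_MEASUREMENT_COLUMNS = ("group_id", "jaw", "tooth", "md", "bl")


def read_measurements(
    path_or_buffer, sep: str = ",", alias: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a crown-diameter table.

    Required columns: ``group_id, jaw, tooth, md, bl``; optional:
    ``group_type, n, side, lat, lon, continent``.  Group and label strings
    are whitespace-trimmed; an optional ``alias`` map renames group_ids
    (e.g. to match tree tip labels).  Duplicate (group_id, jaw, tooth)
    rows are accepted — they are averaged downstream by
    :func:`molaric.molar_metrics.aggregate_group` — and logged here.

    Returns a validated DataFrame (one row per measurement record).
    """
    df = pd.read_csv(path_or_buffer, sep=sep)
    missing = [c for c in REQUIRED_MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement table missing column(s): {missing}")
    df = df.copy()
    for col in ("group_id", "jaw", "tooth"):
        df[col] = df[col].astype(str).str.strip()
    if alias:
        df["group_id"] = df["group_id"].map(lambda g: alias.get(g, g))
    if "group_type" not in df.columns:
        df["group_type"] = "species"
    if "n" not in df.columns:
        df["n"] = pd.NA

    for idx, row in df.iterrows():
        try:
            ToothMeasurement(
                group_id=row["group_id"],
                jaw=row["jaw"],
                tooth=row["tooth"],
                md=float(row["md"]),
                bl=float(row["bl"]),
                group_type=str(row["group_type"]).strip(),
                n=None if pd.isna(row["n"]) else int(row["n"]),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc

    dup = df.duplicated(subset=["group_id", "jaw", "tooth"], keep=False)
    if dup.any():
        logger.info(
            "%d rows share a (group_id, jaw, tooth) key; they will be "
            "averaged during aggregation",
            int(dup.sum()),
        )
    logger.info("read %d measurement rows (%d groups)", len(df), df["group_id"].nunique())
    return df


def read_alias_map(path_or_buffer, sep: str = ",") -> dict[str, str]:
    """Read a two-column (from,to) alias CSV mapping table names to tree tips."""
    df = pd.read_csv(path_or_buffer, sep=sep)
    if df.shape[1] < 2:
        raise FormatError("alias map needs two columns: from,to")
    a, b = df.columns[:2]
    return {
        str(k).strip(): str(v).strip() for k, v in zip(df[a], df[b])
    }


def read_coordinates(path_or_buffer, sep: str = ",") -> pd.DataFrame:
    """Read population coordinates (group_id, lat, lon[, continent])."""
    df = pd.read_csv(path_or_buffer, sep=sep)
    missing = [c for c in ("group_id", "lat", "lon") if c not in df.columns]
    if missing:
        raise FormatError(f"coordinates table missing column(s): {missing}")
    df = df.copy()
    df["group_id"] = df["group_id"].astype(str).str.strip()
    if df["group_id"].duplicated().any():
        raise ValidationError("duplicate group_id in coordinates table")
    for idx, row in df.iterrows():
        GeoLocation(
            group_id=row["group_id"],
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            continent=row.get("continent"),
        )
    return df


def read_newick(path_or_buffer, missing_length: str = "error") -> PhyloTree:
    """Read a rooted Newick tree with branch lengths from a file or path."""
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    return PhyloTree.from_newick(text, missing_length=missing_length)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def prune_to_common(tree: PhyloTree, groups: Iterable[str]) -> PhyloTree:
    """Prune a tree to the tips shared with ``groups``.

    Patristic distances between retained tips are unchanged (collapsed
    unifurcations accumulate their branch lengths).
    """
    groups = {str(g).strip() for g in groups}
    pruned = tree.prune_to(groups)
    dropped = set(tree.tip_labels) - set(pruned.tip_labels)
    if dropped:
        logger.info("pruned %d tips without data: %s", len(dropped), sorted(dropped))
    return pruned


def write_tidy_results(
    df: pd.DataFrame, path, header_comment: str | None = None
) -> None:
    """Write a results table as CSV, optionally with a ``#`` comment header
    carrying the run seed / config hash."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
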