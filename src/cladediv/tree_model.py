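"""Dated phylogenies and clade extraction.

A :class:`DatedTree` wraps a rooted dendropy tree whose branch lengths are in
millions of years (My) and whose tips are named after terminally unresolved
clades (plant families, in the motivating application).  Ages run backward
from the present: extant tips sit at age 0 and the root at the tree height.

Conventions
-----------
* The *crown age* of a node is the longest path from the node to any of its
  descendant tips; tips have crown age 0.
* The *stem age* of a node is the crown age of its parent (the top of its
  subtending branch).  The root has no subtending branch; its stem age is
  defined equal to its crown age so the root clade can still carry a rate
  estimate.
* Clade identifiers are derived from the topology, not the input order:
  a tip's identifier is its label, an internal clade's identifier is
  ``"<alphabetically first tip>+<tip count>"``.  On a tree this is unique
  (disjoint clades have different first tips, nested clades different sizes)
  and stable under any permutation of the input.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "CladeRecord",
    "DatedTree",
    "NewickParseError",
    "TreeValidationError",
    "UltrametricityWarning",
    "enumerate_clades",
    "read_newick",
    "read_newick_file",
    "records_to_dataframe",
    "stem_crown_ages",
    "write_clade_csv",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a :class:`DatedTree` invariant."""


class UltrametricityWarning(UserWarning):
    """Emitted for small (tolerated) deviations from ultrametricity."""


@dataclass(frozen=True)
class CladeRecord:
    """One clade of the phylogeny: tips, ages and attached species richness."""

    clade_id: str
    tip_families: frozenset
    stem_age: float
    crown_age: float
    richness: float
    ln_richness: float

    @property
    def n_tips(self) -> int:
        return len(self.tip_families)


class DatedTree:
    """A rooted, dated tree with validated branch lengths and unique tips.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  The instance takes ownership (it is not copied).
    require_ultrametric:
        If True (default) root-to-tip path lengths must agree.  Relative
        deviations up to ``ultrametric_rtol`` pass silently, deviations up to
        ``hard_rtol`` warn (dating pipelines emit numerical jitter), anything
        larger raises :class:`TreeValidationError`.  Set False for complete
        (extinct-tip-bearing) simulation output.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        require_ultrametric: bool = True,
        ultrametric_rtol: float = 1e-6,
        hard_rtol: float = 1e-3,
    ):
        self._tree = tree
        self.require_ultrametric = require_ultrametric
        self._validate(ultrametric_rtol, hard_rtol)
        self._compute_ages()
        self._assign_ids()

    # -- validation -----------------------------------------------------

    def _validate(self, rtol: float, hard_rtol: float) -> None:
        t = self._tree
        leaves = list(t.leaf_node_iter())
        if not leaves:
            raise TreeValidationError("tree has no tips")
        labels = [self._label_of(lf) for lf in leaves]
        if any(lb is None or lb == "" for lb in labels):
            raise TreeValidationError("every tip must carry a label")
        seen: set = set()
        dupes = sorted({lb for lb in labels if lb in seen or seen.add(lb)})
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                continue
            bl = node.edge.length
            if bl is None:
                raise TreeValidationError(
                    f"missing branch length above node {self._label_of(node) or '<internal>'}"
                )
            if bl < 0:
                raise TreeValidationError(
                    f"negative branch length ({bl}) above node "
                    f"{self._label_of(node) or '<internal>'}"
                )
        # root-to-tip path lengths
        depths: dict = {t.seed_node: 0.0}
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                depths[node] = depths[node.parent_node] + node.edge.length
        tip_depths = [depths[lf] for lf in leaves]
        height = max(tip_depths)
        if height <= 0:
            raise TreeValidationError("tree height must be positive")
        if self.require_ultrametric:
            dev = (height - min(tip_depths)) / height
            if dev > hard_rtol:
                raise TreeValidationError(
                    f"tree is not ultrametric: relative root-to-tip spread {dev:.3g} "
                    f"exceeds tolerance {hard_rtol:g}"
                )
            if dev > rtol:
                warnings.warn(
                    f"root-to-tip path lengths differ by a relative {dev:.3g} "
                    "(tolerated as dating jitter)",
                    UltrametricityWarning,
                    stacklevel=3,
                )

    @staticmethod
    def _label_of(node: dendropy.Node):
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label

    # -- ages and identifiers -------------------------------------------

    def _compute_ages(self) -> None:
        self._crown: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._crown[node] = 0.0
            else:
                self._crown[node] = max(
                    self._crown[ch] + ch.edge.length for ch in node.child_nodes()
                )
        root = self._tree.seed_node
        self._stem: dict = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                self._stem[node] = self._crown[root]  # root convention
            else:
                self._stem[node] = self._crown[node.parent_node]

    def _assign_ids(self) -> None:
        self._tipset: dict = {}
        self._id: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._tipset[node] = frozenset([self._label_of(node)])
                self._id[node] = self._label_of(node)
            else:
                tips = frozenset().union(*(self._tipset[ch] for ch in node.child_nodes()))
                self._tipset[node] = tips
                self._id[node] = f"{min(tips)}+{len(tips)}"

    # -- public surface --------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list:
        return sorted(self._tipset[self._tree.seed_node])

    @property
    def n_tips(self) -> int:
        return len(self._tipset[self._tree.seed_node])

    @property
    def height(self) -> float:
        return self._crown[self._tree.seed_node]

    def nodes(self) -> Iterable[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def clade_id(self, node: dendropy.Node) -> str:
        return self._id[node]

    def crown_age(self, node: dendropy.Node) -> float:
        return self._crown[node]

    def stem_age(self, node: dendropy.Node) -> float:
        return self._stem[node]

    def tip_set(self, node: dendropy.Node) -> frozenset:
        return self._tipset[node]

    def is_bifurcating(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def as_newick(self, precision: int = 12) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=f".{precision}g",
        ).strip()


def read_newick(text: str, **kwargs) -> DatedTree:
    """Parse a Newick string into a validated :class:`DatedTree`.

    Raises :class:`NewickParseError` for malformed input (including a missing
    terminating semicolon) and :class:`TreeValidationError` for structurally
    valid input that violates the dated-tree invariants.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick string must end with ';' (got ...{stripped[-20:]!r})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Multiple occurrences" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return DatedTree(tree, **kwargs)


def read_newick_file(path, **kwargs) -> DatedTree:
    with open(path, "r", encoding="utf-8") as fh:
        return read_newick(fh.read(), **kwargs)


def stem_crown_ages(tree: DatedTree) -> dict:
    """Map every clade id to its ``(stem_age, crown_age)`` pair."""
    return {
        tree.clade_id(node): (tree.stem_age(node), tree.crown_age(node))
        for node in tree.nodes()
    }


def enumerate_clades(tree: DatedTree, richness: Mapping[str, float]) -> list:
    """One :class:`CladeRecord` per node (tips and internal nodes alike).

    ``richness`` maps every tip label to its species richness S ≥ 1; internal
    clade richness is the sum over member families.  A fully bifurcating tree
    with n tips yields exactly 2n−1 records.
    """
    missing = sorted(set(tree.tip_labels) - set(richness))
    if missing:
        raise KeyError(f"no richness entry for families: {missing}")
    records = []
    sums: dict = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            sums[node] = float(richness[DatedTree._label_of(node)])
        else:
            sums[node] = sum(sums[ch] for ch in node.child_nodes())
    for node in tree.nodes():
        s = sums[node]
        if s < 1:
            raise ValueError(
                f"clade {tree.clade_id(node)} has richness {s} < 1; every "
                "sampled family must contain at least one species"
            )
        records.append(
            CladeRecord(
                clade_id=tree.clade_id(node),
                tip_families=tree.tip_set(node),
                stem_age=tree.stem_age(node),
                crown_age=tree.crown_age(node),
                richness=s,
                ln_richness=math.log(s),
            )
        )
    return records


def records_to_dataframe(records: Iterable[CladeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clade_id": [r.clade_id for r in records],
            "tip_count": [r.n_tips for r in records],
            "richness": [r.richness for r in records],
            "ln_richness": [r.ln_richness for r in records],
            "stem_age": [r.stem_age for r in records],
            "crown_age": [r.crown_age for r in records],
        }
    )


def write_clade_csv(records: Iterable[CladeRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
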