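"""Time-calibrated trees (chronograms) and their branching-time reduction.

A chronogram is a rooted, binary, ultrametric tree whose branch lengths are
in units of absolute time (here millions of years, My), so every tip sits at
time 0 (the present) and every internal node has an *age*: its distance to
any descendant tip.  Every tempo statistic and diversification likelihood in
this package consumes not the tree itself but its vector of branching times
``x_2 >= x_3 >= ... >= x_n`` (node ages, ``x_2`` = crown age) together with
the derived internode gaps ``g_k`` and the total lineage-time
``T = sum_k k * g_k``.

Newick parsing is delegated to :mod:`dendropy`; writing uses a small
deterministic emitter (children ordered lexicographically by their smallest
descendant label) so that output is reproducible byte-for-byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "ChronogramError",
    "parse_newick",
    "write_newick",
    "branching_times",
    "prune_to_tips",
    "extract_clade",
]

#: Default ultrametricity tolerance, as a fraction of tree height.
DEFAULT_REL_TOL = 1e-6


class ChronogramError(ValueError):
    """Raised when a tree fails chronogram validation or a Newick string
    cannot be parsed."""


# ---------------------------------------------------------------------------
# BranchingTimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchingTimes:
    """Node ages of a chronogram, sorted oldest first.

    Parameters
    ----------
    x
        Ages ``(x_2, ..., x_n)`` of the ``n - 1`` internal nodes, in My
        before present, sorted descending; ``x_2`` is the crown age.
    """

    x: np.ndarray
    has_ties: bool = field(default=False, compare=False)

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 1:
            raise ChronogramError("need at least one branching time")
        if np.any(np.diff(x) > 0):
            raise ChronogramError("branching times must be sorted descending")
        if x[-1] <= 0:
            raise ChronogramError("branching times must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "has_ties", bool(np.any(np.diff(x) == 0)))

    @property
    def n(self) -> int:
        """Number of tips."""
        return self.x.size + 1

    @property
    def crown_age(self) -> float:
        return float(self.x[0])

    @property
    def g(self) -> np.ndarray:
        """Internode durations ``g_k`` (interval during which exactly *k*
        lineages exist), for k = 2..n; ``g_n`` ends at the present."""
        return np.diff(np.append(self.x, 0.0)) * -1.0

    @property
    def T(self) -> float:
        """Total lineage-time ``sum_k k * g_k`` = ``2 x_2 + sum_{i>=3} x_i``."""
        k = np.arange(2, self.n + 1, dtype=float)
        return float(np.sum(k * self.g))

    def scaled(self, c: float) -> "BranchingTimes":
        """All ages multiplied by ``c > 0`` (used for scale-invariance checks)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return BranchingTimes(self.x * c)

    def to_tsv(self) -> str:
        """Two-column TSV (index, age_My); index i of ``x_i`` starts at 2."""
        lines = ["index\tage_My"]
        lines += [f"{i + 2}\t{a!r}" for i, a in enumerate(self.x)]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Chronogram
# ---------------------------------------------------------------------------

class Chronogram:
    """A validated rooted, binary, ultrametric, time-calibrated tree.

    Wraps a :class:`dendropy.Tree`.  Validation enforces: >= 2 tips, unique
    non-empty tip labels, non-negative branch lengths, binary internal nodes
    (polytomies optionally resolved into zero-length splits), and
    ultrametricity within ``rel_tol`` × tree height (optionally coerced by
    extending terminal branches).  Any root edge length is ignored: all
    analyses are crown-conditioned.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        rel_tol: float = DEFAULT_REL_TOL,
        resolve_polytomies: bool = False,
        coerce_ultrametric: bool = False,
    ):
        self._tree = tree
        self.log: list[str] = []
        self._validate(rel_tol, resolve_polytomies, coerce_ultrametric)
        self._assign_ages()

    # -- validation --------------------------------------------------------

    def _validate(self, rel_tol, resolve_polytomies, coerce_ultrametric):
        t = self._tree
        leaves = t.leaf_nodes()
        if len(leaves) < 2:
            raise ChronogramError("chronogram needs at least 2 tips")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lab is None or lab == "" for lab in labels):
            raise ChronogramError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ChronogramError(f"duplicate tip labels: {dupes}")
        for nd in t.preorder_node_iter():
            if nd is t.seed_node:
                continue  # root edge length ignored (crown conditioning)
            if nd.edge.length is None:
                raise ChronogramError(
                    f"missing branch length above node {nd.taxon.label if nd.taxon else '<internal>'}"
                )
            if nd.edge.length < 0:
                raise ChronogramError("negative branch length")
        # polytomies
        poly = [nd for nd in t.preorder_node_iter() if len(nd.child_nodes()) > 2]
        if poly:
            if not resolve_polytomies:
                raise ChronogramError(
                    f"{len(poly)} polytomies present; pass resolve_polytomies=True "
                    "to expand them into zero-length binary splits"
                )
            self._resolve_polytomies(poly)
            self.log.append(f"resolved {len(poly)} polytomies into zero-length splits")
        for nd in t.preorder_node_iter():
            k = len(nd.child_nodes())
            if k == 1:
                raise ChronogramError("unifurcation in tree")
        # ultrametricity
        depths = {}
        for nd in t.preorder_node_iter():
            if nd is t.seed_node:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + nd.edge.length
        tip_depths = np.array([depths[lf] for lf in leaves])
        height = float(tip_depths.max())
        if height <= 0:
            raise ChronogramError("tree height must be positive")
        dev = float(tip_depths.max() - tip_depths.min())
        if dev > rel_tol * height:
            if not coerce_ultrametric:
                raise ChronogramError(
                    f"tree not ultrametric: tip-depth spread {dev:.6g} exceeds "
                    f"rel_tol*height = {rel_tol * height:.6g}"
                )
            for lf in leaves:
                lf.edge.length += height - depths[lf]
            self.log.append(
                f"coerced ultrametricity: extended terminal branches by up to {dev:.6g} My"
            )
        self.max_ultrametric_deviation = dev
        self.log.append(
            f"validated chronogram: {len(leaves)} tips, height {height:.6g} My, "
            f"max ultrametricity deviation {dev:.3g} My"
        )

    @staticmethod
    def _resolve_polytomies(poly_nodes):
        # deterministic left-ascending expansion into zero-length splits
        for nd in poly_nodes:
            children = sorted(
                nd.child_nodes(),
                key=lambda c: min(lf.taxon.label for lf in c.leaf_iter()),
            )
            while len(children) > 2:
                a = children.pop(0)
                b = children.pop(0)
                for c in (a, b):
                    nd.remove_child(c)
                new = nd.new_child(edge_length=0.0)
                new.add_child(a)
                new.add_child(b)
                children.insert(0, new)

    def _assign_ages(self):
        t = self._tree
        depths = {}
        for nd in t.preorder_node_iter():
            depths[nd] = 0.0 if nd is t.seed_node else depths[nd.parent_node] + nd.edge.length
        height = max(depths[lf] for lf in t.leaf_node_iter())
        for nd in t.preorder_node_iter():
            nd.age_my = height - depths[nd]
        self.height = float(height)

    # -- basic accessors ---------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def tip_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def crown_age(self) -> float:
        return float(self._tree.seed_node.age_my)

    def internal_ages(self) -> np.ndarray:
        """Ages of all internal nodes, sorted descending (crown first)."""
        ages = [nd.age_my for nd in self._tree.preorder_node_iter() if nd.child_nodes()]
        return np.sort(np.asarray(ages, dtype=float))[::-1]

    def copy(self) -> "Chronogram":
        return Chronogram(self._tree.clone(depth=1))

    # -- operations --------------------------------------------------------

    def branching_times(self) -> BranchingTimes:
        return BranchingTimes(self.internal_ages())

    def prune_to_tips(self, keep) -> "Chronogram":
        """Induced subtree on ``keep``; ages of retained splits unchanged."""
        keep = set(keep)
        have = set(lf.taxon.label for lf in self._tree.leaf_node_iter())
        unknown = keep - have
        if unknown:
            raise ChronogramError(f"unknown tip labels: {sorted(unknown)}")
        if len(keep) < 2:
            raise ChronogramError("must keep at least 2 tips")
        t = self._tree.clone(depth=1)
        taxa = [tx for tx in t.taxon_namespace if tx.label in keep]
        t2 = t.extract_tree_with_taxa(taxa=taxa)
        t2.purge_taxon_namespace()
        return Chronogram(t2)

    def extract_clade(self, tips) -> "Chronogram":
        """Subtree rooted at the MRCA of ``tips``, with all its descendants."""
        tips = set(tips)
        have = set(lf.taxon.label for lf in self._tree.leaf_node_iter())
        unknown = tips - have
        if unknown:
            raise ChronogramError(f"unknown tip labels: {sorted(unknown)}")
        t = self._tree.clone(depth=1)
        t.is_rooted = True
        taxa = [tx for tx in t.taxon_namespace if tx.label in tips]
        mrca = t.mrca(taxa=taxa)
        if mrca.parent_node is not None:
            mrca.parent_node.remove_child(mrca)
        mrca.edge.length = None
        sub = dendropy.Tree(seed_node=mrca, taxon_namespace=dendropy.TaxonNamespace())
        sub.is_rooted = True
        sub.update_taxon_namespace()
        return Chronogram(sub)

    # -- output ------------------------------------------------------------

    def write_newick(self, precision: int = 6) -> str:
        return write_newick(self, precision)

    def __repr__(self):
        return f"<Chronogram n_tips={self.n_tips} height={self.height:.4g} My>"


# ---------------------------------------------------------------------------
# module-level operations (functional surface)
# ---------------------------------------------------------------------------

def parse_newick(text: str, **kwargs) -> Chronogram:
    """Parse a Newick string into a validated :class:`Chronogram`.

    ``kwargs`` are forwarded to the :class:`Chronogram` constructor
    (``rel_tol``, ``resolve_polytomies``, ``coerce_ultrametric``).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as e:  # dendropy raises several error classes
        offset = getattr(e, "column_num", None)
        loc = f" (near character {offset})" if offset is not None else ""
        raise ChronogramError(f"malformed Newick{loc}: {e}") from e
    return Chronogram(tree, **kwargs)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Chronogram, precision: int = 6) -> str:
    """Deterministic Newick: children ordered lexicographically by their
    smallest descendant label; branch lengths at ``precision`` decimals."""

    def min_label(nd):
        return min(lf.taxon.label for lf in nd.leaf_iter())

    def emit(nd, buf, top):
        children = sorted(nd.child_nodes(), key=min_label)
        if children:
            buf.write("(")
            for i, c in enumerate(children):
                if i:
                    buf.write(",")
                emit(c, buf, False)
            buf.write(")")
        else:
            buf.write(_quote_label(nd.taxon.label))
        if not top:
            buf.write(f":{nd.edge.length:.{precision}f}")

    buf = io.StringIO()
    emit(tree.tree.seed_node, buf, True)
    buf.write(";")
    return buf.getvalue()


def branching_times(tree: Chronogram) -> BranchingTimes:
    return tree.branching_times()


def prune_to_tips(tree: Chronogram, keep) -> Chronogram:
    return tree.prune_to_tips(keep)


def extract_clade(tree: Chronogram, tips) -> Chronogram:
    return tree.extract_clade(tips)
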