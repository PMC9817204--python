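"""Rooted phylogenies with branch lengths.

The in-memory representation is a flat parent-pointer array plus a
branch x tip incidence matrix, which is what the diversity and
null-model stages consume: per-cell phylogenetic diversity reduces to a
boolean matrix product against this incidence structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "NewickError", "parse_newick"]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or validated."""


@dataclass
class Phylogeny:
    """A rooted tree: node ``i`` has ``parent[i]`` (-1 for the root) and a
    branch of ``length[i]`` leading to its parent.  ``labels[i]`` is the
    taxon name for tips, ``None`` for internal nodes.  A root branch length,
    when present in the source Newick, is kept (single-tip trees are the
    degenerate case where the root is itself a labelled tip)."""

    parent: np.ndarray
    length: np.ndarray
    labels: list
    _incidence: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.float64)
        n = self.parent.size
        if self.length.size != n or len(self.labels) != n:
            raise ValueError("parent/length/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise NewickError(f"tree must have exactly one root, found {roots.size}")
        if not np.all(np.isfinite(self.length)) or np.any(self.length < 0):
            raise NewickError("all branch lengths must be finite and >= 0")
        tips = [l for l in self.labels if l is not None]
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        if not tips:
            raise NewickError("tree has no labelled tips")

    # -- basic structure ------------------------------------------------

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tip_indices(self) -> np.ndarray:
        children = np.zeros(self.parent.size, dtype=bool)
        children[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~children)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return self.tip_indices.size

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (including a root branch if given)."""
        return float(self.length.sum())

    def incidence(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: entry (b, j) is True when tip j
        descends from (or is) node b.  Cached; the basis of every PD/PE
        computation."""
        if self._incidence is None:
            n = self.parent.size
            tips = self.tip_indices
            M = np.zeros((n, tips.size), dtype=bool)
            for j, t in enumerate(tips):
                node = int(t)
                while node >= 0:
                    M[node, j] = True
                    node = int(self.parent[node])
            self._incidence = M
        return self._incidence

    def depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order (root branch excluded)."""
        out = np.empty(self.n_tips)
        for j, t in enumerate(self.tip_indices):
            d, node = 0.0, int(t)
            while self.parent[node] >= 0:
                d += self.length[node]
                node = int(self.parent[node])
            out[j] = d
        return out

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depths()
        span = d.max() - d.min()
        scale = max(d.max(), np.finfo(float).tiny)
        return bool(span <= rtol * scale)

    def relabel(self, mapping: dict[str, str]) -> "Phylogeny":
        """Return a copy with tip labels replaced via ``mapping``."""
        labels = [mapping.get(l, l) if l is not None else None for l in self.labels]
        out = Phylogeny(self.parent.copy(), self.length.copy(), labels)
        out._incidence = self._incidence  # topology unchanged
        return out

    # -- serialization --------------------------------------------------

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)

        def render(node: int) -> str:
            kids = children.get(node, [])
            if kids:
                inner = ",".join(render(k) for k in kids)
                base = f"({inner})"
            else:
                base = self.labels[node]
            if self.parent[node] >= 0 or (not kids) or self.length[node] > 0:
                return f"{base}:{self.length[node]:.17g}"
            return base

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def prune_to(self, keep: set[str]) -> "Phylogeny":
        """Subtree spanning ``keep`` tips plus the path to the root; branches
        with no retained descendant are dropped (degree-2 nodes are kept, so
        total length equals PD of the kept set)."""
        M = self.incidence()
        tip_pos = {self.labels[t]: j for j, t in enumerate(self.tip_indices)}
        missing = keep - set(tip_pos)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        mask = np.zeros(self.n_tips, dtype=bool)
        for s in keep:
            mask[tip_pos[s]] = True
        alive = M[:, mask].any(axis=1)
        idx = np.flatnonzero(alive)
        remap = {int(old): new for new, old in enumerate(idx)}
        parent = np.array(
            [remap.get(int(self.parent[i]), -1) for i in idx], dtype=np.int64
        )
        labels = [self.labels[i] if self.labels[i] in keep else None for i in idx]
        return Phylogeny(parent, self.length[idx], labels)


def _check_parentheses(text: str) -> None:
    depth = 0
    for off, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced ')' at offset {off}")
    if depth != 0:
        raise NewickError(f"unbalanced '(': {depth} unclosed at end of statement")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick statement (terminated by ';') into a
    :class:`Phylogeny`.  Branch lengths are mandatory on every edge except
    the root's; duplicate tips and unbalanced parentheses are errors that
    name the offending label or offset."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError(f"missing ';' terminator at offset {len(text)}")
    if stripped.count(";") != 1:
        raise NewickError("expected a single Newick statement")
    _check_parentheses(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=np.int64)
    length = np.empty(len(nodes), dtype=np.float64)
    labels: list = []
    for i, nd in enumerate(nodes):
        parent[i] = index[id(nd.parent_node)] if nd.parent_node is not None else -1
        el = nd.edge.length
        if el is None:
            if nd.parent_node is None:
                el = 0.0
            else:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                )
        length[i] = float(el)
        labels.append(nd.taxon.label if (nd.taxon and nd.is_leaf()) else None)
    tree = Phylogeny(parent, length, labels)
    if not tree.is_ultrametric():
        warnings.warn(
            "tree is not ultrametric (tip depths differ); PD/PE are still "
            "defined but time-calibration is not guaranteed",
            stacklevel=2,
        )
    return tree
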