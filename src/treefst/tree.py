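"""Rooted population trees with branch coancestry parameters.

A :class:`PopulationTree` represents the hierarchy of ancestral populations:
the root is the global ancestral population, tips are the sampled units
(populations or diploid individuals), and every non-root node carries a
coancestry parameter ``theta`` in [0, 1] for the branch above it.  ``theta``
is the variance of the node's allele frequency about its parent's, scaled by
``p (1 - p)`` — the drift accumulated along that branch.

Two complementary F_ST measures are defined on such a tree:

* ``fst_w`` (correlation form): one minus the product of ``(1 - theta)``
  over the branches *shared* by the root-to-tip paths of the two units —
  the shared component of allele-frequency variance.
* ``fst_h`` (mismatch form): one minus the average, over the two orderings,
  of the product of ``(1 - theta)`` over the *non-shared* branches — the
  divergence of the two units from their most recent common ancestor.

The same path algebra gives the expectation of the moment statistic ``S``
used for inference (:func:`PopulationTree.expected_s`).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PopulationTree",
    "CoancestryEstimates",
    "branch_sets",
    "fst_w",
    "fst_h",
    "expected_s",
    "coancestry_matrices",
]


def _prod_one_minus(thetas: Iterable[float]) -> float:
    """Product of (1 - theta), stable near theta -> 1.

    Computed as ``exp(sum(log1p(-theta)))``; a theta of exactly 1 makes the
    product exactly 0.
    """
    acc = 0.0
    for t in thetas:
        if t >= 1.0:
            return 0.0
        acc += math.log1p(-t)
    return math.exp(acc)


class PopulationTree:
    """Rooted tree whose non-root nodes carry branch parameters theta.

    Parameters
    ----------
    parent
        Mapping node name -> parent name; exactly one node (the root) maps
        to ``None``.  Following the field convention, a node's name also
        names the branch above it.
    theta
        Mapping from every non-root node to its branch parameter in [0, 1].
        Missing entries default to 0.

    Notes
    -----
    Tips (leaves) are the sampled units.  A *final* inferred tree is binary;
    intermediate trees built during clustering may have a multifurcating
    root only.
    """

    def __init__(
        self,
        parent: Mapping[str, str | None],
        theta: Mapping[str, float] | None = None,
    ) -> None:
        parent = dict(parent)
        roots = [n for n, p in parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n, p in parent.items():
            if p is not None and p not in parent:
                raise ValueError(f"parent {p!r} of node {n!r} is not a node")
        self._parent = parent
        self._children: dict[str, list[str]] = {n: [] for n in parent}
        for n, p in parent.items():
            if p is not None:
                self._children[p].append(n)
        for c in self._children.values():
            c.sort()
        # connectivity / acyclicity: every node must reach the root
        for n in parent:
            seen = set()
            while n is not None:
                if n in seen:
                    raise ValueError("cycle detected in parent mapping")
                seen.add(n)
                n = parent[n]
        theta = dict(theta or {})
        if self.root in theta:
            raise ValueError("root carries no branch parameter")
        for q, t in theta.items():
            if q not in parent:
                raise ValueError(f"theta given for unknown node {q!r}")
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"theta[{q!r}] = {t} outside [0, 1]")
        self.theta: dict[str, float] = {
            n: float(theta.get(n, 0.0)) for n in parent if n != self.root
        }

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def star(cls, tips: Iterable[str], theta: Mapping[str, float] | None = None,
             root: str = "0") -> "PopulationTree":
        """Independent-descent (star) tree: every tip a child of the root."""
        tips = list(tips)
        if root in tips:
            raise ValueError("root name collides with a tip label")
        parent: dict[str, str | None] = {root: None}
        parent.update({t: root for t in tips})
        return cls(parent, theta)

    def copy(self) -> "PopulationTree":
        return PopulationTree(dict(self._parent), dict(self.theta))

    # ------------------------------------------------------------------
    # structure queries
    # ------------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self._parent)

    @property
    def branches(self) -> list[str]:
        """Non-root nodes, i.e. the branches of the tree, sorted."""
        return sorted(n for n in self._parent if n != self.root)

    @property
    def tips(self) -> list[str]:
        return sorted(n for n, c in self._children.items() if not c)

    def parent(self, node: str) -> str | None:
        return self._parent[node]

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def is_binary(self) -> bool:
        return all(len(c) == 2 for n, c in self._children.items() if c)

    def path(self, node: str) -> list[str]:
        """Branches on the path from the root down to ``node`` (inclusive)."""
        if node not in self._parent:
            raise KeyError(f"unknown node {node!r}")
        out = []
        while node != self.root:
            out.append(node)
            node = self._parent[node]  # type: ignore[assignment]
        out.reverse()
        return out

    def branch_sets(self, k: str, k2: str) -> tuple[str, set[str], set[str]]:
        """MRCA and the shared/non-shared branch sets for an ordered pair.

        Returns ``(M, Q, R)`` where ``Q`` is the set of branches ancestral
        to both ``k`` and ``k2`` and ``R`` the set ancestral to ``k`` but
        not ``k2``.  Note the asymmetry: ``R(k, k2) != R(k2, k)`` in
        general, while ``Q`` is symmetric.
        """
        pk, pk2 = self.path(k), self.path(k2)
        q = [a for a, b in zip(pk, pk2) if a == b]
        mrca = q[-1] if q else self.root
        qs = set(q)
        rs = set(pk) - set(pk2)
        return mrca, qs, rs

    def clades(self) -> frozenset[frozenset[str]]:
        """Tip sets below every internal (non-tip) node, root included."""
        below: dict[str, set[str]] = {}

        def walk(n: str) -> set[str]:
            ch = self._children[n]
            if not ch:
                return {n}
            s: set[str] = set()
            for c in ch:
                s |= walk(c)
            below[n] = s
            return s

        walk(self.root)
        return frozenset(frozenset(s) for s in below.values())

    # ------------------------------------------------------------------
    # coancestry functionals
    # ------------------------------------------------------------------
    def fst_w(self, k: str, k2: str) -> float:
        """Correlation-form F_ST: 1 - prod over shared branches of (1-theta).

        ``fst_w(k, k)`` is the divergence of the single unit from the root
        population; tips in different root subtrees share no branches and
        give exactly 0.
        """
        _, q, _ = self.branch_sets(k, k2)
        return 1.0 - _prod_one_minus(self.theta[b] for b in q)

    def fst_h(self, k: str, k2: str) -> float:
        """Mismatch-form F_ST: divergence of k and k2 from their MRCA.

        Equals ``1 - 0.5 * (prod over R(k,k2) + prod over R(k2,k))`` of
        ``(1 - theta)``; zero when ``k == k2`` (both products empty).
        """
        _, _, r12 = self.branch_sets(k, k2)
        _, _, r21 = self.branch_sets(k2, k)
        p12 = _prod_one_minus(self.theta[b] for b in r12)
        p21 = _prod_one_minus(self.theta[b] for b in r21)
        return 1.0 - 0.5 * (p12 + p21)

    def expected_s(self, k: str, k2: str) -> float:
        """Model expectation of the moment statistic S for ordered (k, k2).

        ``prod over R(k, k2) of (1 - theta)`` — one minus the correlation of
        two alleles from ``k`` given the frequency at the pair's MRCA.
        """
        if k == k2:
            raise ValueError("expected_s requires two distinct tips")
        _, _, r = self.branch_sets(k, k2)
        return _prod_one_minus(self.theta[b] for b in r)

    def coancestry_matrices(self, order: list[str] | None = None) -> "CoancestryEstimates":
        """All-pairs FSTW / FSTH matrices (diagonals included)."""
        labels = order if order is not None else self.tips
        kk = len(labels)
        w = np.zeros((kk, kk))
        h = np.zeros((kk, kk))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if j < i:
                    continue
                w[i, j] = w[j, i] = self.fst_w(a, b)
                if i != j:
                    h[i, j] = h[j, i] = self.fst_h(a, b)
        return CoancestryEstimates(
            unit_labels=list(labels),
            W=pd.DataFrame(w, index=labels, columns=labels),
            H=pd.DataFrame(h, index=labels, columns=labels),
        )

    # ------------------------------------------------------------------
    # newick round trip
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        """Serialize with theta as branch lengths and internal labels kept."""

        def quote(label: str) -> str:
            if any(c in label for c in " ()[]:;,'\t\n"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def write(n: str) -> str:
            ch = self._children[n]
            s = ""
            if ch:
                s = "(" + ",".join(write(c) for c in ch) + ")"
            s += quote(n)
            if n != self.root:
                s += f":{self.theta[n]:.17g}"
            return s

        return write(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PopulationTree":
        """Parse a newick string; branch lengths are theta values in [0, 1]."""
        import dendropy

        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=False, rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed newick: {exc}") from exc
        parent: dict[str, str | None] = {}
        theta: dict[str, float] = {}
        counter = [0]

        def name_of(node) -> str:
            if node.taxon is not None and node.taxon.label:
                return str(node.taxon.label)
            if node.label:
                return str(node.label)
            counter[0] += 1
            return f"_anon{counter[0]}"

        names: dict[int, str] = {}

        def walk(node, par: str | None) -> None:
            nm = names.setdefault(id(node), name_of(node))
            if nm in parent:
                raise ValueError(f"duplicate node label {nm!r} in newick")
            parent[nm] = par
            if par is not None:
                el = node.edge.length
                t = 0.0 if el is None else float(el)
                if not 0.0 <= t <= 1.0:
                    raise ValueError(f"branch length {t} for {nm!r} outside [0, 1]")
                theta[nm] = t
            for ch in node.child_nodes():
                walk(ch, nm)

        walk(dt.seed_node, None)
        return cls(parent, theta)

    # ------------------------------------------------------------------
    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PopulationTree({len(self.tips)} tips, root={self.root!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationTree):
            return NotImplemented
        return self._parent == other._parent and self.theta == other.theta


@dataclass
class CoancestryEstimates:
    """Tree-based F_ST matrices for a set of units.

    ``W`` holds the correlation-form values (diagonal = single-unit
    divergence from the root population); ``H`` holds the mismatch-form
    values (diagonal exactly 0).  Both are symmetric with entries in [0, 1].
    """

    unit_labels: list[str]
    W: pd.DataFrame
    H: pd.DataFrame

    def to_tsv(self) -> tuple[str, str]:
        """Labelled TSV renderings of (W, H)."""
        bufs = []
        for m in (self.W, self.H):
            buf = io.StringIO()
            m.to_csv(buf, sep="\t", float_format="%.6f")
            bufs.append(buf.getvalue())
        return bufs[0], bufs[1]


# ----------------------------------------------------------------------
# functional aliases (thin wrappers over the methods)
# ----------------------------------------------------------------------
def branch_sets(tree: PopulationTree, k: str, k2: str):
    return tree.branch_sets(k, k2)


def fst_w(tree: PopulationTree, k: str, k2: str) -> float:
    return tree.fst_w(k, k2)


def fst_h(tree: PopulationTree, k: str, k2: str) -> float:
    return tree.fst_h(k, k2)


def expected_s(tree: PopulationTree, k: str, k2: str) -> float:
    return tree.expected_s(k, k2)


def coancestry_matrices(tree: PopulationTree) -> CoancestryEstimates:
    return tree.coancestry_matrices()
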