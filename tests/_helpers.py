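"""Shared test utilities: noiseless S matrices, clade-keyed thetas, and an
exhaustive rooted-binary-topology enumerator used as an independent oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from treefst import PopulationTree


def noiseless_s(tree: PopulationTree) -> pd.DataFrame:
    """Exact model expectations of S for every ordered tip pair."""
    tips = tree.tips
    s = pd.DataFrame(np.nan, index=tips, columns=tips)
    for a in tips:
        for b in tips:
            if a != b:
                s.at[a, b] = tree.expected_s(a, b)
    return s


def theta_by_clade(tree: PopulationTree) -> dict[frozenset, float]:
    """Branch thetas keyed by the tip set below the branch (name-free)."""
    out = {}
    for q in tree.branches:
        below = frozenset(t for t in tree.tips if q in tree.path(t))
        out[below] = tree.theta[q]
    return out


def all_rooted_binary_topologies(tips: list[str]):
    """Yield every rooted binary tree shape on the given labelled tips.

    Enumerates recursively by splitting the tip set at the root; the first
    tip is pinned to the left part to avoid double counting.  Counts follow
    (2K - 3)!! = 3, 15, 105, ... for K = 3, 4, 5, ...
    """

    def shapes(labels: tuple[str, ...]):
        if len(labels) == 1:
            yield labels[0]
            return
        first, rest = labels[0], labels[1:]
        for r in range(len(rest)):
            for right in itertools.combinations(rest, len(rest) - r):
                left = (first,) + tuple(x for x in rest if x not in right)
                if not right:
                    continue
                for ls in shapes(left):
                    for rs in shapes(tuple(right)):
                        yield (ls, rs)

    seen = set()
    for shape in shapes(tuple(tips)):
        key = _canon(shape)
        if key in seen:
            continue
        seen.add(key)
        yield _shape_to_tree(shape, tips)


def _canon(shape):
    if isinstance(shape, str):
        return shape
    a, b = _canon(shape[0]), _canon(shape[1])
    return (a, b) if str(a) <= str(b) else (b, a)


def _shape_to_tree(shape, tips) -> PopulationTree:
    parent: dict[str, str | None] = {"0": None}
    counter = [0]

    def build(node, par: str) -> None:
        if isinstance(node, str):
            parent[node] = par
            return
        counter[0] += 1
        name = f"i{counter[0]}"
        parent[name] = par
        build(node[0], name)
        build(node[1], name)

    if isinstance(shape, str):
        raise ValueError("need at least two tips")
    build(shape[0], "0")
    build(shape[1], "0")
    return PopulationTree(parent)


def random_binary_tree(tips: list[str], rng: np.random.Generator,
                       theta_range=(0.02, 0.3)) -> PopulationTree:
    """Random rooted binary topology with thetas drawn uniformly."""
    if len(tips) < 2:
        raise ValueError("need at least two tips")
    parent: dict[str, str | None] = {"0": None}
    roots = list(tips)
    counter = 0
    while len(roots) > 2:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        counter += 1
        name = f"n{counter}"
        parent[roots[i]] = name
        parent[roots[j]] = name
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [name]
    parent[roots[0]] = "0"
    parent[roots[1]] = "0"
    lo, hi = theta_range
    theta = {n: float(rng.uniform(lo, hi)) for n in parent if n != "0"}
    return PopulationTree(parent, theta)
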