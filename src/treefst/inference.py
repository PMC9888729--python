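"""Joint inference of the population tree and branch coancestry parameters.

Writing ``beta_q = log(1 - theta_q)``, the model expectation of the moment
statistic S for an ordered pair (k, k') is ``exp(sum of beta_q over the
non-shared branches R(k, k'))``.  The fit minimises the logarithmic
least-squares objective

    xi = sum over ordered pairs (log S_kk' - sum_{q in R(kk')} beta_q)^2

subject to ``beta_q <= 0``.  With ``gamma = -beta >= 0`` this is a
non-negative least-squares problem, solved exactly by the Lawson-Hanson
algorithm (``scipy.optimize.nnls``).

Topology search is in two phases.  The *clustering* phase starts from the
star tree (the independent-descent model) and performs K - 2 merge steps;
each step inserts an intermediate ancestral node above the pair of current
root children whose merged tree minimises xi.  The *improvement* phase
then revisits each tip in seeded random order, trying every branch of the
tree with that tip removed as an alternative attachment point and keeping
the placement with smallest xi (the current tree is retained on ties);
full passes repeat until a pass changes nothing or a cap is reached.

Binary trees with K tips all carry 2(K - 1) branch parameters, so xi
values are directly comparable across candidate topologies.  The S matrix
is computed once (cost linear in the number of SNVs); afterwards the
search cost depends only on K.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .counts import AlleleCountMatrix
from .moments import DEFAULT_CLIP_EPS, pair_sums, hudson_pairwise, s_matrix
from .tree import CoancestryEstimates, PopulationTree

__all__ = [
    "FitResult",
    "design_system",
    "fit_thetas",
    "cluster_phase",
    "improve_phase",
    "infer",
    "CoancestryModel",
    "CoancestryResults",
]

# relative slack treating two xi values as tied (determinism of the search)
_TIE_RTOL = 1e-12


@dataclass
class FitResult:
    """Fitted tree and diagnostics of the least-squares problem.

    ``tree`` carries ``theta_hat = 1 - exp(beta_hat)`` on every branch;
    ``xi`` is the residual sum of squares; ``rows_used`` lists the ordered
    pairs whose S value entered the fit.
    """

    tree: PopulationTree
    xi: float
    rows_used: list[tuple[str, str]]
    diagnostics: dict = field(default_factory=dict)


def design_system(
    tree: PopulationTree, s: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]], list[str]]:
    """Build the 0/1 design of the log least squares for a given topology.

    One row per ordered pair (k, k') with a defined S value; column q is 1
    iff branch q lies on the path to k but not to k' (the set R(k, k')).
    The response is ``y = -log S >= 0`` so the solve runs over
    ``gamma = -beta >= 0``.
    """
    tips = tree.tips
    if sorted(s.index) != tips or sorted(s.columns) != tips:
        raise ValueError("S matrix labels do not match tree tips")
    branches = tree.branches
    col = {q: j for j, q in enumerate(branches)}
    rows: list[tuple[str, str]] = []
    xs: list[np.ndarray] = []
    ys: list[float] = []
    paths = {t: set(tree.path(t)) for t in tips}
    for k, k2 in itertools.permutations(tips, 2):
        val = s.at[k, k2]
        if not np.isfinite(val):
            continue
        r = paths[k] - paths[k2]
        x = np.zeros(len(branches))
        for q in r:
            x[col[q]] = 1.0
        rows.append((k, k2))
        xs.append(x)
        ys.append(-float(np.log(val)))
    if not rows:
        raise ValueError("no defined S values; nothing to fit")
    x_mat = np.vstack(xs)
    if not np.any(x_mat.sum(axis=0) > 0):
        raise RuntimeError("design has an all-zero column on a connected tree")
    return x_mat, np.asarray(ys), rows, branches


def fit_thetas(tree: PopulationTree, s: pd.DataFrame) -> FitResult:
    """Solve the constrained log least squares for a fixed topology.

    Returns a tree carrying ``theta_hat`` per branch and the objective
    value xi.  With noiseless S generated from the same topology the
    system is consistent and theta is recovered exactly (xi = 0).
    """
    x, y, rows, branches = design_system(tree, s)
    zero_cols = x.sum(axis=0) == 0
    if zero_cols.any():
        warnings.warn("dropped S rows left branches without data; their theta is 0")
    if x.shape[0] < x.shape[1]:
        warnings.warn("fewer S rows than branches; fit is under-determined")
    gamma, rnorm = nnls(x, y)
    fitted = tree.copy()
    theta_hat = -np.expm1(-gamma)  # 1 - exp(-gamma), gamma >= 0
    for q, t in zip(branches, theta_hat):
        fitted.theta[q] = float(min(max(t, 0.0), 1.0))
    return FitResult(
        tree=fitted,
        xi=float(rnorm**2),
        rows_used=rows,
        diagnostics={"n_rows": len(rows), "n_branches": len(branches)},
    )


def _fresh_names(taken: set[str]) -> "itertools.count":
    """Generator of internal-node names avoiding existing labels."""
    def gen():
        i = 0
        while True:
            i += 1
            name = f"anc{i}"
            if name not in taken:
                yield name
    return gen()


def cluster_phase(s: pd.DataFrame, labels: list[str] | None = None) -> FitResult:
    """Agglomerate a binary tree from the star (independent-descent) start.

    At each of K - 2 steps every pair of current root children is tried:
    an intermediate ancestral node is inserted between the root and the
    pair, the full tree refitted, and the pair with smallest xi kept.  Ties
    (within relative 1e-12) go to the lexicographically smallest pair.
    """
    if labels is None:
        labels = sorted(s.index)
    if len(labels) < 2:
        raise ValueError("need at least two units")
    names = _fresh_names(set(labels) | {"0"})
    tree = PopulationTree.star(labels)
    best = fit_thetas(tree, s)
    for _ in range(len(labels) - 2):
        root_children = sorted(tree.children(tree.root))
        new_name = next(names)
        step_best: FitResult | None = None
        for a, b in itertools.combinations(root_children, 2):
            parent = {n: tree.parent(n) for n in tree.nodes}
            parent[new_name] = tree.root
            parent[a] = new_name
            parent[b] = new_name
            cand = PopulationTree(parent)
            fit = fit_thetas(cand, s)
            if step_best is None or fit.xi < step_best.xi * (1.0 - _TIE_RTOL) - _TIE_RTOL:
                step_best = fit
        assert step_best is not None
        tree = step_best.tree
        best = step_best
    return best


def _reinsert(tree: PopulationTree, tip: str) -> list[PopulationTree]:
    """All trees obtained by regrafting ``tip`` onto the reduced tree.

    The reduced tree is the current tree with ``tip`` removed and its
    former (degree-2) parent suppressed.  Candidates re-use the suppressed
    parent's name and place it above every non-root node of the reduced
    tree; the original placement is generated separately by the caller.
    """
    par = tree.parent(tip)
    assert par is not None
    sib = [c for c in tree.children(par) if c != tip][0]
    grand = tree.parent(par)
    reduced = {n: tree.parent(n) for n in tree.nodes if n not in (tip, par)}
    reduced[sib] = grand  # None when par was the root: sib becomes root
    out: list[PopulationTree] = []
    red_root = sib if grand is None else tree.root
    for v in sorted(reduced):
        if v == red_root:
            continue
        parent = dict(reduced)
        parent[par] = parent[v]
        parent[v] = par
        parent[tip] = par
        out.append(PopulationTree(parent))
    # new parent above the reduced root (recreates the original topology
    # when the tip hung off the root; otherwise a genuine extra candidate
    # only when the reduced root is the global root's single child)
    if grand is None:
        parent = dict(reduced)
        parent[par] = None
        parent[red_root] = par
        parent[tip] = par
        out.append(PopulationTree(parent))
    return out


def improve_phase(
    start: "FitResult | PopulationTree",
    s: pd.DataFrame,
    seed: int = 0,
    passes_cap: int = 10,
) -> FitResult:
    """Tip-regrafting local search; xi is non-increasing across moves.

    Tips are visited in seeded random order (reshuffled each pass).  A move
    is accepted only when it strictly lowers xi beyond the tie tolerance,
    so a tree already at an optimum is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    current = start if isinstance(start, FitResult) else fit_thetas(start, s)
    passes = 0
    for _ in range(passes_cap):
        passes += 1
        changed = False
        tips = current.tree.tips
        order = list(rng.permutation(len(tips)))
        for i in order:
            tip = tips[i]
            best = current
            for cand in _reinsert(current.tree, tip):
                if cand.clades() == current.tree.clades():
                    continue  # current tree retained on ties
                fit = fit_thetas(cand, s)
                if fit.xi < best.xi * (1.0 - _TIE_RTOL) - _TIE_RTOL:
                    best = fit
            if best is not current:
                current = best
                changed = True
        if not changed:
            break
    current.diagnostics["passes"] = passes
    current.diagnostics["seed"] = seed
    return current


def infer(
    acm: AlleleCountMatrix,
    seed: int = 0,
    passes_cap: int = 10,
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> tuple[FitResult, CoancestryEstimates]:
    """End-to-end inference from allele counts.

    Pipeline: pair sums -> clipped S matrix -> clustering phase ->
    improvement phase -> coancestry matrices from the fitted tree.
    """
    ps = pair_sums(acm)
    s = s_matrix(ps, clip_eps=clip_eps)
    fit = cluster_phase(s, labels=list(acm.unit_labels))
    fit = improve_phase(fit, s, seed=seed, passes_cap=passes_cap)
    est = fit.tree.coancestry_matrices(order=list(acm.unit_labels))
    n_pairs = acm.n_units * (acm.n_units - 1)
    fit.diagnostics["rows_dropped"] = n_pairs - len(fit.rows_used)
    return fit, est


# ----------------------------------------------------------------------
# Model / Results surface
# ----------------------------------------------------------------------
class CoancestryModel:
    """Joint coancestry-and-tree model for a set of allele-count units.

    Parameters
    ----------
    counts
        The allele-count data; units may be population samples, diploid
        individuals (2 gametes) or a mixture.
    clip_eps
        Lower clip applied to the S statistic before taking logs.

    Examples
    --------
    >>> model = CoancestryModel.from_counts_table("counts.tsv")  # doctest: +SKIP
    >>> res = model.fit(seed=1)                                  # doctest: +SKIP
    >>> print(res.summary())                                     # doctest: +SKIP
    """

    def __init__(self, counts: AlleleCountMatrix, clip_eps: float = DEFAULT_CLIP_EPS):
        self.counts = counts
        self.clip_eps = clip_eps

    @classmethod
    def from_counts_table(cls, path, clip_eps: float = DEFAULT_CLIP_EPS) -> "CoancestryModel":
        from .counts import load_counts_table

        return cls(load_counts_table(path), clip_eps=clip_eps)

    @classmethod
    def from_vcf(cls, path, popmap=None, clip_eps: float = DEFAULT_CLIP_EPS) -> "CoancestryModel":
        from .counts import from_vcf

        return cls(from_vcf(path, popmap), clip_eps=clip_eps)

    def fit(self, seed: int = 0, passes_cap: int = 10) -> "CoancestryResults":
        fit, est = infer(self.counts, seed=seed, passes_cap=passes_cap,
                         clip_eps=self.clip_eps)
        return CoancestryResults(self, fit, est)


class CoancestryResults:
    """Results of a :class:`CoancestryModel` fit.

    Attributes
    ----------
    tree : PopulationTree
        Fitted binary tree with ``theta_hat`` per branch.
    theta : pandas.Series
        Branch parameter estimates indexed by branch name.
    xi : float
        Final value of the log least-squares objective.
    fst_w, fst_h : pandas.DataFrame
        Tree-based coancestry matrices (shared / non-shared variance).
    """

    def __init__(self, model: CoancestryModel, fit: FitResult,
                 estimates: CoancestryEstimates):
        self.model = model
        self.fit_result = fit
        self.tree = fit.tree
        self.theta = pd.Series(fit.tree.theta, name="theta_hat").sort_index()
        self.xi = fit.xi
        self.rows_used = fit.rows_used
        self.diagnostics = fit.diagnostics
        self.estimates = estimates
        self.fst_w = estimates.W
        self.fst_h = estimates.H

    def hudson_pairwise(self) -> pd.DataFrame:
        """Pairwise ratio-of-sums estimator on the same data, for comparison."""
        return hudson_pairwise(self.model.counts)

    def to_newick(self) -> str:
        return self.tree.to_newick()

    def summary(self) -> str:
        lines = [
            "Coancestry tree fit (log least squares, NNLS)",
            "=" * 46,
            f"units:            {len(self.model.counts.unit_labels)}",
            f"loci:             {self.model.counts.n_loci}",
            f"S rows used:      {len(self.rows_used)}"
            f" (dropped {self.diagnostics.get('rows_dropped', 0)})",
            f"objective xi:     {self.xi:.6g}",
            f"improve passes:   {self.diagnostics.get('passes', 0)}"
            f"  (seed {self.diagnostics.get('seed', 0)})",
            "",
            "branch theta_hat",
            "-" * 24,
        ]
        for q, t in self.theta.items():
            lines.append(f"{q:<8} {t:.4f}")
        lines += ["", "tree: " + self.to_newick()]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CoancestryResults: {len(self.tree.tips)} tips, "
                f"xi={self.xi:.4g}>")
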