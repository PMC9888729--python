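"""Hierarchical beta-drift simulator for allele counts on a population tree.

Each site evolves independently (no linkage): the ancestral frequency p is
drawn from a beta distribution (default beta(0.4, 0.4), a U-shaped spectrum
under which about 19% of sites have p outside (0.01, 0.99) and 36% outside
(0.05, 0.95)); each child population's frequency is drawn conditionally on
its parent's from the beta distribution with mean ``p_parent`` and variance
``theta * p_parent * (1 - p_parent)`` — the unique beta matching those two
moments, with shapes ``a = p(1-theta)/theta`` and ``b = (1-p)(1-theta)/theta``.
Gametes are then sampled binomially at each tip, and only SNV sites (at
least one minor-allele copy somewhere in the pooled sample; no MAF
threshold) are retained.

The optional admixture variant replaces the frequency of one tip's parent
by a deterministic mixture ``alpha * p_source + (1 - alpha) * p_parent``
before that tip's drift draw; the mixture applies only to the named child.

Scenario presets S1-S6 fix gametes-per-unit and sites-per-replicate on the
five-population benchmark tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .counts import AlleleCountMatrix
from .tree import PopulationTree

__all__ = [
    "Admixture",
    "ScenarioConfig",
    "SimReplicate",
    "benchmark_tree",
    "scenario_config",
    "SCENARIOS",
    "draw_child_freq",
    "simulate_replicate",
    "ancestral_tail_check",
    "admixture_truth",
]


def benchmark_tree() -> PopulationTree:
    """The five-population tree used throughout the simulation study.

    Root 0 splits into ancestral populations 1 (parent of A, B) and 2
    (parent of E and of ancestral population 3, itself parent of C, D).
    Branch parameters: theta = 0.15 on branches 1 and 2, 0.10 on D, and
    0.05 on 3, A, B, C, E.
    """
    parent = {
        "0": None,
        "1": "0", "2": "0",
        "A": "1", "B": "1",
        "3": "2", "E": "2",
        "C": "3", "D": "3",
    }
    theta = {"1": 0.15, "2": 0.15, "3": 0.05,
             "A": 0.05, "B": 0.05, "C": 0.05, "E": 0.05, "D": 0.10}
    return PopulationTree(parent, theta)


@dataclass
class Admixture:
    """Deterministic frequency-level admixture into one tip's parent.

    Before drawing ``child``'s frequency, its parent's frequency is
    replaced by ``alpha * p[source] + (1 - alpha) * p[parent(child)]``.
    """

    alpha: float
    child: str = "C"
    source: str = "1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("admixture fraction alpha must be in [0, 1]")


@dataclass
class ScenarioConfig:
    """Simulator settings: theta-labelled tree, sampling sizes, shapes."""

    tree: PopulationTree = field(default_factory=benchmark_tree)
    gametes_per_unit: int = 25
    n_sites: int = 10_000
    ancestral_beta: tuple[float, float] = (0.4, 0.4)
    admixture: Admixture | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.gametes_per_unit < 2:
            raise ValueError("need at least 2 gametes per unit")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if min(self.ancestral_beta) <= 0:
            raise ValueError("beta shapes must be positive")
        if self.admixture is not None:
            if self.admixture.child not in self.tree.tips:
                raise ValueError("admixture child must be a tip")
            if self.admixture.source not in self.tree.nodes:
                raise ValueError("admixture source must be a tree node")


#: Table of scenario presets: gametes sampled per unit, sites simulated.
SCENARIOS: dict[str, tuple[int, int]] = {
    "S1": (25, 10_000),
    "S2": (10, 10_000),
    "S3": (2, 10_000),
    "S4": (25, 1_000),
    "S5": (10, 1_000),
    "S6": (10, 100),
}


def scenario_config(name: str, alpha: float | None = None) -> ScenarioConfig:
    """Preset config for scenarios S1-S6, optionally with admixture."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    gam, sites = SCENARIOS[name]
    adm = None if alpha is None else Admixture(alpha=alpha)
    return ScenarioConfig(gametes_per_unit=gam, n_sites=sites,
                          admixture=adm, name=name)


@dataclass
class SimReplicate:
    """One simulated dataset: true frequencies plus sampled counts.

    ``freqs`` holds the true per-site frequency at every tree node
    (all simulated sites); ``counts`` holds the sampled gametes restricted
    to SNV sites.
    """

    freqs: dict[str, np.ndarray]
    counts: AlleleCountMatrix
    n_sites_total: int
    n_snv: int


def draw_child_freq(p_parent: np.ndarray | float, theta: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Conditional beta drift draw for a child population.

    Mean ``p_parent`` and variance ``theta * p_parent * (1 - p_parent)``.
    Degenerate limits handled exactly: theta = 0 copies the parent;
    a fixed parent frequency (0 or 1) stays fixed; theta = 1 fixes the
    child at 1 with probability ``p_parent``, else 0.
    """
    p = np.atleast_1d(np.asarray(p_parent, dtype=float))
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    if theta == 0.0:
        return p.copy()
    if theta == 1.0:
        return (rng.random(p.shape) < p).astype(float)
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        scale = (1.0 - theta) / theta
        a = p[interior] * scale
        b = (1.0 - p[interior]) * scale
        out[interior] = rng.beta(a, b)
    return out


def _node_order(tree: PopulationTree) -> list[str]:
    """Deterministic parent-before-child traversal (children sorted)."""
    order = [tree.root]
    stack = [tree.root]
    while stack:
        n = stack.pop(0)
        ch = tree.children(n)
        order.extend(ch)
        stack.extend(ch)
    return order


def _simulate_freqs(config: ScenarioConfig, m: int,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Propagate per-site frequencies from the root down to every node."""
    tree = config.tree
    a0, b0 = config.ancestral_beta
    freqs: dict[str, np.ndarray] = {tree.root: rng.beta(a0, b0, size=m)}
    adm = config.admixture
    for node in _node_order(tree)[1:]:
        p_par = freqs[tree.parent(node)]
        if adm is not None and node == adm.child:
            p_par = adm.alpha * freqs[adm.source] + (1.0 - adm.alpha) * p_par
        freqs[node] = draw_child_freq(p_par, tree.theta[node], rng)
    return freqs


def simulate_replicate(config: ScenarioConfig, rng: np.random.Generator) -> SimReplicate:
    """Simulate one replicate: frequencies down the tree, then gametes.

    Sites are independent.  The returned count matrix holds SNV sites only;
    a site is an SNV when the pooled tip sample carries at least one copy
    of each allele.
    """
    tree = config.tree
    m = config.n_sites
    freqs = _simulate_freqs(config, m, rng)
    tips = tree.tips
    n = config.gametes_per_unit
    ref = np.empty((m, len(tips)), dtype=np.int64)
    for j, t in enumerate(tips):
        ref[:, j] = rng.binomial(n, freqs[t])
    total = ref.sum(axis=1)
    snv = (total > 0) & (total < n * len(tips))
    counts = AlleleCountMatrix(
        unit_labels=list(tips),
        loci=[f"S{i + 1}" for i in np.flatnonzero(snv)],
        ref_count=ref[snv],
        n_gametes=np.full((int(snv.sum()), len(tips)), n, dtype=np.int64),
    )
    return SimReplicate(freqs=freqs, counts=counts,
                        n_sites_total=m, n_snv=int(snv.sum()))


def ancestral_tail_check(shapes: tuple[float, float],
                         bounds: tuple[float, float]) -> float:
    """P(p <= lo) + P(p >= hi) for the ancestral beta distribution."""
    a, b = shapes
    lo, hi = bounds
    if min(a, b) <= 0:
        raise ValueError("beta shapes must be positive")
    return float(beta_dist.cdf(lo, a, b) + beta_dist.sf(hi, a, b))


def admixture_truth(
    config: ScenarioConfig,
    n_oracle_sites: int = 1_000_000,
    rng: np.random.Generator | None = None,
    n_batches: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo truth for the mismatch-form F_ST under admixture.

    Simulates population frequencies only (no gamete sampling) and applies
    the mismatch-probability definition with expectations taken over
    sites:

        FSTH(k,k') = 1 - (E[p_k(1-p_k)] + E[p_k'(1-p_k')])
                        / (E[p_k(1-p_k')] + E[p_k'(1-p_k)])

    Returns the K x K truth matrix and a matrix of batch-means standard
    errors.  With alpha = 0 this reproduces the tree-based closed form.
    """
    if config.admixture is None:
        raise ValueError("admixture_truth requires an active admixture setting")
    if rng is None:
        rng = np.random.default_rng(0)
    tips = config.tree.tips
    kk = len(tips)
    per_batch = max(n_oracle_sites // n_batches, 1)
    cross = np.zeros((n_batches, kk, kk))  # E[p_k (1 - p_k')] per batch
    for bi in range(n_batches):
        freqs = _simulate_freqs(config, per_batch, rng)
        p = np.column_stack([freqs[t] for t in tips])
        cross[bi] = (p.T @ (1.0 - p)) / per_batch

    def h_from_cross(c: np.ndarray) -> np.ndarray:
        within = np.diag(c)
        num = within[:, None] + within[None, :]
        den = c + c.T
        with np.errstate(invalid="ignore", divide="ignore"):
            h = 1.0 - num / den
        np.fill_diagonal(h, 0.0)
        return h

    h_batches = np.array([h_from_cross(cross[bi]) for bi in range(n_batches)])
    h = h_from_cross(cross.mean(axis=0))
    se = h_batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return (pd.DataFrame(h, index=tips, columns=tips),
            pd.DataFrame(se, index=tips, columns=tips))
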