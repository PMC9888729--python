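"""Simulation-study evaluation: RMSE, RMSE ratios, topology accuracy.

``run_scenario`` simulates replicates under a scenario configuration,
runs both the pairwise ratio-of-sums estimator and the tree-based
estimator on each, and accumulates per-pair root-mean-square errors
against the exact tree-based truths (or, under admixture, a Monte-Carlo
frequency-level oracle), the fraction of replicates whose inferred rooted
topology matches the truth, and per-replicate Pearson correlations
between estimates and truths across the population pairs.

RMSE is always computed against the exact truth, never against sample
means; the RMSE ratio for a pair is RMSE(pairwise) / RMSE(tree-based),
so values above 1 favour the tree-based estimator.  The per-replicate
correlation is taken across the pairs within a replicate and then
averaged over replicates.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import CoancestryModel
from .moments import hudson_pairwise
from .simulate import ScenarioConfig, admixture_truth, simulate_replicate
from .tree import PopulationTree

__all__ = ["EvaluationReport", "topology_equal", "run_scenario"]


def topology_equal(t1: PopulationTree, t2: PopulationTree) -> bool:
    """Rooted-topology equality: clade (tip-subset) sets coincide.

    Branch parameters and child order are ignored; the tip label sets
    must match.
    """
    if set(t1.tips) != set(t2.tips):
        raise ValueError("trees have different tip label sets")
    return t1.clades() == t2.clades()


@dataclass
class EvaluationReport:
    """Aggregated performance of the estimators over a scenario.

    Pairwise entities are indexed by unordered tip pairs "kk'" (and, for
    the shared-variance estimator, single tips "k" for the diagonal).
    RMSE values are on the natural scale (multiply by 1e4 to compare with
    the conventional tabulations).
    """

    scenario: str
    n_reps: int
    n_excluded: int
    seed: int
    true_fst_h: pd.Series
    true_fst_w: pd.Series
    rmse_tree_h: pd.Series
    rmse_pairwise_h: pd.Series
    rmse_tree_w: pd.Series
    rmse_ratio: pd.Series
    mean_rmse_ratio: float
    topology_fraction: float
    corr_tree_truth: np.ndarray
    mean_corr: float
    diagnostics: dict = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Side-by-side table shaped like the RMSE tabulations."""
        df = pd.DataFrame({
            "true_FSTH": self.true_fst_h,
            "RMSE_tree_H_x1e4": self.rmse_tree_h * 1e4,
            "RMSE_pairwise_H_x1e4": self.rmse_pairwise_h * 1e4,
            "RMSE_ratio": self.rmse_ratio,
        })
        return df

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "n_reps": self.n_reps,
            "n_excluded": self.n_excluded,
            "seed": self.seed,
            "true_fst_h": self.true_fst_h.round(6).to_dict(),
            "true_fst_w": self.true_fst_w.round(6).to_dict(),
            "rmse_tree_h": self.rmse_tree_h.round(8).to_dict(),
            "rmse_pairwise_h": self.rmse_pairwise_h.round(8).to_dict(),
            "rmse_tree_w": self.rmse_tree_w.round(8).to_dict(),
            "rmse_ratio": self.rmse_ratio.round(6).to_dict(),
            "mean_rmse_ratio": round(self.mean_rmse_ratio, 6),
            "topology_fraction": self.topology_fraction,
            "mean_corr": round(self.mean_corr, 6),
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=2)


def _pair_key(a: str, b: str) -> str:
    return "".join(sorted((a, b)))


def run_scenario(
    config: ScenarioConfig,
    n_reps: int,
    seed: int = 0,
    truth_h: pd.DataFrame | None = None,
    oracle_sites: int = 1_000_000,
) -> EvaluationReport:
    """Replicate a scenario and score both estimators against the truth.

    Parameters
    ----------
    config
        Scenario settings (tree with true theta, sample sizes, admixture).
    n_reps
        Number of simulation replicates.
    seed
        Master seed; per-replicate streams are spawned from it, so the
        report is deterministic given (config, n_reps, seed).
    truth_h
        Override for the true mismatch-form F_ST matrix; defaults to the
        tree-based closed form, or to the Monte-Carlo frequency oracle
        when admixture is active.
    """
    tips = config.tree.tips
    pairs = [(a, b) for a, b in itertools.combinations(tips, 2)]
    pair_keys = [_pair_key(a, b) for a, b in pairs]
    w_keys = pair_keys + list(tips)

    est = config.tree.coancestry_matrices()
    if truth_h is None:
        if config.admixture is not None:
            oracle_rng = np.random.default_rng(
                np.random.SeedSequence([seed, 0xAD31]))
            truth_h, _ = admixture_truth(config, oracle_sites, oracle_rng)
        else:
            truth_h = est.H
    true_h = pd.Series([truth_h.at[a, b] for a, b in pairs], index=pair_keys)
    true_w = pd.Series(
        [est.W.at[a, b] for a, b in pairs] + [est.W.at[t, t] for t in tips],
        index=w_keys)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)

    sq_tree_h = np.zeros(len(pairs))
    sq_pair_h = np.zeros(len(pairs))
    sq_tree_w = np.zeros(len(w_keys))
    corr = []
    n_correct = 0
    n_used = 0
    n_excluded = 0
    truth_vec = true_h.to_numpy()

    for child in children:
        rng = np.random.default_rng(child)
        infer_seed = int(child.generate_state(1)[0] % (2**31))
        rep = simulate_replicate(config, rng)
        try:
            hud = hudson_pairwise(rep.counts)
            res = CoancestryModel(rep.counts).fit(seed=infer_seed)
        except ValueError:
            n_excluded += 1
            continue
        hud_vec = np.array([hud.at[a, b] for a, b in pairs])
        if not np.all(np.isfinite(hud_vec)):
            n_excluded += 1
            continue
        tree_h = np.array([res.fst_h.at[a, b] for a, b in pairs])
        tree_w = np.array([res.fst_w.at[a, b] for a, b in pairs]
                          + [res.fst_w.at[t, t] for t in tips])
        sq_tree_h += (tree_h - truth_vec) ** 2
        sq_pair_h += (hud_vec - truth_vec) ** 2
        sq_tree_w += (tree_w - true_w.to_numpy()) ** 2
        if np.std(tree_h) > 0 and np.std(truth_vec) > 0:
            corr.append(float(np.corrcoef(tree_h, truth_vec)[0, 1]))
        n_correct += int(topology_equal(res.tree, config.tree))
        n_used += 1

    if n_used == 0:
        raise RuntimeError("all replicates were excluded")
    rmse_tree_h = pd.Series(np.sqrt(sq_tree_h / n_used), index=pair_keys)
    rmse_pair_h = pd.Series(np.sqrt(sq_pair_h / n_used), index=pair_keys)
    rmse_tree_w = pd.Series(np.sqrt(sq_tree_w / n_used), index=w_keys)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rmse_pair_h / rmse_tree_h
    corr_arr = np.asarray(corr)
    return EvaluationReport(
        scenario=config.name,
        n_reps=n_used,
        n_excluded=n_excluded,
        seed=seed,
        true_fst_h=true_h,
        true_fst_w=true_w,
        rmse_tree_h=rmse_tree_h,
        rmse_pairwise_h=rmse_pair_h,
        rmse_tree_w=rmse_tree_w,
        rmse_ratio=ratio,
        mean_rmse_ratio=float(ratio.mean()),
        topology_fraction=n_correct / n_used,
        corr_tree_truth=corr_arr,
        mean_corr=float(corr_arr.mean()) if corr_arr.size else float("nan"),
        diagnostics={"gametes": config.gametes_per_unit,
                     "sites": config.n_sites,
                     "alpha": None if config.admixture is None
                     else config.admixture.alpha},
    )
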