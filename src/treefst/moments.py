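"""Method-of-moments pair statistics.

For each ordered pair of units (k, k') three per-locus quantities matter:

* ``N_k = p_k (1 - p_k)`` — within-unit heterozygosity of the first unit;
* ``D_kk' = p_k (1 - p_k') + p_k' (1 - p_k)`` — the between-pair mismatch
  sum (algebraically equal to the pairwise-estimator denominator);
* ``N_kk' = (p_k - p_k')^2 - p_k(1-p_k)/(n_k-1) - p_k'(1-p_k')/(n_k'-1)``
  — the bias-corrected numerator of the pairwise (Hudson-type) estimator.

Sums over loci give the multi-locus pairwise estimator ``sum N / sum D``
(ratio of sums, for precision) and the S statistic

    S_kk' = 2 * (n_k / (n_k - 1)) * sum N_k / sum D_kk'

whose model expectation is the product of ``(1 - theta)`` over branches
ancestral to k but not k'.  With missing data the ``n/(n-1)`` factor is
applied per locus inside the sum, which preserves per-locus unbiasedness
of ``p(1-p) * n/(n-1)`` when sample sizes vary across loci.

All sums run in double precision; numpy's pairwise summation keeps them
stable at genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import AlleleCountMatrix

__all__ = ["PairSummaries", "pair_sums", "hudson_pairwise", "s_matrix"]

DEFAULT_CLIP_EPS = 1e-12


@dataclass
class PairSummaries:
    """Accumulated per-pair sums over shared non-missing loci.

    All matrices are K x K and indexed like ``unit_labels``; entry (k, k')
    refers to the *ordered* pair.  ``sum_N_first`` (heterozygosity of the
    first index) is asymmetric, as is ``S``; ``sum_D`` and
    ``sum_N_hudson`` are symmetric.  ``S_defined`` is False exactly where
    ``sum_D`` is 0 (both units fixed at every shared locus).
    ``n_harmonic`` is the per-unit harmonic mean of n_k over observed loci,
    summarising the n/(n-1) correction actually applied.
    """

    unit_labels: list[str]
    sum_N_first: np.ndarray
    sum_D: np.ndarray
    sum_N_hudson: np.ndarray
    n_loci_used: np.ndarray
    S: np.ndarray
    S_defined: np.ndarray
    n_harmonic: np.ndarray


def pair_sums(acm: AlleleCountMatrix) -> PairSummaries:
    """Accumulate N_k, D and the Hudson numerator for every ordered pair.

    Sums are over loci non-missing in *both* members of the pair.  Loci
    monomorphic in the combined pair contribute 0 to both sums
    automatically (every term vanishes), so they never bias S.
    """
    p = acm.frequencies()
    obs = ~acm.missing
    n = acm.n_gametes.astype(float)
    kk = acm.n_units

    het = p * (1.0 - p)                       # N_k per locus
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = n / (n - 1.0)
        het_corr = het / (n - 1.0)            # p(1-p)/(n-1), Hudson correction

    sum_nf = np.zeros((kk, kk))
    sum_nf_scaled = np.zeros((kk, kk))
    sum_d = np.zeros((kk, kk))
    sum_nh = np.zeros((kk, kk))
    used = np.zeros((kk, kk), dtype=np.int64)

    for a in range(kk):
        for b in range(a + 1, kk):
            m = obs[:, a] & obs[:, b]
            pa, pb = p[m, a], p[m, b]
            d = pa * (1.0 - pb) + pb * (1.0 - pa)
            sd = float(np.sum(d))
            sum_d[a, b] = sum_d[b, a] = sd
            nh = (pa - pb) ** 2 - het_corr[m, a] - het_corr[m, b]
            sum_nh[a, b] = sum_nh[b, a] = float(np.sum(nh))
            sum_nf[a, b] = float(np.sum(het[m, a]))
            sum_nf[b, a] = float(np.sum(het[m, b]))
            sum_nf_scaled[a, b] = float(np.sum(factor[m, a] * het[m, a]))
            sum_nf_scaled[b, a] = float(np.sum(factor[m, b] * het[m, b]))
            used[a, b] = used[b, a] = int(np.sum(m))

    defined = sum_d > 0.0
    np.fill_diagonal(defined, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(defined, 2.0 * sum_nf_scaled / np.where(defined, sum_d, 1.0), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_obs = np.where(obs, n, np.nan)
        n_harm = 1.0 / np.nanmean(1.0 / n_obs, axis=0)

    return PairSummaries(
        unit_labels=list(acm.unit_labels),
        sum_N_first=sum_nf,
        sum_D=sum_d,
        sum_N_hudson=sum_nh,
        n_loci_used=used,
        S=s,
        S_defined=defined,
        n_harmonic=n_harm,
    )


def hudson_pairwise(
    acm: AlleleCountMatrix | None = None,
    summaries: PairSummaries | None = None,
) -> pd.DataFrame:
    """Pairwise ratio-of-sums estimator of the mismatch-form F_ST.

    Diagonal is 0 by definition; pairs with ``sum_D == 0`` are NaN
    (undefined).  Individual entries may be negative: the pairwise
    estimator is not constrained to [0, 1].
    """
    if summaries is None:
        if acm is None:
            raise ValueError("pass an AlleleCountMatrix or a PairSummaries")
        summaries = pair_sums(acm)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = summaries.sum_N_hudson / summaries.sum_D
    f = np.where(summaries.S_defined, f, np.nan)
    np.fill_diagonal(f, 0.0)
    labels = summaries.unit_labels
    return pd.DataFrame(f, index=labels, columns=labels)


def s_matrix(ps: PairSummaries, clip_eps: float = DEFAULT_CLIP_EPS) -> pd.DataFrame:
    """Clip raw S values into (0, 1] for the logarithmic least squares.

    In finite samples S can land at 0 (first unit fixed everywhere) or
    slightly above 1; the model expectation lives in (0, 1], so values are
    clipped to ``[clip_eps, 1]``.  Undefined pairs (and the diagonal) are
    NaN and their rows are dropped by the fitting stage.
    """
    if clip_eps <= 0:
        raise ValueError("clip_eps must be positive")
    s = np.where(ps.S_defined, np.clip(ps.S, clip_eps, 1.0), np.nan)
    labels = ps.unit_labels
    return pd.DataFrame(s, index=labels, columns=labels)
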