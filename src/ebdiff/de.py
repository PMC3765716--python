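"""Differential expression with one sample per condition.

Each condition's prior is fitted separately from its own counts; the
posterior of the log fold change ``log(d * lambda_A / lambda_B)`` is an exact
finite discrete distribution (the priors are discrete, so all posteriors
are), and differential expression is declared when the posterior mass beyond
a biological-relevance cutoff ``delta`` (default ln 2) is large.  The
between-condition depth constant ``d`` is estimated from the assumption that
the trimmed majority of genes are not differentially expressed.

The exceedance probability P(|log fc| > delta) is the method's ranking score;
``1 - P`` plays the role of a p-value and is passed to Benjamini-Hochberg for
FDR control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mixing import DiscretePosterior, MixingDistribution, fit_prior, posterior_lambda

__all__ = [
    "logfc_posterior",
    "estimate_norm_constant",
    "de_test",
    "bh_adjust",
    "run_de_single",
    "rank_features",
]

DEFAULT_DELTA = float(np.log(2.0))
DEFAULT_EPSILON = 0.25

RESULT_COLUMNS = [
    "feature_id",
    "count_a",
    "count_b",
    "lambda_hat_a",
    "lambda_hat_b",
    "expected_logfc",
    "de_probability",
    "p_value",
    "fdr",
]


def _merge_atoms(atoms: np.ndarray, weights: np.ndarray, tol: float = 1e-12):
    order = np.argsort(atoms, kind="stable")
    atoms = atoms[order]
    weights = weights[order]
    # group consecutive atoms closer than tol
    new_group = np.empty(atoms.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = np.diff(atoms) > tol
    idx = np.cumsum(new_group) - 1
    merged_w = np.zeros(idx[-1] + 1)
    np.add.at(merged_w, idx, weights)
    merged_a = atoms[new_group]
    return merged_a, merged_w


def logfc_posterior(
    post_a: DiscretePosterior, post_b: DiscretePosterior, log_d: float = 0.0
) -> DiscretePosterior:
    """Exact posterior of ``log_d + log lambda_A - log lambda_B``.

    Enumerates all support pairs; atoms closer than 1e-12 are merged.
    """
    if np.any(post_a.support <= 0) or np.any(post_b.support <= 0):
        raise ValueError("inputs must be lambda-posteriors with positive support")
    atoms = (log_d + np.log(post_a.support)[:, None] - np.log(post_b.support)[None, :]).ravel()
    weights = (post_a.weights[:, None] * post_b.weights[None, :]).ravel()
    merged_a, merged_w = _merge_atoms(atoms, weights)
    return DiscretePosterior(merged_a, merged_w / merged_w.sum())


def estimate_norm_constant(
    posteriors_a, posteriors_b, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Between-condition normalisation offset log d via trimmed mean.

    Per gene, ``m_i = E[log lambda_A | x_A] - E[log lambda_B | x_B]``; genes
    inside the (epsilon, 1-epsilon) quantiles of m (inclusive) are averaged
    and ``log d = -trimmed_mean``, so the trimmed mean of ``log_d + m_i``
    vanishes: the majority of genes are assumed non-differential.
    """
    if len(posteriors_a) != len(posteriors_b):
        raise ValueError("paired posterior lists must have equal length")
    if len(posteriors_a) == 0:
        raise ValueError("no genes to estimate the normalisation constant from")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    m = np.array([a.log_mean() - b.log_mean() for a, b in zip(posteriors_a, posteriors_b)])
    return _trimmed_offset(m, epsilon)


def _trimmed_offset(m: np.ndarray, epsilon: float) -> float:
    lo, hi = np.quantile(m, [epsilon, 1.0 - epsilon])
    kept = m[(m >= lo) & (m <= hi)]
    if kept.size < 10:
        warnings.warn(
            f"only {kept.size} genes in the trimmed set; log d is unstable",
            stacklevel=3,
        )
    return float(-kept.mean())


def de_test(logfc_post: DiscretePosterior, delta: float = DEFAULT_DELTA):
    """Exceedance test: P(|log fc| > delta) and its complement.

    Returns ``(de_probability, p_value)`` with ``p_value = 1 - de_probability``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    de_p = float(logfc_post.weights[np.abs(logfc_post.support) > delta].sum())
    de_p = min(max(de_p, 0.0), 1.0)
    return de_p, 1.0 - de_p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_features(results: pd.DataFrame) -> pd.DataFrame:
    """Order a results table by evidence for differential expression.

    Descending exceedance probability, ties broken by |expected log fc|
    descending, then feature_id for full determinism.
    """
    key = results.assign(_abs_lfc=results["expected_logfc"].abs())
    key = key.sort_values(
        ["de_probability", "_abs_lfc", "feature_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    return key.drop(columns="_abs_lfc")


def run_de_single(
    counts_a,
    counts_b,
    delta: float = DEFAULT_DELTA,
    epsilon: float = DEFAULT_EPSILON,
    feature_ids=None,
    grid=None,
    priors: tuple[MixingDistribution, MixingDistribution] | None = None,
) -> pd.DataFrame:
    """End-to-end single-replicate differential expression.

    Fits a prior per condition, estimates the between-condition offset log d,
    and scores every gene by the posterior probability that its absolute log
    fold change exceeds ``delta``.  Deterministic: no sampling anywhere, and
    genes with identical count pairs receive identical records.

    Returns a DataFrame (input gene order) with the fitted ``log_d`` and the
    priors stored in ``.attrs``.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    if counts_a.shape != counts_b.shape or counts_a.ndim != 1:
        raise ValueError("count vectors must be 1-D over the same gene universe")
    if feature_ids is None:
        feature_ids = [f"gene_{i}" for i in range(counts_a.size)]

    if priors is None:
        g_a = fit_prior(counts_a, grid=grid)
        g_b = fit_prior(counts_b, grid=grid)
    else:
        g_a, g_b = priors

    post_a, elog_a, mean_a = _posterior_cache(g_a, counts_a)
    post_b, elog_b, mean_b = _posterior_cache(g_b, counts_b)

    m = elog_a[counts_a] - elog_b[counts_b]
    log_d = _trimmed_offset(m, epsilon)

    # The logfc atom layout is shared by every gene pair: precompute the
    # exceedance indicator once and score each unique count pair by two
    # weight contractions.
    diff = log_d + np.log(g_a.support)[:, None] - np.log(g_b.support)[None, :]
    exceed = (np.abs(diff) > delta).astype(float)

    pairs = counts_a.astype(np.int64) * (counts_b.max() + 1) + counts_b
    _, first, inverse = np.unique(pairs, return_index=True, return_inverse=True)
    de_p_unique = np.empty(first.size)
    for u, gi in enumerate(first):
        wa = post_a[counts_a[gi]].weights
        wb = post_b[counts_b[gi]].weights
        de_p_unique[u] = float(wa @ exceed @ wb)
    de_probability = np.clip(de_p_unique[inverse], 0.0, 1.0)
    p_value = 1.0 - de_probability

    results = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "count_a": counts_a,
            "count_b": counts_b,
            "lambda_hat_a": mean_a[counts_a],
            "lambda_hat_b": mean_b[counts_b],
            "expected_logfc": log_d + m,
            "de_probability": de_probability,
            "p_value": p_value,
            "fdr": bh_adjust(p_value),
        }
    )
    results.attrs["log_d"] = log_d
    results.attrs["prior_a"] = g_a
    results.attrs["prior_b"] = g_b
    return results


def _posterior_cache(g: MixingDistribution, counts: np.ndarray):
    """Posterior, E[log lambda] and posterior mean for every count value seen.

    Indexed by count value so identical counts share one record exactly.
    """
    unique = np.unique(counts)
    posts: dict[int, DiscretePosterior] = {}
    elog = np.full(int(counts.max()) + 1, np.nan)
    mean = np.full(int(counts.max()) + 1, np.nan)
    for x in unique:
        post = posterior_lambda(g, int(x))
        posts[int(x)] = post
        elog[int(x)] = post.log_mean()
        mean[int(x)] = post.mean()
    return posts, elog, mean
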