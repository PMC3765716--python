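"""Nonparametric prior estimation for RNA-seq read counts.

The observed read count of a gene is modelled as Poisson with mean
``lambda = gamma * d * l`` (expression level x depth x length; length is fixed
to 1 throughout, since fold-change inference cancels it).  The prior over
``lambda`` is a *discrete mixing distribution* G estimated nonparametrically
from all genes in a sample: conditioning on a gene being seen (x >= 1) the
counts follow a mixture of zero-truncated Poissons with mixing distribution Q,
and the conditional nonparametric maximum likelihood estimate (NPMLE) of Q is
computed by EM over a fixed candidate grid.  Q and G are in one-to-one
correspondence through the tilt ``dQ(lambda) ∝ (1 - e^-lambda) dG(lambda)``,
so the fitted prior also prices genes with zero observed reads.

All mixture arithmetic is carried out in log space so that counts in the 1e5
range do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "MixingDistribution",
    "CountFrequencyTable",
    "DiscretePosterior",
    "fit_npmle",
    "fit_prior",
    "q_to_g",
    "g_to_q",
    "mixture_pmf",
    "log_mixture_pmf",
    "eb_estimate",
    "posterior_lambda",
    "default_grid",
]


@dataclass(frozen=True)
class MixingDistribution:
    """Discrete prior over expression levels: support points and weights.

    ``support`` holds expression levels (strictly positive, strictly
    increasing); ``weights`` are the prior probabilities, summing to one.
    """

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        if support.ndim != 1 or weights.ndim != 1:
            raise ValueError("support and weights must be 1-D")
        if support.size != weights.size or support.size < 1:
            raise ValueError("support and weights must have equal length >= 1")
        if not np.all(support > 0):
            raise ValueError("support values must be strictly positive")
        if not np.all(np.diff(support) > 0):
            raise ValueError("support must be strictly increasing without duplicates")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1 within 1e-10")

    def mean(self) -> float:
        return float(np.dot(self.support, self.weights))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.support - m) ** 2, self.weights))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.support.size


@dataclass(frozen=True)
class CountFrequencyTable:
    """Distinct observed counts and their gene frequencies.

    The zero-count frequency ``n0`` is carried along (it is needed to price
    unseen genes) but excluded from the conditional NPMLE objective, which
    conditions on x >= 1.
    """

    counts: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        freqs = np.asarray(self.frequencies, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "frequencies", freqs)
        if counts.ndim != 1 or freqs.ndim != 1 or counts.size != freqs.size:
            raise ValueError("counts and frequencies must be 1-D of equal length")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.diff(counts) <= 0):
            raise ValueError("counts must be distinct and sorted ascending")
        if np.any(freqs < 1):
            raise ValueError("frequencies must be >= 1")

    @classmethod
    def from_counts(cls, counts) -> "CountFrequencyTable":
        counts = np.asarray(counts)
        if counts.size == 0:
            raise ValueError("empty count vector")
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValueError("counts must be nonnegative integers")
        values, freqs = np.unique(counts.astype(np.int64), return_counts=True)
        return cls(values, freqs)

    @property
    def n0(self) -> int:
        """Number of genes with zero observed reads."""
        if self.counts.size and self.counts[0] == 0:
            return int(self.frequencies[0])
        return 0

    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.counts >= 1
        return self.counts[mask], self.frequencies[mask]


@dataclass(frozen=True)
class DiscretePosterior:
    """A discrete distribution over a finite support (lambda or log fold change)."""

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        if support.size != weights.size or support.size < 1:
            raise ValueError("support and weights must have equal length >= 1")
        if np.any(weights < -1e-15):
            raise ValueError("weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1 within 1e-10")

    def mean(self) -> float:
        return float(np.dot(self.support, self.weights))

    def log_mean(self) -> float:
        """E[log(support)] — only meaningful for positive support."""
        return float(np.dot(np.log(self.support), self.weights))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.support.size


# ---------------------------------------------------------------------------
# NPMLE of the mixing distribution
# ---------------------------------------------------------------------------

def default_grid(counts, n_points: int = 400, margin: float = 1.25) -> np.ndarray:
    """Geometric candidate grid spanning the observed counts.

    Runs from ``max(0.01, min positive count / 10)`` to ``margin * max count``.
    """
    counts = np.asarray(counts, dtype=float)
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError("no expressed genes")
    lo = max(0.01, positive.min() / 10.0)
    hi = margin * counts.max()
    if hi <= lo:
        hi = lo * 10.0
    return np.geomspace(lo, hi, n_points)


def _log_truncated_poisson(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log pmf of the zero-truncated Poisson, shape (len(x), len(lam)).

    log f(x; lam) = x log lam - log(x!) - log(e^lam - 1); the last term is
    evaluated as lam + log1p(-e^-lam) to stay finite for large lam.
    """
    x = x[:, None].astype(float)
    lam = lam[None, :]
    log_denom = lam + np.log1p(-np.exp(-lam))
    return x * np.log(lam) - gammaln(x + 1.0) - log_denom


def fit_npmle(
    table: CountFrequencyTable,
    grid=None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    prune: float = 1e-8,
) -> MixingDistribution:
    """Conditional NPMLE of the mixing distribution Q of the truncated mixture.

    Maximises ``sum_{x>=1} n_x log f_Q(x)`` with
    ``f_Q(x) = ∫ lambda^x / (x! (e^lambda - 1)) dQ(lambda)`` by EM over a fixed
    candidate grid, starting from uniform weights (deterministic).  Support
    points whose converged weight falls below ``prune`` are dropped.

    Parameters
    ----------
    table:
        Observed count/frequency table; zero counts are ignored here.
    grid:
        Candidate support points; defaults to :func:`default_grid` on the
        table's counts.
    tol:
        Stop when the conditional log-likelihood improves by less than this.
    max_iter:
        Iteration cap for the EM loop.
    """
    x, n = table.positive()
    if x.size == 0:
        raise ValueError("no expressed genes")
    if grid is None:
        grid = default_grid(table.counts)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty candidate grid")
    if np.any(grid <= 0):
        raise ValueError("grid points must be strictly positive")
    grid = np.unique(grid)

    log_f = _log_truncated_poisson(x, grid)  # (U, K)
    n = n.astype(float)
    total = n.sum()
    # scale each count's component likelihoods to max 1 so the EM loop can
    # run in linear space without underflow; the scaling constant is
    # restored in the log-likelihood
    row_max = log_f.max(axis=1)
    f_scaled = np.exp(log_f - row_max[:, None])
    q = np.full(grid.size, 1.0 / grid.size)

    last_ll = -np.inf
    for _ in range(max_iter):
        marg = f_scaled @ q  # (U,)
        ll = float(np.dot(n, np.log(marg) + row_max))
        # E-step responsibilities folded into the M-step update
        q = q * (f_scaled.T @ (n / marg)) / total
        q = np.clip(q, 0.0, None)
        q /= q.sum()
        if ll - last_ll < tol and np.isfinite(last_ll):
            last_ll = ll
            break
        last_ll = ll
    keep = q >= prune
    if not np.any(keep):
        keep = q == q.max()
    q = q[keep]
    q /= q.sum()
    return MixingDistribution(grid[keep], q)


def conditional_log_likelihood(q: MixingDistribution, table: CountFrequencyTable) -> float:
    """``sum_{x>=1} n_x log f_Q(x)`` for any candidate mixing distribution."""
    x, n = table.positive()
    log_f = _log_truncated_poisson(x, q.support)
    with np.errstate(divide="ignore"):
        log_w = np.log(q.weights)
    return float(np.dot(n.astype(float), logsumexp(log_w[None, :] + log_f, axis=1)))


def q_to_g(q: MixingDistribution) -> MixingDistribution:
    """Map the truncated-mixture prior Q back to the full prior G.

    ``g_k ∝ q_k / (1 - e^{-lambda_k})`` on the same support.
    """
    tilt = -np.expm1(-q.support)
    w = q.weights / tilt
    return MixingDistribution(q.support, w / w.sum())


def g_to_q(g: MixingDistribution) -> MixingDistribution:
    """Inverse of :func:`q_to_g`: ``q_k ∝ g_k (1 - e^{-lambda_k})``."""
    w = g.weights * (-np.expm1(-g.support))
    return MixingDistribution(g.support, w / w.sum())


def fit_prior(counts, grid=None, tol: float = 1e-8, max_iter: int = 5000) -> MixingDistribution:
    """Fit the full prior G from a raw count vector (NPMLE of Q, then untilt)."""
    table = CountFrequencyTable.from_counts(counts)
    if table.positive()[0].size == 0:
        raise ValueError("no expressed genes")
    if grid is None:
        grid = default_grid(table.counts)
    return q_to_g(fit_npmle(table, grid=grid, tol=tol, max_iter=max_iter))


# ---------------------------------------------------------------------------
# Mixture pmf and empirical-Bayes posterior machinery
# ---------------------------------------------------------------------------

def log_mixture_pmf(g: MixingDistribution, x) -> np.ndarray:
    """log h_G(x) = log ∫ lambda^x e^-lambda / x! dG(lambda), vectorised in x."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0) or np.any(x_arr != np.floor(x_arr)):
        raise ValueError("x must be a nonnegative integer")
    with np.errstate(divide="ignore"):
        log_w = np.log(g.weights)
    lam = g.support
    terms = (
        log_w[None, :]
        + x_arr[:, None] * np.log(lam)[None, :]
        - lam[None, :]
        - gammaln(x_arr + 1.0)[:, None]
    )
    out = logsumexp(terms, axis=1)
    return out if np.ndim(x) else float(out[0])


def mixture_pmf(g: MixingDistribution, x) -> np.ndarray:
    """Marginal probability h_G(x) of observing x reads under prior G."""
    return np.exp(log_mixture_pmf(g, x))


def eb_estimate(g: MixingDistribution, x: int) -> float:
    """Empirical-Bayes (posterior-mean) expression estimate for count x.

    ``lambda_hat = (x + 1) h_G(x + 1) / h_G(x)`` — finite and positive for any
    x within the reach of the prior, including x = 0.
    """
    log_h = log_mixture_pmf(g, [x, x + 1])
    if not np.isfinite(log_h[0]):
        raise ValueError("count outside prior support; refit with wider grid")
    return float(np.exp(np.log(x + 1.0) + log_h[1] - log_h[0]))


def posterior_lambda(g: MixingDistribution, x: int) -> DiscretePosterior:
    """Posterior of lambda given count x: weights ∝ g_k lambda_k^x e^-lambda_k."""
    if x < 0 or x != int(x):
        raise ValueError("x must be a nonnegative integer")
    with np.errstate(divide="ignore"):
        log_w = np.log(g.weights) + x * np.log(g.support) - g.support
    norm = logsumexp(log_w)
    if not np.isfinite(norm):
        raise ValueError("count outside prior support; refit with wider grid")
    return DiscretePosterior(g.support, np.exp(log_w - norm))
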