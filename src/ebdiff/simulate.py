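"""Count simulators and ranking metrics for benchmarking.

Three designs, mirroring the usual two-condition benchmark layouts:

* ``dataset2`` — no replicates, Poisson counts; a fixed fraction of genes is
  differentially expressed with fold factor b (half up, half 1/b down).
* ``dataset3`` — like dataset2 but with biological replicates and Gamma
  over-dispersion (negative-binomial counts).
* ``dataset1`` — replicates with a *different* prior per condition; every
  gene's truth is its realised |log fold change| and the benchmark is purely
  about ranking.

Library size means the expected total count of a sample; the per-sample
depth factor is chosen as ``d = library_size / sum(lambda)`` so the expected
total matches the drawn size, while realised totals fluctuate by sampling.

Synthetic priors replace the empirical ones a real study would fit from deep
reference samples.  The default family reproduces the canonical RNA-seq
shape: a large spike of lowly expressed genes, a log-normal body and a heavy
right tail of a few very highly expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve

from .mixing import MixingDistribution
from .replicates import CountMatrix

__all__ = [
    "SimulationTruth",
    "make_synthetic_prior",
    "simulate_dataset1",
    "simulate_dataset2",
    "simulate_dataset3",
    "simulate_exon_dataset",
    "p_tau",
    "roc_points",
]


@dataclass
class SimulationTruth:
    """Per-gene ground truth emitted alongside a simulated count matrix.

    ``genes`` has columns lambda_a, lambda_b, is_de, b, true_abs_logfc;
    ``library_sizes`` / ``norm_constants`` are per sample (matching the
    CountMatrix column order)."""

    genes: pd.DataFrame
    library_sizes: np.ndarray
    norm_constants: np.ndarray
    seed: object
    scheme: str

    def ranking(self) -> list:
        """Feature ids ordered by decreasing true |log fold change|."""
        order = self.genes["true_abs_logfc"].to_numpy().argsort(kind="stable")[::-1]
        return list(self.genes.index[order])


# ---------------------------------------------------------------------------
# Synthetic priors
# ---------------------------------------------------------------------------

def make_synthetic_prior(
    shape: str = "figure1", seed: int = 0, n_points: int = 250, **params
) -> MixingDistribution:
    """Build a synthetic discrete expression prior.

    Families
    --------
    ``figure1`` (default)
        Low-expression exponential spike + log-normal body + Pareto right
        tail, discretised on a geometric grid from 0.05 to 5000: most genes
        lowly expressed, a few consuming a large share of the reads.  The
        seed jitters the component parameters slightly so replicate
        benchmark runs use distinct but equally shaped priors.
    ``lognormal``
        Discretised log-normal with moderate tails (``meanlog``, ``sdlog``);
        suitable when finite, stable higher moments are required (e.g.
        moment-based dispersion estimation).
    ``two-point``
        Point masses at ``support`` with ``weights`` (exact, no jitter).
    """
    rng = np.random.default_rng(seed)
    if shape == "two-point":
        support = np.asarray(params.get("support", (2.0, 50.0)), dtype=float)
        weights = np.asarray(params.get("weights", (0.7, 0.3)), dtype=float)
        return MixingDistribution(support, weights / weights.sum())

    grid = np.geomspace(params.get("min_lambda", 0.05), params.get("max_lambda", 5000.0), n_points)
    # trapezoid-style cell widths for discretising densities on the grid
    widths = np.empty_like(grid)
    widths[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    widths[0] = grid[1] - grid[0]
    widths[-1] = grid[-1] - grid[-2]

    if shape == "lognormal":
        meanlog = params.get("meanlog", np.log(30.0))
        sdlog = params.get("sdlog", 0.25)
        dens = np.exp(-0.5 * ((np.log(grid) - meanlog) / sdlog) ** 2) / grid
    elif shape == "figure1":
        spike_scale = 2.0 * np.exp(rng.normal(0.0, 0.05))
        meanlog = np.log(30.0) + rng.normal(0.0, 0.1)
        sdlog = 1.2
        tail_min, tail_alpha = 50.0, 0.5
        spike = np.exp(-grid / spike_scale) / spike_scale
        body = np.exp(-0.5 * ((np.log(grid) - meanlog) / sdlog) ** 2) / (
            grid * sdlog * np.sqrt(2 * np.pi)
        )
        tail = np.where(grid >= tail_min, grid ** (-1.0 - tail_alpha), 0.0)
        tail = tail / max((tail * widths).sum(), 1e-300)
        spike = spike / (spike * widths).sum()
        body = body / (body * widths).sum()
        dens = 0.55 * spike + 0.35 * body + 0.10 * tail
    else:
        raise ValueError(f"unknown synthetic prior family {shape!r}")

    w = dens * widths
    return MixingDistribution(grid, w / w.sum())


def _sample_lambda(prior: MixingDistribution, u: np.ndarray) -> np.ndarray:
    """Inverse-cdf draw so equal priors + shared uniforms give equal draws."""
    cum = np.cumsum(prior.weights)
    cum[-1] = 1.0
    return prior.support[np.searchsorted(cum, u, side="left")]


def _check_libsize(libsize_range) -> tuple[float, float]:
    lo, hi = libsize_range
    if not (0 < lo <= hi):
        raise ValueError("library size range must satisfy 0 < low <= high")
    return float(lo), float(hi)


def _assign_de(rng, n_genes: int, n_de: int, fold: float):
    if n_de % 2 != 0:
        raise ValueError("n_de must be even (half up-, half down-regulated)")
    if not 0 <= n_de <= n_genes:
        raise ValueError("n_de must be between 0 and n_genes")
    b = np.ones(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    b[de_idx[: n_de // 2]] = fold
    b[de_idx[n_de // 2 :]] = 1.0 / fold
    return b, np.isin(np.arange(n_genes), de_idx)


def _nb_counts(rng, lam: np.ndarray, theta: float, d: float) -> np.ndarray:
    """One replicate: Poisson(d * e) with e ~ Gamma(shape lam/theta, scale theta)."""
    if theta <= 0:
        return rng.poisson(d * lam)
    e = rng.gamma(shape=lam / theta, scale=theta)
    return rng.poisson(d * e)


def _truth_frame(feature_ids, lam_a, lam_b, is_de, b) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lambda_a": lam_a,
            "lambda_b": lam_b,
            "is_de": is_de,
            "b": b,
            "true_abs_logfc": np.abs(np.log(lam_a) - np.log(lam_b)),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def simulate_dataset2(
    prior: MixingDistribution,
    n_genes: int = 10_000,
    n_de: int = 1_000,
    fold: float = 4.0,
    libsize_range=(300_000, 900_000),
    seed=None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Poisson counts, one sample per condition, shared prior.

    lambda_B is drawn from the prior; differential genes get
    ``lambda_A = b * lambda_B`` with b = fold for half of them and 1/fold for
    the other half.
    """
    lo, hi = _check_libsize(libsize_range)
    rng = np.random.default_rng(seed)
    lam_b = _sample_lambda(prior, rng.uniform(size=n_genes))
    b, is_de = _assign_de(rng, n_genes, n_de, fold)
    lam_a = b * lam_b

    libs = rng.uniform(lo, hi, size=2)
    d = np.array([libs[0] / lam_a.sum(), libs[1] / lam_b.sum()])
    counts = np.column_stack([rng.poisson(d[0] * lam_a), rng.poisson(d[1] * lam_b)])

    ids = [f"gene_{i}" for i in range(n_genes)]
    matrix = CountMatrix(ids, ["A_1", "B_1"], ["A", "B"], counts, d)
    truth = SimulationTruth(_truth_frame(ids, lam_a, lam_b, is_de, b), libs, d, seed, "dataset2")
    return matrix, truth


def simulate_dataset3(
    prior: MixingDistribution,
    theta: float,
    n_genes: int = 10_000,
    n_de: int = 1_000,
    fold: float = 4.0,
    n_reps: int = 7,
    libsize_range=(300_000, 900_000),
    seed=None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Negative-binomial counts with ``n_reps`` replicates per condition."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n_reps < 2:
        raise ValueError("dataset3 needs at least two replicates per condition")
    lo, hi = _check_libsize(libsize_range)
    rng = np.random.default_rng(seed)
    lam_b = _sample_lambda(prior, rng.uniform(size=n_genes))
    b, is_de = _assign_de(rng, n_genes, n_de, fold)
    lam_a = b * lam_b

    libs = rng.uniform(lo, hi, size=2 * n_reps)
    d = np.concatenate([libs[:n_reps] / lam_a.sum(), libs[n_reps:] / lam_b.sum()])
    cols = []
    for j in range(n_reps):
        cols.append(_nb_counts(rng, lam_a, theta, d[j]))
    for j in range(n_reps):
        cols.append(_nb_counts(rng, lam_b, theta, d[n_reps + j]))

    ids = [f"gene_{i}" for i in range(n_genes)]
    samples = [f"A_{j+1}" for j in range(n_reps)] + [f"B_{j+1}" for j in range(n_reps)]
    labels = ["A"] * n_reps + ["B"] * n_reps
    matrix = CountMatrix(ids, samples, labels, np.column_stack(cols), d)
    truth = SimulationTruth(_truth_frame(ids, lam_a, lam_b, is_de, b), libs, d, seed, "dataset3")
    return matrix, truth


def simulate_dataset1(
    prior_a: MixingDistribution,
    prior_b: MixingDistribution,
    theta_a: float,
    theta_b: float,
    n_genes: int = 10_000,
    n_reps: int = 7,
    libsize_range=(300_000, 900_000),
    seed=None,
    share_lambda_draws: bool = False,
) -> tuple[CountMatrix, SimulationTruth]:
    """Replicated counts with a different prior per condition.

    Each condition's expression levels are drawn from its own prior; the
    ground truth for ranking is the realised |log(lambda_A / lambda_B)|.
    With ``share_lambda_draws`` both conditions reuse the same uniforms, so
    identical priors give identical expression (an exact null).
    """
    lo, hi = _check_libsize(libsize_range)
    rng = np.random.default_rng(seed)
    u_a = rng.uniform(size=n_genes)
    u_b = u_a if share_lambda_draws else rng.uniform(size=n_genes)
    lam_a = _sample_lambda(prior_a, u_a)
    lam_b = _sample_lambda(prior_b, u_b)

    libs = rng.uniform(lo, hi, size=2 * n_reps)
    d = np.concatenate([libs[:n_reps] / lam_a.sum(), libs[n_reps:] / lam_b.sum()])
    cols = [_nb_counts(rng, lam_a, theta_a, d[j]) for j in range(n_reps)]
    cols += [_nb_counts(rng, lam_b, theta_b, d[n_reps + j]) for j in range(n_reps)]

    ids = [f"gene_{i}" for i in range(n_genes)]
    samples = [f"A_{j+1}" for j in range(n_reps)] + [f"B_{j+1}" for j in range(n_reps)]
    labels = ["A"] * n_reps + ["B"] * n_reps
    matrix = CountMatrix(ids, samples, labels, np.column_stack(cols), d)
    b = lam_a / lam_b
    truth = SimulationTruth(
        _truth_frame(ids, lam_a, lam_b, b != 1.0, b), libs, d, seed, "dataset1"
    )
    return matrix, truth


def simulate_exon_dataset(
    gene_lambda_a,
    gene_lambda_b,
    proportions_a,
    proportions_b,
    seed=None,
):
    """Simulate counting-bin counts for a set of genes.

    ``gene_lambda_*`` give each gene's expression level per condition;
    ``proportions_*`` give, per gene, the share of the gene's reads falling
    in each of its bins (rows sum to 1; one row per gene, ragged lists
    allowed).  Gene counts are Poisson(lambda); bin k counts are
    Poisson(lambda * p_k).

    Returns ``(bins_a, bins_b, gene_counts_a, gene_counts_b)`` in the layout
    :func:`ebdiff.exons.run_exon_usage` expects.
    """
    rng = np.random.default_rng(seed)
    lam_a = np.asarray(gene_lambda_a, dtype=float)
    lam_b = np.asarray(gene_lambda_b, dtype=float)
    if lam_a.size != lam_b.size or lam_a.size != len(proportions_a):
        raise ValueError("per-gene inputs must have equal length")
    rows = []
    for i in range(lam_a.size):
        p_a = np.asarray(proportions_a[i], dtype=float)
        p_b = np.asarray(proportions_b[i], dtype=float)
        if p_a.size != p_b.size:
            raise ValueError("bin layout must match between conditions")
        for k in range(p_a.size):
            rows.append(
                (
                    f"gene_{i}",
                    f"gene_{i}:{k:03d}",
                    rng.poisson(lam_a[i] * p_a[k]),
                    rng.poisson(lam_b[i] * p_b[k]),
                )
            )
    table = pd.DataFrame(rows, columns=["gene_id", "bin_id", "count_a", "count_b"])
    bins_a = table[["gene_id", "bin_id"]].assign(sample_1=table["count_a"])
    bins_b = table[["gene_id", "bin_id"]].assign(sample_1=table["count_b"])
    ids = [f"gene_{i}" for i in range(lam_a.size)]
    gene_counts_a = pd.Series(rng.poisson(lam_a), index=ids, name="sample_1")
    gene_counts_b = pd.Series(rng.poisson(lam_b), index=ids, name="sample_1")
    return bins_a, bins_b, gene_counts_a, gene_counts_b


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def p_tau(ranking, truth_ranking, tau: int) -> float:
    """Fraction of the true top-tau features recovered in a method's top tau."""
    n = len(truth_ranking)
    if not 1 <= tau <= n:
        raise ValueError(f"tau must be in [1, {n}]")
    return len(set(ranking[:tau]) & set(truth_ranking[:tau])) / tau


def roc_points(scores, truth):
    """ROC curve of a score against binary truth labels.

    Returns ``(fpr, tpr, area)``; equal scores are grouped into one step.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        raise ValueError("truth labels contain a single class; ROC undefined")
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    return fpr, tpr, float(auc(fpr, tpr))
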