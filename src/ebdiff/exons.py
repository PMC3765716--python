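"""Differential exon usage via counting bins.

When transcripts of a gene disagree on exon boundaries, the exonic union is
cut at every distinct boundary into *counting bins*, so each bin belongs to a
fixed set of transcripts (the flattened, DEXSeq-style annotation).  Bin read
counts are modelled with the same discrete empirical-Bayes machinery as
genes: a bin-level prior is fitted per condition, each bin gets a posterior
over its expression level t given its count y, and the tested statistic is
the change in *relative* usage

    | log(t_Ak / E[lambda_A | x_A]) - log(t_Bk / E[lambda_B | x_B]) | > delta,

where E[lambda | x] is the gene-level empirical-Bayes expression of the host
gene, treated as a known scalar.  A uniform gene-level fold change therefore
cancels; only shifts in the share of the gene's reads falling in the bin
score highly.  The default cutoff log 3 targets "exon switch" events: bins
whose inclusion level changes more than three-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import bh_adjust
from .mixing import MixingDistribution, fit_prior, posterior_lambda
from .replicates import (
    _replicate_log_weights,
    deepest_sample,
    estimate_theta_replicates,
    quantile_normalize_within,
)
from scipy.special import logsumexp

__all__ = [
    "CountingBin",
    "flatten_counting_bins",
    "flatten_gene_models",
    "run_exon_usage",
    "read_gtf_exons",
    "write_flattened_gff",
]

DEFAULT_EXON_DELTA = float(np.log(3.0))


@dataclass(frozen=True)
class CountingBin:
    """A minimal exonic interval (0-based half-open) covered by a fixed
    transcript set of its gene."""

    gene_id: str
    bin_id: str
    chromosome: str
    start: int
    end: int
    transcripts: tuple = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid bin interval [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def flatten_counting_bins(
    transcript_exons: dict, gene_id: str = "gene", chromosome: str = "."
) -> list[CountingBin]:
    """Cut a gene's exons into counting bins at every distinct boundary.

    ``transcript_exons`` maps transcript id -> list of (start, end) 0-based
    half-open exon intervals.  The exonic union is partitioned at every exon
    boundary; sub-intervals covered by no exon are dropped.  Each bin records
    the transcripts containing it.  Bin ids are ``gene_id:NNN`` with a
    zero-padded rank.  The operation is idempotent.
    """
    intervals = []
    for tid, exons in transcript_exons.items():
        for start, end in exons:
            if end <= start:
                raise ValueError(
                    f"malformed exon [{start}, {end}) in transcript {tid} of gene {gene_id}"
                )
            intervals.append((int(start), int(end), tid))
    if not intervals:
        return []
    boundaries = np.unique([b for s, e, _ in intervals for b in (s, e)])
    bins = []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        covering = tuple(sorted({tid for cs, ce, tid in intervals if cs <= s and e <= ce}))
        if covering:
            bins.append((int(s), int(e), covering))
    return [
        CountingBin(gene_id, f"{gene_id}:{i:03d}", chromosome, s, e, tids)
        for i, (s, e, tids) in enumerate(bins)
    ]


def flatten_gene_models(genes: dict) -> list[CountingBin]:
    """Flatten several genes at once.

    ``genes`` maps gene_id -> (chromosome, {transcript_id: [(start, end), ...]}).
    """
    out = []
    for gene_id, (chrom, transcripts) in genes.items():
        out.extend(flatten_counting_bins(transcripts, gene_id=gene_id, chromosome=chrom))
    return out


# ---------------------------------------------------------------------------
# GTF/GFF2 bridging (1-based inclusive on disk, 0-based half-open in memory)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf_exons(path) -> dict:
    """Read exon features from a GTF/GFF2 file into gene models.

    Returns ``{gene_id: (chromosome, {transcript_id: [(start, end), ...]})}``
    with 0-based half-open coordinates; strand is ignored (bins are
    strand-agnostic within a gene).
    """
    genes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            tx_id = attrs.get("transcript_id")
            if gene_id is None or tx_id is None:
                raise ValueError(f"{path}:{lineno}: exon lacks gene_id/transcript_id")
            start = int(fields[3]) - 1  # to 0-based half-open
            end = int(fields[4])
            chrom, transcripts = genes.setdefault(gene_id, (fields[0], {}))
            transcripts.setdefault(tx_id, []).append((start, end))
    return genes


def write_flattened_gff(bins: list[CountingBin], path) -> None:
    """Write counting bins as GFF lines (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for b in bins:
            attrs = f'gene_id "{b.gene_id}"; bin_id "{b.bin_id}"; transcripts "{"+".join(b.transcripts)}"'
            fh.write(
                "\t".join(
                    [
                        b.chromosome,
                        "ebdiff",
                        "counting_bin",
                        str(b.start + 1),
                        str(b.end),
                        ".",
                        ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Differential usage test
# ---------------------------------------------------------------------------

def _condition_posteriors(counts: np.ndarray, grid=None):
    """Fit a prior on the deepest (normalised) sample and return per-feature
    posterior weight matrix plus the prior.  Single-sample input uses the
    plain Poisson posterior; replicates go through the hierarchical model."""
    counts = np.atleast_2d(counts)
    norm = quantile_normalize_within(counts)
    ref = deepest_sample(counts)
    g = fit_prior(norm[:, ref], grid=grid)
    theta = estimate_theta_replicates(norm)
    log_w = _replicate_log_weights(norm, g, theta, np.ones(norm.shape[1]))
    W = np.exp(log_w - logsumexp(log_w, axis=1, keepdims=True))
    return W, g


def _as_count_matrix(table: pd.DataFrame, value_columns) -> np.ndarray:
    arr = table[list(value_columns)].to_numpy()
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("bin counts must be nonnegative integers")
        arr = arr.astype(np.int64)
    return arr


def run_exon_usage(
    bins_a: pd.DataFrame,
    bins_b: pd.DataFrame,
    gene_counts_a,
    gene_counts_b,
    delta: float = DEFAULT_EXON_DELTA,
    grid=None,
) -> pd.DataFrame:
    """Test every counting bin for differential usage between two conditions.

    ``bins_a``/``bins_b`` are DataFrames with columns ``gene_id``, ``bin_id``
    and one or more sample count columns (same bin order in both).
    ``gene_counts_a``/``gene_counts_b`` are gene-level count Series (indexed
    by gene_id) or single-column DataFrames / matrices of replicate columns.

    Bin posteriors are scaled by the host gene's empirical-Bayes expression
    E[lambda | x]; the exceedance probability of the shifted log-ratio beyond
    ``delta`` is reported per bin, with Benjamini-Hochberg FDR across all
    tested bins.  Bins whose gene is absent from the gene-level table are
    flagged ``untestable``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if not bins_a["bin_id"].equals(bins_b["bin_id"]):
        raise ValueError("bin tables must list the same bins in the same order")
    meta_cols = {"gene_id", "bin_id"}
    samp_a = [c for c in bins_a.columns if c not in meta_cols]
    samp_b = [c for c in bins_b.columns if c not in meta_cols]

    y_a = _as_count_matrix(bins_a, samp_a)
    y_b = _as_count_matrix(bins_b, samp_b)
    W_a, g_bin_a = _condition_posteriors(y_a, grid=grid)
    W_b, g_bin_b = _condition_posteriors(y_b, grid=grid)

    gene_mean_a = _gene_eb_means(gene_counts_a, grid=grid)
    gene_mean_b = _gene_eb_means(gene_counts_b, grid=grid)

    genes = bins_a["gene_id"].to_numpy()
    testable = np.array(
        [
            g in gene_mean_a.index
            and g in gene_mean_b.index
            and np.isfinite(gene_mean_a[g])
            and gene_mean_a[g] > 0
            and np.isfinite(gene_mean_b[g])
            and gene_mean_b[g] > 0
            for g in genes
        ]
    )

    log_sup = np.log(g_bin_a.support)[:, None] - np.log(g_bin_b.support)[None, :]
    usage_a = W_a @ g_bin_a.support
    usage_b = W_b @ g_bin_b.support

    de_probability = np.full(len(genes), np.nan)
    for i in np.flatnonzero(testable):
        shift = float(np.log(gene_mean_b[genes[i]]) - np.log(gene_mean_a[genes[i]]))
        exceed = (np.abs(log_sup + shift) > delta).astype(float)
        de_probability[i] = float(np.clip(W_a[i] @ exceed @ W_b[i], 0.0, 1.0))

    p_value = np.where(testable, 1.0 - de_probability, np.nan)
    fdr = np.full(len(genes), np.nan)
    if testable.any():
        fdr[testable] = bh_adjust(p_value[testable])

    results = pd.DataFrame(
        {
            "gene_id": genes,
            "bin_id": bins_a["bin_id"].to_numpy(),
            "count_a": y_a.sum(axis=1),
            "count_b": y_b.sum(axis=1),
            "usage_mean_a": usage_a
            / np.array([gene_mean_a.get(g, np.nan) for g in genes]),
            "usage_mean_b": usage_b
            / np.array([gene_mean_b.get(g, np.nan) for g in genes]),
            "de_probability": de_probability,
            "p_value": p_value,
            "fdr": fdr,
            "status": np.where(testable, "tested", "untestable"),
        }
    )
    results.attrs["prior_bins_a"] = g_bin_a
    results.attrs["prior_bins_b"] = g_bin_b
    return results


def _gene_eb_means(gene_counts, grid=None) -> pd.Series:
    """Gene-level empirical-Bayes expression E[lambda | x] per gene.

    Accepts a Series (one sample) or DataFrame (replicate columns; quantile
    normalised, prior fitted on the deepest sample, replicate posterior
    means)."""
    if isinstance(gene_counts, pd.Series):
        frame = gene_counts.to_frame()
    elif isinstance(gene_counts, pd.DataFrame):
        frame = gene_counts
    else:
        raise TypeError("gene counts must be a pandas Series or DataFrame")
    counts = frame.to_numpy()
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("gene counts must be nonnegative integers")
    W, g = _condition_posteriors(counts.astype(np.int64), grid=grid)
    return pd.Series(W @ g.support, index=frame.index)
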