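"""Readers and writers for count tables, priors and result tables.

Everything is tab-separated text.  Result and prior files carry
``#``-prefixed metadata header lines (run id, package version, config echo)
and store floats at 17 significant digits, so write/read round-trips are
lossless.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mixing import MixingDistribution
from .replicates import CountMatrix

__all__ = [
    "RunConfig",
    "read_counts",
    "write_count_matrix",
    "write_prior",
    "read_prior",
    "write_results",
    "read_results",
    "file_checksum",
]

HTSEQ_SPECIAL_PREFIX = "__"


@dataclass
class RunConfig:
    """Tunable analysis parameters with their conventional defaults.

    ``delta`` is the log-fold-change relevance cutoff (natural log; ln 2 by
    default), ``epsilon`` the normalisation trim fraction (0.25: the middle
    half of genes anchors the depth constant), and the grid parameters steer
    the NPMLE candidate support.
    """

    delta: float = float(np.log(2.0))
    epsilon: float = 0.25
    grid_points: int = 400
    grid_margin: float = 1.25
    tol: float = 1e-8
    max_iter: int = 5000
    fdr_threshold: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")

    def as_metadata(self) -> dict:
        return {k: v for k, v in asdict(self).items()}


def file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_count(token: str, path, lineno: int) -> int:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: count {token!r} is not a number") from None
    if value < 0 or value != int(value):
        raise ValueError(f"{path}:{lineno}: count {token!r} is not a nonnegative integer")
    return int(value)


def read_counts(path, layout: str = "auto", conditions=None) -> CountMatrix:
    """Read a count table into a :class:`CountMatrix`.

    ``layout`` is ``htseq-pair`` (two columns, gene TAB count, no header),
    ``matrix`` (header row of sample names, first column gene ids) or
    ``auto``.  HTSeq summary rows (``__no_feature`` etc.) are dropped; gene
    order follows the file.  ``conditions`` optionally assigns a condition
    label per sample (defaults to "A" for every sample).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty count file")

    first = lines[0].split("\t")
    if layout == "auto":
        is_pair = len(first) == 2 and _looks_numeric(first[1])
        layout = "htseq-pair" if is_pair else "matrix"

    if layout == "htseq-pair":
        ids, counts, dropped = [], [], 0
        for lineno, line in enumerate(lines, 1):
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if fields[0].startswith(HTSEQ_SPECIAL_PREFIX):
                dropped += 1
                continue
            ids.append(fields[0])
            counts.append(_parse_count(fields[1], path, lineno))
        _check_duplicates(ids, path)
        matrix = np.asarray(counts, dtype=np.int64)[:, None]
        samples = ["sample_1"]
    elif layout == "matrix":
        header = first
        samples = header[1:] if len(header) > 1 else ["sample_1"]
        ids, rows, dropped = [], [], 0
        for lineno, line in enumerate(lines[1:], 2):
            fields = line.split("\t")
            if len(fields) != len(samples) + 1:
                raise ValueError(f"{path}:{lineno}: expected {len(samples) + 1} columns")
            if fields[0].startswith(HTSEQ_SPECIAL_PREFIX):
                dropped += 1
                continue
            ids.append(fields[0])
            rows.append([_parse_count(tok, path, lineno) for tok in fields[1:]])
        _check_duplicates(ids, path)
        matrix = np.asarray(rows, dtype=np.int64)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if dropped:
        import logging

        logging.getLogger("ebdiff").info(
            "%s: dropped %d special summary row(s)", path, dropped
        )
    if conditions is None:
        conditions = ["A"] * len(samples)
    return CountMatrix(ids, samples, list(conditions), matrix)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _check_duplicates(ids, path) -> None:
    seen = set()
    for g in ids:
        if g in seen:
            raise ValueError(f"{path}: duplicate gene_id {g!r}")
        seen.add(g)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def _write_metadata(fh, metadata: dict | None) -> None:
    if metadata:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")


def write_prior(g: MixingDistribution, path, metadata: dict | None = None) -> None:
    """Serialise a discrete prior as a two-column TSV (lossless)."""
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        fh.write("lambda\tweight\n")
        for lam, w in zip(g.support, g.weights):
            fh.write(f"{lam:.17g}\t{w:.17g}\n")


def read_prior(path) -> MixingDistribution:
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return MixingDistribution(
        frame["lambda"].to_numpy(float), frame["weight"].to_numpy(float)
    )


def write_results(results: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a results table as TSV with ``#`` metadata lines, 17 digits."""
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        results.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
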