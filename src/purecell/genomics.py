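"""Genomic frequency summaries: exact binomial and Fisher tests and the
fraction of the genome altered by copy number."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

DEFAULT_CN_THRESHOLD = 0.2


def binomial_frequency_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p for k mutated lines of n at tumour rate p0.

    Two-sidedness by the minimum-likelihood rule: sum the probabilities of
    all outcomes no more likely than the observed one.
    """
    if not 0 <= k <= n:
        raise InvalidInputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise InvalidInputError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binomtest(k, n, p0).pvalue)


def mutation_binomial_tests(summary: pd.DataFrame) -> pd.DataFrame:
    """Binomial test per gene of cell-line mutation counts vs tumour frequency.

    ``summary`` needs columns mutated_count, total and tumour_frequency
    (index: gene). Adds ``cell_line_frequency`` and ``p_value``.
    """
    out = summary.copy()
    out["cell_line_frequency"] = out["mutated_count"] / out["total"]
    out["p_value"] = [
        binomial_frequency_test(int(r.mutated_count), int(r.total), float(r.tumour_frequency))
        for r in out.itertuples()
    ]
    return out


def fraction_genome_altered(segments: pd.DataFrame, threshold: float = DEFAULT_CN_THRESHOLD) -> float:
    """Length fraction of segments with |log2 copy-number ratio| strictly above
    ``threshold``."""
    if segments.shape[0] == 0:
        raise InvalidInputError("empty segment table")
    lengths = segments["length"].to_numpy(dtype=float)
    ratios = segments["log2_ratio"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise InvalidInputError("segment lengths must be positive")
    total = lengths.sum()
    if total <= 0:
        raise InvalidInputError("zero total segment length")
    altered = lengths[np.abs(ratios) > threshold].sum()
    return float(altered / total)


def composition_fisher_test(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 contingency table.

    Tail assembly by the minimum-likelihood rule over the hypergeometric
    distribution of tables with the observed margins.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise InvalidInputError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InvalidInputError("every row and column margin must be positive")
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided").pvalue)


def read_segments(path) -> pd.DataFrame:
    """Read a segment table: either columns (length, log2_ratio) or BED-like
    (chrom, start, end, log2_ratio) with half-open 0-based coordinates."""
    seg = pd.read_csv(path, sep="\t")
    if {"length", "log2_ratio"} <= set(seg.columns):
        return seg[["length", "log2_ratio"]]
    if {"chrom", "start", "end", "log2_ratio"} <= set(seg.columns):
        out = seg.copy()
        out["length"] = out["end"] - out["start"]
        return out[["chrom", "start", "end", "length", "log2_ratio"]]
    raise InvalidInputError(
        "segment table needs (length, log2_ratio) or (chrom, start, end, log2_ratio)"
    )
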