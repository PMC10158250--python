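"""Exact k-mer enrichment against the uniform null of the saturated library.

Because the prey library is built over the complete 4**k insert space with
uniform synthesis, the null distribution of extracted-read counts is exactly
known: with N extracted reads and no binding, each k-mer's count is
Binomial(N, 4**-k).  Selection by a binding transcription factor inflates the
counts of bound k-mers, so over-representation is scored with the exact
binomial upper tail, Benjamini-Hochberg corrected across all 4**k tests —
including unobserved k-mers, which belong to the test family.  This turns the
informal "more repetitions means more likely bound" reasoning into a
calibrated test, and catches motifs that alignment-based discovery can miss
despite high frequency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .extract import KmerTable
from .library_model import IupacPattern, enumerate_inserts, iupac_match, iupac_search

__all__ = ["kmer_enrichment", "count_motif_reads", "saturation_report"]


def kmer_enrichment(table: KmerTable) -> pd.DataFrame:
    """Score every k-mer of the 4**k space for over-representation.

    Returns a DataFrame with columns ``kmer, count, expected, fold, p_value,
    q_value``, sorted by q-value, then fold (descending), then k-mer.  The
    p-value is the exact binomial upper tail P(X >= c) under the uniform
    null; q-values are Benjamini-Hochberg across all 4**k k-mers.
    """
    n_reads = table.total
    if n_reads < 1:
        raise ValueError("empty k-mer table: no reads to test against the null")
    kmers = enumerate_inserts(table.k)
    space = len(kmers)
    counts = np.array([table.counts.get(km, 0) for km in kmers], dtype=np.int64)
    p0 = 1.0 / space
    expected = n_reads * p0
    # P(X >= c) = sf(c - 1); c = 0 gives exactly 1.
    p_values = sps.binom.sf(counts - 1, n_reads, p0)
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "count": counts,
            "expected": expected,
            "fold": counts / expected,
            "p_value": p_values,
            "q_value": q_values,
        }
    )
    df = df.sort_values(
        ["q_value", "fold", "kmer"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def count_motif_reads(
    table: KmerTable, pattern: IupacPattern | str, mode: str = "substring"
) -> int:
    """Reads whose insert matches a known IUPAC motif.

    ``mode="exact"`` requires the whole insert to match (pattern width must
    equal k); ``mode="substring"`` counts a read once if the pattern matches
    at any offset within the insert.
    """
    if isinstance(pattern, str):
        pattern = IupacPattern(pattern)
    if mode == "exact":
        if pattern.width != table.k:
            raise ValueError(
                f"exact mode requires pattern width {pattern.width} == k {table.k}"
            )
        return sum(c for km, c in table.counts.items() if iupac_match(pattern, km))
    if mode == "substring":
        if pattern.width > table.k:
            raise ValueError(f"pattern width {pattern.width} exceeds k {table.k}")
        return sum(c for km, c in table.counts.items() if iupac_search(pattern, km))
    raise ValueError("mode must be 'exact' or 'substring'")


def saturation_report(table: KmerTable) -> dict[str, float]:
    """Library-quality diagnostics over the full 4**k count vector.

    ``coverage`` is the fraction of the insert space observed at least once;
    ``gini`` is the Gini coefficient of the counts (zeros included), 0 for a
    perfectly even library.
    """
    space = 4**table.k
    coverage = table.unique_count / space
    counts = np.zeros(space, dtype=np.float64)
    observed = np.fromiter(table.counts.values(), dtype=np.float64, count=table.unique_count)
    counts[: observed.size] = observed  # order is irrelevant to the Gini
    total = counts.sum()
    if total == 0:
        gini = 0.0
    else:
        counts.sort()
        ranks = np.arange(1, space + 1)
        gini = float((2.0 * (ranks * counts).sum()) / (space * total) - (space + 1) / space)
    return {"coverage": coverage, "gini": gini}
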