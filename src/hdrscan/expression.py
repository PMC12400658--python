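"""TPM computation and the percentile-rank expression screen.

TPM (transcripts per million) divides each gene's read count by its length,
then scales each condition so the values sum to one million:

    TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j)

The rank percentile of a gene within a condition is
``100 * (# expressed genes with strictly greater TPM) / (# expressed genes)``,
so the most highly expressed gene sits at percentile 0 and "rank percentile
under 50" means the upper half of expressed genes.  A gene passes the
high-expression screen when it is under the cutoff in at least one condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM matrix from a genes x conditions count table and gene lengths (bp).

    Counts must be nonnegative and lengths positive; a condition with zero
    total rate is an error (its TPM would be undefined).
    """
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes without length: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    dead = totals.index[totals <= 0].tolist()
    if dead:
        raise ValueError(f"condition(s) with zero total expression: {dead}")
    return rate.div(totals, axis=1) * 1e6


def percentile_rank(tpm: pd.DataFrame, expressed_min_tpm: float = 0.0) -> pd.DataFrame:
    """Per-condition rank percentiles among expressed genes.

    A gene is *expressed* in a condition when its TPM exceeds
    ``expressed_min_tpm``.  Unexpressed genes get NaN.  Ties share a
    percentile (strictly-greater counting), so the top gene is at 0.
    """
    out = pd.DataFrame(np.nan, index=tpm.index, columns=tpm.columns)
    for cond in tpm.columns:
        col = tpm[cond]
        expressed = col > expressed_min_tpm
        n = int(expressed.sum())
        if n == 0:
            raise ValueError(f"condition {cond!r} has no expressed genes")
        vals = col[expressed]
        greater = vals.rank(method="min", ascending=False) - 1
        out.loc[expressed, cond] = 100.0 * greater / n
    return out


def high_expression_screen(percentiles: pd.DataFrame, cutoff: float = 50.0) -> pd.Series:
    """Flag genes with rank percentile strictly under ``cutoff`` in >= 1
    condition (NaN percentiles never flag)."""
    return (percentiles < cutoff).any(axis=1)


def expression_report(
    tpm: pd.DataFrame, percentiles: pd.DataFrame, cutoff: float = 50.0
) -> pd.DataFrame:
    """Tidy gene x condition report with TPM, rank percentile and the
    per-gene high-expression flag."""
    flags = high_expression_screen(percentiles, cutoff)
    rows = []
    for gene in tpm.index:
        for cond in tpm.columns:
            rows.append(
                (gene, cond, tpm.at[gene, cond], percentiles.at[gene, cond], bool(flags[gene]))
            )
    return pd.DataFrame(
        rows, columns=["gene", "condition", "tpm", "rank_percentile", "high_expression"]
    )
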