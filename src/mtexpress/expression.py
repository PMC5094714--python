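"""Library-size normalization and gene-presence filtering of count matrices.

Normalization is the median-of-ratios procedure: a pseudo-reference sample
is formed from per-gene geometric means (over genes expressed in every
sample), and each sample's size factor is the median ratio of its counts to
the reference.  Long-RNA and tRNA count matrices are distinct libraries and
must be normalized separately, never jointly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["size_factors", "normalize", "presence_filter"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    The reference set is the genes with strictly positive counts in every
    sample; the geometric mean is computed in log space.  Raises when no
    gene is positive everywhere (callers should filter genes first).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; filter genes "
            "(e.g. presence_filter) before computing size factors"
        )
    log_counts = np.log(values[all_positive])
    log_ref = log_counts.mean(axis=1)  # geometric mean in log space
    ratios = log_counts - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        missing = list(factors.index[factors.isna()])
        raise ValueError(f"samples without size factors: {missing}")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors


def presence_filter(
    counts: pd.DataFrame, min_presence_fraction: float = 0.9
) -> list[str]:
    """Genes with reads in more than the given fraction of samples.

    A gene is retained iff (samples with count > 0) / (samples) strictly
    exceeds ``min_presence_fraction`` — "more than", so a gene present in
    exactly the threshold fraction is dropped.  Mirrors the tRNA-panel
    reduction from 22 to the well-covered genes in sparse small-RNA data.
    """
    if not 0.0 <= min_presence_fraction <= 1.0:
        raise ValueError("min_presence_fraction must lie in [0, 1]")
    presence = (counts > 0).sum(axis=1) / counts.shape[1]
    return list(counts.index[presence > min_presence_fraction])
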