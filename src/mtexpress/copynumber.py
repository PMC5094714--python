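"""mtDNA copy-number estimation from DNA coverage and group comparison.

Because each cell carries many mitochondrial genomes against two nuclear
genome copies, the ratio of mean per-base DNA read coverage over the mtDNA
to the mean autosomal coverage estimates the per-cell mtDNA copy number.
The mtDNA interval is fixed to positions 1-16,499 (skipping the very end of
the control region) and the nuclear baseline is one 100,000-base window per
autosome starting at position 20,100,000, aggregated as the unweighted mean
of the 22 window means (windows are equal length, so this is the pooled
per-base mean).  Group differences in copy number are tested
nonparametrically with the Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MT_INTERVAL = (1, 16499)  # 1-based inclusive
AUTOSOMAL_WINDOW = (20_100_000, 20_199_999)  # inclusive start, 100,000 bases
N_AUTOSOMES = 22

__all__ = [
    "MT_INTERVAL",
    "AUTOSOMAL_WINDOW",
    "CopyNumberEstimate",
    "KruskalResult",
    "interval_mean_coverage",
    "estimate_copy_number",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    mt_mean: float
    autosomal_mean: float
    ratio: float


@dataclass(frozen=True)
class KruskalResult:
    """Kruskal-Wallis H with its degrees of freedom and total sample size."""

    statistic: float
    pvalue: float
    df: int
    n: int


def interval_mean_coverage(
    track: np.ndarray | pd.Series, interval: tuple[int, int]
) -> float:
    """Arithmetic mean of per-base coverage over a 1-based inclusive interval.

    ``track`` is indexed so that element 0 is position 1.
    """
    start, end = interval
    values = np.asarray(track, dtype=float)
    if start < 1 or end > len(values) or end < start:
        raise ValueError(
            f"interval {interval} outside track of length {len(values)}"
        )
    return float(values[start - 1:end].mean())


def estimate_copy_number(
    mt_mean: float,
    autosomal_window_means: Sequence[float],
    sample_id: str = "",
    require_all_autosomes: bool = True,
) -> CopyNumberEstimate:
    """mtDNA copy number as the mtDNA : autosomal mean-coverage ratio."""
    windows = np.asarray(autosomal_window_means, dtype=float)
    if require_all_autosomes and windows.size != N_AUTOSOMES:
        raise ValueError(
            f"expected {N_AUTOSOMES} autosomal window means, got {windows.size} "
            "(pass require_all_autosomes=False to override)"
        )
    if windows.size == 0:
        raise ValueError("no autosomal windows given")
    autosomal_mean = float(windows.mean())
    if autosomal_mean <= 0:
        raise ValueError("autosomal mean coverage must be positive")
    return CopyNumberEstimate(
        sample_id=sample_id,
        mt_mean=float(mt_mean),
        autosomal_mean=autosomal_mean,
        ratio=float(mt_mean) / autosomal_mean,
    )


def estimate_copy_numbers(coverage: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-sample estimates from a coverage-summary table.

    Expects the layout written by the simulator / coverage reader: a
    ``mt_mean`` column plus 22 ``chr*_window_mean`` columns.
    """
    window_cols = [c for c in coverage.columns if c.endswith("_window_mean")]
    rows = [
        estimate_copy_number(
            row["mt_mean"],
            [row[c] for c in window_cols],
            sample_id=str(row.get("sample_id", idx)),
            require_all_autosomes=len(window_cols) == N_AUTOSOMES,
        )
        for idx, row in coverage.iterrows()
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "mt_mean": [r.mt_mean for r in rows],
            "autosomal_mean": [r.autosomal_mean for r in rows],
            "copy_number": [r.ratio for r in rows],
        }
    ).set_index("sample_id", drop=False)


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence,
    method: str = "chi2",
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> KruskalResult:
    """Kruskal-Wallis rank test of a value vector against group labels.

    The tie-corrected H statistic is referred to a chi-squared distribution
    with (groups − 1) degrees of freedom; ``method="permutation"`` instead
    estimates the p-value by label permutation, preferable for very small
    groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and group labels must align")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    parts = [values[labels == g] for g in uniq]
    df = len(uniq) - 1
    if np.ptp(values) == 0:
        # all observations tied: every rank is the mid-rank, H is exactly 0
        return KruskalResult(statistic=0.0, pvalue=1.0, df=df, n=len(values))
    h, p = stats.kruskal(*parts)
    h = float(h)
    if method == "permutation":
        rng = rng or np.random.default_rng()
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            hp, _ = stats.kruskal(*[values[perm == g] for g in uniq])
            if hp >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    elif method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    return KruskalResult(statistic=h, pvalue=float(p), df=df, n=len(values))
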