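"""Stratified split-replication consistency testing of eQTL associations.

A single significant scan on one cohort division can reflect the luck of
the draw.  The consistency procedure re-divides the cohort many times
(default 500) into two groups while preserving the proportions of sex and
ethnicity in each, treats the halves as biological replicates — each half
gets its own size factors, site filters and Bonferroni family — and counts,
per (site, allele, gene) pair, the fraction of divisions in which the
association was significant in BOTH halves.  Pairs whose fraction strictly
exceeds a cutoff (default 60%) are certified as consistently replicating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mtexpress import eqtl, expression
from mtexpress.eqtl import GenotypeMatrix

__all__ = [
    "stratified_split",
    "run_replicates",
    "consistency_report",
]

REPORT_COLUMNS = [
    "site", "allele", "gene", "n_replicates", "n_replicated", "fraction",
]


def stratified_split(
    samples: pd.DataFrame,
    strata_keys: Sequence[str] = ("sex", "population"),
    n_groups: int = 2,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Random group assignment preserving stratum proportions.

    Within each stratum cell (e.g. sex × ethnicity), samples are shuffled
    and dealt round-robin into ``n_groups``, so per-stratum group sizes
    differ by at most one (an 11-member stratum splits 6/5).  Strata
    smaller than ``n_groups`` still have all members assigned.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    for key in strata_keys:
        if key not in samples.columns:
            raise ValueError(f"stratum key {key!r} not in sample table")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    assignment = pd.Series(index=samples.index, dtype=int, name="group")
    grouped = samples.groupby(list(strata_keys), sort=True, observed=True)
    for _, members in grouped:
        idx = np.array(members.index)
        rng.shuffle(idx)
        assignment.loc[idx] = np.arange(len(idx)) % n_groups
    return assignment


def _significant_pairs(
    counts: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    members: list,
    alpha: float,
    min_carriers: int,
    max_major_freq: float,
    family: str,
) -> set[tuple] | None:
    sub_counts = counts[members]
    try:
        factors = expression.size_factors(sub_counts)
    except ValueError:
        return None
    norm = expression.normalize(sub_counts, factors)
    results = eqtl.scan(
        norm,
        genotypes.subset_samples(members),
        None if covariates is None else covariates.loc[members],
        family=family,
        min_carriers=min_carriers,
        max_major_freq=max_major_freq,
    )
    if len(results) == 0:
        return set()
    if alpha >= 1:  # degenerate level: every emitted test counts as a hit
        hits = results
    else:
        threshold = eqtl.bonferroni_threshold(alpha, results.attrs["n_tests"])
        hits = results[results["p"] < threshold]
    return set(zip(hits["site"], hits["allele"], hits["gene"]))


def run_replicates(
    counts: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    samples: pd.DataFrame,
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    strata_keys: Sequence[str] = ("sex", "population"),
    mode: str = "both",
    min_carriers: int = 10,
    max_major_freq: float = 0.95,
) -> pd.DataFrame:
    """Count, per association, the divisions in which it replicated.

    Per replicate the cohort is split 2-ways with ``stratified_split``;
    normalization (size factors), site filters, the scan and its Bonferroni
    threshold are recomputed from scratch inside each half.  With
    ``mode="both"`` (default) a (site, allele, gene) pair replicates iff it
    is Bonferroni-significant in both halves; ``mode="either"`` requires
    one.  Replicates in which a half cannot be normalized or fit are
    skipped and the denominator adjusted.  Raw counts (not pre-normalized
    values) are the required input.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if mode not in ("both", "either"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    tally: dict[tuple, int] = {}
    tested: set[tuple] = set()
    n_effective = 0
    for _ in range(n_replicates):
        groups = stratified_split(samples, strata_keys, n_groups=2, seed=rng)
        half_hits: list[set[tuple] | None] = []
        for g in (0, 1):
            members = list(groups.index[groups == g])
            half_hits.append(
                _significant_pairs(
                    counts, genotypes, covariates, members, alpha,
                    min_carriers, max_major_freq, family=f"replicate-half{g}",
                )
            )
        if any(h is None for h in half_hits):
            continue  # half not analyzable; denominator adjusted
        n_effective += 1
        a, b = half_hits  # type: ignore[misc]
        replicated = (a & b) if mode == "both" else (a | b)
        tested |= a | b
        for pair in replicated:
            tally[pair] = tally.get(pair, 0) + 1

    pairs = sorted(tested | set(tally))
    report = pd.DataFrame(
        {
            "site": [p[0] for p in pairs],
            "allele": [p[1] for p in pairs],
            "gene": [p[2] for p in pairs],
            "n_replicates": n_effective,
            "n_replicated": [tally.get(p, 0) for p in pairs],
        }
    )
    report["fraction"] = (
        report["n_replicated"] / n_effective if n_effective else np.nan
    )
    report.attrs["mode"] = mode
    report.attrs["n_requested"] = n_replicates
    return report.sort_values(
        ["fraction", "site", "allele", "gene"], ascending=[False, True, True, True]
    ).reset_index(drop=True)


def consistency_report(
    report: pd.DataFrame, cutoff: float = 0.6
) -> pd.DataFrame:
    """Associations whose replication fraction strictly exceeds the cutoff.

    Returns one row per passing (site, allele, gene); genes can be grouped
    by their associated site sets downstream.  A fraction exactly at the
    cutoff does not pass ("more than").
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if len(report) == 0:
        return report.copy()
    passing = report[report["fraction"] > cutoff].copy()
    passing.attrs["cutoff"] = cutoff
    return passing.reset_index(drop=True)
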