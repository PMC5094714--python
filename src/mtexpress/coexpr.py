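"""Co-expression screening of nuclear genes against the mtDNA transcriptome.

Nuclear regulators of mitochondrial gene expression should co-vary with
their mitochondrial targets.  The screen computes Pearson correlations
between each mtDNA-encoded mRNA/rRNA gene and every nuclear gene
(Bonferroni family = #mt genes × #nuclear genes), then keeps only
co-expressed genes that are additionally differentially expressed between
macro-haplogroup backgrounds under covariate adjustment (the two-stage
filter).  The surviving set is summarized by its L / non-L expression
ratios and tested for functional enrichment against a user-supplied
annotation with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mtexpress import eqtl

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_screen",
    "two_stage_filter",
    "direction_summary",
    "DirectionSummary",
    "fold_enrichment",
    "enrichment",
]


def _pearson_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-by-row Pearson r between two matrices sharing columns."""
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(sa, sb)
    return r, sa, sb


def pearson_screen(
    mt_expression: pd.DataFrame,
    nuclear_expression: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Pearson correlation screen with Bonferroni retention.

    Both matrices are genes × samples, sample-aligned.  The two-sided
    p-value uses the t transform r·√((n−2)/(1−r²)) with n−2 degrees of
    freedom.  Pairs with p below alpha / (#mt × #nuclear) are returned;
    zero-variance genes are skipped with a log message.  The full family
    size is available as ``attrs["family_size"]``.
    """
    if list(mt_expression.columns) != list(nuclear_expression.columns):
        nuclear_expression = nuclear_expression[mt_expression.columns]
    n = mt_expression.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for the correlation screen")
    family = mt_expression.shape[0] * nuclear_expression.shape[0]
    threshold = eqtl.bonferroni_threshold(alpha, family)

    a = mt_expression.to_numpy(dtype=float)
    b = nuclear_expression.to_numpy(dtype=float)
    r, sa, sb = _pearson_matrix(a, b)
    for name, sd in (("mtDNA", sa), ("nuclear", sb)):
        if (sd == 0).any():
            which = (
                list(mt_expression.index[sa == 0]) if name == "mtDNA"
                else list(nuclear_expression.index[sb == 0])
            )
            logger.warning("zero-variance %s genes skipped: %s", name, which)
    r_clip = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_clip * np.sqrt((n - 2) / np.maximum(1 - r_clip**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    valid = np.outer(sa > 0, sb > 0)
    hit = valid & (p < threshold)
    mt_idx, nuc_idx = np.nonzero(hit)
    out = pd.DataFrame(
        {
            "mt_gene": mt_expression.index.to_numpy()[mt_idx],
            "nuclear_gene": nuclear_expression.index.to_numpy()[nuc_idx],
            "r": r_clip[mt_idx, nuc_idx],
            "n": n,
            "p": p[mt_idx, nuc_idx],
        }
    ).sort_values("p", kind="stable").reset_index(drop=True)
    out.attrs["family_size"] = family
    out.attrs["threshold"] = threshold
    return out


def two_stage_filter(
    candidates: pd.DataFrame | Sequence[str],
    expression: pd.DataFrame,
    group_labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha2: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Keep co-expressed genes that are also group-differential.

    ``candidates`` is the output of ``pearson_screen`` (or a plain gene
    list).  Stage 2 fits the linear association model with the macro-group
    indicator as predictor and the usual covariates, Bonferroni-corrected
    over the stage-1 survivors (``family_size`` defaults to the number of
    candidate genes).  Returns the genes passing both stages with their
    stage-2 p-values.
    """
    if isinstance(candidates, pd.DataFrame):
        genes = list(pd.unique(candidates["nuclear_gene"]))
    else:
        genes = list(dict.fromkeys(candidates))
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise KeyError(f"candidate genes absent from expression matrix: {missing}")
    family = family_size if family_size is not None else len(genes)
    if family == 0:
        return pd.DataFrame(columns=["gene", "stage2_p", "effect"])
    threshold = eqtl.bonferroni_threshold(alpha2, family)

    group_labels = group_labels.reindex(expression.columns)
    levels = sorted(group_labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 macro-groups, found {levels}")
    x = (group_labels == levels[0]).astype(float).to_numpy()
    cov = None if covariates is None else covariates.loc[expression.columns]

    rows = []
    for gene in genes:
        result = eqtl.fit_linear(
            expression.loc[gene].to_numpy(dtype=float), x, cov,
            site=f"macro-group[{levels[0]}]", gene=gene, family="two-stage",
        )
        if result.p < threshold:
            rows.append((gene, result.p, result.effect))
    out = pd.DataFrame(rows, columns=["gene", "stage2_p", "effect"])
    out.attrs["stage2_family_size"] = family
    out.attrs["stage2_threshold"] = threshold
    return out.sort_values("stage2_p", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class DirectionSummary:
    """Per-gene group expression ratios and the share with ratio > 1."""

    ratios: pd.Series  # gene -> mean(L) / mean(non-L)
    up_share: float


def direction_summary(
    genes: Sequence[str],
    normalized_expression: pd.DataFrame,
    group_labels: pd.Series,
    numerator_group: str = "L",
) -> DirectionSummary:
    """Ratio of mean normalized expression, numerator group over the rest."""
    group_labels = group_labels.reindex(normalized_expression.columns)
    in_num = (group_labels == numerator_group).to_numpy()
    if in_num.sum() == 0 or (~in_num).sum() == 0:
        raise ValueError("both groups must be non-empty")
    sub = normalized_expression.loc[list(genes)]
    num = sub.loc[:, in_num].mean(axis=1)
    den = sub.loc[:, ~in_num].mean(axis=1)
    ratios = (num / den).rename("ratio")
    return DirectionSummary(ratios=ratios, up_share=float((ratios > 1).mean()))


def fold_enrichment(observed: float, expected: float) -> float:
    """Observed over expected count ratio."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return observed / expected


def enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set against a background.

    For each term: observed = |set ∩ term|, expected = |set| × |term ∩
    background| / |background|, fold = observed / expected, and p is the
    upper hypergeometric tail P(X ≥ observed).  Terms with no background
    genes are skipped.  Fold enrichment is identical under binomial or
    hypergeometric sampling models since it is a ratio of counts.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    n_bg = len(background)
    n_set = len(gene_set)
    rows = []
    for term, members in annotation.items():
        term_bg = set(members) & background
        if not term_bg:
            logger.info("term %s has no background genes, skipped", term)
            continue
        observed = len(gene_set & term_bg)
        expected = n_set * len(term_bg) / n_bg
        p = float(stats.hypergeom.sf(observed - 1, n_bg, len(term_bg), n_set))
        rows.append(
            (term, observed, expected, fold_enrichment(observed, expected)
             if expected > 0 else np.nan, p)
        )
    return pd.DataFrame(
        rows, columns=["term", "observed", "expected", "fold_enrichment", "p"]
    ).sort_values("p", kind="stable").reset_index(drop=True)
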