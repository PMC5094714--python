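"""SNP-expression association scans with covariate adjustment.

The workhorse is an ordinary-least-squares linear model of normalized
expression on an allele predictor plus covariates (sex, lab of origin,
mtDNA copy number), the model family used by standard matrix eQTL scans.
Haploid mtDNA sites are encoded as one 0/1 indicator per tested minor
allele (each minor tested one-at-a-time against all other alleles, so a
tri-allelic site contributes two 1-df tests); diploid nuclear SNPs enter as
additive 0/1/2 dosages.  Sites are pre-filtered by minor-allele carrier
count and a major-allele frequency ceiling.  Multiple testing is controlled
by Bonferroni correction within each scan family, whose size equals the
number of emitted tests.

Beyond the pooled scan the module offers per-population stratified scans
and a background-masking contrast: the pooled allele effect next to
per-background effects with a Wald/Cochran heterogeneity statistic, which
exposes eQTLs whose opposing effects on different haplotype backgrounds
cancel in the pooled analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AssociationResult",
    "MaskingReport",
    "site_filters",
    "build_covariate_matrix",
    "encode_design",
    "fit_linear",
    "scan",
    "bonferroni_threshold",
    "stratified_scan",
    "background_contrast",
]

RESULT_COLUMNS = [
    "site", "allele", "gene", "n", "effect", "se", "t", "df", "p", "family",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Sites × samples genotypes, haploid (bases) or diploid (dosages).

    Haploid entries are single characters in {A,C,G,T,N}; diploid entries
    are integer dosages 0-2 (NaN for missing).  ``meta`` may carry per-site
    annotation (position, gene, SNP location) aligned to ``data.index``.
    """

    data: pd.DataFrame
    ploidy: str
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        if self.ploidy == "haploid" and len(self.data):
            bad = set(np.unique(self.data.to_numpy().astype(str))) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid haploid alleles: {sorted(bad)}")
        if self.ploidy == "diploid" and len(self.data):
            values = self.data.to_numpy(dtype=float)
            called = values[~np.isnan(values)]
            if ((called < 0) | (called > 2) | (called != np.round(called))).any():
                raise ValueError("diploid dosages must be integers in 0..2")
        if self.meta is not None and not self.meta.index.equals(self.data.index):
            raise ValueError("meta index must match site index")

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def sites(self) -> list:
        return list(self.data.index)

    def subset_samples(self, samples: Sequence) -> "GenotypeMatrix":
        return GenotypeMatrix(
            data=self.data[list(samples)], ploidy=self.ploidy, meta=self.meta
        )


@dataclass(frozen=True)
class AssociationResult:
    """One allele-expression test from the linear model."""

    site: str
    allele: str | None
    gene: str
    n: int
    effect: float
    se: float
    t: float
    df: int
    p: float
    family: str = ""


def _allele_summary(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = row[row != "N"]
    uniq, counts = np.unique(called, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return uniq[order], counts[order]


def site_filters(
    genotypes: GenotypeMatrix,
    min_carriers: int = 10,
    max_major_freq: float = 0.95,
) -> GenotypeMatrix:
    """Drop sites too rare or too monomorphic to test.

    A site is retained iff at least one non-major allele has at least
    ``min_carriers`` carriers AND the major-allele frequency does not
    exceed ``max_major_freq``.  Missing calls are excluded from frequency
    denominators.
    """
    keep = []
    for site, row in zip(genotypes.data.index, genotypes.data.to_numpy()):
        if genotypes.ploidy == "haploid":
            uniq, counts = _allele_summary(row.astype(str))
            total = counts.sum()
            if len(uniq) < 2 or total == 0:
                continue
            major_freq = counts[0] / total
            if counts[1:].max() >= min_carriers and major_freq <= max_major_freq:
                keep.append(site)
        else:
            dosage = row.astype(float)
            dosage = dosage[~np.isnan(dosage)]
            if dosage.size == 0:
                continue
            p_alt = dosage.sum() / (2 * dosage.size)
            major_freq = max(p_alt, 1 - p_alt)
            carriers = int(
                (dosage > 0).sum() if p_alt <= 0.5 else (dosage < 2).sum()
            )
            if carriers >= min_carriers and major_freq <= max_major_freq:
                keep.append(site)
    return GenotypeMatrix(
        data=genotypes.data.loc[keep],
        ploidy=genotypes.ploidy,
        meta=None if genotypes.meta is None else genotypes.meta.loc[keep],
    )


def build_covariate_matrix(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Numeric covariate design: categoricals to indicators, constants dropped.

    Categorical columns (e.g. sex, lab) are expanded to 0/1 indicators with
    the first level as the dropped reference; numeric columns (e.g. mtDNA
    copy number, entered untransformed) pass through.  Columns constant over
    the given samples are dropped automatically.
    """
    if covariates is None or covariates.shape[1] == 0:
        return None
    pieces = []
    for col in covariates.columns:
        series = covariates[col]
        if series.isna().any():
            raise ValueError(f"covariate {col!r} has missing values")
        if pd.api.types.is_numeric_dtype(series):
            pieces.append(series.astype(float).to_frame(col))
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:  # first level is the reference
                pieces.append(
                    (series.astype(str) == level).astype(float)
                    .to_frame(f"{col}[{level}]")
                )
    design = pd.concat(pieces, axis=1)
    keep = [c for c in design.columns if design[c].nunique() > 1]
    dropped = set(design.columns) - set(keep)
    if dropped:
        logger.info("dropping constant covariate columns: %s", sorted(dropped))
    return design[keep] if keep else None


@dataclass(frozen=True)
class Design:
    """Predictor encoding for one allele test at one site."""

    site: str
    allele: str | None
    x: np.ndarray           # predictor over the non-missing samples
    mask: np.ndarray        # boolean: samples with a called genotype
    covariates: pd.DataFrame | None


def encode_design(
    site: str,
    genotype_row: pd.Series | np.ndarray,
    ploidy: str,
    covariates: pd.DataFrame | None = None,
    min_carriers: int = 1,
) -> list[Design]:
    """Predictor columns for a site: per-minor-allele 0/1, or dosage.

    Haploid sites yield one design per minor allele with at least
    ``min_carriers`` carriers (each tested against all other alleles);
    diploid sites yield a single additive-dosage design.  Covariates are
    re-reduced within the non-missing subset so levels absent there do not
    produce degenerate columns.
    """
    row = np.asarray(genotype_row)
    designs: list[Design] = []
    if ploidy == "haploid":
        row = row.astype(str)
        mask = row != "N"
        uniq, counts = _allele_summary(row)
        for allele, carriers in zip(uniq[1:], counts[1:]):
            if carriers < min_carriers:
                continue
            x = (row[mask] == allele).astype(float)
            designs.append(
                Design(site=site, allele=str(allele), x=x, mask=mask,
                       covariates=_subset_covariates(covariates, mask))
            )
    elif ploidy == "diploid":
        values = row.astype(float)
        mask = ~np.isnan(values)
        designs.append(
            Design(site=site, allele="dosage", x=values[mask], mask=mask,
                   covariates=_subset_covariates(covariates, mask))
        )
    else:
        raise ValueError(f"unknown ploidy {ploidy!r}")
    return designs


def _subset_covariates(
    covariates: pd.DataFrame | None, mask: np.ndarray
) -> pd.DataFrame | None:
    if covariates is None:
        return None
    sub = covariates.loc[np.asarray(mask)]
    keep = [c for c in sub.columns if sub[c].nunique() > 1]
    return sub[keep] if keep else None


def _ols(
    y: np.ndarray, x: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[float, float, float, int, float, int]:
    """OLS of y on [x, covariates, 1]; returns stats for the x coefficient."""
    n = len(y)
    cols = [x]
    names = ["predictor"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    cols.append(np.ones(n))
    names.append("intercept")
    design = np.column_stack(cols)
    k = design.shape[1]
    if n <= k:
        raise ValueError(f"n={n} too small for {k} design columns")
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        # identify offending columns via the QR diagonal
        _, r = np.linalg.qr(design)
        bad = [names[i] for i in range(k) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    effect = float(beta[0])
    if se == 0.0:
        t = np.inf if effect != 0 else 0.0
    else:
        t = effect / se
    p = float(2 * stats.t.sf(abs(t), df))
    return effect, se, float(t), df, p, n


def fit_linear(
    y: np.ndarray | pd.Series,
    x: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    site: str = "",
    allele: str | None = None,
    gene: str = "",
    family: str = "",
) -> AssociationResult:
    """OLS association of one expression vector with one allele predictor.

    Reported effect/SE/t/p are for the allele column; the p-value is
    two-sided from the t distribution with residual degrees of freedom.
    Rows with missing values in y or x are removed (per-test deletion).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    cov = None if covariates is None else covariates.loc[ok]
    if cov is not None:
        keep = [c for c in cov.columns if cov[c].nunique() > 1]
        cov = cov[keep] if keep else None
    if np.ptp(x[ok]) == 0:
        raise ValueError("predictor is constant after missing-data removal")
    effect, se, t, df, p, n = _ols(y[ok], x[ok], cov)
    return AssociationResult(
        site=site, allele=allele, gene=gene, n=n,
        effect=effect, se=se, t=t, df=df, p=p, family=family,
    )


def scan(
    expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    family: str = "mtDNA-scan",
    min_carriers: int = 10,
    max_major_freq: float = 0.95,
    apply_filters: bool = True,
) -> pd.DataFrame:
    """Test every retained site × gene pair; results sorted by p-value.

    ``expression`` is a normalized genes × samples matrix sample-aligned
    with the genotypes; ``covariates`` is a raw per-sample table (see
    ``build_covariate_matrix``).  All genes are fit jointly per design with
    a shared least-squares solve.  The returned frame carries the family
    label and ``attrs["n_tests"]`` for Bonferroni bookkeeping; its test
    count equals the number of emitted rows.
    """
    samples = genotypes.samples
    if not set(samples) <= set(expression.columns):
        missing = sorted(set(samples) - set(expression.columns))
        raise ValueError(f"expression matrix lacks samples: {missing[:5]}")
    expr = expression[samples]
    if covariates is not None:
        covariates = covariates.loc[samples]
    cov_num = build_covariate_matrix(covariates)

    if apply_filters:
        genotypes = site_filters(genotypes, min_carriers, max_major_freq)

    genes = list(expr.index)
    y_all = expr.to_numpy(dtype=float)  # genes × samples
    records: list[tuple] = []
    for site in genotypes.sites:
        designs = encode_design(
            site, genotypes.data.loc[site], genotypes.ploidy, cov_num,
            min_carriers=min_carriers if genotypes.ploidy == "haploid" else 1,
        )
        if not designs:
            logger.info("site %s: no testable allele, skipped", site)
        for design in designs:
            mask = design.mask
            x = design.x
            if np.ptp(x) == 0:
                logger.info(
                    "site %s allele %s: constant predictor, skipped",
                    site, design.allele,
                )
                continue
            cols = [x]
            if design.covariates is not None:
                cols.extend(
                    design.covariates[c].to_numpy(dtype=float)
                    for c in design.covariates.columns
                )
            cols.append(np.ones(mask.sum()))
            dmat = np.column_stack(cols)
            n, k = dmat.shape
            if n <= k:
                logger.info("site %s: too few samples (%d), skipped", site, n)
                continue
            ysub = y_all[:, mask].T  # n × genes
            beta, _, _, _ = np.linalg.lstsq(dmat, ysub, rcond=None)
            resid = ysub - dmat @ beta
            df = n - k
            sigma2 = (resid * resid).sum(axis=0) / df
            c00 = np.linalg.inv(dmat.T @ dmat)[0, 0]
            se = np.sqrt(sigma2 * c00)
            effect = beta[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = np.where(se > 0, effect / se,
                                np.where(effect != 0, np.inf, 0.0))
            pval = 2 * stats.t.sf(np.abs(tval), df)
            for g_idx, gene in enumerate(genes):
                records.append(
                    (str(site), design.allele, gene, n,
                     float(effect[g_idx]), float(se[g_idx]),
                     float(tval[g_idx]), df, float(pval[g_idx]), family)
                )
    result = pd.DataFrame(records, columns=RESULT_COLUMNS)
    result = result.sort_values("p", kind="stable").reset_index(drop=True)
    result.attrs["n_tests"] = len(result)
    result.attrs["family"] = family
    return result


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def stratified_scan(
    expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    strata: pd.Series,
    min_stratum_n: int = 30,
    **scan_kwargs,
) -> dict[str, pd.DataFrame]:
    """Independent full scans within each stratum (e.g. population).

    Site filters and Bonferroni family sizes are stratum-specific, so a
    variant common only within one population is testable there even if
    rare overall.  Strata smaller than ``min_stratum_n`` are skipped with a
    warning.
    """
    out: dict[str, pd.DataFrame] = {}
    strata = strata.reindex(genotypes.samples)
    for level in sorted(strata.dropna().unique()):
        members = list(strata.index[strata == level])
        if len(members) < min_stratum_n:
            logger.warning(
                "stratum %s has %d samples (< %d), skipped",
                level, len(members), min_stratum_n,
            )
            continue
        out[str(level)] = scan(
            expression[members],
            genotypes.subset_samples(members),
            None if covariates is None else covariates.loc[members],
            family=f"stratified:{level}",
            **scan_kwargs,
        )
    return out


@dataclass(frozen=True)
class MaskingReport:
    """Pooled vs per-background allele effects and their heterogeneity."""

    pooled: AssociationResult
    per_background: dict[str, AssociationResult]
    excluded_backgrounds: tuple[str, ...]
    heterogeneity_stat: float | None
    heterogeneity_p: float | None
    heterogeneity_df: int | None


def background_contrast(
    y: pd.Series | np.ndarray,
    genotype_row: pd.Series | np.ndarray,
    backgrounds: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    allele: str | None = None,
    gene: str = "",
) -> MaskingReport:
    """Contrast an allele's effect across genetic backgrounds.

    Fits the pooled allele effect and each background's own effect, and
    reports a heterogeneity statistic (Cochran's Q over the per-background
    effects, a Wald difference test when there are two backgrounds).
    Opposite-sign effects of similar size across backgrounds produce the
    masking signature: each background significant, the pooled effect near
    zero, the heterogeneity test significant.  Backgrounds in which the
    tested allele is absent (or fixed) are excluded and flagged.
    """
    y = pd.Series(np.asarray(y, dtype=float))
    row = np.asarray(genotype_row)
    backgrounds = np.asarray(backgrounds).astype(str)
    if row.dtype.kind in "UOS" and not np.issubdtype(row.dtype, np.number):
        alleles = row.astype(str)
        mask = alleles != "N"
        if allele is None:
            uniq, counts = _allele_summary(alleles)
            if len(uniq) < 2:
                raise ValueError("site is monomorphic")
            allele = str(uniq[1])
        x = np.where(mask, (alleles == allele).astype(float), np.nan)
    else:
        x = row.astype(float)
        allele = allele or "dosage"

    pooled = fit_linear(
        y, x, covariates, site="pooled", allele=allele, gene=gene,
        family="background-contrast",
    )
    per_background: dict[str, AssociationResult] = {}
    excluded: list[str] = []
    for level in sorted(np.unique(backgrounds)):
        sel = backgrounds == level
        x_sub = x[sel]
        called = x_sub[~np.isnan(x_sub)]
        if called.size == 0 or np.ptp(called) == 0:
            excluded.append(level)
            logger.warning(
                "background %s lacks both alleles, excluded from contrast", level
            )
            continue
        cov_sub = None if covariates is None else covariates.loc[sel]
        per_background[level] = fit_linear(
            y[sel].reset_index(drop=True), x_sub, None if cov_sub is None
            else cov_sub.reset_index(drop=True),
            site=f"background:{level}", allele=allele, gene=gene,
            family="background-contrast",
        )
    if len(per_background) >= 2:
        effects = np.array([r.effect for r in per_background.values()])
        ses = np.array([r.se for r in per_background.values()])
        w = 1.0 / ses**2
        pooled_eff = (w * effects).sum() / w.sum()
        q = float((w * (effects - pooled_eff) ** 2).sum())
        df = len(effects) - 1
        p = float(stats.chi2.sf(q, df))
        het = (q, p, df)
    else:
        het = (None, None, None)
    return MaskingReport(
        pooled=pooled,
        per_background=per_background,
        excluded_backgrounds=tuple(excluded),
        heterogeneity_stat=het[0],
        heterogeneity_p=het[1],
        heterogeneity_df=het[2],
    )
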