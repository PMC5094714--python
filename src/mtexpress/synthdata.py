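"""Synthetic cohorts with the statistical structure of a haplogroup eQTL study.

The generator emulates a bulk RNA-seq cohort in which mitochondrial sequence
variation is organized into haplogroup clades: a deep African-like clade
("L") versus the pooled out-of-Africa clades, each clade carrying its own
defining SNPs on an rCRS-like 16,569-base coordinate frame.  Downstream
observables are produced with the dependencies the analysis assumes:

* base-count pileups per sample, with sequencing error and universal
  RNA-DNA difference (RDD) sites where every sample's RNA carries the same
  allele regardless of its DNA haplotype;
* negative-binomial gene counts whose means carry planted haplogroup,
  nuclear-genotype, and covariate effects on top of per-sample library-size
  factors;
* diploid nuclear genotypes in Hardy-Weinberg proportions;
* DNA coverage summaries whose mtDNA:autosome ratio reflects a planted
  mtDNA copy number.

All randomness flows from a single seed; each generator draws from its own
fixed substream, so adding one simulation step never perturbs another's
draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mtexpress.mtconsensus import MT_LENGTH, PileupMatrix
from mtexpress.phylo import HaplogroupDefinition

__all__ = [
    "SimulationConfig",
    "default_baseline_means",
    "gene_classes",
    "simulate_reference",
    "simulate_haplotypes",
    "simulate_cohort",
    "simulate_pileups",
    "simulate_counts",
    "simulate_nuclear_genotypes",
    "simulate_dna_coverage",
]

_BASES = np.array(list("ACGT"))

# fixed substream offsets (never renumber: reproducibility contract)
_STREAM_REFERENCE = 0
_STREAM_HAPLOTYPES = 1
_STREAM_COHORT = 2
_STREAM_PILEUPS = 3
_STREAM_COUNTS = 4
_STREAM_NUCLEAR = 5
_STREAM_COVERAGE = 6

_MT_MRNA = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)
_MT_RRNA = ("MT-RNR1", "MT-RNR2")
_MT_TRNA = tuple(
    f"MT-T{aa}" for aa in (
        "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
        "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
    )
)
_LABS = tuple(f"lab{i}" for i in range(1, 8))  # seven contributing labs


def default_baseline_means(
    n_nuclear: int = 0,
    nuclear_mean: float = 100.0,
    mrna_mean: float = 2000.0,
    rrna_mean: float = 10000.0,
    trna_mean: float = 500.0,
) -> dict[str, float]:
    """Baseline expected counts for the default gene panel.

    The mitochondrial panel is the 13 mRNAs, 2 rRNAs and 22 tRNAs of the
    human mtDNA; nuclear genes are named ``NUC0001`` onward.
    """
    means: dict[str, float] = {}
    means.update({g: mrna_mean for g in _MT_MRNA})
    means.update({g: rrna_mean for g in _MT_RRNA})
    means.update({g: trna_mean for g in _MT_TRNA})
    for i in range(n_nuclear):
        means[f"NUC{i + 1:04d}"] = nuclear_mean
    return means


def gene_classes(genes: Iterable[str]) -> pd.Series:
    """Classify gene ids into mt-mRNA / mt-rRNA / mt-tRNA / nuclear."""
    def cls(g: str) -> str:
        if g in _MT_MRNA:
            return "mt-mRNA"
        if g in _MT_RRNA:
            return "mt-rRNA"
        if g in _MT_TRNA:
            return "mt-tRNA"
        return "nuclear"

    genes = list(genes)
    return pd.Series([cls(g) for g in genes], index=genes, name="gene_class")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``planted_effects`` entries are ``(gene, predictor, log_fold_change)``
    where the predictor is a clade or macro-group label (indicator effect),
    a nuclear SNP id (additive per dosage unit), ``"sex=<level>"`` /
    ``"lab=<level>"`` (covariate indicator), or ``"copy_number"`` (per unit
    of standardized log copy number).
    """

    n_samples: int = 400
    clade_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"L": 0.2, "nonL": 0.8}
    )
    n_defining_snps_per_clade: int = 3
    recurrent_sites: tuple[int, ...] = ()
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    nb_dispersion: float = 0.1
    baseline_means: Mapping[str, float] = field(
        default_factory=default_baseline_means
    )
    depth_mean: float = 100.0
    error_rate: float = 0.01
    rdd_sites: tuple[tuple[int, str], ...] = ()
    copy_number_range: tuple[float, float] = (50.0, 500.0)
    libsize_sigma: float = 0.3
    confound_lab_with_clade: float = 0.0
    reference_length: int = MT_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.clade_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clade_freqs sum to {total}, expected 1")
        if any(f < 0 for f in self.clade_freqs.values()):
            raise ValueError("clade frequencies must be non-negative")
        if len(self.clade_freqs) < 1:
            raise ValueError("at least one clade required")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 0.5)")
        bad = {g: m for g, m in self.baseline_means.items() if m <= 0}
        if bad:
            raise ValueError(f"non-positive baseline means: {bad}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.copy_number_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"invalid copy_number_range {self.copy_number_range}")
        for pos, allele in self.rdd_sites:
            if not 1 <= pos <= self.reference_length:
                raise ValueError(f"RDD position {pos} outside reference")
            if allele not in "ACGT":
                raise ValueError(f"invalid RDD allele {allele!r}")
        if not 0.0 <= self.confound_lab_with_clade <= 1.0:
            raise ValueError("confound_lab_with_clade must be in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config_seed), stream])


def simulate_reference(config: SimulationConfig) -> str:
    """Random reference sequence on the configured coordinate frame."""
    rng = _rng(config.seed, _STREAM_REFERENCE)
    return "".join(_BASES[rng.integers(0, 4, size=config.reference_length)])


def simulate_haplotypes(
    config: SimulationConfig, reference: str
) -> tuple[HaplogroupDefinition, dict[str, str]]:
    """Plant clade-defining SNPs on a star phylogeny over the reference.

    Each clade receives ``n_defining_snps_per_clade`` private defining SNPs
    at positions disjoint across clades.  Every configured recurrent site is
    additionally planted with one shared derived allele on (at least) two
    independent branches, emulating homoplasy.
    """
    if len(config.clade_freqs) < 2:
        raise ValueError("simulate_haplotypes requires at least 2 clades")
    if len(reference) != config.reference_length:
        raise ValueError("reference length does not match config")
    rng = _rng(config.seed, _STREAM_HAPLOTYPES)
    clades = sorted(config.clade_freqs)
    recurrent = set(config.recurrent_sites)
    for pos in recurrent:
        if not 1 <= pos <= len(reference):
            raise ValueError(f"recurrent site {pos} outside reference length")

    n_needed = config.n_defining_snps_per_clade * len(clades)
    candidates = np.setdiff1d(
        np.arange(1, len(reference) + 1), np.fromiter(recurrent, dtype=int, count=len(recurrent))
    )
    positions = rng.choice(candidates, size=n_needed, replace=False)

    defining: dict[str, list[tuple[int, str]]] = {"ROOT": []}
    cursor = 0
    for clade in clades:
        own = sorted(
            int(p) for p in positions[cursor:cursor + config.n_defining_snps_per_clade]
        )
        cursor += config.n_defining_snps_per_clade
        variants = []
        for pos in own:
            ref_base = reference[pos - 1]
            derived = rng.choice([b for b in "ACGT" if b != ref_base])
            variants.append((pos, str(derived)))
        defining[clade] = variants

    for pos in sorted(recurrent):
        ref_base = reference[pos - 1]
        allele = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        chosen = rng.choice(clades, size=min(2, len(clades)), replace=False)
        for clade in chosen:
            defining[clade].append((pos, allele))

    parent = {"ROOT": None, **{c: "ROOT" for c in clades}}
    hapdef = HaplogroupDefinition(
        parent=parent,
        defining={c: tuple(v) for c, v in defining.items()},
        reference_length=len(reference),
    )

    sequences: dict[str, str] = {}
    for clade in clades:
        seq = list(reference)
        for pos, allele in hapdef.cumulative(clade):
            seq[pos - 1] = allele
        sequences[clade] = "".join(seq)
    return hapdef, sequences


def macro_group_of(clade: str) -> str:
    """Deterministic macro-group: clades labelled ``L*`` are African-like."""
    return "L" if clade.startswith("L") else "nonL"


def simulate_cohort(
    config: SimulationConfig, haplotypes: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Sample table: clade, macro-group, population, sex, lab, copy number.

    Clades are drawn i.i.d. from ``clade_freqs``; sex and lab are drawn
    independently of clade unless ``confound_lab_with_clade`` > 0, in which
    case L-like samples are pushed toward the first lab with that
    probability (for testing covariate adjustment under confounding).
    Per-sample true library-size factors are log-normal.
    """
    clades = sorted(config.clade_freqs)
    if haplotypes is not None and not set(clades) <= set(haplotypes):
        raise ValueError("clade_freqs contain clades absent from haplotypes")
    if config.n_samples < len(clades):
        raise ValueError(
            f"n_samples={config.n_samples} smaller than number of clades"
        )
    rng = _rng(config.seed, _STREAM_COHORT)
    freqs = np.array([config.clade_freqs[c] for c in clades])
    assignment = rng.choice(clades, size=config.n_samples, p=freqs)
    macro = np.array([macro_group_of(c) for c in assignment])
    sex = rng.choice(["female", "male"], size=config.n_samples)
    lab = rng.choice(_LABS, size=config.n_samples)
    if config.confound_lab_with_clade > 0:
        push = rng.random(config.n_samples) < config.confound_lab_with_clade
        lab = np.where((macro == "L") & push, _LABS[0], lab)
    lo, hi = config.copy_number_range
    copy_number = rng.uniform(lo, hi, size=config.n_samples)
    size_factor = np.exp(rng.normal(0.0, config.libsize_sigma, config.n_samples))
    population = np.where(macro == "L", "AFR", "EUR")
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(config.n_samples)],
            "population": population,
            "clade": assignment,
            "macro_group": macro,
            "sex": sex,
            "lab": lab,
            "true_copy_number": copy_number,
            "true_size_factor": size_factor,
        }
    ).set_index("sample_id", drop=False)


def simulate_pileups(
    samples: pd.DataFrame,
    haplotypes: Mapping[str, str],
    config: SimulationConfig,
    hapdef: HaplogroupDefinition | None = None,
) -> dict[str, PileupMatrix]:
    """Base-count pileups per sample with sequencing error and RDD sites.

    Depth at each position is Poisson(``depth_mean``); each read reports the
    haplotype base with probability 1−``error_rate`` and a uniformly chosen
    other base otherwise.  At RDD sites every sample's reads carry the
    configured RNA allele, regardless of clade — the transcriptome-wide
    signature of a universal RNA-DNA difference.
    """
    if hapdef is not None:
        defined = {
            pos for c in hapdef.clades for pos, _ in hapdef.cumulative(c)
        }
        clash = defined & {pos for pos, _ in config.rdd_sites}
        if clash:
            raise ValueError(
                f"RDD sites collide with clade-defining positions: {sorted(clash)}"
            )
    rng = _rng(config.seed, _STREAM_PILEUPS)
    length = config.reference_length
    base_index = {b: i for i, b in enumerate("ACGT")}

    hap_codes = {
        clade: np.array([base_index[b] for b in seq], dtype=np.int64)
        for clade, seq in haplotypes.items()
    }
    rdd_pos = np.array([p for p, _ in config.rdd_sites], dtype=np.int64)
    rdd_code = np.array([base_index[a] for _, a in config.rdd_sites], dtype=np.int64)

    out: dict[str, PileupMatrix] = {}
    for sample_id, clade in zip(samples["sample_id"], samples["clade"]):
        codes = hap_codes[clade].copy()
        if rdd_pos.size:
            codes[rdd_pos - 1] = rdd_code
        depth = rng.poisson(config.depth_mean, size=length)
        counts = np.zeros((length, 4), dtype=np.int64)
        if config.error_rate > 0:
            n_err = rng.binomial(depth, config.error_rate)
        else:
            n_err = np.zeros(length, dtype=np.int64)
        correct = depth - n_err
        counts[np.arange(length), codes] = correct
        if config.error_rate > 0:
            # distribute errors uniformly over the three non-haplotype bases
            err_split = rng.multinomial(n_err, [1 / 3] * 3)
            others = np.argsort(
                np.eye(4, dtype=np.int64)[codes], axis=1, kind="stable"
            )[:, :3]
            np.put_along_axis(
                counts, others,
                np.take_along_axis(counts, others, axis=1) + err_split, axis=1,
            )
        out[sample_id] = PileupMatrix(sample_id=sample_id, counts=counts)
    return out


def _effect_multiplier(
    gene: str,
    config: SimulationConfig,
    samples: pd.DataFrame,
    nuclear_genotypes=None,
) -> np.ndarray:
    n = len(samples)
    log_mult = np.zeros(n)
    log_cn = np.log(samples["true_copy_number"].to_numpy())
    z_cn = (log_cn - log_cn.mean()) / (log_cn.std() or 1.0)
    for eff_gene, predictor, lfc in config.planted_effects:
        if eff_gene != gene:
            continue
        if predictor == "copy_number":
            log_mult += lfc * z_cn
        elif "=" in predictor:
            col, level = predictor.split("=", 1)
            if col not in samples.columns:
                raise ValueError(f"unknown covariate predictor {predictor!r}")
            log_mult += lfc * (samples[col] == level).to_numpy(float)
        elif predictor in set(samples["clade"]) | set(samples["macro_group"]):
            hit = (samples["clade"] == predictor) | (
                samples["macro_group"] == predictor
            )
            log_mult += lfc * hit.to_numpy(float)
        else:
            if nuclear_genotypes is None:
                raise ValueError(
                    f"predictor {predictor!r} needs nuclear genotypes"
                )
            dosage = nuclear_genotypes.data.loc[predictor].to_numpy(float)
            log_mult += lfc * dosage
    return np.exp(log_mult)


def simulate_counts(
    samples: pd.DataFrame,
    config: SimulationConfig,
    nuclear_genotypes=None,
) -> pd.DataFrame:
    """Negative-binomial gene counts with planted effects.

    mean(gene, sample) = baseline(gene) × size_factor(sample) ×
    exp(Σ planted log-fold-changes active for that sample); the variance is
    μ + αμ² with dispersion α (α = 0 gives the Poisson limit).
    """
    rng = _rng(config.seed, _STREAM_COUNTS)
    genes = list(config.baseline_means)
    sf = samples["true_size_factor"].to_numpy()
    rows = []
    for gene in genes:
        mu = config.baseline_means[gene] * sf * _effect_multiplier(
            gene, config, samples, nuclear_genotypes
        )
        if config.nb_dispersion == 0:
            rows.append(rng.poisson(mu))
        else:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            rows.append(rng.negative_binomial(r, p))
    return pd.DataFrame(
        np.asarray(rows), index=pd.Index(genes, name="gene"),
        columns=samples["sample_id"],
    )


def true_site_matrix(
    samples: pd.DataFrame,
    hapdef: HaplogroupDefinition,
    haplotypes: Mapping[str, str],
):
    """Haploid genotype matrix read off the true DNA haplotypes.

    Rows are the union of clade-defining positions; each sample carries its
    clade's base.  This is the DNA-side ground truth against which the
    RNA-derived site matrix (pileups -> consensus -> variants) can be
    compared.
    """
    from mtexpress.eqtl import GenotypeMatrix

    positions = sorted(
        {pos for c in hapdef.clades for pos, _ in hapdef.cumulative(c)}
    )
    data = pd.DataFrame(
        {
            sample_id: [haplotypes[clade][p - 1] for p in positions]
            for sample_id, clade in zip(samples["sample_id"], samples["clade"])
        },
        index=pd.Index(positions, name="site"),
    )
    return GenotypeMatrix(data=data, ploidy="haploid")


def simulate_nuclear_genotypes(
    samples: pd.DataFrame,
    n_snps: int,
    maf: float | Sequence[float] = 0.3,
    linked_effects: Iterable[tuple[str, str, float]] = (),
    seed: int | None = None,
):
    """Diploid dosage genotypes in Hardy-Weinberg proportions.

    SNPs are named ``rs0000001`` onward so planted trans-effects (whose
    predictors must be among these names) can be traced.  ``maf`` may be a
    scalar or per-SNP vector in (0, 0.5].
    """
    from mtexpress.eqtl import GenotypeMatrix

    maf_arr = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,))
    if ((maf_arr <= 0) | (maf_arr > 0.5)).any():
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(
        [int(seed), _STREAM_NUCLEAR] if seed is not None else None
    )
    names = [f"rs{i + 1:07d}" for i in range(n_snps)]
    missing = {p for _, p, _ in linked_effects} - set(names)
    if missing:
        raise ValueError(
            f"linked effect SNPs not covered by n_snps naming: {sorted(missing)}"
        )
    n = len(samples)
    dosage = rng.binomial(2, maf_arr[:, None], size=(n_snps, n))
    data = pd.DataFrame(
        dosage, index=pd.Index(names, name="site"), columns=samples["sample_id"]
    )
    return GenotypeMatrix(data=data, ploidy="diploid")


def simulate_dna_coverage(
    samples: pd.DataFrame,
    nuclear_depth: float,
    seed: int | None = None,
    noise: bool = True,
    mt_interval_length: int = 16499,
    window_length: int = 100_000,
) -> pd.DataFrame:
    """Per-sample DNA coverage summaries reflecting mtDNA copy number.

    Mean mtDNA coverage is ``nuclear_depth × true_copy_number`` and each of
    the 22 autosomal window means is ``nuclear_depth``, with Poisson read
    noise over the interval lengths when ``noise`` is on.
    """
    if nuclear_depth <= 0:
        raise ValueError("nuclear_depth must be positive")
    rng = np.random.default_rng(
        [int(seed), _STREAM_COVERAGE] if seed is not None else None
    )
    n = len(samples)
    cn = samples["true_copy_number"].to_numpy()
    mt_rate = nuclear_depth * cn
    if noise:
        mt_mean = rng.poisson(mt_rate * mt_interval_length) / mt_interval_length
        auto = (
            rng.poisson(nuclear_depth * window_length, size=(n, 22))
            / window_length
        )
    else:
        mt_mean = mt_rate
        auto = np.full((n, 22), float(nuclear_depth))
    frame = pd.DataFrame(
        auto, columns=[f"chr{i}_window_mean" for i in range(1, 23)],
        index=samples.index,
    )
    frame.insert(0, "mt_mean", mt_mean)
    frame.insert(0, "sample_id", samples["sample_id"])
    return frame
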