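import numpy as np
import pandas as pd
import pytest

from mtexpress import expression, eqtl, synthdata


@pytest.fixture(scope="session")
def small_config():
    """Two-clade cohort on a short coordinate frame, error-free pileups."""
    return synthdata.SimulationConfig(
        n_samples=60,
        reference_length=2000,
        depth_mean=50.0,
        error_rate=0.0,
        rdd_sites=((500, "G"),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    reference = synthdata.simulate_reference(small_config)
    hapdef, haplotypes = synthdata.simulate_haplotypes(small_config, reference)
    samples = synthdata.simulate_cohort(small_config, haplotypes)
    return reference, hapdef, haplotypes, samples


@pytest.fixture(scope="session")
def planted_cohort():
    """n=400 cohort with a −0.5 log-fold-change planted on 10 mtDNA genes."""
    baselines = synthdata.default_baseline_means(n_nuclear=120)
    planted_genes = [g for g in baselines if g.startswith("MT-")][:10]
    config = synthdata.SimulationConfig(
        n_samples=400,
        baseline_means=baselines,
        planted_effects=tuple((g, "L", -0.5) for g in planted_genes),
        nb_dispersion=0.1,
        reference_length=2000,
        seed=7,
    )
    reference = synthdata.simulate_reference(config)
    hapdef, haplotypes = synthdata.simulate_haplotypes(config, reference)
    samples = synthdata.simulate_cohort(config, haplotypes)
    counts = synthdata.simulate_counts(samples, config)
    genotypes = synthdata.true_site_matrix(samples, hapdef, haplotypes)
    covariates = samples[["sex", "lab", "true_copy_number"]].rename(
        columns={"true_copy_number": "copy_number"}
    )
    return {
        "config": config,
        "planted_genes": set(planted_genes),
        "samples": samples,
        "counts": counts,
        "genotypes": genotypes,
        "covariates": covariates,
    }


@pytest.fixture(scope="session")
def normalized_planted(planted_cohort):
    counts = planted_cohort["counts"]
    factors = expression.size_factors(counts)
    return expression.normalize(counts, factors)
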