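import numpy as np
import pandas as pd
import pytest

from germdiv import (
    GenoSimConfig,
    PhenoSimConfig,
    TraitSchema,
    TraitTable,
    simulate_genotypes,
    simulate_phenotypes,
)
from germdiv.io import GenotypeMatrix


@pytest.fixture(scope="session")
def qualitative_schema() -> TraitSchema:
    """Schema with the descriptor-standard qualitative codings (fruit
    shape uses the non-contiguous code set {1, 2, 6, 7})."""
    return TraitSchema(
        kinds={
            "FL": "quantitative",
            "FD": "quantitative",
            "FS": "qualitative",
            "RC": "qualitative",
        },
        codes={"FS": frozenset({1, 2, 6, 7}), "RC": frozenset({1, 2, 3})},
    )


@pytest.fixture(scope="session")
def small_pheno():
    """Small structured phenotype dataset: 3 groups x 12 accessions,
    8 traits, two years with 3 replicates."""
    cfg = PhenoSimConfig(
        n_groups=3, accessions_per_group=12, n_traits=8,
        group_separation=6.0, seed=11,
    )
    return simulate_phenotypes(cfg)


@pytest.fixture(scope="session")
def small_geno():
    """Small structured genotype dataset: 3 pops x 20 samples, 600 loci."""
    cfg = GenoSimConfig(
        n_pops=3, samples_per_pop=20, n_loci=600, fst=0.10,
        selfing_rate=0.63, missing_rate=0.02, seed=7,
    )
    return simulate_genotypes(cfg)


def make_geno(genotypes, sample_ids=None, depth=None) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a dosage array."""
    genotypes = np.asarray(genotypes, dtype=np.int16)
    n, m = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * 10, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(sample_ids, loci, genotypes, depth)


@pytest.fixture()
def tiny_trait_table(qualitative_schema) -> TraitTable:
    values = pd.DataFrame(
        {
            "FL": [35.2, 41.0, 28.9],
            "FD": [44.1, 46.2, 39.8],
            "FS": [1, 6, 2],
            "RC": [3, 1, 2],
        },
        index=["A1", "A2", "A3"],
    )
    return TraitTable(
        accession_ids=["A1", "A2", "A3"],
        trait_names=list(values.columns),
        values=values,
        schema=qualitative_schema,
    )
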