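"""Synthetic phenotype and genotype generators.

These generators produce data with exactly the statistical structure the
analysis stages assume, so parameter recovery is testable offline:

* Phenotypes: accessions belong to G latent groups; each trait value is
  group mean + year main effect + a genotype x year interaction draw +
  Gaussian residual, observed over two years with replicates.  Group
  centers are placed so each group is displaced along its own trait
  direction, giving a controlled between-group separation in units of
  residual SD.

* Genotypes: a Balding-Nichols structured population.  Each locus draws
  an ancestral frequency p, each subpopulation draws its frequency from
  Beta(p(1-F)/F, (1-p)(1-F)/F) (variance F p(1-p), so pairwise
  Weir-Cockerham FST recovers F), and genotypes are sampled at the
  partial-selfing inbreeding equilibrium f = s/(2-s)
  (P(het) = 2pq(1-f)).  Uniform missingness and a Poisson depth field
  emulate the post-calling VCF.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from germdiv.io import (
    MISSING,
    GenotypeMatrix,
    TraitSchema,
    TraitTable,
    write_popmap,
    write_trait_table,
    write_vcf,
)


@dataclass
class PhenoSimConfig:
    """Study-shaped phenotype simulation.

    Defaults emulate the source design: ~209 accessions in 6 latent
    groups observed over 2 years with 3 replicate fruits per
    accession-year, 20 quantitative traits.  ``group_separation`` is the
    Euclidean distance between any two group centers in units of
    residual SD; ``year_effects`` are additive per-year shifts (units of
    residual SD) applied to all traits; ``interaction_sd`` scales the
    genotype x year interaction draws.
    """

    n_groups: int = 6
    accessions_per_group: int = 35
    n_traits: int = 20
    group_separation: float = 6.0
    year_effects: tuple[float, ...] = (0.0, 1.0)
    interaction_sd: float = 0.3
    residual_sd: float = 1.0
    replicates: int = 3
    n_qualitative: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.accessions_per_group < 1 or self.n_traits < 1:
            raise ValueError("counts must be positive")
        if min(self.interaction_sd, self.residual_sd) < 0 or self.group_separation < 0:
            raise ValueError("SDs and separation must be non-negative")


@dataclass
class PhenoSimTruth:
    groups: pd.Series  # accession -> true group (1..G)
    group_centers: np.ndarray  # G x n_traits
    year_effects: np.ndarray
    interactions: np.ndarray  # accession x year draws (shared across traits)


def _group_centers(g: int, t: int, separation: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Orthonormal random group directions scaled so every pair of group
    centers is exactly ``separation`` apart; spreading each direction
    across all traits keeps the separation intact under per-trait
    standardization downstream."""
    if g > t:
        raise ValueError("need n_traits >= n_groups for orthogonal group axes")
    raw = rng.normal(size=(t, g))
    q, _ = np.linalg.qr(raw)  # columns orthonormal
    return (separation / np.sqrt(2.0)) * q[:, :g].T


def simulate_phenotypes(
    config: PhenoSimConfig,
) -> tuple[TraitTable, pd.DataFrame, PhenoSimTruth]:
    """Generate a phenotype dataset.

    Returns ``(table, long, truth)``: ``table`` is the TraitTable of
    per-accession across-year means (the layout the diversity and
    PCA/clustering stages consume), ``long`` the replicate-level records
    (accession, year, rep, trait columns) for ANOVA, and ``truth`` the
    generating group labels and effects.
    """
    rng = np.random.default_rng(config.seed)
    g, a, t = config.n_groups, config.accessions_per_group, config.n_traits
    n = g * a
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]
    groups = np.repeat(np.arange(1, g + 1), a)
    centers = _group_centers(g, t, config.group_separation, rng) * config.residual_sd
    years = list(range(1, len(config.year_effects) + 1))
    year_eff = np.asarray(config.year_effects) * config.residual_sd

    interactions = rng.normal(0.0, config.interaction_sd * config.residual_sd,
                              size=(n, len(years)))
    records = []
    for yi, year in enumerate(years):
        for rep in range(1, config.replicates + 1):
            noise = rng.normal(0.0, config.residual_sd, size=(n, t))
            vals = centers[groups - 1] + year_eff[yi] + interactions[:, [yi]] + noise
            for i, acc in enumerate(accessions):
                records.append({"accession": acc, "year": year, "rep": rep,
                                **{f"T{j + 1:02d}": vals[i, j] for j in range(t)}})
    long = pd.DataFrame(records)

    trait_names = [f"T{j + 1:02d}" for j in range(t)]
    means = long.groupby("accession", sort=False)[trait_names].mean()
    means = means.loc[accessions]

    kinds: dict[str, object] = {tn: "quantitative" for tn in trait_names}
    codes: dict[str, frozenset[int]] = {}
    values = means.copy()
    for q in range(config.n_qualitative):
        name = f"Q{q + 1:02d}"
        allowed = (1, 2, 3)
        # group-skewed multinomial so qualitative traits also carry structure
        probs = np.tile([0.2, 0.3, 0.5], (g, 1))
        for k in range(g):
            probs[k] = np.roll(probs[k], k % 3)
        draws = np.array(
            [rng.choice(allowed, p=probs[grp - 1]) for grp in groups]
        )
        values[name] = draws
        kinds[name] = "qualitative"
        codes[name] = frozenset(allowed)

    schema = TraitSchema(kinds={k: str(v) for k, v in kinds.items()}, codes=codes)
    table = TraitTable(
        accession_ids=accessions,
        trait_names=list(values.columns),
        values=values,
        schema=schema,
    )
    truth = PhenoSimTruth(
        groups=pd.Series(groups, index=accessions, name="group"),
        group_centers=centers,
        year_effects=year_eff,
        interactions=interactions,
    )
    return table, long, truth


@dataclass
class GenoSimConfig:
    """Balding-Nichols structured-population genotype simulation.

    Defaults emulate the inferred study structure: 6 subpopulations,
    differentiation ``fst`` on the scale of the observed pairwise values
    (0.055-0.117), and a selfing rate whose inbreeding equilibrium
    f = s/(2-s) matches the observed FIS ~ 0.46 (s = 0.63).  Ancestral
    allele frequencies are Uniform(0.05, 0.95) so loci pass a 5% MAF
    filter with high probability.
    """

    n_pops: int = 6
    samples_per_pop: int = 30
    n_loci: int = 2000
    fst: float = 0.08
    selfing_rate: float = 0.63
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    missing_rate: float = 0.0
    mean_depth: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if min(self.n_pops, self.samples_per_pop, self.n_loci) < 1:
            raise ValueError("counts must be positive")

    @property
    def equilibrium_f(self) -> float:
        """Inbreeding coefficient at partial-selfing equilibrium, s/(2-s)."""
        s = self.selfing_rate
        return s / (2.0 - s)


@dataclass
class GenoSimTruth:
    ancestral_p: np.ndarray
    subpop_p: np.ndarray  # n_pops x n_loci
    fst: float
    equilibrium_f: float


def simulate_genotypes(
    config: GenoSimConfig,
) -> tuple[GenotypeMatrix, dict[str, str], GenoSimTruth]:
    """Draw a structured genotype matrix plus its population map and the
    generating truth (ancestral and subpopulation frequencies)."""
    rng = np.random.default_rng(config.seed)
    p_anc = rng.uniform(config.ancestral_low, config.ancestral_high, config.n_loci)
    f_st = config.fst
    if f_st > 0:
        alpha = p_anc * (1.0 - f_st) / f_st
        beta = (1.0 - p_anc) * (1.0 - f_st) / f_st
        sub_p = rng.beta(alpha, beta, size=(config.n_pops, config.n_loci))
    else:
        sub_p = np.tile(p_anc, (config.n_pops, 1))

    f = config.equilibrium_f
    n = config.n_pops * config.samples_per_pop
    geno = np.empty((n, config.n_loci), dtype=np.int16)
    sample_ids = []
    popmap: dict[str, str] = {}
    for k in range(config.n_pops):
        p = sub_p[k]
        q = 1.0 - p
        probs = np.stack(
            [q * q + f * p * q, 2.0 * p * q * (1.0 - f), p * p + f * p * q]
        )  # 3 x n_loci genotype law at inbreeding equilibrium
        u = rng.random((config.samples_per_pop, config.n_loci))
        c0 = probs[0]
        c1 = probs[0] + probs[1]
        block = np.where(u < c0, 0, np.where(u < c1, 1, 2)).astype(np.int16)
        rows = slice(k * config.samples_per_pop, (k + 1) * config.samples_per_pop)
        geno[rows] = block
        for i in range(config.samples_per_pop):
            sid = f"P{k + 1}S{i + 1:03d}"
            sample_ids.append(sid)
            popmap[sid] = f"pop{k + 1}"

    depth = rng.poisson(config.mean_depth, size=geno.shape).astype(np.int32)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING
        depth[miss] = 0

    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, config.n_loci + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = GenotypeMatrix(sample_ids, loci, geno, depth)
    truth = GenoSimTruth(
        ancestral_p=p_anc, subpop_p=sub_p, fst=f_st, equilibrium_f=f
    )
    return matrix, popmap, truth


def write_fixture_bundle(
    out_dir: str | Path,
    *,
    pheno_config: PhenoSimConfig | None = None,
    geno_config: GenoSimConfig | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Emit a small, fast fixture bundle: trait CSV, VCF, popmap TSV.

    Defaults are sized for test use (60 samples, 500 loci); the written
    VCF parses back through :func:`germdiv.io.read_vcf`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if pheno_config is None:
        pheno_config = PhenoSimConfig(
            n_groups=3, accessions_per_group=10, n_traits=6, seed=seed
        )
    if geno_config is None:
        geno_config = GenoSimConfig(
            n_pops=3, samples_per_pop=20, n_loci=500, seed=seed
        )
    table, long, _ = simulate_phenotypes(pheno_config)
    geno, popmap, _ = simulate_genotypes(geno_config)
    paths = {
        "traits": out_dir / "traits.csv",
        "traits_long": out_dir / "traits_by_year.csv",
        "vcf": out_dir / "genotypes.vcf",
        "popmap": out_dir / "popmap.tsv",
    }
    write_trait_table(table, paths["traits"])
    long.to_csv(paths["traits_long"], index=False, float_format="%.10g")
    write_vcf(geno, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    return paths
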