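"""Readers and writers for the pipeline's standard formats.

Trait tables are delimited text (CSV/TSV, header row of trait names,
first column = accession id).  Genotypes come from VCF 4.x with
per-genotype GT and optionally DP; the three study filters (per-genotype
minimum depth, per-locus missingness, minor-allele frequency) are
applied at read time in that fixed order.  Population maps are
two-column TSV.  Trees travel as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (alt-allele dosage is otherwise 0/1/2).
MISSING: int = -1


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSchema:
    """Declares each trait's kind and, for qualitative traits, allowed codes.

    ``kinds`` maps trait name -> ``"quantitative"`` or ``"qualitative"``;
    ``codes`` maps each qualitative trait to its set of legal integer codes
    (codes are kept exactly as printed in the descriptor standard, so
    non-contiguous sets such as fruit shape {1, 2, 6, 7} are preserved).
    """

    kinds: Mapping[str, str]
    codes: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, kind in self.kinds.items():
            if kind not in ("quantitative", "qualitative"):
                raise ValueError(f"trait {trait!r}: unknown kind {kind!r}")
            if kind == "qualitative" and trait not in self.codes:
                raise ValueError(f"qualitative trait {trait!r} has no declared codes")

    def is_qualitative(self, trait: str) -> bool:
        return self.kinds[trait] == "qualitative"

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "TraitSchema":
        """Build from a plain mapping, e.g. parsed YAML:
        ``{trait: "quantitative"}`` or ``{trait: {"kind": "qualitative", "codes": [1,2,6,7]}}``.
        """
        kinds: dict[str, str] = {}
        codes: dict[str, frozenset[int]] = {}
        for trait, val in d.items():
            if isinstance(val, str):
                kinds[trait] = val
            else:
                kinds[trait] = val["kind"]  # type: ignore[index]
                if "codes" in val:  # type: ignore[operator]
                    codes[trait] = frozenset(int(c) for c in val["codes"])  # type: ignore[index]
        return cls(kinds=kinds, codes=codes)


@dataclass
class TraitTable:
    """Accessions x traits grid with per-trait kind information.

    Qualitative traits are stored as their integer codes; missing cells
    are NaN.  ``years`` is optional and enables the multi-year ANOVA
    input layout where the same accession appears once per year.
    """

    accession_ids: list[str]
    trait_names: list[str]
    values: pd.DataFrame  # index = accession ids (or row number when years given)
    schema: TraitSchema
    years: list[int] | None = None

    def __post_init__(self) -> None:
        if self.years is None and len(set(self.accession_ids)) != len(self.accession_ids):
            dupes = pd.Series(self.accession_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate accession ids: {dupes}")
        for trait in self.trait_names:
            if self.schema.is_qualitative(trait):
                allowed = self.schema.codes[trait]
                col = self.values[trait].dropna()
                bad = col[~col.isin(list(allowed))]
                if len(bad):
                    row = bad.index[0]
                    raise ValueError(
                        f"trait {trait!r}, row {row!r}: code {bad.iloc[0]:g} not in "
                        f"allowed codes {sorted(allowed)}"
                    )

    @property
    def quantitative_traits(self) -> list[str]:
        return [t for t in self.trait_names if not self.schema.is_qualitative(t)]

    @property
    def qualitative_traits(self) -> list[str]:
        return [t for t in self.trait_names if self.schema.is_qualitative(t)]

    def trait(self, name: str) -> pd.Series:
        return self.values[name]


def read_trait_table(
    path: str | Path,
    schema: TraitSchema,
    *,
    sep: str | None = None,
    year_column: str | None = None,
) -> TraitTable:
    """Read a delimited trait table into a validated :class:`TraitTable`.

    The first column holds accession ids; remaining columns are traits
    declared in ``schema``.  Unparseable cells become missing (NaN).
    Duplicate accession ids (outside multi-year layout) and qualitative
    codes outside the declared set raise ``ValueError``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["", "NA"], keep_default_na=True)
    id_col = df.columns[0]
    accessions = df[id_col].astype(str).tolist()
    years = None
    if year_column is not None:
        years = df[year_column].astype(int).tolist()
        df = df.drop(columns=[year_column])
    traits = [c for c in df.columns if c != id_col]
    unknown = [t for t in traits if t not in schema.kinds]
    if unknown:
        raise ValueError(f"traits not declared in schema: {unknown}")
    values = df[traits].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(accessions if years is None else range(len(accessions)))
    return TraitTable(
        accession_ids=accessions,
        trait_names=traits,
        values=values,
        schema=schema,
        years=years,
    )


def write_trait_table(table: TraitTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a trait table back to delimited text (round-trips with
    :func:`read_trait_table` up to float formatting)."""
    out = table.values.copy()
    out.insert(0, "accession", table.accession_ids)
    if table.years is not None:
        out.insert(1, "year", table.years)
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Genotypes (VCF)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes as alt-allele dosage codes.

    ``genotypes`` is samples x loci with values in {0, 1, 2, MISSING};
    ``depth`` (optional) carries the per-genotype read depth.  Positions
    are 1-based as in VCF.  Missing genotypes are excluded from every
    frequency sum downstream.
    """

    sample_ids: list[str]
    loci: pd.DataFrame  # columns: chrom, pos, ref, alt
    genotypes: np.ndarray  # int8/int16, shape (n_samples, n_loci)
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("genotype matrix shape does not match samples x loci")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.genotypes != MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus alt-allele frequency over called genotypes (NaN if none)."""
        called = self.called()
        geno = np.where(called, self.genotypes, 0)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, geno.sum(axis=0) / (2.0 * n), np.nan)

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            loci=self.loci,
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
        )


@dataclass
class VcfFilterLog:
    """Per-rule attrition counts from :func:`read_vcf`.

    ``records_in - (non_snp + multiallelic + missingness + maf) == records_out``
    always holds; ``genotypes_depth_masked`` counts individual calls set
    to missing by the depth rule, not dropped records.
    """

    records_in: int = 0
    non_snp: int = 0
    multiallelic: int = 0
    missingness: int = 0
    maf: int = 0
    records_out: int = 0
    genotypes_depth_masked: int = 0

    def dropped_total(self) -> int:
        return self.non_snp + self.multiallelic + self.missingness + self.maf


def read_vcf(
    path: str | Path,
    *,
    min_depth: int = 3,
    max_missing_rate: float = 0.1,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, VcfFilterLog]:
    """Read a VCF into a filtered :class:`GenotypeMatrix`.

    Filter order is fixed: (1) genotypes with per-sample DP below
    ``min_depth`` are masked missing, (2) loci whose missing fraction
    exceeds ``max_missing_rate`` are dropped, (3) loci whose minor-allele
    frequency over the remaining calls falls below ``min_maf`` are
    dropped.  Multiallelic records and non-SNP alleles are removed up
    front.  Half-missing and phased genotypes are handled (./1 counts as
    missing; | and / are equivalent).

    Returns the matrix together with a :class:`VcfFilterLog`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no sample columns")
    if "FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError("VCF header declares no GT format field")

    log = VcfFilterLog()
    kept_geno: list[np.ndarray] = []
    kept_depth: list[np.ndarray] = []
    kept_loci: list[tuple[str, int, str, str]] = []

    for rec in vcf:
        log.records_in += 1
        if len(rec.ALT) != 1:
            log.multiallelic += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or rec.ALT[0] not in "ACGT":
            log.non_snp += 1
            continue
        # allele pairs; -1 marks a missing allele, so ./1 is fully missing
        alleles = np.array(rec.genotypes, dtype=np.int16)[:, :2]
        geno = np.where(
            (alleles < 0).any(axis=1), MISSING, alleles.sum(axis=1)
        ).astype(np.int16)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int32)
            dp = np.where(dp < 0, 0, dp)  # cyvcf2 encodes missing DP as negative
            masked = (dp < min_depth) & (geno != MISSING)
            log.genotypes_depth_masked += int(masked.sum())
            geno = np.where(dp < min_depth, MISSING, geno)
        missing_frac = np.mean(geno == MISSING)
        if missing_frac > max_missing_rate:
            log.missingness += 1
            continue
        called = geno != MISSING
        n_called = called.sum()
        p = np.where(called, geno, 0).sum() / (2.0 * n_called)
        maf = min(p, 1.0 - p)
        if maf < min_maf:
            log.maf += 1
            continue
        kept_geno.append(geno)
        kept_depth.append(
            dp if dp is not None else np.full(len(samples), -1, dtype=np.int32)
        )
        kept_loci.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        log.records_out += 1

    loci = pd.DataFrame(kept_loci, columns=["chrom", "pos", "ref", "alt"])
    genotypes = (
        np.array(kept_geno, dtype=np.int16).T
        if kept_geno
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    depth = (
        np.array(kept_depth, dtype=np.int32).T
        if kept_depth
        else np.empty((len(samples), 0), dtype=np.int32)
    )
    return GenotypeMatrix(samples, loci, genotypes, depth), log


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when present)."""
    has_dp = geno.depth is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in geno.loci["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT:DP" if has_dp else "GT"
        for j, locus in enumerate(geno.loci.itertuples(index=False)):
            cells = []
            for i in range(geno.n_samples):
                g = gt_strings[int(geno.genotypes[i, j])]
                if has_dp:
                    d = int(geno.depth[i, j])
                    g = f"{g}:{d if d >= 0 else '.'}"
                cells.append(g)
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Population maps
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path, geno: GenotypeMatrix | None = None) -> dict[str, str]:
    """Read a two-column (sample, population) TSV into a dict.

    When a genotype matrix is supplied, every mapped sample must exist in
    it and every population must be non-empty.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    popmap = dict(zip(df["sample"], df["pop"]))
    if geno is not None:
        unknown = set(popmap) - set(geno.sample_ids)
        if unknown:
            raise ValueError(f"popmap samples absent from genotype matrix: {sorted(unknown)}")
    return popmap


def write_popmap(popmap: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a tree (``germdiv.popgen.NJTree`` or dendropy Tree) as Newick
    with branch lengths at full precision."""
    newick = tree.to_newick() if hasattr(tree, "to_newick") else None
    if newick is None:
        import dendropy

        if not isinstance(tree, dendropy.Tree):
            raise TypeError("expected an NJTree or dendropy.Tree")
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    n_leaves = newick.count(",") + 1
    if n_leaves < 2:
        raise ValueError("refusing to write a tree with fewer than 2 leaves")
    with open(path, "w") as fh:
        fh.write(newick if newick.endswith("\n") else newick + "\n")


def read_newick(path: str | Path):
    """Read a Newick file into a dendropy Tree (taxa preserved as labels)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
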