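"""Population-genetic statistics from a filtered genotype matrix.

Per-population diversity indices at biallelic SNPs (observed and
expected heterozygosity, Shannon index, effective allele number,
unbiased gene diversity, nucleotide diversity, and Wright's FIS/FIT),
pairwise Weir & Cockerham (1984) FST as a ratio of summed variance
components across loci, an allele-sharing p-distance matrix between
individuals, a Saitou-Nei neighbor-joining tree, and genotype PCA on a
GCTA-style genetic relationship matrix.

All frequency sums run over called genotypes only; per-locus statistics
are averaged across the variant (post-filter) sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from germdiv.io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Per-locus frequencies
# ---------------------------------------------------------------------------

def _pop_indices(geno: GenotypeMatrix, popmap: dict[str, str]) -> dict[str, np.ndarray]:
    pops: dict[str, list[int]] = {}
    sample_pos = {s: i for i, s in enumerate(geno.sample_ids)}
    for sample, pop in popmap.items():
        if sample not in sample_pos:
            raise ValueError(f"popmap sample {sample!r} absent from genotype matrix")
        pops.setdefault(pop, []).append(sample_pos[sample])
    for pop, idx in pops.items():
        if not idx:
            raise ValueError(f"population {pop!r} is empty")
    return {pop: np.array(sorted(idx)) for pop, idx in sorted(pops.items())}


@dataclass
class LocusFrequencies:
    """Per-population per-locus allele frequencies.

    Arrays are loci-long: ``p`` alt-allele frequency, ``n`` called
    diploid count, ``h_obs`` observed-heterozygote fraction.  Loci with
    no calls in a population carry NaN (n = 0) and are skipped in that
    population's averages.
    """

    populations: list[str]
    p: dict[str, np.ndarray] = field(default_factory=dict)
    n: dict[str, np.ndarray] = field(default_factory=dict)
    h_obs: dict[str, np.ndarray] = field(default_factory=dict)


def locus_frequencies(geno: GenotypeMatrix, popmap: dict[str, str]) -> LocusFrequencies:
    """Alt-allele frequency, call count and observed-het fraction per
    population per locus, from called genotypes only."""
    pops = _pop_indices(geno, popmap)
    out = LocusFrequencies(populations=list(pops))
    for pop, idx in pops.items():
        g = geno.genotypes[idx]
        called = g != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2.0 * n), np.nan)
            h = np.where(n > 0, np.where(called, g == 1, False).sum(axis=0) / n, np.nan)
        out.p[pop] = p
        out.n[pop] = n
        out.h_obs[pop] = h
    return out


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def inbreeding_coefficient(ho: float, he: float) -> float:
    """Wright's fixation index 1 - Ho/He (NaN when He = 0)."""
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def _shannon(p: np.ndarray) -> np.ndarray:
    """Per-locus two-allele Shannon index -p ln p - q ln q (0 at fixation)."""
    q = 1.0 - p
    with np.errstate(invalid="ignore", divide="ignore"):
        term_p = np.where(p > 0, -p * np.log(p), 0.0)
        term_q = np.where(q > 0, -q * np.log(q), 0.0)
    return term_p + term_q


def population_diversity(
    geno: GenotypeMatrix, popmap: dict[str, str]
) -> pd.DataFrame:
    """Per-population diversity indices averaged across variant loci.

    Columns: He (expected heterozygosity 2pq), Ho (observed), I (Shannon
    index), Ne (effective allele number 1/(p^2+q^2)), nei_unbiased
    (2n/(2n-1) x He), Pi (per-variant-site nucleotide diversity, the same
    small-sample-corrected quantity), FIS = 1 - mean(Ho)/mean(He), and
    FIT = 1 - mean(Ho)/mean(He_total) against the pooled total
    population.  The final "Average" row is the unweighted mean of the
    population rows.
    """
    freqs = locus_frequencies(geno, popmap)
    # total-population He per locus, for FIT
    called_all = geno.genotypes != MISSING
    n_tot = called_all.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_tot = np.where(
            n_tot > 0,
            np.where(called_all, geno.genotypes, 0).sum(axis=0) / (2.0 * n_tot),
            np.nan,
        )
    he_total_mean = float(np.nanmean(2.0 * p_tot * (1.0 - p_tot)))

    rows = []
    for pop in freqs.populations:
        p = freqs.p[pop]
        n = freqs.n[pop]
        h = freqs.h_obs[pop]
        use = n > 0
        if not use.any():
            raise ValueError(f"population {pop!r} has no called loci")
        p, n, h = p[use], n[use].astype(float), h[use]
        q = 1.0 - p
        he = 2.0 * p * q
        ne = 1.0 / (p * p + q * q)
        corr = np.where(2 * n > 1, 2 * n / (2 * n - 1), np.nan)
        he_mean = float(he.mean())
        ho_mean = float(h.mean())
        rows.append(
            {
                "population": pop,
                "n_loci": int(use.sum()),
                "He": he_mean,
                "Ho": ho_mean,
                "I": float(_shannon(p).mean()),
                "Ne": float(ne.mean()),
                "nei_unbiased": float(np.nanmean(corr * he)),
                "Pi": float(np.nanmean(corr * he)),
                "FIS": inbreeding_coefficient(ho_mean, he_mean),
                "FIT": inbreeding_coefficient(ho_mean, he_total_mean),
            }
        )
    df = pd.DataFrame(rows).set_index("population")
    avg = df.mean(numeric_only=True)
    avg["n_loci"] = df["n_loci"].mean()
    df.loc["Average"] = avg
    return df


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c) for two
    populations, plus a usability mask.

    a is the among-population component, b the among-individual-
    within-population component, c the within-individual (heterozygote)
    component; the multi-locus estimator is sum(a)/sum(a+b+c).
    """
    r = 2.0
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    usable = (n1 > 0) & (n2 > 0)
    n_bar = (n1 + n2) / r
    usable &= n_bar > 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, usable


def pairwise_fst(
    geno: GenotypeMatrix,
    popmap: dict[str, str],
    *,
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Pairwise multi-locus Weir & Cockerham (1984) FST.

    For each population pair, theta = sum_l a_l / sum_l (a_l+b_l+c_l)
    over loci with calls in both populations (the ratio-of-sums
    convention VCFtools' weighted estimate uses).  Negative estimates
    are reported as computed unless ``clamp_negative`` floors them at 0.
    """
    freqs = locus_frequencies(geno, popmap)
    pops = freqs.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c, usable = _wc_components(
                freqs.n[pops[i]], freqs.p[pops[i]], freqs.h_obs[pops[i]],
                freqs.n[pops[j]], freqs.p[pops[j]], freqs.h_obs[pops[j]],
            )
            denom = (a + b + c)[usable].sum()
            if not usable.any() or denom == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            theta = a[usable].sum() / denom
            if clamp_negative:
                theta = max(theta, 0.0)
            out[i, j] = out[j, i] = theta
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# p-distance and neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing p-distance between individuals.

    d(i, j) = mean over loci called in both of |g_i - g_j| / 2 on the
    dosage scale, i.e. the expected proportion of differing alleles.
    A pair sharing no called locus is an error.
    """
    g = geno.genotypes.astype(float)
    g[geno.genotypes == MISSING] = np.nan
    n = geno.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g[i + 1:]) / 2.0  # NaN where either missing
        shared = np.sum(~np.isnan(diff), axis=1)
        if np.any(shared == 0):
            j = i + 1 + int(np.argmax(shared == 0))
            raise ValueError(
                f"samples {geno.sample_ids[i]!r} and {geno.sample_ids[j]!r} "
                "share no called loci"
            )
        row = np.nanmean(diff, axis=1)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return pd.DataFrame(d, index=geno.sample_ids, columns=geno.sample_ids)


@dataclass
class _Node:
    name: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick_fragment(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{child.newick_fragment()}:{length:.12g}"
            for child, length in self.children
        )
        return f"({inner})"


@dataclass
class NJTree:
    """Unrooted neighbor-joining tree (the root node is the final
    trifurcation; branch lengths on the p-distance scale, negative
    lengths reported as computed)."""

    root: _Node
    leaf_names: list[str]

    def to_newick(self) -> str:
        return self.root.newick_fragment() + ";"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.to_newick(), schema="newick")


def neighbor_joining(dist: pd.DataFrame) -> NJTree:
    """Saitou-Nei neighbor joining on a complete symmetric matrix.

    Iteratively joins the pair minimizing the Q-criterion
    Q(i,j) = (m-2) d(i,j) - R_i - R_j (R = row sums), with branch
    lengths from the standard two-point formulas.  Ties resolve to the
    lexicographically smallest active (i, j) index pair, so output is
    deterministic.  Exact (topology and lengths) on additive matrices.
    """
    d = dist.to_numpy(dtype=float).copy()
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains NaN/inf")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square symmetric")
    names = [str(x) for x in dist.index]
    m = len(names)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[_Node] = [_Node(name=nm) for nm in names]
    active = list(range(m))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major => smallest (i, j) among ties
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for au in active:
            if au in (i, j):
                continue
            duk = 0.5 * (d[i, au] + d[j, au] - dij)
            d[new_idx, au] = d[au, new_idx] = duk
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [new_idx]

    # final trifurcation
    i, j, l = active
    li = 0.5 * (d[i, j] + d[i, l] - d[j, l])
    lj = 0.5 * (d[i, j] + d[j, l] - d[i, l])
    ll = 0.5 * (d[i, l] + d[j, l] - d[i, j])
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[l], ll)])
    return NJTree(root=root, leaf_names=names)


# ---------------------------------------------------------------------------
# Genotype PCA (GRM)
# ---------------------------------------------------------------------------

def genetic_relationship_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """GCTA-style GRM: dosages centered at 2p and scaled by
    sqrt(2p(1-p)) per locus, then A = Z Z^T / m.

    Monomorphic loci (p in {0, 1}) are skipped; missing genotypes are
    imputed at the locus mean (2p), i.e. contribute 0 after centering.
    """
    p = geno.allele_frequencies()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci for the GRM")
    g = geno.genotypes[:, poly].astype(float)
    pp = p[poly]
    g[geno.genotypes[:, poly] == MISSING] = np.nan
    z = (g - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    z = np.nan_to_num(z, nan=0.0)
    m = z.shape[1]
    return z @ z.T / m


def genotype_pca(geno: GenotypeMatrix, *, n_components: int = 10):
    """Principal components of genetic structure: eigendecomposition of
    the GRM; returns (coordinates DataFrame, eigenvalues).

    Coordinates are the top unit-norm eigenvectors scaled by the square
    root of their eigenvalues (so Euclidean distances in PC space
    approximate relationship distances).
    """
    grm = genetic_relationship_matrix(geno)
    eigvals, eigvecs = np.linalg.eigh(grm)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    k = min(n_components, len(eigvals))
    coords = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0.0, None))
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=geno.sample_ids, columns=cols),
        eigvals,
    )
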