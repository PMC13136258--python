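"""Population-genetic statistics: frequencies, diversity indices,
Weir-Cockerham FST, p-distance, neighbor joining, genotype PCA."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from germdiv.io import MISSING
from germdiv.popgen import (
    genetic_relationship_matrix,
    genotype_pca,
    inbreeding_coefficient,
    locus_frequencies,
    neighbor_joining,
    p_distance_matrix,
    pairwise_fst,
    population_diversity,
)
from germdiv.simulate import GenoSimConfig, simulate_genotypes

from conftest import make_geno


class TestLocusFrequencies:
    def test_direct_counts(self):
        geno = make_geno([[0], [1], [2]])
        fr = locus_frequencies(geno, {"S1": "p", "S2": "p", "S3": "p"})
        assert fr.p["p"][0] == pytest.approx(0.5)
        assert fr.h_obs["p"][0] == pytest.approx(1 / 3)
        assert fr.n["p"][0] == 3

    def test_fixed_alternative(self):
        geno = make_geno([[2], [2]])
        fr = locus_frequencies(geno, {"S1": "p", "S2": "p"})
        assert fr.p["p"][0] == 1.0

    def test_missing_excluded_and_hand_table(self):
        # 6-sample toy, 2 loci, against a hand-counted table
        geno = make_geno(
            [[0, 1], [1, MISSING], [2, 0], [0, 0], [1, 2], [MISSING, 1]]
        )
        popmap = {f"S{i}": ("a" if i <= 3 else "b") for i in range(1, 7)}
        fr = locus_frequencies(geno, popmap)
        # pop a = S1,S2,S3: locus1 dosages (0,1,2) -> p=0.5, het 1/3
        assert fr.p["a"][0] == pytest.approx(0.5)
        # pop a locus2: (1, miss, 0) -> p=1/4 over 2 called
        assert fr.p["a"][1] == pytest.approx(0.25)
        assert fr.n["a"][1] == 2
        # pop b = S4,S5,S6: locus1 (0,1,miss) -> p=0.25; locus2 (0,2,1) -> p=0.5
        assert fr.p["b"][0] == pytest.approx(0.25)
        assert fr.h_obs["b"][1] == pytest.approx(1 / 3)

    def test_unknown_sample_errors(self):
        geno = make_geno([[0], [1]])
        with pytest.raises(ValueError, match="absent"):
            locus_frequencies(geno, {"S1": "a", "SX": "a"})


class TestPopulationDiversity:
    def test_closed_forms_at_half_frequency(self):
        # p = 0.5 under HWE genotypes: He = 0.5, Ne = 2, I = ln 2
        geno = make_geno([[0], [1], [1], [2]])
        stats = population_diversity(geno, {s: "p" for s in geno.sample_ids})
        row = stats.loc["p"]
        assert row["He"] == pytest.approx(0.5)
        assert row["Ne"] == pytest.approx(2.0)
        assert row["I"] == pytest.approx(np.log(2))
        assert row["Ho"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "ho, he, fis", [(0.125, 0.236, 0.470), (0.18, 0.33, 0.45)]
    )
    def test_fixation_index_identity(self, ho, he, fis):
        """1 - Ho/He reproduces the published inbreeding coefficients."""
        assert inbreeding_coefficient(ho, he) == pytest.approx(fis, abs=5e-3)

    def test_fis_identity_holds_exactly(self, small_geno):
        geno, popmap, _ = small_geno
        stats = population_diversity(geno, popmap)
        for pop in stats.index[:-1]:  # skip the Average row
            row = stats.loc[pop]
            assert row["FIS"] == pytest.approx(
                1.0 - row["Ho"] / row["He"], abs=1e-12
            )

    def test_average_row_is_unweighted_mean(self, small_geno):
        geno, popmap, _ = small_geno
        stats = population_diversity(geno, popmap)
        pops = stats.drop(index="Average")
        np.testing.assert_allclose(
            stats.loc["Average", ["He", "Ho", "Ne", "FIS"]].astype(float),
            pops[["He", "Ho", "Ne", "FIS"]].mean().astype(float),
            rtol=1e-12,
        )

    def test_fit_uses_total_heterozygosity(self, small_geno):
        geno, popmap, _ = small_geno
        stats = population_diversity(geno, popmap)
        # FIT >= FIS on structured data (Wahlund: He_total >= mean He_pop)
        pops = stats.drop(index="Average")
        assert (pops["FIT"] >= pops["FIS"] - 1e-9).all()

    def test_fixed_locus_fis_missing(self):
        geno = make_geno([[2], [2], [2]])
        stats = population_diversity(geno, {s: "p" for s in geno.sample_ids})
        assert np.isnan(stats.loc["p", "FIS"])


class TestPairwiseFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(10)
        block = rng.binomial(2, 0.4, size=(30, 300)).astype(np.int16)
        geno = make_geno(np.vstack([block, block]))
        popmap = {f"S{i + 1}": ("a" if i < 30 else "b") for i in range(60)}
        fst = pairwise_fst(geno, popmap)
        # duplicated arrays have zero between-pop variance, so the
        # unbiased estimator sits at or slightly below zero
        assert -0.05 < fst.loc["a", "b"] <= 0.0

    def test_complete_differentiation(self):
        geno = make_geno(
            np.vstack([np.zeros((40, 100)), np.full((40, 100), 2)]).astype(np.int16)
        )
        popmap = {f"S{i + 1}": ("a" if i < 40 else "b") for i in range(80)}
        fst = pairwise_fst(geno, popmap)
        assert fst.loc["a", "b"] == pytest.approx(1.0, abs=0.02)

    def test_symmetric_zero_diagonal(self, small_geno):
        geno, popmap, _ = small_geno
        fst = pairwise_fst(geno, popmap)
        np.testing.assert_allclose(fst.to_numpy(), fst.to_numpy().T)
        assert np.allclose(np.diag(fst), 0.0)

    def test_clamp_option(self):
        rng = np.random.default_rng(11)
        # tiny samples of one panmictic pool often give negative estimates
        block = rng.binomial(2, 0.5, size=(8, 50)).astype(np.int16)
        geno = make_geno(block)
        popmap = {f"S{i + 1}": ("a" if i < 4 else "b") for i in range(8)}
        clamped = pairwise_fst(geno, popmap, clamp_negative=True)
        assert clamped.loc["a", "b"] >= 0.0

    def test_balding_nichols_recovery_two_pops(self):
        """Pairwise Weir-Cockerham estimates recover the simulated
        differentiation (F = 0.10) within Monte-Carlo error."""
        estimates = []
        for seed in range(20):
            cfg = GenoSimConfig(
                n_pops=2, samples_per_pop=10, n_loci=200, fst=0.10,
                selfing_rate=0.0, seed=seed,
            )
            geno, popmap, _ = simulate_genotypes(cfg)
            estimates.append(pairwise_fst(geno, popmap).iloc[0, 1])
        assert 0.07 <= np.mean(estimates) <= 0.13


class TestPDistance:
    def test_identical_and_maximal(self):
        geno = make_geno([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        d = p_distance_matrix(geno)
        assert d.iloc[0, 1] == 0.0
        geno2 = make_geno([[0, 0], [2, 2]])
        assert p_distance_matrix(geno2).iloc[0, 1] == 1.0

    def test_hand_example_with_missing(self):
        # 3 samples x 4 loci; pairwise-complete means
        geno = make_geno(
            [[0, 1, 2, MISSING], [1, 1, 0, 2], [2, MISSING, 2, 0]]
        )
        d = p_distance_matrix(geno)
        # S1-S2: |0-1|+|1-1|+|2-0| over 3 shared loci, /2 -> (1+0+2)/6
        assert d.iloc[0, 1] == pytest.approx(3 / 6)
        # S1-S3: loci 1,3 shared -> (2+0)/4
        assert d.iloc[0, 2] == pytest.approx(0.5)
        # S2-S3: loci 1,3,4 shared -> (1+2+2)/6
        assert d.iloc[1, 2] == pytest.approx(5 / 6)

    def test_no_shared_loci_errors(self):
        geno = make_geno([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="share no called loci"):
            p_distance_matrix(geno)


def random_additive_matrix(n_taxa: int, rng) -> tuple[pd.DataFrame, dendropy.Tree]:
    """Random binary tree with positive branch lengths and its exact
    patristic (additive) distance matrix — the NJ consistency oracle."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    tree.taxon_namespace.sort(key=lambda t: t.label)
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon.label = taxa[i]
    for edge in tree.edges():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.1, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    lut = {t.label: t for t in tree.taxon_namespace}
    d = pd.DataFrame(
        [[pdm.patristic_distance(lut[a], lut[b]) if a != b else 0.0
          for b in labels] for a in labels],
        index=labels, columns=labels,
    )
    return d, tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(d)
        assert tree.to_newick() == "(A:1,B:1,C:3);"

    def test_four_taxon_additive_exact(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:4))
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(d).to_dendropy()
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        d.loc[a, b], abs=1e-9
                    )
        # cherry (A,B) present: A and B are siblings
        mrca = pdm.mrca(taxa["A"], taxa["B"])
        assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == {"A", "B"}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_taxa):
        """NJ is consistent: patristic distances of the inferred tree
        reproduce any additive input matrix."""
        rng = np.random.default_rng(n_taxa)
        d, _ = random_additive_matrix(n_taxa, rng)
        out = neighbor_joining(d).to_dendropy()
        pdm = out.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in out.taxon_namespace}
        for a in d.index:
            for b in d.index:
                if a != b:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        d.loc[a, b], abs=1e-9
                    )

    def test_agrees_with_dendropy_topology(self):
        """Independent-route check: same topology as dendropy's NJ."""
        rng = np.random.default_rng(99)
        d, _ = random_additive_matrix(6, rng)
        mine = neighbor_joining(d).to_dendropy()

        csv = "," + ",".join(d.columns) + "\n" + "\n".join(
            f"{a}," + ",".join(f"{d.loc[a, b]:.10f}" for b in d.columns)
            for a in d.index
        )
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        ns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine.as_string(schema="newick"),
                               schema="newick", taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=theirs.as_string(schema="newick"),
                               schema="newick", taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_nan_rejected_and_min_taxa(self):
        bad = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            neighbor_joining(bad)
        small = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"), dtype=float)
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(small)


class TestGenotypePca:
    def test_clones_identical_coordinates(self):
        rng = np.random.default_rng(12)
        row = rng.binomial(2, 0.4, size=100).astype(np.int16)
        other = rng.binomial(2, 0.4, size=(6, 100)).astype(np.int16)
        geno = make_geno(np.vstack([row, row, other]))
        coords, _ = genotype_pca(geno, n_components=3)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_grm_matches_brute_force(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, 0.5, size=(5, 8)).astype(np.int16)
        # ensure polymorphic loci
        g[0] = 0
        g[1] = 2
        geno = make_geno(g)
        grm = genetic_relationship_matrix(geno)
        p = geno.allele_frequencies()
        keep = (p > 0) & (p < 1)
        z = (g[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        expected = z @ z.T / keep.sum()
        np.testing.assert_allclose(grm, expected, atol=1e-10)

    def test_monomorphic_loci_skipped(self):
        g = np.zeros((4, 3), dtype=np.int16)
        g[:, 1] = [0, 1, 1, 2]
        geno = make_geno(g)
        grm = genetic_relationship_matrix(geno)
        assert grm.shape == (4, 4)

    def test_structured_populations_separate_on_pc1(self):
        cfg = GenoSimConfig(
            n_pops=2, samples_per_pop=25, n_loci=800, fst=0.2,
            selfing_rate=0.0, seed=21,
        )
        geno, popmap, _ = simulate_genotypes(cfg)
        coords, eigvals = genotype_pca(geno, n_components=2)
        labels = np.array([popmap[s] for s in geno.sample_ids])
        from sklearn.metrics import silhouette_score

        sil = silhouette_score(coords[["PC1"]], labels)
        assert sil > 0.5
        assert eigvals[0] > eigvals[1]
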