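"""Distance matrices, neighbor joining, rooting, and tree comparison."""
import dendropy
import numpy as np
import pytest

from mitopop.io import ValidationError
from mitopop.phylo import (DistanceMatrix, from_newick, jukes_cantor,
                           neighbor_joining, p_distance_matrix,
                           population_rf, robinson_foulds,
                           root_with_outgroup, to_newick)


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths and its additive
    distance matrix (path lengths between tips)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = {t: ([t], {t: 0.0}) for t in taxa}  # tips below, dist to each
    newicks = {t: t for t in taxa}
    keys = list(taxa)
    d = {}
    while len(keys) > 1:
        i, j = sorted(rng.choice(len(keys), size=2, replace=False))
        a, b = keys[i], keys[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        (ta, da), (tb, db) = nodes[a], nodes[b]
        for x in ta:
            for y in tb:
                d[(x, y)] = d[(y, x)] = da[x] + la + db[y] + lb
        merged = ta + tb
        dist = {x: da[x] + la for x in ta}
        dist.update({y: db[y] + lb for y in tb})
        name = f"({newicks[a]}:{la},{newicks[b]}:{lb})"
        key = name
        nodes[key] = (merged, dist)
        newicks[key] = name
        keys = [k for k in keys if k not in (a, b)] + [key]
    mat = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(n_taxa):
            if x != y:
                mat[x, y] = d[(taxa[x], taxa[y])]
    return DistanceMatrix(taxa, mat), newicks[keys[0]] + ";"


def patristic(tree):
    """Tip-to-tip path lengths from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], out


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestPDistance:
    def test_identical_and_divergent_rows(self):
        aln = [("a", "A" * 100), ("b", "A" * 95 + "C" * 5), ("c", "A" * 100)]
        d = p_distance_matrix(aln)
        assert d[("a", "c")] == 0.0
        assert d[("a", "b")] == pytest.approx(0.05)

    def test_gap_handling_by_mode(self):
        aln = [("a", "AAAA-"), ("b", "AAAAC")]
        assert p_distance_matrix(aln, "without_indels")[("a", "b")] == 0.0
        assert p_distance_matrix(aln, "with_indels")[("a", "b")] == pytest.approx(0.2)

    def test_symmetric_on_random_alignments(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT-"), 60)) for _ in range(6)]
        d = p_distance_matrix([(f"t{i}", r) for i, r in enumerate(rows)],
                              "with_indels")
        assert np.allclose(d.values, d.values.T)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0.0, 0.4, 0.6],
                                     [0.4, 0.0, 0.8],
                                     [0.6, 0.8, 0.0]]))
        tree = neighbor_joining(d)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 0.1, "b": 0.3, "c": 0.5})

    def test_additive_four_taxon_exact_recovery(self):
        rng = np.random.default_rng(1)
        d, newick = random_additive_tree(rng, 4)
        tree = neighbor_joining(d)
        assert robinson_foulds(tree, from_newick(newick)) == 0
        labels, pat = patristic(tree)
        order = [d.taxa.index(x) for x in labels]
        assert np.allclose(pat, d.values[np.ix_(order, order)], atol=1e-9)

    def test_zero_divergence_gives_zero_branches(self):
        d = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        tree = neighbor_joining(d)
        for edge in tree.preorder_edge_iter():
            assert not edge.length

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        for _ in range(10):
            d, _ = random_additive_tree(rng, 7)
            noise = rng.uniform(0, 0.02, size=d.values.shape)
            vals = d.values + (noise + noise.T)  # keep exact symmetry
            vals = np.maximum(vals, vals.T)
            np.fill_diagonal(vals, 0.0)
            noisy = DistanceMatrix(d.taxa, vals)
            mine = neighbor_joining(noisy)
            ref = skbio.tree.nj(skbio.DistanceMatrix(noisy.values, ids=noisy.taxa))
            assert robinson_foulds(mine, from_newick(str(ref.root()))) == 0


class TestRooting:
    def test_outgroup_sister_to_all_ingroup(self):
        rng = np.random.default_rng(3)
        d, _ = random_additive_tree(rng, 6)
        rooted = root_with_outgroup(neighbor_joining(d), "t0")
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [{l.taxon.label for l in c.leaf_iter()} for c in children]
        assert {"t0"} in sides

    def test_rooting_preserves_unrooted_topology(self):
        rng = np.random.default_rng(4)
        d, _ = random_additive_tree(rng, 6)
        tree = neighbor_joining(d)
        assert robinson_foulds(root_with_outgroup(tree, "t3"), tree) == 0

    def test_missing_outgroup_raises(self):
        rng = np.random.default_rng(5)
        d, _ = random_additive_tree(rng, 4)
        with pytest.raises(KeyError):
            root_with_outgroup(neighbor_joining(d), "absent")


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert robinson_foulds(t, from_newick(to_newick(t))) == 0

    def test_conflicting_four_taxon_trees(self):
        t1 = from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_invariant_to_tip_order(self):
        t1 = from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = from_newick("((d:1,c:1):1,(b:1,a:1):1);")
        assert robinson_foulds(t1, t2) == 0


class TestJukesCantor:
    def test_small_distance_nearly_identity(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.01], [0.01, 0.0]]))
        jc = jukes_cantor(d)
        assert jc[("a", "b")] == pytest.approx(0.01, rel=0.02)


class TestPopulationRf:
    def test_concordant_and_discordant(self):
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                "c1": "C", "c2": "C", "d1": "D", "d2": "D"}
        planted = "((A:1,B:1):1,(C:1,D:1):1);"
        good = from_newick(
            "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,((c1:1,c2:1):1,(d1:1,d2:1):1):1);")
        assert population_rf(good, pops, planted) == 0
        mixed = from_newick(
            "(((a1:1,b2:1):1,(b1:1,a2:1):1):1,((c1:1,c2:1):1,(d1:1,d2:1):1):1);")
        assert population_rf(mixed, pops, planted) > 0


class TestSimulationCladeRecovery:
    """Populations simulated with distinct intron signatures and >= 0.01
    between-population divergence are recovered as clades by both the
    concatenated-CDS tree and the binary-character intron tree, and the
    two trees are concordant at the population level."""

    TREE = ("((wine_euro:0.005,north_american:0.005):0.002,"
            "(west_african:0.005,sake:0.005):0.002);")

    def _simulate(self, seed):
        from mitopop.introns import binary_distance
        from mitopop.simulate import (SimConfig, distinct_intron_profiles,
                                      simulate_population_set)
        profiles = distinct_intron_profiles()
        pops = ["wine_euro", "north_american", "west_african", "sake"]
        cfg = SimConfig(
            n_strains_per_population=3, genome_length_target=16_000,
            population_tree=self.TREE,
            intron_site_profiles={p: profiles[p] for p in pops},
            gc_class_count_profiles={p: {} for p in pops},
            intergenic_indel_rate=0.0, within_population_divergence=0.001,
            # neutral CDS rates: the stated condition is >= 0.01
            # substitutions/site between populations at the analyzed sites
            cds_rate_scale=1.0, nonsynonymous_acceptance=1.0,
            n_conserved_clusters=0, rng_seed=seed)
        return simulate_population_set(cfg)

    @pytest.mark.parametrize("seed", range(4))
    def test_cds_and_intron_trees_concordant_with_planted_populations(self, seed):
        import numpy as np
        from mitopop.introns import binary_distance
        from mitopop.simulate import GENE_ORDER
        genomes, truth = self._simulate(seed)
        aln = truth.alignment
        cds_cols = np.flatnonzero(
            np.isin(truth.column_gene, list(GENE_ORDER))
            & (aln.region_labels == "exon"))
        cds_rows = [(t, aln.array[i, cds_cols].tobytes().decode())
                    for i, t in enumerate(aln.taxa)]
        cds_tree = neighbor_joining(p_distance_matrix(cds_rows))
        intron_tree = neighbor_joining(
            binary_distance(truth.intron_presence.astype(float)))
        assert population_rf(cds_tree, truth.populations,
                             truth.population_tree) == 0
        assert population_rf(intron_tree, truth.populations,
                             truth.population_tree) == 0


class TestAdditiveRecoveryProperty:
    def test_nj_recovers_random_additive_trees(self):
        """NJ is exact on additive matrices (4-12 taxa, 200 replicates)."""
        rng = np.random.default_rng(42)
        for rep in range(200):
            n = int(rng.integers(4, 13))
            d, newick = random_additive_tree(rng, n)
            tree = neighbor_joining(d)
            assert robinson_foulds(tree, from_newick(newick)) == 0
            labels, pat = patristic(tree)
            order = [d.taxa.index(x) for x in labels]
            assert np.allclose(pat, d.values[np.ix_(order, order)], atol=1e-8)
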