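"""Distance matrices, neighbor-joining trees, rooting, and tree comparison.

The neighbor-joining implementation follows Saitou & Nei's agglomeration
with the standard Q criterion. Trees are dendropy objects throughout, so
Newick serialization and Robinson-Foulds comparison ride on dendropy.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .io import ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxa")
        if np.isnan(self.values).any():
            raise ValidationError("NaN in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValidationError("nonzero diagonal in distance matrix")
        if (self.values < -1e-12).any():
            raise ValidationError("negative distances")

    def __getitem__(self, pair):
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return self.values[i, j]


def _usable_matrix(rows: np.ndarray, with_indels: bool) -> np.ndarray:
    usable = np.isin(rows, np.frombuffer(b"ACGT", dtype=np.uint8))
    if with_indels:
        usable |= rows == ord("-")
    return usable


def p_distance_matrix(alignment, mode: str = "without_indels") -> DistanceMatrix:
    """Proportion of differing sites among sites usable in both sequences.

    ``alignment`` is either a :class:`~mitopop.diversity.MultipleAlignment`
    or a list of ``(taxon, aligned_sequence)`` tuples. In
    ``without_indels`` mode gap columns are dropped pairwise; in
    ``with_indels`` mode a gap is a fifth state.
    """
    if hasattr(alignment, "array"):
        taxa, arr = list(alignment.taxa), alignment.array
    else:
        taxa = [t for t, _ in alignment]
        arr = np.array(
            [np.frombuffer(s.upper().encode(), dtype=np.uint8) for _, s in alignment]
        )
    if mode not in {"with_indels", "without_indels"}:
        raise ValueError(f"unknown mode {mode!r}")
    usable = _usable_matrix(arr, mode == "with_indels")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = usable[i] & usable[j]
            m = int(shared.sum())
            if m == 0:
                raise ValidationError(
                    f"no shared usable sites between {taxa[i]} and {taxa[j]}"
                )
            diff = int((arr[i][shared] != arr[j][shared]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(taxa, d)


def jukes_cantor(d: DistanceMatrix) -> DistanceMatrix:
    """Jukes-Cantor correction of p-distances (optional; divergence here is
    small enough that the correction is nearly the identity)."""
    p = d.values
    if (p >= 0.75).any():
        raise ValidationError("p-distance >= 0.75 not JC-correctable")
    vals = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(d.taxa), vals)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the lowest (i, j) index pair so
    output is reproducible. Negative branch lengths are clamped to zero
    with the deficit transferred to the sister branch.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    if np.isnan(D.values).any():
        raise ValidationError("NaN in distance matrix")

    tns = dendropy.TaxonNamespace(list(D.taxa))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for label in D.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)

    d = D.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair among ties
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < q[best[0], best[1]] - 1e-15:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to all other active nodes
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for c in active:
            if c in (i, j):
                continue
            d[u, c] = d[c, u] = 0.5 * (d[i, c] + d[j, c] - dij)
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [u]

    # final trifurcation
    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, taxon: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    leaf = None
    for node in rooted.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == taxon:
            leaf = node
            break
    if leaf is None:
        raise KeyError(f"outgroup taxon {taxon!r} not in tree")
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half)
    rooted.is_rooted = True
    return rooted


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric difference of
    nontrivial bipartitions), computed on the unrooted topologies."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=tns,
                          preserve_underscores=True)
    b = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=tns,
                          preserve_underscores=True)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def population_rf(tree: dendropy.Tree, populations: dict,
                  planted_newick: str) -> int:
    """Distance between a strain-level tree and a planted population
    topology.

    0 means every population is monophyletic (as an unrooted bipartition)
    and the induced population-level topology matches the planted tree;
    otherwise the RF distance of the induced topology plus 2 per
    non-monophyletic population.
    """
    strain_tree = from_newick(to_newick(tree))
    labels = {l.taxon.label for l in strain_tree.leaf_node_iter()}
    clades = set()
    for node in strain_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    pops: dict = {}
    for strain, pop in populations.items():
        if strain in labels:
            pops.setdefault(pop, set()).add(strain)
    n_bad = 0
    reps = []
    for pop, members in sorted(pops.items()):
        members = frozenset(members)
        if members not in clades and frozenset(labels - members) not in clades:
            n_bad += 1
        reps.append((pop, sorted(members)[0]))
    induced = strain_tree.extract_tree_with_taxa_labels([r for _, r in reps])
    for leaf in induced.leaf_node_iter():
        for pop, rep in reps:
            if leaf.taxon.label == rep:
                leaf.taxon = dendropy.Taxon(label=pop)
    rf = robinson_foulds(induced, from_newick(planted_newick))
    return rf + 2 * n_bad


# ---------------------------------------------------------------------------
# Newick


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(path) -> dendropy.Tree:
    return from_newick(Path(path).read_text())
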