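"""Neighbor joining, separation queries, bootstrap and consensus."""

import numpy as np
import pytest

from hotspotscan import (
    DistanceMatrix,
    SimConfig,
    bootstrap_separation_support,
    is_monophyletic_midpoint,
    majority_rule_consensus,
    neighbor_joining,
    parse_tree,
    random_split_consensus,
    simulate_dataset,
    species_separation,
)
from hotspotscan.phylo import _leafsets, has_bipartition

from conftest import make_alignment


def _patristic(tree, a, b):
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.patristic_distance(ta, tb)


def _bipartitions(tree):
    """Independent bipartition enumeration for oracle comparisons."""
    full = frozenset(l.taxon.label for l in tree.leaf_node_iter())

    def collect(node):
        if node.is_leaf():
            return frozenset([node.taxon.label])
        s = frozenset().union(*(collect(c) for c in node.child_nodes()))
        if node.parent_node is not None and 1 < len(s) < len(full) - 1:
            sides.add(min(s, full - s, key=sorted))
        return s

    sides = set()
    collect(tree.seed_node)
    return sides


def random_additive_case(rng, n_leaves):
    """Random binary unrooted topology with positive lengths and its exact
    leaf-to-leaf path-length matrix (the oracle that generated the data)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    # random sequential joins; track leaf-path lengths through a simple graph
    import networkx as nx

    g = nx.Graph()
    nodes = list(labels)
    g.add_nodes_from(nodes)
    nxt = 0
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = f"i{nxt}"; nxt += 1
        g.add_edge(nodes[i], u, weight=float(rng.uniform(0.5, 2.0)))
        g.add_edge(nodes[j], u, weight=float(rng.uniform(0.5, 2.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [u]
    centre = f"i{nxt}"
    for n in nodes:
        g.add_edge(n, centre, weight=float(rng.uniform(0.5, 2.0)))
    D = np.zeros((n_leaves, n_leaves))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for a in range(n_leaves):
        for b in range(n_leaves):
            D[a, b] = paths[labels[a]][labels[b]]
    # oracle bipartitions = leaf splits of the generating graph's internal edges
    sides = set()
    full = frozenset(labels)
    for e in g.edges:
        h = g.copy(); h.remove_edge(*e)
        comp = frozenset(c for c in nx.node_connected_component(h, e[0]) if c in full)
        if 1 < len(comp) < n_leaves - 1:
            sides.add(min(comp, full - comp, key=sorted))
    return labels, D, sides


def test_two_leaf_tree_single_edge():
    t = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))
    assert _patristic(t, "A", "B") == pytest.approx(1.0)


def test_three_leaf_closed_form():
    D = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    t = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
    # a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 3
    assert _patristic(t, "A", "B") == pytest.approx(3.0)
    assert _patristic(t, "A", "C") == pytest.approx(4.0)
    assert _patristic(t, "B", "C") == pytest.approx(5.0)


def test_nj_recovers_generating_topology():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(6, 9))
        labels, D, truth_sides = random_additive_case(rng, n)
        t = neighbor_joining(DistanceMatrix(labels, D))
        assert _bipartitions(t) == truth_sides


def test_nj_edge_count_and_leaf_preservation():
    rng = np.random.default_rng(9)
    for n in (4, 7, 12):
        raw = rng.uniform(1, 4, size=(n, n))
        D = (raw + raw.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"x{i}" for i in range(n)]
        t = neighbor_joining(DistanceMatrix(labels, D))
        assert sum(1 for _ in t.leaf_node_iter()) == n
        n_edges = sum(1 for node in t.preorder_node_iter() if node.parent_node)
        assert n_edges == 2 * n - 3


def test_nj_agrees_with_scikit_bio_on_additive_matrix():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    import io

    rng = np.random.default_rng(17)
    labels, D, _ = random_additive_case(rng, 7)
    D = (D + D.T) / 2  # exact symmetry for skbio's validator
    ours = _bipartitions(neighbor_joining(DistanceMatrix(labels, D)))
    sk_tree = sk_nj(SkDM(D, ids=labels))
    buf = io.StringIO()
    sk_tree.write(buf)
    theirs = _bipartitions(parse_tree(buf.getvalue()))
    assert ours == theirs


def test_fewer_than_two_labels_rejected():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["A"], np.zeros((1, 1))))


# --- separation & monophyly --------------------------------------------------

def test_species_separation_clean_split():
    t = parse_tree("((A1:1,A2:1):1,(B1:1,B2:1):1);")
    assert species_separation(t, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})


def test_species_separation_interleaved():
    t = parse_tree("((A1:1,B1:1):1,(A2:1,B2:1):1);")
    assert not species_separation(t, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})


def test_separation_agrees_with_bruteforce_on_random_trees():
    rng = np.random.default_rng(23)
    for _ in range(20):
        labels, D, _ = random_additive_case(rng, 10)
        t = neighbor_joining(DistanceMatrix(labels, D))
        picks = rng.choice(labels, size=4, replace=False)
        side = set(picks)
        full = frozenset(labels)
        expected = any(
            s == frozenset(side) or s == full - side for s in _leafsets(t)
        )
        assert has_bipartition(t, side) == expected


def test_midpoint_monophyly_detects_intruder():
    # x sits inside the left cluster; unrooted complement would hide that
    t = parse_tree("(((A1:0.1,A2:0.1):0.1,x:0.1):5.0,(B1:0.1,B2:0.1):0.1);")
    assert not is_monophyletic_midpoint(t, {"B1", "B2", "x"})
    assert is_monophyletic_midpoint(t, {"A1", "A2", "x"})


# --- bootstrap ---------------------------------------------------------------

def test_zero_variation_support_deterministic_regression():
    """All-identical alignment: every replicate hits the documented
    lexicographic tie-break, so support is a fixed value (locked at 100 here:
    same-species haplotype labels sort together and coalesce first)."""
    seqs = {f"a{i}": ("A" * 60, "A" * 60) for i in range(1, 4)}
    seqs.update({f"b{i}": ("A" * 60, "A" * 60) for i in range(1, 4)})
    aln = make_alignment(seqs)
    species = {s: s[0].upper() for s in seqs}
    s1 = bootstrap_separation_support(aln, species, reps=20, seed=1)
    s2 = bootstrap_separation_support(aln, species, reps=20, seed=99)
    assert s1 == s2 == 100.0


def test_hotspot_gene_support_high_background_low(small_sim):
    ds, truth = small_sim
    species = ds.species_map
    hot = next(g for g, c in truth.gene_class.items() if c == "hotspot")
    bg = next(g for g, c in truth.gene_class.items() if c == "background")
    assert bootstrap_separation_support(ds.gene(hot), species, reps=100, seed=7) >= 95
    assert bootstrap_separation_support(ds.gene(hot), species, reps=100, seed=7, level="protein") >= 95
    assert bootstrap_separation_support(ds.gene(bg), species, reps=100, seed=7, level="protein") < 95


def test_bootstrap_seed_reproducible(small_sim):
    ds, truth = small_sim
    g = ds.nuclear_genes[0]
    s1 = bootstrap_separation_support(g, ds.species_map, reps=30, seed=5)
    s2 = bootstrap_separation_support(g, ds.species_map, reps=30, seed=5)
    assert s1 == s2


# --- consensus ---------------------------------------------------------------

def test_consensus_of_identical_trees_keeps_topology():
    trees = [parse_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);") for _ in range(10)]
    cons = majority_rule_consensus(trees)
    assert _bipartitions(cons) == _bipartitions(trees[0])
    supports = [float(n.label) for n in cons.preorder_node_iter()
                if not n.is_leaf() and n.label]
    assert supports and all(s == 100.0 for s in supports)


def test_consensus_retains_majority_split_with_its_percentage():
    with_x = parse_tree("((A:1,B:1):1,C:1,D:1);")
    without = parse_tree("((A:1,C:1):1,B:1,D:1);")
    cons = majority_rule_consensus([with_x] * 6 + [without] * 4)
    assert _bipartitions(cons) == {frozenset({"A", "B"})}
    labels = [n.label for n in cons.preorder_node_iter() if not n.is_leaf() and n.label]
    assert labels == ["60"]


def test_consensus_matches_bruteforce_split_counts():
    rng = np.random.default_rng(31)
    labels = None
    trees = []
    base_labels, D, _ = random_additive_case(rng, 8)
    for _ in range(9):
        _, D, _ = random_additive_case(rng, 8)
        trees.append(neighbor_joining(DistanceMatrix(base_labels, D)))
    counts = {}
    for t in trees:
        for s in _bipartitions(t):
            counts[s] = counts.get(s, 0) + 1
    expected = {s for s, c in counts.items() if c / len(trees) > 0.5}
    assert _bipartitions(majority_rule_consensus(trees)) == expected


def test_consensus_mismatched_leafsets_rejected():
    t1 = parse_tree("((A,B),C,D);")
    t2 = parse_tree("((A,B),C,E);")
    with pytest.raises(ValueError):
        majority_rule_consensus([t1, t2])


def test_consensus_of_single_tree_is_that_tree_at_full_support():
    t = parse_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
    cons = majority_rule_consensus([t])
    assert _bipartitions(cons) == _bipartitions(t)


# --- random splits -----------------------------------------------------------

def test_random_split_zero_variation_fully_deterministic():
    """Zero-variation alignment: the lexicographic tie-break makes every block
    tree identical, so the consensus is that fixed topology at 100% support
    (not an arbitrary resolution)."""
    from hotspotscan import write_tree

    seqs = {f"s{i}": ("A" * 40, "A" * 40) for i in range(6)}
    aln = make_alignment(seqs)
    cons, block_trees, _ = random_split_consensus(aln, k=4, seed=1)
    assert len(block_trees) == 4
    assert len({write_tree(t) for t in block_trees}) == 1
    supports = [float(n.label) for n in cons.preorder_node_iter()
                if not n.is_leaf() and n.label]
    assert supports and all(s == 100.0 for s in supports)
    cons2, _, _ = random_split_consensus(aln, k=4, seed=99)
    assert write_tree(cons2) == write_tree(cons)


def test_random_split_structured_alignment_full_support(small_sim):
    from hotspotscan import concatenate

    ds, _ = small_sim
    cat = concatenate(ds, [g.gene_id for g in ds.nuclear_genes])
    cons, block_trees, support = random_split_consensus(
        cat, k=2, seed=3, species_map=ds.species_map)
    assert support == 100.0


def test_random_split_deterministic_for_seed(small_sim):
    from hotspotscan import concatenate, write_tree

    ds, _ = small_sim
    cat = concatenate(ds, [g.gene_id for g in ds.nuclear_genes[:6]])
    c1, _, s1 = random_split_consensus(cat, k=5, seed=11, species_map=ds.species_map)
    c2, _, s2 = random_split_consensus(cat, k=5, seed=11, species_map=ds.species_map)
    assert write_tree(c1) == write_tree(c2) and s1 == s2


def test_random_split_requires_at_least_two_blocks(small_sim):
    ds, _ = small_sim
    with pytest.raises(ValueError):
        random_split_consensus(ds.nuclear_genes[0], k=1, seed=0)
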