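"""Distance-based tree inference and support estimation.

Trees are built by Saitou–Nei neighbor joining on percent p-distance matrices,
mirroring the distance trees of the original analysis. Q-matrix ties are broken
by the lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest leaf), which makes degenerate zero-variation inputs fully
deterministic. Negative branch lengths are clamped to zero.

Species separation ("can this gene's tree split the two species into clean
clades?") is assessed by column bootstrap: resample alignment columns with
replacement, rebuild the NJ tree, and ask whether some edge bipartitions the
leaves exactly along species lines.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .core_io import PhasedGeneAlignment
from .divergence import comparable_mask, translate_cds

log = logging.getLogger("hotspotscan")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(v < 0):
            raise ValueError("negative distances")
        self.values = v


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _nj_topology(D: np.ndarray, labels: list[str]):
    """Core NJ. Returns (children, root_id, cluster_masks) where ``children``
    maps an internal node id to [(child_id, branch_length), ...], leaf ids are
    0..n-1 in label order, and ``cluster_masks`` holds the leaf bitmask of
    every internal cluster created (= the tree's non-trivial bipartitions)."""
    n = len(labels)
    children: dict[int, list[tuple[int, float]]] = {}
    cluster_masks: list[int] = []
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        root = 2
        half = D[0, 1] / 2.0
        children[root] = [(0, half), (1, half)]
        return children, root, cluster_masks

    ids = list(range(n))
    minlabel = {i: labels[i] for i in range(n)}
    mask = {i: 1 << i for i in range(n)}
    Dcur = D.astype(float).copy()
    next_id = n

    while len(ids) > 3:
        m = len(ids)
        r = Dcur.sum(axis=1)
        # r_i + r_j first: keeps Q bit-exactly symmetric so ties pair up
        Q = (m - 2) * Dcur - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tie_pairs = np.argwhere(Q == qmin)
        best = min(
            (tuple(sorted((minlabel[ids[i]], minlabel[ids[j]]))), i, j)
            for i, j in tie_pairs
            if i < j
        )
        _, i, j = best
        dij = Dcur[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        children[u] = [(ids[i], li), (ids[j], lj)]
        mask[u] = mask[ids[i]] | mask[ids[j]]
        minlabel[u] = min(minlabel[ids[i]], minlabel[ids[j]])
        cluster_masks.append(mask[u])

        newrow = 0.5 * (Dcur[i, :] + Dcur[j, :] - dij)
        keep = [k for k in range(m) if k != i and k != j]
        size = m - 1
        Dnew = np.zeros((size, size))
        Dnew[: size - 1, : size - 1] = Dcur[np.ix_(keep, keep)]
        Dnew[size - 1, : size - 1] = newrow[keep]
        Dnew[: size - 1, size - 1] = newrow[keep]
        Dcur = Dnew
        ids = [ids[k] for k in keep] + [u]

    a, b, c = ids
    dab, dac, dbc = Dcur[0, 1], Dcur[0, 2], Dcur[1, 2]
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    root = next_id
    children[root] = [(a, la), (b, lb), (c, lc)]
    return children, root, cluster_masks


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree over ``dm.labels`` (branch lengths in the matrix units)."""
    children, root_id, _ = _nj_topology(dm.values, dm.labels)
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node_id: int) -> dendropy.Node:
        node = dendropy.Node()
        if node_id < len(dm.labels):
            node.taxon = taxa.get_taxon(dm.labels[node_id])
        else:
            for child_id, length in children[node_id]:
                child = build(child_id)
                child.edge.length = length
                node.add_child(child)
        return node

    tree.seed_node = build(root_id)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartition queries
# ---------------------------------------------------------------------------

def _leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label set below every non-root node (each is one side of an edge)."""
    out = []

    def walk(node) -> frozenset[str]:
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(walk(c) for c in node.child_nodes()))
        if node.parent_node is not None:
            out.append(s)
        return s

    walk(tree.seed_node)
    return out


def has_bipartition(tree: dendropy.Tree, side: set[str]) -> bool:
    """True iff removing some edge splits the leaves into ``side`` vs the rest."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    side = frozenset(side)
    if not side < all_leaves or not side:
        raise ValueError("side must be a proper non-empty subset of the leaf set")
    other = all_leaves - side
    return any(s == side or s == other for s in _leafsets(tree))


def species_separation(tree: dendropy.Tree, species_map: dict[str, str]) -> bool:
    """True iff one edge bipartitions the leaves exactly along species lines.

    Leaf labels of the form ``<specimen>-h<k>`` are mapped through their
    specimen; every leaf must resolve to a species."""
    by_species: dict[str, set[str]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        sid = label.rsplit("-h", 1)[0] if "-h" in label else label
        sp = species_map.get(label, species_map.get(sid))
        if sp is None:
            raise ValueError(f"leaf {label!r} has no species assignment")
        by_species.setdefault(sp, set()).add(label)
    if len(by_species) != 2 or any(not v for v in by_species.values()):
        raise ValueError("species separation needs exactly two non-empty species")
    side = min(by_species.values(), key=lambda s: (len(s), sorted(s)))
    return has_bipartition(tree, side)


def is_monophyletic(tree: dendropy.Tree, group: set[str]) -> bool:
    """Monophyly of a leaf-label group on an unrooted tree."""
    return has_bipartition(tree, set(group))


def is_monophyletic_midpoint(tree: dendropy.Tree, group: set[str]) -> bool:
    """Monophyly of a group after midpoint rooting.

    On an unrooted tree the complement of any intact clade is trivially a
    bipartition side, so a species whose members are scattered by introgression
    can still look "monophyletic" in the unrooted sense. Rooting at the
    midpoint of the longest leaf-to-leaf path (the conventional root for
    distance trees without an outgroup) restores the rooted reading: the group
    is monophyletic iff some rooted clade equals it exactly."""
    group = frozenset(group)
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)

    found = False

    def walk(node) -> frozenset[str]:
        nonlocal found
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(walk(c) for c in node.child_nodes()))
        if s == group:
            found = True
        return s

    walk(t.seed_node)
    return found


# ---------------------------------------------------------------------------
# column bootstrap for species separation
# ---------------------------------------------------------------------------

def _haplotype_matrix(alignment: PhasedGeneAlignment, level: str):
    """(labels, uint8 matrix rows=haplotypes, comparability masks)."""
    if level not in ("dna", "protein"):
        raise ValueError("level must be 'dna' or 'protein'")
    labels, rows = [], []
    for sid, hap, seq in alignment.haplotypes():
        if level == "protein":
            seq = translate_cds(seq, alignment.frame_offset)
        labels.append(f"{sid}-h{hap}")
        rows.append(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
    mat = np.vstack(rows)
    comp = np.vstack([comparable_mask(row, protein=(level == "protein")) for row in mat])
    return labels, mat, comp


def _pairwise_site_arrays(mat: np.ndarray, comp: np.ndarray):
    """Per-pair boolean (diff, comparable) arrays of shape (n_pairs, n_columns)."""
    n = mat.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    diff = np.empty((len(pairs), mat.shape[1]), dtype=np.float64)
    compm = np.empty_like(diff)
    for k, (i, j) in enumerate(pairs):
        c = comp[i] & comp[j]
        compm[k] = c
        diff[k] = (mat[i] != mat[j]) & c
    return pairs, diff, compm


def _species_masks(labels: list[str], species_map: dict[str, str]) -> tuple[int, int]:
    species = sorted({species_map[l.rsplit("-h", 1)[0]] for l in labels})
    if len(species) != 2:
        raise ValueError("expected exactly two species")
    mask_a = 0
    for idx, label in enumerate(labels):
        if species_map[label.rsplit("-h", 1)[0]] == species[0]:
            mask_a |= 1 << idx
    full = (1 << len(labels)) - 1
    return mask_a, full & ~mask_a


def _separates(D: np.ndarray, labels: list[str], mask_a: int, mask_b: int) -> bool:
    n = len(labels)
    if bin(mask_a).count("1") == 1 or bin(mask_b).count("1") == 1:
        return True  # a pendant leaf edge always isolates a singleton species
    _, _, cluster_masks = _nj_topology(D, labels)
    full = (1 << n) - 1
    for m in cluster_masks:
        if m == mask_a or m == mask_b or (full & ~m) in (mask_a, mask_b):
            return True
    return False


def bootstrap_separation_support(
    alignment: PhasedGeneAlignment,
    species_map: dict[str, str],
    reps: int = 100,
    seed: int = 0,
    level: str = "dna",
) -> float:
    """Percent of column-bootstrap replicates whose NJ tree separates the species.

    Replicates containing a haplotype pair with zero comparable columns are
    counted as non-separating (and logged)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels, mat, comp = _haplotype_matrix(alignment, level)
    n_cols = mat.shape[1]
    if n_cols == 0:
        raise ValueError("empty alignment")
    pairs, diff, compm = _pairwise_site_arrays(mat, comp)
    mask_a, mask_b = _species_masks(labels, species_map)

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_cols, size=(reps, n_cols))
    counts = np.zeros((n_cols, reps))
    for r in range(reps):
        counts[:, r] = np.bincount(draws[r], minlength=n_cols)

    diffs_rep = diff @ counts      # (n_pairs, reps)
    comps_rep = compm @ counts
    n = len(labels)
    n_sep = 0
    for r in range(reps):
        if np.any(comps_rep[:, r] == 0):
            log.warning("bootstrap replicate %d has an incomparable pair; counted as non-separating", r)
            continue
        pct = 100.0 * diffs_rep[:, r] / comps_rep[:, r]
        D = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            D[i, j] = D[j, i] = pct[k]
        if _separates(D, labels, mask_a, mask_b):
            n_sep += 1
    return 100.0 * n_sep / reps


def distance_matrix_from_alignment(
    alignment: PhasedGeneAlignment, level: str = "dna", one_per_specimen: bool = False
) -> DistanceMatrix:
    """Full-data percent p-distance matrix over haplotype leaves (or one leaf
    per specimen, e.g. for effectively haploid mitochondrial alignments)."""
    labels, mat, comp = _haplotype_matrix(alignment, level)
    if one_per_specimen:
        keep = [i for i, l in enumerate(labels) if l.endswith("-h1")]
        labels = [labels[i].rsplit("-h", 1)[0] for i in keep]
        mat, comp = mat[keep], comp[keep]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = comp[i] & comp[j]
            nc = int(c.sum())
            if nc == 0:
                raise ValueError(f"incomparable pair {labels[i]}, {labels[j]}")
            D[i, j] = D[j, i] = 100.0 * int(((mat[i] != mat[j]) & c).sum()) / nc
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _tree_splits(tree: dendropy.Tree, anchor: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each encoded as the side excluding ``anchor``."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for s in _leafsets(tree):
        side = s if anchor not in s else all_leaves - s
        if 1 < len(side) < len(all_leaves) - 0 and len(all_leaves - side) > 1:
            splits.add(side)
    return splits


def split_frequencies(trees: list[dendropy.Tree]) -> tuple[dict[frozenset[str], int], frozenset[str]]:
    leafsets = {frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees do not share one leaf set")
    all_leaves = next(iter(leafsets))
    anchor = min(all_leaves)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in _tree_splits(t, anchor):
            counts[split] = counts.get(split, 0) + 1
    return counts, all_leaves


def split_support(trees: list[dendropy.Tree], side: set[str]) -> float:
    """Percent of trees containing the given bipartition side."""
    counts, all_leaves = split_frequencies(trees)
    anchor = min(all_leaves)
    side = frozenset(side)
    key = side if anchor not in side else all_leaves - side
    return 100.0 * counts.get(key, 0) / len(trees)


def majority_rule_consensus(trees: list[dendropy.Tree], threshold: float = 0.5) -> dendropy.Tree:
    """Consensus containing exactly the bipartitions present in more than
    ``threshold`` of the input trees, each annotated with its occurrence
    percentage as node support. Output may be multifurcating."""
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    counts, all_leaves = split_frequencies(trees)
    n = len(trees)
    retained = sorted(
        ((side, 100.0 * c / n) for side, c in counts.items() if c / n > threshold),
        key=lambda item: (-len(item[0]), sorted(item[0])),
    )

    # clades > 50% are pairwise compatible; nest them under a root at the anchor
    Node = dict
    root: Node = {"leafset": all_leaves, "children": [], "support": None, "leaf": None}
    for leaf in sorted(all_leaves):
        root["children"].append({"leafset": frozenset([leaf]), "children": [], "support": None, "leaf": leaf})
    for side, support in retained:
        host = root
        descended = True
        while descended:
            descended = False
            for child in host["children"]:
                if side <= child["leafset"] and len(child["leafset"]) > len(side):
                    host = child
                    descended = True
                    break
        new = {"leafset": side, "children": [], "support": support, "leaf": None}
        inside = [c for c in host["children"] if c["leafset"] <= side]
        host["children"] = [c for c in host["children"] if not (c["leafset"] <= side)] + [new]
        new["children"] = inside

    taxa = dendropy.TaxonNamespace(sorted(all_leaves))
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(spec: Node) -> dendropy.Node:
        node = dendropy.Node()
        if spec["leaf"] is not None:
            node.taxon = taxa.get_taxon(spec["leaf"])
        else:
            if spec["support"] is not None:
                node.label = f"{spec['support']:g}"
            for child in sorted(spec["children"], key=lambda c: min(c["leafset"])):
                node.add_child(build(child))
        return node

    tree.seed_node = build(root)
    tree.is_rooted = False
    return tree


def random_split_consensus(
    alignment: PhasedGeneAlignment,
    k: int,
    seed: int,
    species_map: dict[str, str] | None = None,
    threshold: float = 0.5,
    level: str = "dna",
):
    """Randomly permute alignment columns, cut into ``k`` near-equal blocks,
    build one NJ tree per block, and return
    ``(consensus_tree, block_trees, species_split_support_pct)``.

    The species-split support is the percent of block trees whose NJ topology
    separates the two species (None when no species_map is given)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if alignment.length < k:
        raise ValueError("alignment shorter than the number of blocks")
    labels, mat, comp = _haplotype_matrix(alignment, level)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(mat.shape[1])
    blocks = np.array_split(perm, k)

    block_trees = []
    n_sep = 0
    masks = _species_masks(labels, species_map) if species_map else None
    n = len(labels)
    for block in blocks:
        sub, subc = mat[:, block], comp[:, block]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                c = subc[i] & subc[j]
                nc = int(c.sum())
                D[i, j] = D[j, i] = (
                    100.0 * int(((sub[i] != sub[j]) & c).sum()) / nc if nc else 0.0
                )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        block_trees.append(tree)
        if masks and _separates(D, labels, *masks):
            n_sep += 1
    consensus = majority_rule_consensus(block_trees, threshold)
    support = 100.0 * n_sep / k if masks else None
    return consensus, block_trees, support
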