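"""Speciation-hotspot calling and the statistics built on top of it.

A gene is a *raw* hotspot when both its DNA tree and its protein tree separate
the two species with bootstrap support at or above the threshold (default 95%).
A raw hotspot is *conserved* when, in at least one species, the maximal
intraspecific protein divergence stays below the conservation ceiling (default
0.4%) — this removes fast-evolving genes that separate species only because
they tolerate many mutations.

Enrichment uses an exact upper-tail binomial test on flat GO labels:
m = hotspot genes carrying the term, N = number of hotspot genes, p = the
background probability of carrying the term across the analysis universe.
No GO-graph propagation and no multiple-testing correction gates the call
(terms below alpha are "enriched"); a Benjamini–Hochberg column is emitted for
information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import OrthologGroup, Thresholds
from .divergence import GeneDivergenceProfile

_TINY = float(np.nextafter(0, 1))


@dataclass
class HotspotCallSet:
    raw_hotspots: set[str]
    conserved_hotspots: set[str]

    def __post_init__(self):
        if not self.conserved_hotspots <= self.raw_hotspots:
            raise ValueError("conserved hotspots must be a subset of raw hotspots")


def call_hotspots(
    profiles: dict[str, GeneDivergenceProfile],
    supports: dict[str, tuple[float, float]],
    thresholds: Thresholds | None = None,
) -> HotspotCallSet:
    """Apply the two hotspot criteria to per-gene profiles and bootstrap supports.

    ``supports`` maps gene_id -> (dna_support_pct, protein_support_pct); both
    tables must cover the same gene set."""
    thr = thresholds or Thresholds()
    if set(profiles) != set(supports):
        raise ValueError("profiles and supports cover different gene sets")
    raw, conserved = set(), set()
    for gene_id, (dna_s, prot_s) in supports.items():
        if dna_s >= thr.support_min and prot_s >= thr.support_min:
            raw.add(gene_id)
            prof = profiles[gene_id]
            if prof.prot_incomparable:
                continue
            if min(prof.prot_max_intra_by_species.values()) < thr.conserved_max_intra_prot:
                conserved.add(gene_id)
    return HotspotCallSet(raw_hotspots=raw, conserved_hotspots=conserved)


def binomial_upper_tail(m: int, N: int, p_bg: float) -> float:
    """Exact P(X >= m) for X ~ Binomial(N, p_bg)."""
    if not 0 <= m <= N:
        raise ValueError("need 0 <= m <= N")
    if not 0.0 <= p_bg <= 1.0:
        raise ValueError("p_bg outside [0, 1]")
    if m == 0:
        return 1.0
    p = float(stats.binom.sf(m - 1, N, p_bg))
    return min(max(p, _TINY), 1.0)


@dataclass
class EnrichmentResult:
    term: str
    m: int
    N: int
    p_bg: float
    p_value: float
    enriched: bool
    bh_q: float = float("nan")  # informational only


def go_enrichment(
    gene_set: set[str],
    universe: set[str],
    annotations: dict[str, set[str]],
    thresholds: Thresholds | None = None,
    annotated_only: bool = False,
) -> list[EnrichmentResult]:
    """Binomial enrichment of GO terms in ``gene_set`` against ``universe``.

    The universe defaults to all coverage-filtered genes including unannotated
    ones (they dilute the background probability); ``annotated_only`` restricts
    it to genes with at least one term. Results sorted by ascending p-value."""
    thr = thresholds or Thresholds()
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if annotated_only:
        universe = {g for g in universe if annotations.get(g)}
        gene_set = gene_set & universe
        if not universe:
            raise ValueError("empty universe after annotated-only restriction")
    term_bg: dict[str, int] = {}
    for g in universe:
        for t in annotations.get(g, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
    term_m: dict[str, int] = {}
    for g in gene_set:
        for t in annotations.get(g, ()):
            term_m[t] = term_m.get(t, 0) + 1

    N = len(gene_set)
    results = []
    for term, m in term_m.items():
        p_bg = term_bg[term] / len(universe)
        p = binomial_upper_tail(m, N, p_bg)
        results.append(EnrichmentResult(term, m, N, p_bg, p, enriched=p < thr.enrich_alpha))
    results.sort(key=lambda r: (r.p_value, r.term))
    if results:
        pvals = np.array([r.p_value for r in results])
        n = len(pvals)
        q = pvals * n / np.arange(1, n + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        for r, qv in zip(results, q):
            r.bh_q = float(min(qv, 1.0))
    return results


@dataclass
class OverlapDirection:
    m: int
    N: int
    p_bg: float
    p_value: float


@dataclass
class OverlapTestResult:
    """Cross-genus hotspot overlap, evaluated in both directions; the larger
    (conservative) p-value is the headline."""

    direction_1: OverlapDirection
    direction_2: OverlapDirection

    @property
    def conservative_p(self) -> float:
        return max(self.direction_1.p_value, self.direction_2.p_value)


def overlap_test(
    groups: dict[str, tuple[set[str], set[str]]],
    hotspots_genus1: set[str],
    hotspots_genus2: set[str],
) -> OverlapTestResult:
    """Binomial test for hotspot overlap across two genera.

    ``groups`` maps group_id -> (genus-1 gene set, genus-2 gene set), restricted
    to ortholog groups with members from both genera. m = groups containing
    hotspots from both genera; for each direction, N = groups containing the
    focal genus' hotspots and p = probability that a group contains the other
    genus' hotspots."""
    shared = {gid: v for gid, v in groups.items() if v[0] and v[1]}
    if not shared:
        raise ValueError("no ortholog groups shared by both genera")
    with_1 = {gid for gid, (g1, _) in shared.items() if g1 & hotspots_genus1}
    with_2 = {gid for gid, (_, g2) in shared.items() if g2 & hotspots_genus2}
    m = len(with_1 & with_2)
    total = len(shared)
    d1 = OverlapDirection(m, len(with_1), len(with_2) / total,
                          binomial_upper_tail(m, len(with_1), len(with_2) / total) if with_1 else 1.0)
    d2 = OverlapDirection(m, len(with_2), len(with_1) / total,
                          binomial_upper_tail(m, len(with_2), len(with_1) / total) if with_2 else 1.0)
    return OverlapTestResult(d1, d2)


# ---------------------------------------------------------------------------
# ortholog families and expansions
# ---------------------------------------------------------------------------

@dataclass
class Family:
    family_id: str
    members: dict[str, list[tuple[str, int]]]      # species -> [(gene_id, length)]
    go_terms: set[str] = field(default_factory=set)

    def count(self, species: str) -> int:
        return len(self.members.get(species, []))

    def total_length(self, species: str) -> int:
        return sum(ln for _, ln in self.members.get(species, []))


@dataclass
class FamilyTable:
    families: list[Family]
    species: list[str]                              # full species universe


def merge_ortholog_groups(
    raw_groups: list[OrthologGroup],
    annotations: dict[str, set[str]] | None = None,
) -> FamilyTable:
    """Merge raw ortholog groups that share Drosophila anchor proteins into
    families (transitive closure via union–find). Groups without Drosophila
    members remain singleton families. GO terms of a family are the union over
    its member genes."""
    seen: dict[str, str] = {}
    for grp in raw_groups:
        for species, members in grp.members.items():
            for gene_id, _ in members:
                key = f"{species}:{gene_id}"
                if key in seen:
                    raise ValueError(f"gene {gene_id} ({species}) assigned to both "
                                     f"{seen[key]} and {grp.group_id}")
                seen[key] = grp.group_id

    parent = {i: i for i in range(len(raw_groups))}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_dmel: dict[str, int] = {}
    for i, grp in enumerate(raw_groups):
        for d in grp.dmel_ids:
            if d in by_dmel:
                union(i, by_dmel[d])
            else:
                by_dmel[d] = i

    clusters: dict[int, list[OrthologGroup]] = {}
    for i, grp in enumerate(raw_groups):
        clusters.setdefault(find(i), []).append(grp)

    families = []
    species_universe: set[str] = set()
    for root in sorted(clusters):
        grps = clusters[root]
        members: dict[str, list[tuple[str, int]]] = {}
        go: set[str] = set()
        for grp in grps:
            for species, mm in grp.members.items():
                members.setdefault(species, []).extend(mm)
                species_universe.add(species)
                if annotations:
                    for gene_id, _ in mm:
                        go |= annotations.get(gene_id, set())
        fam_id = "+".join(sorted(g.group_id for g in grps))
        families.append(Family(fam_id, {k: sorted(v) for k, v in members.items()}, go))
    return FamilyTable(families, sorted(species_universe))


def detect_expansions(
    table: FamilyTable, focal_species: str, thresholds: Thresholds | None = None
) -> list[str]:
    """Families whose focal-species gene count AND total protein length both
    strictly exceed ``expansion_factor`` times the mean over the other species
    (species absent from a family count as zero)."""
    thr = thresholds or Thresholds()
    if focal_species not in table.species:
        raise ValueError(f"focal species {focal_species!r} absent from family table")
    others = [sp for sp in table.species if sp != focal_species]
    if not others:
        raise ValueError("need at least 2 species to call expansions")
    expanded = []
    for fam in table.families:
        mean_count = sum(fam.count(sp) for sp in others) / len(others)
        mean_len = sum(fam.total_length(sp) for sp in others) / len(others)
        if (fam.count(focal_species) > thr.expansion_factor * mean_count
                and fam.total_length(focal_species) > thr.expansion_factor * mean_len):
            expanded.append(fam.family_id)
    return expanded
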