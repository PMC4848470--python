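"""End-to-end orchestration of the scan on a dataset (synthetic or loaded).

The analysis drivers, the test suite and the acceptance script all run through
these functions so that every reported number comes from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .barcode_select import BarcodeExon, select_barcode_exons, select_barcode_genes
from .core_io import Dataset, Thresholds
from .divergence import GeneDivergenceProfile, concatenate, coverage_filter, gene_profile
from .hotspot_scan import EnrichmentResult, HotspotCallSet, call_hotspots, go_enrichment
from .phylo import (
    bootstrap_separation_support,
    distance_matrix_from_alignment,
    is_monophyletic,
    is_monophyletic_midpoint,
    neighbor_joining,
    random_split_consensus,
    species_separation,
)
from .synthetic_data import TruthTable


@dataclass
class ScanResult:
    analyzable_genes: list[str]
    profiles: dict[str, GeneDivergenceProfile]
    supports: dict[str, tuple[float, float]]
    calls: HotspotCallSet
    enrichment: list[EnrichmentResult]
    barcode_genes: list[str]
    barcode_exons: list[BarcodeExon] = field(default_factory=list)

    @property
    def enriched_terms(self) -> set[str]:
        return {r.term for r in self.enrichment if r.enriched}


def compute_profiles(dataset: Dataset, thresholds: Thresholds | None = None):
    """Coverage filter + per-gene divergence profiles for nuclear genes."""
    thr = thresholds or Thresholds()
    species_map = dataset.species_map
    analyzable = [g for g in coverage_filter(dataset, thr)
                  if not dataset.gene(g).is_mito]
    profiles = {g: gene_profile(dataset.gene(g), species_map) for g in analyzable}
    return analyzable, profiles


def compute_supports(
    dataset: Dataset,
    gene_ids: list[str],
    thresholds: Thresholds | None = None,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Bootstrap species-separation support per gene at the DNA and protein
    level. Per-gene replicate seeds are derived deterministically from ``seed``."""
    thr = thresholds or Thresholds()
    species_map = dataset.species_map
    seeder = np.random.default_rng(seed)
    supports = {}
    for gene_id in gene_ids:
        aln = dataset.gene(gene_id)
        s_dna = bootstrap_separation_support(
            aln, species_map, reps=thr.bootstrap_reps,
            seed=int(seeder.integers(0, 2**31 - 1)), level="dna")
        s_prot = bootstrap_separation_support(
            aln, species_map, reps=thr.bootstrap_reps,
            seed=int(seeder.integers(0, 2**31 - 1)), level="protein")
        supports[gene_id] = (s_dna, s_prot)
    return supports


def run_scan(
    dataset: Dataset,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    with_exons: bool = True,
) -> ScanResult:
    """Full scan: profiles -> supports -> hotspot calls -> GO enrichment ->
    barcode genes and exons."""
    thr = thresholds or Thresholds()
    analyzable, profiles = compute_profiles(dataset, thr)
    supports = compute_supports(dataset, analyzable, thr, seed=seed)
    calls = call_hotspots(profiles, supports, thr)
    universe = set(analyzable)
    enrichment = (
        go_enrichment(calls.conserved_hotspots, universe, dataset.go_annotations, thr)
        if calls.conserved_hotspots else []
    )
    enriched_terms = {r.term for r in enrichment if r.enriched}
    barcode_genes = select_barcode_genes(profiles, enriched_terms, dataset.go_annotations, thr)
    exons: list[BarcodeExon] = []
    if with_exons:
        species_map = dataset.species_map
        for gene_id in barcode_genes:
            exons.extend(select_barcode_exons(dataset.gene(gene_id), species_map, thr))
    return ScanResult(analyzable, profiles, supports, calls, enrichment, barcode_genes, exons)


def recovery_metrics(called: set[str], truth: TruthTable, target_class: str = "hotspot"):
    """(sensitivity, precision) of a called gene set against a planted class."""
    planted = {g for g, c in truth.gene_class.items() if c == target_class}
    if not planted:
        raise ValueError(f"no planted genes of class {target_class!r}")
    tp = len(called & planted)
    sensitivity = tp / len(planted)
    precision = tp / len(called) if called else 0.0
    return sensitivity, precision


def enrichment_metrics(enrichment: list[EnrichmentResult], truth: TruthTable):
    """(designed-term recall, false-enrichment rate among neutral tested terms)."""
    designed = truth.designed_enriched_terms
    flagged = {r.term for r in enrichment if r.enriched}
    tested_neutral = {r.term for r in enrichment} - designed
    recall = len(flagged & designed) / len(designed) if designed else float("nan")
    false_rate = len(flagged & tested_neutral) / len(tested_neutral) if tested_neutral else 0.0
    return recall, false_rate


@dataclass
class IncongruenceResult:
    """Nuclear vs mitochondrial genealogy contrast on one dataset."""

    nuclear_separates: bool
    nuclear_split_support: float          # % of random-split block trees with the species split
    mito_b_monophyletic: bool
    mito_a_monophyletic: bool
    introgressed_inside_a: bool


def incongruence_analysis(
    dataset: Dataset,
    truth: TruthTable | None = None,
    thresholds: Thresholds | None = None,
    seed: int = 0,
) -> IncongruenceResult:
    """Build the concatenated nuclear tree (with random-split consensus support
    for the species bipartition) and the concatenated mitochondrial tree, then
    test species monophyly on each."""
    thr = thresholds or Thresholds()
    species_map = dataset.species_map
    nuclear_ids = [g.gene_id for g in dataset.nuclear_genes]
    mito_ids = [g.gene_id for g in dataset.mito_genes]
    if not nuclear_ids or not mito_ids:
        raise ValueError("need both nuclear and mitochondrial genes")

    nuc = concatenate(dataset, nuclear_ids)
    nuc_tree = neighbor_joining(distance_matrix_from_alignment(nuc, level="dna"))
    nuclear_separates = species_separation(nuc_tree, species_map)
    _, _, split_sup = random_split_consensus(
        nuc, k=thr.split_count, seed=seed, species_map=species_map,
        threshold=thr.consensus_threshold)

    mito = concatenate(dataset, mito_ids)
    mito_tree = neighbor_joining(
        distance_matrix_from_alignment(mito, level="dna", one_per_specimen=True))
    species_of = {sid: sp for sid, sp in species_map.items()}
    groups: dict[str, set[str]] = {}
    for leaf in mito_tree.leaf_node_iter():
        groups.setdefault(species_of[leaf.taxon.label], set()).add(leaf.taxon.label)
    species = sorted(groups)
    # midpoint-rooted monophyly: the unrooted complement reading would call a
    # species monophyletic whenever the OTHER species forms a clade
    a_mono = is_monophyletic_midpoint(mito_tree, groups[species[0]])
    b_mono = is_monophyletic_midpoint(mito_tree, groups[species[1]])

    introgressed_inside_a = False
    if truth and truth.introgressed_specimens:
        moved = groups[species[1]] - truth.introgressed_specimens
        # introgression signature: the A mitochondria plus those of the
        # introgressed B specimens travel together, while B alone is broken
        combined = groups[species[0]] | truth.introgressed_specimens
        introgressed_inside_a = (not b_mono) and is_monophyletic(mito_tree, combined) and bool(moved)

    return IncongruenceResult(
        nuclear_separates=nuclear_separates,
        nuclear_split_support=split_sup,
        mito_b_monophyletic=b_mono,
        mito_a_monophyletic=a_mono,
        introgressed_inside_a=introgressed_inside_a,
    )


def mean_coding_interspecific_divergence(dataset: Dataset) -> float:
    """Mean percent p-distance over all interspecific haplotype pairs of the
    concatenated nuclear coding alignment."""
    from .divergence import p_distance

    nuc = concatenate(dataset, [g.gene_id for g in dataset.nuclear_genes])
    species_map = dataset.species_map
    haps = nuc.haplotypes()
    vals = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            if species_map[haps[i][0]] != species_map[haps[j][0]]:
                vals.append(p_distance(haps[i][2], haps[j][2]).percent)
    return float(np.mean(vals))
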