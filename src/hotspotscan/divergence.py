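"""Sequence arithmetic: p-distances, CDS translation, per-gene divergence profiles.

Distances are uncorrected p-distances with pairwise deletion: a column enters a
pair's comparison only when both characters are unambiguous (A/C/G/T for DNA,
one of the 20 standard amino acids for protein). Intraspecific comparisons
include the two haplotypes of a single specimen, so within-species divergence
subsumes individual heterozygosity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .core_io import Dataset, PhasedGeneAlignment, Thresholds

log = logging.getLogger("hotspotscan")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

AA_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
_DNA_OK = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PDistance:
    """Result of one pairwise comparison. ``incomparable`` marks a pair with no
    shared unambiguous columns; such pairs are excluded from min/max profiles."""

    percent: float
    diff_count: int
    comparable_count: int

    @property
    def incomparable(self) -> bool:
        return self.comparable_count == 0


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def comparable_mask(arr: np.ndarray, protein: bool = False) -> np.ndarray:
    """Boolean mask of unambiguous characters for one encoded sequence."""
    if protein:
        ok = np.frombuffer("".join(sorted(AA_STANDARD)).encode(), dtype=np.uint8)
    else:
        ok = _DNA_OK
    return np.isin(arr, ok)


def p_distance(seq1: str, seq2: str, protein: bool = False) -> PDistance:
    """Percent of differing positions among pairwise-comparable columns."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences have unequal lengths")
    a, b = _to_bytes(seq1), _to_bytes(seq2)
    comp = comparable_mask(a, protein) & comparable_mask(b, protein)
    n_comp = int(comp.sum())
    if n_comp == 0:
        return PDistance(float("nan"), 0, 0)
    diffs = int(((a != b) & comp).sum())
    return PDistance(100.0 * diffs / n_comp, diffs, n_comp)


def translate_cds(dna_seq: str, frame_offset: int = 0) -> str:
    """Translate an aligned CDS with the standard genetic code.

    Codons containing N or '-' translate to 'X'; stop codons translate to 'X'
    (internal stops additionally log a warning); a trailing partial codon is
    dropped. Total function: never raises on sequence content.
    """
    seq = dna_seq.upper()[frame_offset:]
    n_codons = len(seq) // 3
    out = []
    for i in range(n_codons):
        codon = seq[3 * i: 3 * i + 3]
        if "N" in codon or "-" in codon:
            out.append("X")
            continue
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            if i < n_codons - 1:
                log.warning("internal stop codon %s at codon %d", codon, i)
            aa = "X"
        out.append(aa)
    return "".join(out)


@dataclass
class GeneDivergenceProfile:
    """Per-gene minimum interspecific / maximum intraspecific divergence at the
    DNA and protein level, plus raw DNA difference counts.

    ``dna_max_intra`` is the max over both species; the per-species values back
    the hotspot conservation rule ("conserved within at least one species")."""

    gene_id: str
    dna_min_inter: float
    dna_max_intra: float
    dna_max_intra_by_species: dict[str, float]
    prot_min_inter: float
    prot_max_intra: float
    prot_max_intra_by_species: dict[str, float]
    count_min_inter: int
    count_max_intra: int
    n_comparable_sites: int
    prot_incomparable: bool = False


def _pair_stats(haps: list[tuple[str, int, str]], species_map: dict[str, str], protein: bool):
    """(min_inter, max_intra, max_intra_by_species, count_min_inter, count_max_intra, n_sites)."""
    species = sorted({species_map[sid] for sid, _, _ in haps})
    min_inter = math.inf
    count_min_inter = None
    max_intra = -math.inf
    count_max_intra = 0
    by_species = {sp: -math.inf for sp in species}
    n_sites = 0
    any_inter = False
    for (sid1, _, s1), (sid2, _, s2) in itertools.combinations(haps, 2):
        sp1, sp2 = species_map[sid1], species_map[sid2]
        d = p_distance(s1, s2, protein=protein)
        if d.incomparable:
            continue
        n_sites = max(n_sites, d.comparable_count)
        if sp1 == sp2:
            max_intra = max(max_intra, d.percent)
            count_max_intra = max(count_max_intra, d.diff_count)
            by_species[sp1] = max(by_species[sp1], d.percent)
        else:
            any_inter = True
            min_inter = min(min_inter, d.percent)
            count_min_inter = d.diff_count if count_min_inter is None else min(count_min_inter, d.diff_count)
    if not any_inter:
        return None
    if max_intra == -math.inf:
        max_intra, count_max_intra = 0.0, 0
    by_species = {sp: (0.0 if v == -math.inf else v) for sp, v in by_species.items()}
    return min_inter, max_intra, by_species, count_min_inter, count_max_intra, n_sites


def gene_profile(alignment: PhasedGeneAlignment, species_map: dict[str, str]) -> GeneDivergenceProfile:
    """Exhaustive haplotype-pair divergence profile of one gene."""
    haps = alignment.haplotypes()
    present_species = {species_map[sid] for sid, _, _ in haps}
    if len(present_species) < 2:
        raise ValueError(f"gene {alignment.gene_id}: fewer than two species present")

    dna = _pair_stats(haps, species_map, protein=False)
    if dna is None:
        raise ValueError(f"gene {alignment.gene_id}: no comparable interspecific DNA pair")
    prot_haps = [(sid, hap, translate_cds(seq, alignment.frame_offset)) for sid, hap, seq in haps]
    prot = _pair_stats(prot_haps, species_map, protein=True)
    if prot is None:
        # all-X translations: flagged incomparable, fails selection downstream
        prot = (math.nan, math.nan, {sp: math.nan for sp in sorted(present_species)}, 0, 0, 0)
        prot_incomparable = True
    else:
        prot_incomparable = False

    return GeneDivergenceProfile(
        gene_id=alignment.gene_id,
        dna_min_inter=dna[0], dna_max_intra=dna[1], dna_max_intra_by_species=dna[2],
        prot_min_inter=prot[0], prot_max_intra=prot[1], prot_max_intra_by_species=prot[2],
        count_min_inter=int(dna[3]), count_max_intra=int(dna[4]),
        n_comparable_sites=int(dna[5]),
        prot_incomparable=prot_incomparable,
    )


def coverage_filter(dataset: Dataset, thresholds: Thresholds | None = None) -> list[str]:
    """Genes with enough data for analysis: for EACH species, at least
    ``coverage_min_specimens`` specimens whose two haplotypes are both at least
    ``coverage_min`` non-missing ('N' is missing; gaps count as covered)."""
    thr = thresholds or Thresholds()
    species_map = dataset.species_map
    all_species = sorted(set(species_map.values()))
    kept = []
    for gene in dataset.genes:
        length = gene.length
        if length == 0:
            continue
        ok_per_species = {sp: 0 for sp in all_species}
        for sid in gene.specimen_ids:
            fractions = []
            for hap in (1, 2):
                arr = _to_bytes(gene.sequences[(sid, hap)])
                fractions.append(1.0 - (arr == ord("N")).sum() / length)
            if min(fractions) >= thr.coverage_min:
                ok_per_species[species_map[sid]] += 1
        if all(ok_per_species[sp] >= thr.coverage_min_specimens for sp in all_species):
            kept.append(gene.gene_id)
    return kept


def concatenate(dataset: Dataset, gene_ids: list[str]) -> PhasedGeneAlignment:
    """Concatenate genes column-wise in the given order. Specimens missing a
    gene are padded with 'N'. Per-gene boundaries are kept on the result as
    ``exons`` intervals (one interval per gene)."""
    if not gene_ids:
        raise ValueError("empty gene list")
    genes = [dataset.gene(g) for g in gene_ids]
    specimens = sorted({sid for g in genes for sid in g.specimen_ids})
    parts: dict[tuple[str, int], list[str]] = {(sid, h): [] for sid in specimens for h in (1, 2)}
    boundaries = []
    offset = 0
    for g in genes:
        for sid in specimens:
            for h in (1, 2):
                parts[(sid, h)].append(g.sequences.get((sid, h), "N" * g.length))
        boundaries.append((offset, offset + g.length))
        offset += g.length
    sequences = {k: "".join(v) for k, v in parts.items()}
    is_mito = all(g.is_mito for g in genes)
    return PhasedGeneAlignment(
        gene_id="+".join(gene_ids[:3]) + (f"+{len(gene_ids) - 3}more" if len(gene_ids) > 3 else ""),
        sequences=sequences, exons=boundaries, is_mito=is_mito, frame_offset=0,
    )


def profiles_frame(profiles: list[GeneDivergenceProfile]):
    """Flatten profiles into a tidy table (one row per gene) for TSV output."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {
            "gene_id": p.gene_id,
            "dna_min_inter": p.dna_min_inter, "dna_max_intra": p.dna_max_intra,
            "prot_min_inter": p.prot_min_inter, "prot_max_intra": p.prot_max_intra,
            "count_min_inter": p.count_min_inter, "count_max_intra": p.count_max_intra,
            "n_comparable_sites": p.n_comparable_sites,
            "prot_incomparable": int(p.prot_incomparable),
        }
        for sp, v in sorted(p.dna_max_intra_by_species.items()):
            row[f"dna_max_intra_{sp}"] = v
        for sp, v in sorted(p.prot_max_intra_by_species.items()):
            row[f"prot_max_intra_{sp}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
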