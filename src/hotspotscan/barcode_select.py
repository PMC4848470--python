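"""Diagnostic nuclear-barcode selection.

Gene-level rule: a candidate barcode gene must beat the 0.1-point margin
(minimal interspecific minus maximal intraspecific divergence, at both the DNA
and the protein level) and carry at least one GO term enriched among the
speciation hotspots.

Exon-level rules, evaluated on the exon sub-alignment over all haplotypes:

1. each 25-bp terminal flank (primer site) has at most 2 variable positions;
2. min interspecific minus max intraspecific percent divergence > 1.0 (strict);
3. min interspecific raw difference count exceeds the max intraspecific count
   by at least 2.

A variable position is a column with >= 2 distinct A/C/G/T states across all
haplotypes; columns varying only through N or gaps are not primer-relevant
variation. Flank counting is per-flank (each terminus is an independent primer
site); set ``flanks_combined=True`` for the total-across-both-flanks reading.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_io import PhasedGeneAlignment, Thresholds
from .divergence import GeneDivergenceProfile, p_distance


@dataclass
class BarcodeExon:
    gene_id: str
    exon_index: int
    interval: tuple[int, int]
    flank_variable_counts: tuple[int, int]
    min_inter_pct: float
    max_intra_pct: float
    min_inter_count: int
    max_intra_count: int
    passed: bool
    fail_reasons: tuple[str, ...] = ()


def select_barcode_genes(
    profiles: dict[str, GeneDivergenceProfile],
    enriched_terms: set[str],
    annotations: dict[str, set[str]],
    thresholds: Thresholds | None = None,
) -> list[str]:
    """Genes passing the divergence margin at both levels AND annotated with at
    least one hotspot-enriched GO term. The margin is inclusive ("at least")."""
    thr = thresholds or Thresholds()
    selected = []
    for gene_id in sorted(profiles):
        p = profiles[gene_id]
        if p.prot_incomparable:
            continue
        dna_margin = p.dna_min_inter - p.dna_max_intra
        prot_margin = p.prot_min_inter - p.prot_max_intra
        if dna_margin < thr.barcode_gene_margin or prot_margin < thr.barcode_gene_margin:
            continue
        if not (annotations.get(gene_id, set()) & enriched_terms):
            continue
        selected.append(gene_id)
    return selected


def _variable_columns(rows: np.ndarray) -> np.ndarray:
    """Boolean mask over columns with >= 2 distinct unambiguous bases."""
    n_cols = rows.shape[1]
    out = np.zeros(n_cols, dtype=bool)
    acgt = [ord(b) for b in "ACGT"]
    present = np.stack([(rows == b).any(axis=0) for b in acgt])
    out = present.sum(axis=0) >= 2
    return out


def select_barcode_exons(
    alignment: PhasedGeneAlignment,
    species_map: dict[str, str],
    thresholds: Thresholds | None = None,
    flanks_combined: bool = False,
) -> list[BarcodeExon]:
    """Evaluate the three PCR-barcode criteria on every exon of a gene."""
    thr = thresholds or Thresholds()
    haps = alignment.haplotypes()
    rows = np.vstack([np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, _, seq in haps])
    length = alignment.length
    results = []
    for idx, (start, end) in enumerate(alignment.exons):
        if not (0 <= start < end <= length):
            raise ValueError(f"exon [{start},{end}) outside alignment of length {length}")
        sub = rows[:, start:end]
        exon_len = end - start
        reasons: list[str] = []
        flank = thr.primer_flank_len
        if exon_len < 2 * flank:
            results.append(BarcodeExon(
                alignment.gene_id, idx, (start, end), (-1, -1),
                float("nan"), float("nan"), 0, 0, passed=False,
                fail_reasons=("too_short_for_flanks",),
            ))
            continue

        variable = _variable_columns(sub)
        left = int(variable[:flank].sum())
        right = int(variable[exon_len - flank:].sum())
        if flanks_combined:
            if left + right > thr.primer_max_variable:
                reasons.append("flank_variation")
        else:
            if left > thr.primer_max_variable or right > thr.primer_max_variable:
                reasons.append("flank_variation")

        sub_seqs = [(sid, hap, seq[start:end]) for sid, hap, seq in haps]
        min_inter, max_intra = float("inf"), 0.0
        min_inter_count, max_intra_count = None, 0
        any_inter = False
        for (sid1, _, s1), (sid2, _, s2) in itertools.combinations(sub_seqs, 2):
            d = p_distance(s1, s2)
            if d.incomparable:
                continue
            if species_map[sid1] == species_map[sid2]:
                max_intra = max(max_intra, d.percent)
                max_intra_count = max(max_intra_count, d.diff_count)
            else:
                any_inter = True
                min_inter = min(min_inter, d.percent)
                min_inter_count = d.diff_count if min_inter_count is None else min(min_inter_count, d.diff_count)
        if not any_inter:
            reasons.append("no_comparable_interspecific_pair")
            min_inter, min_inter_count = float("nan"), 0
        else:
            if min_inter - max_intra <= thr.exon_margin:
                reasons.append("divergence_margin")
            if min_inter_count < max_intra_count + thr.exon_min_extra_diffs:
                reasons.append("difference_count")

        results.append(BarcodeExon(
            alignment.gene_id, idx, (start, end), (left, right),
            min_inter, max_intra,
            int(min_inter_count or 0), int(max_intra_count),
            passed=not reasons, fail_reasons=tuple(reasons),
        ))
    return results
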