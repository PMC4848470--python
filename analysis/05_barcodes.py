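#!/usr/bin/env python
"""Diagnostic nuclear-barcode selection.

Selects genes whose minimal interspecific divergence beats the maximal
intraspecific divergence by >= 0.1 points at both the DNA and protein level
and that carry a hotspot-enriched GO term; then screens their exons with the
three PCR criteria (conserved 25-bp flanks, >1.0% divergence margin, >= 2
extra fixed differences). Writes barcode_genes.tsv and barcode_exons.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hotspotscan import load_dataset, select_barcode_exons, select_barcode_genes
from hotspotscan.pipeline import compute_profiles


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    dataset = load_dataset(args.data_dir)
    enr_tsv = args.out_dir / "enrichment.tsv"
    if not enr_tsv.exists():
        raise SystemExit("run 04_hotspots.py first (enrichment.tsv missing)")
    enr = pd.read_csv(enr_tsv, sep="\t")
    enriched_terms = set(enr.loc[enr.enriched == 1, "term"])

    analyzable, profiles = compute_profiles(dataset)
    genes = select_barcode_genes(profiles, enriched_terms, dataset.go_annotations)
    pd.DataFrame({"gene_id": genes}).to_csv(
        args.out_dir / "barcode_genes.tsv", sep="\t", index=False)
    print(f"{len(genes)} candidate barcode genes "
          f"(margin >= 0.1 at both levels, enriched GO term)")

    species_map = dataset.species_map
    rows = []
    for g in genes:
        for e in select_barcode_exons(dataset.gene(g), species_map):
            rows.append({
                "gene_id": e.gene_id, "exon_index": e.exon_index,
                "start": e.interval[0], "end": e.interval[1],
                "flank_var_left": e.flank_variable_counts[0],
                "flank_var_right": e.flank_variable_counts[1],
                "min_inter_pct": e.min_inter_pct, "max_intra_pct": e.max_intra_pct,
                "min_inter_count": e.min_inter_count, "max_intra_count": e.max_intra_count,
                "passed": int(e.passed), "fail_reasons": ";".join(e.fail_reasons),
            })
    exons = pd.DataFrame(rows)
    exons.to_csv(args.out_dir / "barcode_exons.tsv", sep="\t", index=False, float_format="%.4g")
    n_pass = int(exons.passed.sum()) if len(exons) else 0
    print(f"{n_pass} / {len(exons)} exons pass all three PCR-barcode criteria")


if __name__ == "__main__":
    main()
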