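#!/usr/bin/env python
"""Specimen-table summary statistics for the eight published genomes.

Species means of the mapped noncoding fraction (reference specimen excluded),
heterozygosity ranges, the between-species mapping t-test, and the
heterozygosity-latitude correlation. Writes summary.json.
"""

import argparse
import json
from pathlib import Path

from hotspotscan import (
    compare_species_mapping,
    field_range,
    het_latitude_association,
    load_specimen_fixture,
    species_mean,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    recs = load_specimen_fixture()
    comparison = compare_species_mapping(recs)
    assoc = het_latitude_association(recs)
    summary = {
        "mean_mapped_noncoding_cecrops_pct": species_mean(
            recs, "mapped_noncoding_pct", "cecrops", exclude_reference=True, round_to=0),
        "mean_mapped_noncoding_isobeon_pct": species_mean(
            recs, "mapped_noncoding_pct", "isobeon", round_to=0),
        "het_range_pct": field_range(recs, "het_pct", 1),
        "het_coding_range_pct": field_range(recs, "het_coding_pct", 2),
        "mapping_t_pooled": comparison.t_pooled,
        "mapping_p_pooled_one_sided": comparison.p_pooled_one_sided,
        "mapping_p_welch_one_sided": comparison.p_welch_one_sided,
        "het_latitude_pearson_r": assoc.pearson_r,
        "het_latitude_pearson_p_two_sided": assoc.pearson_p_two_sided,
        "het_latitude_spearman_rho": assoc.spearman_rho,
    }
    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"mapped noncoding: cecrops {summary['mean_mapped_noncoding_cecrops_pct']:.0f}% "
          f"vs isobeon {summary['mean_mapped_noncoding_isobeon_pct']:.0f}% "
          f"(pooled one-sided p = {comparison.p_pooled_one_sided:.5f})")
    print(f"heterozygosity {summary['het_range_pct'][0]}%..{summary['het_range_pct'][1]}% "
          f"(coding {summary['het_coding_range_pct'][0]}%..{summary['het_coding_range_pct'][1]}%)")
    print(f"heterozygosity vs latitude: Pearson r = {assoc.pearson_r:.3f} "
          f"(two-sided p = {assoc.pearson_p_two_sided:.3f})")


if __name__ == "__main__":
    main()
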