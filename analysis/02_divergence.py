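#!/usr/bin/env python
"""Per-gene divergence profiles for the coverage-filtered nuclear gene set.

For every analyzable gene: minimum interspecific and maximum intraspecific
p-distance at the DNA and protein level (intraspecific includes the two
haplotypes of one specimen), plus raw difference counts. Writes profiles.tsv.
"""

import argparse
from pathlib import Path

from hotspotscan import load_dataset
from hotspotscan.divergence import profiles_frame
from hotspotscan.pipeline import compute_profiles


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    dataset = load_dataset(args.data_dir)
    analyzable, profiles = compute_profiles(dataset)
    frame = profiles_frame([profiles[g] for g in analyzable])
    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = args.out_dir / "profiles.tsv"
    frame.to_csv(out, sep="\t", index=False, float_format="%.6g")

    n_margin = int(((frame.dna_min_inter - frame.dna_max_intra >= 0.1)
                    & (frame.prot_min_inter - frame.prot_max_intra >= 0.1)).sum())
    print(f"profiled {len(frame)} / {len(dataset.nuclear_genes)} nuclear genes -> {out}")
    print(f"mean min-interspecific DNA divergence: {frame.dna_min_inter.mean():.3f}%")
    print(f"genes clearing the 0.1-point barcode margin at both levels: {n_margin}")


if __name__ == "__main__":
    main()
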