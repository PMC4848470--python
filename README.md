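# hotspotscan

Speciation-hotspot scanning for pairs of closely related species from phased
per-gene alignments.

Two butterfly species can look almost identical, share mitochondrial DNA —
and still be separated by a deep split in their nuclear genomes that is
carried by a minority of genes. This package implements the comparative
workflow for that situation, modelled on the *Calycopis cecrops* /
*C. isobeon* (Lycaenidae) study design of 3 + 5 fully sequenced specimens with
two haplotype sequences per specimen:

* **per-gene divergence profiles** — minimum interspecific vs maximum
  intraspecific p-distance at the DNA and protein level, with raw difference
  counts and a per-species coverage filter (≥ 50% of columns known in ≥ 2
  specimens of each species);
* **trees and support** — Saitou–Nei neighbor joining on percent p-distance
  matrices over haplotype leaves, column-bootstrap support for the species
  bipartition, majority-rule and random-split (100-block) consensus, and
  midpoint-rooted monophyly queries for nucleo-mitochondrial incongruence;
* **hotspot calling** — a gene is a raw hotspot when bootstrap support ≥ 95%
  at both the DNA and the protein level, and a conserved ("speciation")
  hotspot when additionally its intraspecific protein divergence stays below
  0.4% in at least one species;
* **GO enrichment** — exact binomial upper tail P(X ≥ m), X ~ Binomial(N, p),
  with m = hotspots carrying the term, N = hotspots, p = background term
  frequency; terms with p < 0.01 are enriched. The same statistic drives the
  cross-genus hotspot overlap test and the enrichment of expanded gene
  families (families merged via shared Drosophila anchors; expansion = focal
  count and total protein length both > 1.5× the other-species mean);
* **nuclear barcodes** — genes whose min-interspecific divergence beats the
  max-intraspecific divergence by ≥ 0.1 points at both levels and that carry a
  hotspot-enriched GO term; within them, exons with conserved 25-bp primer
  flanks (≤ 2 variable positions each), a > 1.0% divergence margin, and ≥ 2
  extra fixed interspecific differences;
* **specimen summaries** — Table-style species means and ranges, the
  between-species mapping t-test and the heterozygosity–latitude correlation;
* **a seeded synthetic-data generator** with planted ground truth (hotspot /
  background / unconserved gene classes, designed-enriched GO terms,
  mitochondrial introgression) so the whole pipeline is testable without any
  sequencing data.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

The packaged specimen table carries the published mapping and heterozygosity
statistics of the eight sequenced specimens:

```bash
python analysis/06_specimen_summary.py
```

```
mapped noncoding: cecrops 88% vs isobeon 83% (pooled one-sided p = 0.00023)
heterozygosity 1.2%..2.0% (coding 0.56%..1.04%)
heterozygosity vs latitude: Pearson r = -0.738 (two-sided p = 0.036)
```

Same-species reads map to 88% of noncoding reference positions vs 83% for the
sister species — a significant contrast (p = 0.00023) that quantifies
noncoding divergence — and heterozygosity rises toward the tropics.

The synthetic pipeline runs as numbered stages:

```bash
python analysis/01_simulate.py --seed 11      # dataset + ground truth
python analysis/02_divergence.py              # per-gene profiles
python analysis/03_trees.py --seed 11         # supports, trees, incongruence
python analysis/04_hotspots.py                # hotspot calls + GO enrichment
python analysis/05_barcodes.py                # barcode genes and exons
```

```
140 / 300 genes separate the species by DNA (bootstrap >= 95)
88 / 300 separate at both the DNA and protein level
nuclear tree separates species: True (random-split support 100%)
mito tree: isobeon monophyletic = False, introgressed specimen inside cecrops clade = True
88 raw hotspots (29%), 30 conserved hotspots
5 GO terms enriched at p < 0.01: GO:0000002, GO:0000003, GO:0000001, GO:0000004, GO:0000005
recovery vs planted hotspots: sensitivity 1.00, precision 1.00
27 candidate barcode genes (margin >= 0.1 at both levels, enriched GO term)
26 / 100 exons pass all three PCR-barcode criteria
```

The scan recovers every planted hotspot with no false conserved calls, flags
exactly the five designed-enriched GO terms, and reproduces the hallmark
discordance: the nuclear concatenation separates the species with full
random-split support while the mitochondrial tree places the introgressed
*isobeon* specimen inside the *cecrops* clade, breaking *isobeon* monophyly.

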