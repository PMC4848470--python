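# Methods

## Scope

`hotspotscan` re-creates, as a tested pipeline over phased per-gene alignments,
the comparative-genomic workflow used to dissect a pair of recently diverged
butterfly species (*Calycopis cecrops*, 3 specimens, vs *C. isobeon*, 5
specimens): per-gene divergence profiling, tree-based speciation-hotspot
calling, binomial GO enrichment, cross-genus overlap testing, gene-family
expansion detection, diagnostic nuclear-barcode exon selection, and
specimen-table summary statistics. Sequencing, assembly, read mapping and SNP
calling are out of scope; the pipeline starts from phased alignments (two
haplotype sequences per specimen per gene) and tabular annotations. A seeded
synthetic-data generator stands in for the sequencing data and carries a
ground-truth table so every stage can be validated against planted signal.

## Distances and divergence profiles

All distances are uncorrected p-distances in percent with pairwise deletion: a
column contributes to a pair only when both characters are unambiguous (A/C/G/T
for DNA; one of the 20 standard amino acids for protein). At the divergence
levels involved (≤ ~6%) multiple-hit corrections (JC69, K2P) would change
nothing material, and percent-of-differing-positions is the scale on which all
thresholds are defined.

Per gene, over every pair of haplotype sequences:

* `dna_min_inter` / `prot_min_inter` — minimum divergence across all
  between-species haplotype pairs;
* `dna_max_intra` / `prot_max_intra` — maximum across within-species pairs,
  *including* the two haplotypes of a single specimen (trees carry both
  haplotypes as leaves, so within-species variation subsumes heterozygosity),
  also tracked per species for the conservation rule;
* raw difference counts (`count_min_inter`, `count_max_intra`) on DNA, used by
  the count-based barcode criterion.

Translation uses the standard genetic code; codons containing N or a gap, and
stop codons, translate to X (internal stops additionally log a warning); X is
non-comparable. Genes whose translations are entirely X are flagged
incomparable at the protein level and fail selection rather than erroring.

A gene enters the analysis only if, in **each** species, at least 2 specimens
have both haplotypes ≥ 50% non-N (`coverage_min`, `coverage_min_specimens`) —
the "no less than 50% covered in at least two specimens per species" filter.

## Trees and support

Trees are built by Saitou–Nei neighbor joining on percent p-distance matrices
over haplotype leaves. NJ replaces likelihood inference deliberately: distance
trees on percent differences are part of the original workflow, NJ is exactly
specifiable without external binaries, and at these shallow divergences the
species bipartition is distance-identifiable. Two numerical conventions make
the implementation fully deterministic and testable:

* Q-matrix ties are broken by the lexicographically smallest pair of cluster
  labels (a cluster is labelled by its smallest leaf). A zero-variation
  alignment therefore yields one fixed topology, and its bootstrap support is a
  regression-locked constant rather than an accident of argmin order.
* The Q matrix is computed as `(m−2)·D − (r_i + r_j)` with the row sums added
  first, which keeps it bit-exactly symmetric so that tied minima appear in
  mirrored pairs; negative branch lengths are clamped to zero.

**Species separation** of a tree is the existence of an edge whose removal
bipartitions the leaves exactly along species lines. Per-gene support is the
percentage of column-bootstrap replicates (resample columns with replacement to
the original length; default 100 replicates) whose NJ tree separates the
species; computed independently at the DNA level and on the translated
sequences. A replicate containing a haplotype pair with zero comparable columns
counts as non-separating and is logged.

**Consensus.** The majority-rule consensus retains bipartitions occurring in
strictly more than the threshold fraction (default 0.5) of input trees,
annotated with their occurrence percentage; retained splits are mutually
compatible and nested by size. The random-split diagnostic permutes the
concatenated alignment's columns (seeded), cuts them into k = 100 near-equal
blocks, builds one NJ tree per block, and reports the percentage of block trees
that separate the species — a deliberately data-starved support measure that,
unlike whole-alignment bootstrap, does not saturate at 100% for arbitrarily
weak signal.

**Monophyly and rooting.** On an unrooted tree, the complement of any intact
clade is itself a bipartition side, so a species scattered by introgression
would still be called "monophyletic" whenever the *other* species forms a
clade. The incongruence analysis therefore evaluates monophyly after midpoint
rooting (the conventional root for outgroup-free distance trees): a group is
monophyletic iff some rooted clade equals it exactly. With one introgressed
specimen the longest path runs between the two mitochondrial types, the
midpoint lands on the between-type edge, and species B is correctly reported
broken.

## Hotspot calling and enrichment

A gene is a **raw hotspot** when both its DNA and its protein bootstrap
separation support reach `support_min` (default 95, inclusive — the source
texts alternate between "> 95" and ">= 95"; the inclusive reading is the
configurable default). A raw hotspot is a **conserved hotspot** when the
maximal intraspecific protein divergence is below 0.4%
(`conserved_max_intra_prot`) in at least one species; this removes
fast-evolving proteins that separate species only because they tolerate many
substitutions.

GO terms are flat labels (no ontology-graph propagation — matching the
operational description of the original analysis, and a noted divergence from
modern GO practice). Enrichment of a term in the hotspot set is the exact
binomial upper tail P(X ≥ m), X ~ Binomial(N, p): m hotspot genes carrying the
term, N hotspots, p the fraction of the analysis universe carrying the term.
The universe defaults to all coverage-filtered genes including unannotated ones
(they legitimately dilute p); an `annotated_only` flag restricts it. Terms with
p-value < 0.01 (`enrich_alpha`) are enriched; no multiple-testing correction
gates the call, but a Benjamini–Hochberg q-value column is emitted for
information. The tail itself is delegated to `scipy.stats.binom.sf` and is
verified in the tests against an independent exact-integer summation oracle to
1e−12 absolute up to N = 10^4.

The cross-genus **overlap test** restricts to ortholog groups with members
from both genera and computes the binomial tail in both directions (N = groups
containing genus-1 hotspots with p from genus-2, and vice versa), headlining
the larger p-value, since the original description does not fix the direction.

**Families and expansions.** Raw ortholog groups sharing any Drosophila anchor
protein are merged transitively (union–find; groups without anchors stay
singleton families). A family counts as expanded in the focal species when its
gene count AND total protein length both strictly exceed 1.5×
(`expansion_factor`) the mean over the other species, means taken over all
other species in the table including those where the family is absent.

## Barcode selection

Gene level: minimal interspecific divergence at least 0.1 points
(`barcode_gene_margin`, inclusive) above the maximal intraspecific divergence
at *both* the DNA and protein level, plus at least one GO term flagged
enriched among the hotspots. Exon level, on the exon sub-alignment over all
haplotypes:

1. each terminal 25-column flank (`primer_flank_len`) has at most 2
   (`primer_max_variable`) variable positions — a variable position is a column
   with ≥ 2 distinct A/C/G/T states; columns varying only through N or gaps are
   not primer-relevant. The limit applies per flank (each terminus is an
   independent primer site); a combined-total reading is available via a flag;
2. min interspecific minus max intraspecific percent divergence strictly
   greater than 1.0 (`exon_margin`);
3. minimal interspecific raw difference count at least 2
   (`exon_min_extra_diffs`) above the maximal intraspecific count.

Exons shorter than two flanks auto-fail with a reason code; all criteria and
failure reasons are reported per exon.

## Specimen summaries

Species means and ranges are rounded half-up at the printed precision. The
reference specimen is excluded from mapping means and comparisons — its reads
built the reference genome, so its mapping fractions are ~100% by construction,
and the published 88% species mean is only recoverable without it. The
between-species mapping contrast is a two-sample t-test reported in both
pooled-variance and Welch flavours with one- and two-sided p-values; on the
packaged eight-specimen table the pooled one-sided variant reproduces the
published p = 0.00023 (the Welch variant gives 8.3e−5), so the pooled one-sided
value is the headline. The heterozygosity–latitude association reports Pearson
r with t-test p-values plus Spearman rank correlation; on the packaged table
the correlation is negative (r ≈ −0.74), while the exact test behind the
published "P = 0.01" is not recoverable from standard variants and is therefore
reported but not asserted.

## The synthetic-data generator

`simulate_dataset` emulates the study design, not sequencing: per nuclear gene
an ancestral CDS (random sense codons, 150–500 codons — the scale of typical
insect CDSs) splits into two species consensus sequences differing at a
class-specific rate `d_inter`, and each specimen receives two haplotypes
independently mutated from its species consensus at rate `d_intra`. Pairwise
intraspecific divergence and individual heterozygosity therefore both emerge
at ~2·d_intra. Substitutions are per-site independent with a uniform choice
among the three alternative bases (Jukes–Cantor-like; p-distance analyses do
not reward more sophistication); a fraction `nonsyn_frac` (default 0.5) of
substitutions is placed at codon positions 1–2 (approximately nonsynonymous),
the rest at position 3; replacements that would create a stop codon are
resampled.

Three nuclear gene classes (defaults: 10% hotspot, 10% unconserved, rest
background):

| class        | d_inter (%) | d_intra (%) | intraspecific mutations |
|--------------|------------|------------|--------------------------|
| hotspot      | 2.0        | 0.2        | synonymous (3rd position, amino-acid-preserving) |
| background   | 0.3        | 0.3        | positional mix            |
| unconserved  | 2.0        | 2.0        | positional mix            |

Making hotspot-class intraspecific variation synonymous is the defining
biology of a speciation hotspot — the protein is under purifying selection
within each species while diverging between them — and it is also what makes
the <0.4% protein-conservation rule recoverable at all: with even a 50%
nonsynonymous share, 0.2% intraspecific DNA variation would already push the
maximal intraspecific protein divergence past 0.4% in most genes. Under these
defaults the concatenated coding alignment shows ~1.5% interspecific divergence
and 0.89–0.96% per-specimen coding heterozygosity, on the scale of the
published 1.3–1.5% and 0.56–1.04%.

Mitochondrial genes (13, matching the animal mitogenome complement) are a
single molecule per specimen (emitted with h1 = h2 to keep one alignment
type, flagged `is_mito`), diverging at `mito_d` = 0.2% between species with
`mito_d_intra` = 0.05% individual variation; each introgressed species-B
specimen (default: the last B specimen) draws its mitochondrion from the
species-A consensus instead. GO labels: 50 flat terms attached with base
probability 0.05 per gene; 5 designed-enriched terms ride on hotspot genes
with an 8× odds multiplier. The generator is byte-deterministic for a fixed
config and seed.

What the generator does **not** emulate — hence what passing tests do not
show about real data: indels and alignment error (gaps appear only in real
input), recombination and coalescent gene-tree variance, rate heterogeneity
across sites and lineages, base-composition bias, missing data from uneven
coverage, GO-term correlation structure, and paralogy. Recovery statistics on
synthetic data are upper bounds on what the rules could achieve on the real
genomes.

## Problem sizes used in validation

The simulation-backed checks run at 300 nuclear genes + 13 mitochondrial genes
with the 3 + 5 specimen design — large enough that class fractions, enrichment
counts and the random-split diagnostic (100 blocks of ~3,000 columns, the
block size of the original 100-split analysis) are all well-populated, and
chosen as the package's standard desk-scale validation size. The published
whole-genome counts (16,306 genes; 1653/780 hotspots; 1232/148 barcode genes;
98 exons; the cross-genus overlap p = 5.86e−12) depend on the full sequencing
data and genus-wide hotspot lists and are not reproducible from desk-scale
synthetic data; the pipeline reports the corresponding quantities for whatever
dataset it is given.

## Known limitations

* NJ with the lexicographic tie-break is deterministic but the tie-break is a
  convention; on genuinely tied data other NJ implementations return different
  (equally valid) topologies.
* The binomial enrichment treats genes as exchangeable; gene length and
  annotation density biases are not modelled.
* Midpoint-rooted monophyly assumes the deepest split lies between the groups
  being contrasted; with rate asymmetry the midpoint can land elsewhere.
* The two-direction overlap test brackets, but cannot pin, the original
  single-direction printed p-values without the second genus' hotspot counts.
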