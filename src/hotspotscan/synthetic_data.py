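"""Two-species phased-genome simulator with known ground truth.

The generator emulates the statistical structure of a pair of recently diverged
butterfly species sequenced at low specimen numbers (3 + 5 by default):

* an ancestral CDS per gene (no internal stops), from which two species
  consensus sequences diverge at a class-specific rate ``d_inter``;
* per specimen, two haplotypes independently mutated from the species consensus
  at rate ``d_intra`` — so within-specimen heterozygosity and within-species
  divergence both emerge from the same draws (pairwise intra divergence is on
  the order of 2*d_intra);
* three nuclear gene classes: *hotspot* (high interspecific, low intraspecific
  divergence; intraspecific mutations are synonymous, modelling purifying
  selection on the protein), *background* (inter ~ intra, no species signal),
  and *unconserved* (fast-evolving at both levels);
* mitochondrial genes carried as a single molecule per specimen (h1 = h2) with
  low interspecific divergence, and optional introgression: selected species-B
  specimens carry a species-A-derived mitochondrion;
* flat GO labels, with designed-enriched terms attached to hotspot genes at a
  configurable odds multiplier.

Substitutions are per-site independent with a uniform choice among the three
alternative bases (Jukes–Cantor-like); replacements that would create a stop
codon are resampled. A fraction ``nonsyn_frac`` of substitutions is placed at
codon positions 1–2 (approximately nonsynonymous), the rest at position 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Dataset, PhasedGeneAlignment, SpecimenRecord
from .divergence import _CODON_TABLE, p_distance

_BASES = "ACGT"
_STOPS = {c for c, aa in _CODON_TABLE.items() if aa == "*"}
_SENSE_CODONS = sorted(c for c in _CODON_TABLE if c not in _STOPS)
# synonymous third-position alternatives for each sense codon
_SYN3: dict[str, str] = {}
for _c in _SENSE_CODONS:
    _SYN3[_c] = "".join(
        b for b in _BASES
        if b != _c[2] and (_c[:2] + b) not in _STOPS and _CODON_TABLE[_c[:2] + b] == _CODON_TABLE[_c]
    )

NUCLEAR_CLASSES = ("hotspot", "background", "unconserved")


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-species dataset.

    Divergence rates are percent per site. Defaults mirror the published
    setting: 3 + 5 specimens, ~10% hotspot genes, background interspecific
    divergence comparable to intraspecific variation, 13 mitochondrial genes
    with low divergence, and one introgressed species-B specimen."""

    n_genes: int = 300
    gene_len_range: tuple[int, int] = (150, 500)      # codons
    n_specimens_A: int = 3
    n_specimens_B: int = 5
    frac_hotspot: float = 0.10
    frac_unconserved: float = 0.10
    d_inter: dict = field(default_factory=lambda: {"hotspot": 2.0, "background": 0.3, "unconserved": 2.0})
    d_intra: dict = field(default_factory=lambda: {"hotspot": 0.2, "background": 0.3, "unconserved": 2.0})
    nonsyn_frac: float = 0.5
    n_mito_genes: int = 13
    mito_d: float = 0.2
    mito_d_intra: float = 0.05
    introgressed_specimens: list[str] | None = None   # default: last species-B specimen
    go_terms: int = 50
    enriched_terms: int = 5
    enrich_odds: float = 8.0
    go_base_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_hotspot", "frac_unconserved", "nonsyn_frac", "go_base_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_hotspot + self.frac_unconserved > 1.0:
            raise ValueError("frac_hotspot + frac_unconserved > 1")
        rates = list(self.d_inter.values()) + list(self.d_intra.values()) + [self.mito_d, self.mito_d_intra]
        if any(d < 0 for d in rates):
            raise ValueError("negative divergence rate")
        if any(d > 100 for d in rates):
            raise ValueError("divergence rate above 100%")
        if self.gene_len_range[0] < 20 or self.gene_len_range[0] > self.gene_len_range[1]:
            raise ValueError("bad gene_len_range")

    @property
    def specimen_ids_A(self) -> list[str]:
        return [f"cec{i + 1}" for i in range(self.n_specimens_A)]

    @property
    def specimen_ids_B(self) -> list[str]:
        return [f"iso{i + 1}" for i in range(self.n_specimens_B)]

    def resolved_introgressed(self) -> list[str]:
        if self.introgressed_specimens is not None:
            return list(self.introgressed_specimens)
        ids = self.specimen_ids_B
        return [ids[-1]] if ids else []


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    gene_class: dict[str, str]
    designed_enriched_terms: set[str]
    introgressed_specimens: set[str]
    seed: int


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _mutate(
    rng: np.random.Generator,
    codons: list[str],
    rate_pct: float,
    nonsyn_frac: float,
    synonymous_only: bool = False,
) -> list[str]:
    """Independent substitutions at ``rate_pct`` percent of nucleotide sites.

    ``synonymous_only`` restricts mutations to amino-acid-preserving
    third-position changes (used for hotspot-class intraspecific variation)."""
    codons = list(codons)
    n_nt = 3 * len(codons)
    n_mut = rng.binomial(n_nt, rate_pct / 100.0)
    for _ in range(n_mut):
        for _attempt in range(40):
            ci = int(rng.integers(0, len(codons)))
            codon = codons[ci]
            if synonymous_only:
                alts = _SYN3[codon]
                if not alts:
                    continue
                base = alts[int(rng.integers(0, len(alts)))]
                codons[ci] = codon[:2] + base
                break
            pos = int(rng.integers(0, 2)) if rng.random() < nonsyn_frac else 2
            alts = [b for b in _BASES if b != codon[pos]]
            rng.shuffle(alts)
            placed = False
            for base in alts:
                new = codon[:pos] + base + codon[pos + 1:]
                if new not in _STOPS:
                    codons[ci] = new
                    placed = True
                    break
            if placed:
                break
    return codons


def _diverge_pair(rng, ancestral, d_inter, nonsyn_frac):
    """Split an ancestral CDS into two species consensus sequences differing at
    ~d_inter percent of sites (each lineage receives about half the changes)."""
    a = _mutate(rng, ancestral, d_inter / 2.0, nonsyn_frac)
    b = _mutate(rng, ancestral, d_inter / 2.0, nonsyn_frac)
    return a, b


# ---------------------------------------------------------------------------
# exon structure
# ---------------------------------------------------------------------------

_MIN_EXON = 60


def simulate_exon_structure(alignment: PhasedGeneAlignment, n_exons: int, seed: int) -> PhasedGeneAlignment:
    """Assign ``n_exons`` contiguous intervals (each >= 60 columns) tiling the
    alignment. Deterministic for a fixed seed."""
    length = alignment.length
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if length < n_exons * _MIN_EXON:
        raise ValueError(f"alignment length {length} too short for {n_exons} exons of >= {_MIN_EXON}")
    rng = np.random.default_rng(seed)
    extra = length - n_exons * _MIN_EXON
    shares = rng.multinomial(extra, np.full(n_exons, 1.0 / n_exons)) if extra else np.zeros(n_exons, int)
    exons = []
    start = 0
    for i in range(n_exons):
        end = start + _MIN_EXON + int(shares[i])
        exons.append((start, end))
        start = end
    alignment.exons = exons
    return alignment


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _assign_classes(rng, config: SimConfig) -> list[str]:
    n = config.n_genes
    n_hot = int(round(config.frac_hotspot * n))
    n_unc = int(round(config.frac_unconserved * n))
    classes = ["hotspot"] * n_hot + ["unconserved"] * n_unc + ["background"] * (n - n_hot - n_unc)
    rng.shuffle(classes)
    return classes


def simulate_dataset(config: SimConfig) -> tuple[Dataset, TruthTable]:
    """Generate a phased two-species dataset plus its ground truth.

    Deterministic (byte-identical output) for a fixed config and seed."""
    rng = np.random.default_rng(config.seed)
    ids_a, ids_b = config.specimen_ids_A, config.specimen_ids_B
    introgressed = [s for s in config.resolved_introgressed() if s in ids_b]

    classes = _assign_classes(rng, config)
    genes: list[PhasedGeneAlignment] = []
    gene_class: dict[str, str] = {}
    het_diffs = {sid: 0 for sid in ids_a + ids_b}
    het_sites = {sid: 0 for sid in ids_a + ids_b}

    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:04d}"
        cls = classes[gi]
        gene_class[gene_id] = cls
        n_codons = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
        ancestral = _random_cds(rng, n_codons)
        cons_a, cons_b = _diverge_pair(rng, ancestral, config.d_inter[cls], config.nonsyn_frac)
        syn_only = cls == "hotspot"
        sequences: dict[tuple[str, int], str] = {}
        for sid, cons in [(s, cons_a) for s in ids_a] + [(s, cons_b) for s in ids_b]:
            for hap in (1, 2):
                mutated = _mutate(rng, cons, config.d_intra[cls], config.nonsyn_frac, synonymous_only=syn_only)
                sequences[(sid, hap)] = "".join(mutated)
        aln = PhasedGeneAlignment(gene_id, sequences, [], is_mito=False, frame_offset=0)
        n_exons = max(1, aln.length // 240)
        simulate_exon_structure(aln, n_exons, seed=int(rng.integers(0, 2**31 - 1)))
        genes.append(aln)
        for sid in ids_a + ids_b:
            d = p_distance(sequences[(sid, 1)], sequences[(sid, 2)])
            het_diffs[sid] += d.diff_count
            het_sites[sid] += d.comparable_count

    for mi in range(config.n_mito_genes):
        gene_id = f"mito{mi + 1:02d}"
        gene_class[gene_id] = "mito"
        n_codons = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
        ancestral = _random_cds(rng, n_codons)
        cons_a, cons_b = _diverge_pair(rng, ancestral, config.mito_d, config.nonsyn_frac)
        sequences = {}
        for sid in ids_a + ids_b:
            source = cons_a if (sid in ids_a or sid in introgressed) else cons_b
            molecule = "".join(_mutate(rng, source, config.mito_d_intra, config.nonsyn_frac))
            sequences[(sid, 1)] = molecule
            sequences[(sid, 2)] = molecule
        genes.append(PhasedGeneAlignment(gene_id, sequences, [], is_mito=True, frame_offset=0))

    # flat GO labels; designed-enriched terms ride on hotspot genes
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_terms)]
    designed = set(terms[: config.enriched_terms])
    go: dict[str, set[str]] = {}
    for gene_id, cls in gene_class.items():
        if cls == "mito":
            continue
        assigned = set()
        for term in terms:
            p = config.go_base_prob
            if cls == "hotspot" and term in designed:
                p = min(1.0, p * config.enrich_odds)
            if rng.random() < p:
                assigned.add(term)
        if assigned:
            go[gene_id] = assigned

    specimens = []
    for idx, sid in enumerate(ids_a):
        het = 100.0 * het_diffs[sid] / het_sites[sid] if het_sites[sid] else 0.0
        specimens.append(SpecimenRecord(
            specimen_id=sid, species="cecrops",
            latitude=33.0 - 1.5 * idx, longitude=-93.0 - idx,
            is_reference=(idx == 0),
            mapped_noncoding_pct=100.0 if idx == 0 else 88.5,
            mapped_coding_pct=99.9 if idx == 0 else 97.6,
            het_pct=min(het, 100.0), het_coding_pct=min(het, 100.0), coverage=14.0,
        ))
    for idx, sid in enumerate(ids_b):
        het = 100.0 * het_diffs[sid] / het_sites[sid] if het_sites[sid] else 0.0
        specimens.append(SpecimenRecord(
            specimen_id=sid, species="isobeon",
            latitude=31.0 - 4.0 * idx, longitude=-96.0 - idx,
            is_reference=False,
            mapped_noncoding_pct=83.5, mapped_coding_pct=97.5,
            het_pct=min(het, 100.0), het_coding_pct=min(het, 100.0), coverage=14.0,
        ))

    dataset = Dataset(specimens, genes, go, [])
    truth = TruthTable(
        gene_class=gene_class,
        designed_enriched_terms=designed,
        introgressed_specimens=set(introgressed),
        seed=config.seed,
    )
    return dataset, truth


def read_truth(path) -> TruthTable:
    """Inverse of write_truth."""
    gene_class: dict[str, str] = {}
    designed: set[str] = set()
    introgressed: set[str] = set()
    seed = 0
    for line in open(path):
        line = line.rstrip("\n")
        if line.startswith("# seed="):
            seed = int(line.split("=", 1)[1])
        elif line.startswith("# designed_enriched_terms="):
            designed = {t for t in line.split("=", 1)[1].split(",") if t}
        elif line.startswith("# introgressed_specimens="):
            introgressed = {s for s in line.split("=", 1)[1].split(",") if s}
        elif line and not line.startswith("#") and not line.startswith("gene_id\t"):
            gene_id, cls = line.split("\t")
            gene_class[gene_id] = cls
    return TruthTable(gene_class, designed, introgressed, seed)


def write_truth(truth: TruthTable, path) -> None:
    """truth.tsv: one gene per row plus header comments for the rest."""
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed}\n")
        fh.write(f"# designed_enriched_terms={','.join(sorted(truth.designed_enriched_terms))}\n")
        fh.write(f"# introgressed_specimens={','.join(sorted(truth.introgressed_specimens))}\n")
        fh.write("gene_id\tgene_class\n")
        for gene_id in sorted(truth.gene_class):
            fh.write(f"{gene_id}\t{truth.gene_class[gene_id]}\n")
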