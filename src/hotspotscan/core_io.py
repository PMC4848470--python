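"""Domain types and on-disk formats shared by every pipeline stage.

A dataset on disk is a directory with::

    specimens.tsv           one row per specimen (metadata + Table-2-style stats)
    genes.tsv               gene_id, is_mito, frame_offset, exons ("a-b,c-d", 0-based half-open)
    genes/<gene_id>.fasta   phased alignment, headers "specimenID|species|h1" / "...|h2"
    go_annotations.tsv      gene_id <TAB> comma-separated GO ids (optional)
    ortholog_groups.tsv     group_id <TAB> species <TAB> comma "gene:length" members (optional;
                            species "dmel" rows carry the Drosophila anchor proteins)

All divergence values are carried in percent; raw difference counts are integers.
Missing data is 'N' (unknown site) or '-' (gap); lowercase input is upcased on read.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("hotspotscan")

DNA_ALPHABET = set("ACGTN-")

# sha256 of the packaged Table-2 specimen fixture; guards against silent edits
_FIXTURE_SHA256 = "d778677b612aef2ea1f96c9b581b9dac153631f887761f71ca0e82b12c3b4ab5"


class DatasetError(ValueError):
    """Raised for malformed dataset files or invariant violations."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced specimen and its mapping/heterozygosity statistics."""

    specimen_id: str
    species: str
    latitude: float
    longitude: float
    is_reference: bool = False
    mapped_noncoding_pct: float = 100.0
    mapped_coding_pct: float = 100.0
    het_pct: float = 0.0
    het_coding_pct: float = 0.0
    coverage: float = 0.0

    def __post_init__(self):
        for name in ("mapped_noncoding_pct", "mapped_coding_pct", "het_pct", "het_coding_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DatasetError(f"{self.specimen_id}: {name}={v} outside [0, 100]")
        if self.coverage < 0:
            raise DatasetError(f"{self.specimen_id}: negative coverage")


@dataclass
class PhasedGeneAlignment:
    """One gene's aligned DNA with two haplotype rows per specimen.

    ``sequences`` maps (specimen_id, haplotype in {1, 2}) to an aligned string over
    {A,C,G,T,N,-}. ``exons`` are sorted, non-overlapping, 0-based half-open column
    intervals. Mitochondrial genes carry identical h1/h2 rows (one observed molecule).
    """

    gene_id: str
    sequences: dict[tuple[str, int], str]
    exons: list[tuple[int, int]] = field(default_factory=list)
    is_mito: bool = False
    frame_offset: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise DatasetError(f"gene {self.gene_id}: unequal sequence lengths {sorted(lengths)}")
        if self.frame_offset not in (0, 1, 2):
            raise DatasetError(f"gene {self.gene_id}: bad frame offset {self.frame_offset}")
        by_specimen: dict[str, set[int]] = {}
        for (sid, hap), seq in self.sequences.items():
            if hap not in (1, 2):
                raise DatasetError(f"gene {self.gene_id}: haplotype {hap} for {sid} not in {{1,2}}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise DatasetError(f"gene {self.gene_id}: illegal characters {sorted(bad)} in {sid}")
            by_specimen.setdefault(sid, set()).add(hap)
        for sid, haps in by_specimen.items():
            if haps != {1, 2}:
                raise DatasetError(
                    f"gene {self.gene_id}: specimen {sid} has haplotypes {sorted(haps)}, expected both h1 and h2"
                )
        length = self.length
        prev_end = 0
        for start, end in self.exons:
            if not (0 <= start < end <= length):
                raise DatasetError(f"gene {self.gene_id}: exon [{start},{end}) outside [0,{length})")
            if start < prev_end:
                raise DatasetError(f"gene {self.gene_id}: overlapping/unsorted exons")
            prev_end = end

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def specimen_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self.sequences})

    def haplotypes(self) -> list[tuple[str, int, str]]:
        """All (specimen_id, haplotype, sequence) triples in deterministic order."""
        return [(sid, hap, self.sequences[(sid, hap)]) for sid, hap in sorted(self.sequences)]


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff of the scan, with the study's published defaults.

    support_min            bootstrap % both the DNA and protein tree must reach (95)
    conserved_max_intra_prot  protein intraspecific divergence ceiling, percent (0.4)
    barcode_gene_margin    min(inter) - max(intra) margin for barcode genes, points (0.1)
    primer_flank_len       primer-binding flank length in columns (25)
    primer_max_variable    variable positions tolerated per flank (2)
    exon_margin            exon-level divergence margin, points, strict (1.0)
    exon_min_extra_diffs   extra fixed differences required between species (2)
    expansion_factor       focal/other-species ratio calling a family expanded (1.5)
    enrich_alpha           binomial enrichment p-value cutoff (0.01)
    coverage_min           min fraction of non-N columns per haplotype (0.5)
    coverage_min_specimens min qualifying specimens per species (2)
    split_count            number of random splits of the concatenated alignment (100)
    consensus_threshold    majority-rule retention fraction (0.5)
    bootstrap_reps         column-bootstrap replicates per gene (100)
    """

    support_min: float = 95.0
    conserved_max_intra_prot: float = 0.4
    barcode_gene_margin: float = 0.1
    primer_flank_len: int = 25
    primer_max_variable: int = 2
    exon_margin: float = 1.0
    exon_min_extra_diffs: int = 2
    expansion_factor: float = 1.5
    enrich_alpha: float = 0.01
    coverage_min: float = 0.5
    coverage_min_specimens: int = 2
    split_count: int = 100
    consensus_threshold: float = 0.5
    bootstrap_reps: int = 100

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise DatasetError(f"threshold {name} must be strictly positive, got {v}")


@dataclass
class OrthologGroup:
    """A raw ortholog group: per-species (gene_id, protein_length) members plus
    the Drosophila proteins it mapped to (used for family merging)."""

    group_id: str
    members: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    dmel_ids: frozenset[str] = frozenset()


@dataclass
class Dataset:
    specimens: list[SpecimenRecord]
    genes: list[PhasedGeneAlignment]
    go_annotations: dict[str, set[str]] = field(default_factory=dict)
    ortholog_groups: list[OrthologGroup] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        sids = [s.specimen_id for s in self.specimens]
        if len(sids) != len(set(sids)):
            raise DatasetError("duplicate specimen_id in specimen table")
        known = set(sids)
        gene_ids = [g.gene_id for g in self.genes]
        if len(gene_ids) != len(set(gene_ids)):
            raise DatasetError("duplicate gene_id")
        for g in self.genes:
            unknown = set(g.specimen_ids) - known
            if unknown:
                raise DatasetError(f"gene {g.gene_id} references unknown specimens {sorted(unknown)}")

    @property
    def species_map(self) -> dict[str, str]:
        return {s.specimen_id: s.species for s in self.specimens}

    def gene(self, gene_id: str) -> PhasedGeneAlignment:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def nuclear_genes(self) -> list[PhasedGeneAlignment]:
        return [g for g in self.genes if not g.is_mito]

    @property
    def mito_genes(self) -> list[PhasedGeneAlignment]:
        return [g for g in self.genes if g.is_mito]


# ---------------------------------------------------------------------------
# dataset reading / writing
# ---------------------------------------------------------------------------

_SPECIMEN_COLUMNS = [
    "specimen_id", "species", "latitude", "longitude", "is_reference",
    "mapped_noncoding_pct", "mapped_coding_pct", "het_pct", "het_coding_pct", "coverage",
]


def _records_from_frame(df: pd.DataFrame) -> list[SpecimenRecord]:
    missing = set(_SPECIMEN_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"specimen table missing columns {sorted(missing)}")
    return [
        SpecimenRecord(
            specimen_id=str(r.specimen_id),
            species=str(r.species),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
            is_reference=bool(int(r.is_reference)),
            mapped_noncoding_pct=float(r.mapped_noncoding_pct),
            mapped_coding_pct=float(r.mapped_coding_pct),
            het_pct=float(r.het_pct),
            het_coding_pct=float(r.het_coding_pct),
            coverage=float(r.coverage),
        )
        for r in df.itertuples(index=False)
    ]


def _parse_fasta_header(header: str) -> tuple[str, str, int]:
    parts = header.split("|")
    if len(parts) != 3 or parts[2] not in ("h1", "h2"):
        raise DatasetError(
            f"FASTA header {header!r} not parseable as 'specimen|species|h1' or '...|h2'"
        )
    return parts[0], parts[1], int(parts[2][1])


def _exons_to_text(exons: list[tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in exons)


def _exons_from_text(text: str) -> list[tuple[int, int]]:
    text = text.strip()
    if not text:
        return []
    out = []
    for part in text.split(","):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return out


def load_dataset(directory: str | Path) -> Dataset:
    """Read a dataset directory. Missing optional tables yield empty structures."""
    directory = Path(directory)
    spec_path = directory / "specimens.tsv"
    if not spec_path.exists():
        raise DatasetError(f"specimen table missing: {spec_path}")
    specimens = _records_from_frame(pd.read_csv(spec_path, sep="\t"))
    species_of = {s.specimen_id: s.species for s in specimens}

    meta: dict[str, dict] = {}
    genes_tsv = directory / "genes.tsv"
    if genes_tsv.exists():
        gdf = pd.read_csv(genes_tsv, sep="\t", dtype={"exons": str}, keep_default_na=False)
        for r in gdf.itertuples(index=False):
            meta[str(r.gene_id)] = {
                "is_mito": bool(int(r.is_mito)),
                "frame_offset": int(r.frame_offset),
                "exons": _exons_from_text(str(r.exons)),
            }

    genes: list[PhasedGeneAlignment] = []
    gene_dir = directory / "genes"
    if gene_dir.is_dir():
        for path in sorted(gene_dir.glob("*.fasta")):
            gene_id = path.stem
            seqs: dict[tuple[str, int], str] = {}
            for rec in SeqIO.parse(str(path), "fasta"):
                sid, species, hap = _parse_fasta_header(rec.id)
                if sid not in species_of:
                    raise DatasetError(f"gene {gene_id}: unknown specimen {sid!r}")
                if species_of[sid] != species:
                    raise DatasetError(
                        f"gene {gene_id}: specimen {sid} labelled {species!r} "
                        f"but specimen table says {species_of[sid]!r}"
                    )
                key = (sid, hap)
                if key in seqs:
                    raise DatasetError(f"gene {gene_id}: more than 2 sequences for specimen {sid}")
                seqs[key] = str(rec.seq).upper()
            m = meta.get(gene_id, {"is_mito": False, "frame_offset": 0, "exons": []})
            genes.append(PhasedGeneAlignment(gene_id, seqs, m["exons"], m["is_mito"], m["frame_offset"]))

    go: dict[str, set[str]] = {}
    go_path = directory / "go_annotations.tsv"
    if go_path.exists():
        for line in go_path.read_text().splitlines():
            if not line.strip() or line.startswith("gene_id\t"):
                continue
            gene_id, _, terms = line.partition("\t")
            go[gene_id] = {t for t in terms.strip().split(",") if t}

    groups: list[OrthologGroup] = []
    og_path = directory / "ortholog_groups.tsv"
    if og_path.exists():
        acc: dict[str, OrthologGroup] = {}
        for line in og_path.read_text().splitlines():
            if not line.strip() or line.startswith("group_id\t"):
                continue
            group_id, species, members = line.split("\t")
            grp = acc.setdefault(group_id, OrthologGroup(group_id))
            if species == "dmel":
                grp.dmel_ids = grp.dmel_ids | frozenset(m for m in members.split(",") if m)
            else:
                parsed = []
                for m in members.split(","):
                    if not m:
                        continue
                    gid, _, length = m.partition(":")
                    parsed.append((gid, int(length) if length else 0))
                grp.members.setdefault(species, []).extend(parsed)
        groups = [acc[k] for k in sorted(acc)]

    return Dataset(specimens, genes, go, groups)


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id, "species": s.species,
                "latitude": s.latitude, "longitude": s.longitude,
                "is_reference": int(s.is_reference),
                "mapped_noncoding_pct": s.mapped_noncoding_pct,
                "mapped_coding_pct": s.mapped_coding_pct,
                "het_pct": s.het_pct, "het_coding_pct": s.het_coding_pct,
                "coverage": s.coverage,
            }
            for s in dataset.specimens
        ]
    ).to_csv(directory / "specimens.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "is_mito": int(g.is_mito),
             "frame_offset": g.frame_offset, "exons": _exons_to_text(g.exons)}
            for g in dataset.genes
        ]
    ).to_csv(directory / "genes.tsv", sep="\t", index=False)

    gene_dir = directory / "genes"
    gene_dir.mkdir(exist_ok=True)
    species_of = dataset.species_map
    for g in dataset.genes:
        records = [
            SeqRecord(Seq(seq), id=f"{sid}|{species_of[sid]}|h{hap}", description="")
            for sid, hap, seq in g.haplotypes()
        ]
        SeqIO.write(records, str(gene_dir / f"{g.gene_id}.fasta"), "fasta")

    if dataset.go_annotations:
        with open(directory / "go_annotations.tsv", "w") as fh:
            fh.write("gene_id\tgo_terms\n")
            for gene_id in sorted(dataset.go_annotations):
                fh.write(f"{gene_id}\t{','.join(sorted(dataset.go_annotations[gene_id]))}\n")

    if dataset.ortholog_groups:
        with open(directory / "ortholog_groups.tsv", "w") as fh:
            fh.write("group_id\tspecies\tmembers\n")
            for grp in dataset.ortholog_groups:
                for species in sorted(grp.members):
                    joined = ",".join(f"{gid}:{ln}" for gid, ln in grp.members[species])
                    fh.write(f"{grp.group_id}\t{species}\t{joined}\n")
                if grp.dmel_ids:
                    fh.write(f"{grp.group_id}\tdmel\t{','.join(sorted(grp.dmel_ids))}\n")


# ---------------------------------------------------------------------------
# Newick round-trip (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_tree(newick_text: str) -> dendropy.Tree:
    """Parse a Newick string (optional internal-node support labels) into an
    unrooted dendropy Tree. Duplicate leaf labels are rejected."""
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # malformed text, unbalanced parens, duplicates
        raise DatasetError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = False
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise DatasetError("duplicate leaf labels in Newick input")
    return tree


def write_tree(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick, keeping internal-node support labels."""
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


# ---------------------------------------------------------------------------
# packaged Table-2 specimen fixture
# ---------------------------------------------------------------------------

def load_specimen_fixture() -> list[SpecimenRecord]:
    """The eight sequenced specimens with their published mapping and
    heterozygosity statistics and collection latitudes."""
    raw = resources.files("hotspotscan").joinpath("data/table2_specimens.tsv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise DatasetError("specimen fixture corrupted (checksum mismatch)")
    records = _records_from_frame(pd.read_csv(io.BytesIO(raw), sep="\t"))
    if len(records) != 8:
        raise DatasetError("specimen fixture corrupted (expected 8 records)")
    return records


def specimen_fixture_sha256() -> str:
    raw = resources.files("hotspotscan").joinpath("data/table2_specimens.tsv").read_bytes()
    return hashlib.sha256(raw).hexdigest()


def write_config(thresholds: Thresholds, path: str | Path) -> None:
    Path(path).write_text(json.dumps(thresholds.__dict__, indent=2) + "\n")


def load_config(path: str | Path) -> Thresholds:
    return Thresholds(**json.loads(Path(path).read_text()))
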