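"""Reading annotated mitogenome flat files, gene-name normalization, filters.

Records arrive as GenBank flat files with CDS features. Gene names are
normalized to the 13 canonical mitochondrial protein-coding genes, minus
strand features are stored coding-sense, and the two inclusion filters are
applied in order: completeness (all 13 protein-CDS present) then minimum
sample size per species.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_alignment import ALL_PROTEIN_GENES

logger = logging.getLogger(__name__)

CANONICAL_GENES = frozenset(ALL_PROTEIN_GENES)

# Case-insensitive synonym table for gene/locus style names (spaces, hyphens
# and underscores removed, leading MT- stripped before lookup).
_GENE_SYNONYMS: Dict[str, str] = {
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPSYNTHASEF0SUBUNIT6": "ATP6",
    "ATPSYNTHASEFOSUBUNIT6": "ATP6", "ATP SYNTHASE 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPSYNTHASEF0SUBUNIT8": "ATP8",
    "ATPSYNTHASEFOSUBUNIT8": "ATP8",
    "COX1": "COX1", "COXI": "COX1", "CO1": "COX1", "COI": "COX1",
    "COX2": "COX2", "COXII": "COX2", "CO2": "COX2", "COII": "COX2",
    "COX3": "COX3", "COXIII": "COX3", "CO3": "COX3", "COIII": "COX3",
    "CYTB": "CYTB", "CYB": "CYTB", "COB": "CYTB", "CYTOCHROMEB": "CYTB",
    "ND1": "ND1", "NAD1": "ND1", "NADH1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L", "NADH4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH6": "ND6",
}

_PRODUCT_PATTERNS: List[Tuple[re.Pattern, str]] = [
    (re.compile(r"NADH[ -]?DEHYDROGENASE[ ,]*SUBUNIT[ -]?(\d)L?", re.I), "ND"),
    (re.compile(r"CYTOCHROME[ -]?C[ -]?OXIDASE[ ,]*SUBUNIT[ -]?(I{1,3}|[123])", re.I), "COX"),
    (re.compile(r"CYTOCHROME[ -]?B", re.I), "CYTB"),
    (re.compile(r"ATP[ -]?SYNTHASE[ A-Z0]*SUBUNIT[ -]?([68])", re.I), "ATP"),
]
_ROMAN = {"I": "1", "II": "2", "III": "3"}


def normalize_gene_name(raw: Optional[str]) -> Optional[str]:
    """Map a raw gene or product string to a canonical gene name, or None.

    Total function: tRNA/rRNA/unrecognized names return None.
    """
    if not raw:
        return None
    text = raw.strip().upper()
    if text.startswith("TRNA") or "RIBOSOMAL" in text or "RRNA" in text:
        return None
    key = re.sub(r"[\s_\-]", "", text)
    key = re.sub(r"^MT", "", key) if re.match(r"^MT(?=[A-Z])", key) else key
    if key in _GENE_SYNONYMS:
        return _GENE_SYNONYMS[key]
    for pattern, prefix in _PRODUCT_PATTERNS:
        m = pattern.search(text)
        if not m:
            continue
        if prefix == "CYTB":
            return "CYTB"
        token = m.group(1).upper()
        token = _ROMAN.get(token, token)
        if prefix == "ND":
            name = "ND" + token + ("L" if text.rstrip().endswith("4L") else "")
            return name if name in CANONICAL_GENES else None
        name = prefix + token
        return name if name in CANONICAL_GENES else None
    return None


@dataclass
class GeneFeature:
    """One protein-CDS: canonical name, genomic span(s), strand, coding-sense sequence."""

    canonical_name: str
    span: List[Tuple[int, int]]  # 0-based half-open intervals, annotation order
    strand: str  # '+' or '-'
    nucleotide_sequence: str

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.span)


@dataclass
class AnnotatedMitogenome:
    record_id: str
    species: str
    genome_length: int
    circular: bool
    genes: Dict[str, GeneFeature] = field(default_factory=dict)
    genome_sequence: Optional[str] = None

    def has_all_protein_genes(self) -> bool:
        return set(self.genes) >= CANONICAL_GENES

    def missing_genes(self) -> List[str]:
        return sorted(CANONICAL_GENES - set(self.genes))


@dataclass
class SpeciesDataset:
    species: str
    genomes: List[AnnotatedMitogenome]
    family: str = "Unknown"


@dataclass
class RunReport:
    """Per-stage record counts for the extraction run."""

    files_read: int = 0
    records_parsed: int = 0
    records_unparseable: int = 0
    features_dropped: int = 0
    duplicates_resolved: int = 0
    incomplete_genomes: int = 0
    small_species: int = 0

    def as_rows(self) -> List[Tuple[str, int]]:
        return [
            ("files_read", self.files_read),
            ("records_parsed", self.records_parsed),
            ("records_unparseable", self.records_unparseable),
            ("features_dropped", self.features_dropped),
            ("duplicates_resolved", self.duplicates_resolved),
            ("incomplete_genomes", self.incomplete_genomes),
            ("small_species", self.small_species),
        ]


def _binomial(organism: str) -> str:
    """Collapse subspecies strings to the binomial (first two words)."""
    words = organism.split()
    return " ".join(words[:2]) if len(words) >= 2 else organism


def _open_flatfile(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _feature_to_gene(
    feature: SeqFeature, record: SeqRecord
) -> Optional[GeneFeature]:
    names = feature.qualifiers.get("gene", []) + feature.qualifiers.get("product", [])
    canonical = None
    for raw in names:
        canonical = normalize_gene_name(raw)
        if canonical:
            break
    if canonical is None:
        return None
    strand = "-" if feature.location.strand == -1 else "+"
    span = [(int(part.start), int(part.end)) for part in feature.location.parts]
    seq = str(feature.extract(record.seq)).upper()
    return GeneFeature(
        canonical_name=canonical,
        span=span,
        strand=strand,
        nucleotide_sequence=seq,
    )


def read_flatfiles(
    paths: Sequence[Path], report: Optional[RunReport] = None
) -> List[AnnotatedMitogenome]:
    """Parse GenBank flat files into :class:`AnnotatedMitogenome` records.

    Unparseable records are skipped with a warning; CDS features with no
    recognizable gene name are dropped; duplicate annotations of one gene
    resolve to the longest feature (tie: first in genome order).
    """
    report = report if report is not None else RunReport()
    genomes: List[AnnotatedMitogenome] = []
    for path in paths:
        path = Path(path)
        report.files_read += 1
        try:
            with _open_flatfile(path) as handle:
                records = list(SeqIO.parse(handle, "genbank"))
        except Exception as exc:  # noqa: BLE001 - malformed third-party input
            logger.warning("skipping unparseable file %s: %s", path, exc)
            report.records_unparseable += 1
            continue
        for record in records:
            try:
                genome = _record_to_genome(record, report)
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping record in %s: %s", path, exc)
                report.records_unparseable += 1
                continue
            genomes.append(genome)
            report.records_parsed += 1
    return genomes


def _record_to_genome(record: SeqRecord, report: RunReport) -> AnnotatedMitogenome:
    organism = record.annotations.get("organism", "")
    if not organism:
        for feature in record.features:
            if feature.type == "source":
                organism = feature.qualifiers.get("organism", [""])[0]
                break
    if not organism:
        raise ValueError(f"record {record.id} has no organism")
    genes: Dict[str, GeneFeature] = {}
    for feature in record.features:
        if feature.type != "CDS":
            continue
        gene = _feature_to_gene(feature, record)
        if gene is None:
            logger.warning(
                "record %s: CDS with unrecognized name %s dropped",
                record.id,
                feature.qualifiers.get("gene", feature.qualifiers.get("product")),
            )
            report.features_dropped += 1
            continue
        existing = genes.get(gene.canonical_name)
        if existing is not None:
            report.duplicates_resolved += 1
            logger.warning(
                "record %s: duplicate %s annotation, keeping the longer feature",
                record.id,
                gene.canonical_name,
            )
            if gene.length <= existing.length:
                continue
        genes[gene.canonical_name] = gene
    return AnnotatedMitogenome(
        record_id=record.id,
        species=_binomial(organism),
        genome_length=len(record.seq),
        circular=record.annotations.get("topology", "") == "circular",
        genes=genes,
        genome_sequence=str(record.seq).upper() if len(record.seq) else None,
    )


def filter_complete_genomes(
    genomes: Iterable[AnnotatedMitogenome],
    report: Optional[RunReport] = None,
) -> Tuple[List[AnnotatedMitogenome], List[AnnotatedMitogenome]]:
    """Keep genomes carrying all 13 canonical protein-CDS."""
    kept, dropped = [], []
    for genome in genomes:
        if genome.has_all_protein_genes():
            kept.append(genome)
        else:
            logger.warning(
                "genome %s missing genes %s", genome.record_id, genome.missing_genes()
            )
            dropped.append(genome)
    if report is not None:
        report.incomplete_genomes += len(dropped)
    return kept, dropped


def group_by_species(
    genomes: Iterable[AnnotatedMitogenome],
    taxonomy: Optional[Mapping[str, str]] = None,
) -> List[SpeciesDataset]:
    taxonomy = taxonomy or {}
    buckets: Dict[str, List[AnnotatedMitogenome]] = {}
    for genome in genomes:
        buckets.setdefault(genome.species, []).append(genome)
    return [
        SpeciesDataset(
            species=species,
            genomes=buckets[species],
            family=taxonomy.get(species, "Unknown"),
        )
        for species in sorted(buckets)
    ]


def filter_min_sample(
    datasets: Iterable[SpeciesDataset],
    min_n: int = 5,
    report: Optional[RunReport] = None,
) -> Tuple[List[SpeciesDataset], List[SpeciesDataset]]:
    """Keep species with at least ``min_n`` genomes (after completeness)."""
    kept, dropped = [], []
    for dataset in datasets:
        (kept if len(dataset.genomes) >= min_n else dropped).append(dataset)
    if report is not None:
        report.small_species += len(dropped)
    for dataset in dropped:
        logger.warning(
            "species %s dropped: %d < %d genomes",
            dataset.species,
            len(dataset.genomes),
            min_n,
        )
    return kept, dropped


def load_taxonomy(path: Path) -> Dict[str, str]:
    """Read a two-column species<TAB>family table (comments with '#')."""
    taxonomy: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or parts[0].lower() == "species":
            continue
        taxonomy[parts[0]] = parts[1]
    return taxonomy


def packaged_taxonomy() -> Dict[str, str]:
    return load_taxonomy(Path(__file__).parent / "data" / "taxonomy.tsv")


def write_flatfile(genome: AnnotatedMitogenome, path: Path) -> None:
    """Serialize a genome (with its sequence) back to a GenBank flat file."""
    if genome.genome_sequence is None:
        raise ValueError(f"genome {genome.record_id} carries no sequence")
    record = SeqRecord(
        Seq(genome.genome_sequence),
        id=genome.record_id,
        name=genome.record_id.split(".")[0][:16],
        description=f"{genome.species} mitochondrion, complete genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["organism"] = genome.species
    record.annotations["date"] = "01-JAN-2024"
    record.annotations["data_file_division"] = "MAM"
    source = SeqFeature(
        FeatureLocation(0, genome.genome_length),
        type="source",
        qualifiers={"organism": [genome.species]},
    )
    record.features.append(source)
    strand_code = {"+": 1, "-": -1}
    for name in sorted(genome.genes):
        gene = genome.genes[name]
        locs = [
            FeatureLocation(s, e, strand=strand_code[gene.strand])
            for s, e in gene.span
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        record.features.append(
            SeqFeature(location, type="CDS", qualifiers={"gene": [name]})
        )
    SeqIO.write([record], str(path), "genbank")
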