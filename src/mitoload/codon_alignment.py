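"""Codon-aware translation, protein-guided alignment, and supergene assembly.

Coding sequences are translated under the vertebrate mitochondrial code,
proteins are aligned (internal progressive aligner or an imported external
alignment), nucleotides are threaded back onto the protein columns so that
every alignment column triple is a codon, ambiguous codons are masked, and
the twelve heavy-strand genes are concatenated into a single supergene.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.cluster.hierarchy import linkage

logger = logging.getLogger(__name__)

#: Heavy-strand protein-coding genes, in fixed concatenation order.
HEAVY_STRAND_GENES: Tuple[str, ...] = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5",
)
#: All 13 mitochondrial protein-coding genes (ND6 is light-strand).
ALL_PROTEIN_GENES: Tuple[str, ...] = HEAVY_STRAND_GENES + ("ND6",)

DNA = frozenset("ACGT")
GAP_CODON = "---"
STOP_SYMBOL = "*"


class InternalStopError(ValueError):
    """Raised when a CDS contains a premature (non-terminal) stop codon."""


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon -> amino-acid map plus stop and start codon sets."""

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset
    start_codons: frozenset

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; 'X' if the codon is not pure unambiguous DNA."""
        if len(codon) != 3 or not set(codon) <= DNA:
            return "X"
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def sense_codons(self) -> List[str]:
        return [c for c in sorted(self.codon_to_aa) if c not in self.stop_codons]


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 2) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table.

    Table 2 (vertebrate mitochondrial) is the default: ATA codes Met,
    TGA codes Trp, and AGA/AGG are stop codons.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP_SYMBOL
    if len(mapping) != 64:
        raise AssertionError(f"incomplete codon table {table_id}")
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=mapping,
        stop_codons=frozenset(table.stop_codons),
        start_codons=frozenset(table.start_codons),
    )


def clean_cds(cds: str, code: GeneticCode) -> str:
    """Trim a 1-2 nt trailing partial codon and a single terminal stop codon.

    Mitochondrial stop codons are frequently completed by polyadenylation,
    so a trailing overhang is trimmed with a warning rather than rejected.
    """
    seq = cds.upper().replace("U", "T")
    overhang = len(seq) % 3
    if overhang:
        logger.warning("trimming %d-nt partial codon from CDS end", overhang)
        seq = seq[: len(seq) - overhang]
    if len(seq) == 0:
        raise ValueError("empty CDS after trimming partial codon")
    if code.is_stop(seq[-3:]):
        seq = seq[:-3]
    if len(seq) == 0:
        raise ValueError("CDS contains only a stop codon")
    return seq


def translate(cds: str, code: GeneticCode) -> str:
    """Translate a CDS; codons with N/ambiguity become 'X'.

    A single terminal stop is stripped before return; an internal stop
    raises :class:`InternalStopError` (callers exclude such records).
    """
    seq = clean_cds(cds, code)
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if set(codon) <= DNA and code.is_stop(codon):
            raise InternalStopError(f"internal stop codon {codon} at nt {i}")
        aas.append(code.aa(codon))
    return "".join(aas)


# ---------------------------------------------------------------------------
# Protein alignment
# ---------------------------------------------------------------------------

@dataclass
class ProteinAlignment:
    gene: str
    rows: Dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        ncol = self.n_columns
        for rid, row in self.rows.items():
            if len(row) != ncol:
                raise ValueError(f"ragged alignment row {rid} in {self.gene}")


@lru_cache(maxsize=1)
def _blosum62() -> Tuple[Dict[str, int], np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    index = {a: i for i, a in enumerate(alphabet)}
    return index, np.asarray(mat, dtype=float)


def _column_scores(cols_a: List[str], cols_b: List[str]) -> np.ndarray:
    """Mean BLOSUM62 score between all residue pairs of two profile columns.

    Gap characters contribute zero; scores form an (len_a, len_b) matrix.
    """
    index, mat = _blosum62()
    nsym = len(index)

    def freqs(cols: List[str]) -> np.ndarray:
        out = np.zeros((len(cols), nsym))
        for i, col in enumerate(cols):
            for ch in col:
                if ch != "-":
                    out[i, index.get(ch, index["X"])] += 1.0
        return out

    fa, fb = freqs(cols_a), freqs(cols_b)
    na = max(len(cols_a[0]), 1) if cols_a else 1
    nb = max(len(cols_b[0]), 1) if cols_b else 1
    return (fa @ mat @ fb.T) / (na * nb)


def _profile_align(
    rows_a: List[str],
    rows_b: List[str],
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> Tuple[List[str], List[str]]:
    """Gotoh (affine-gap) global alignment of two alignment profiles.

    A gap of length g costs ``gap_open + g * gap_extend``.
    Returns the two row sets expanded with the merged gap columns.
    """
    m, n = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(m)]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(n)]
    score = _column_scores(cols_a, cols_b)

    neg = -1e30  # effective -inf that stays finite under addition
    M = np.full((m + 1, n + 1), neg)
    X = np.full((m + 1, n + 1), neg)  # gap in B (consumes A column)
    Y = np.full((m + 1, n + 1), neg)  # gap in A (consumes B column)
    M[0, 0] = 0.0
    js = np.arange(n + 1, dtype=float)
    Y[0, 1:] = gap_open + gap_extend * js[1:]
    # Row-vectorized Gotoh: X depends on the previous row; Y within a row is
    # an affine-gap prefix maximum over M of the same row.
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + score[i - 1, :]
        X[i] = np.maximum(M[i - 1] + gap_open + gap_extend, X[i - 1] + gap_extend)
        shifted = np.maximum.accumulate(M[i] + gap_open - gap_extend * js)
        Y[i, 1:] = gap_extend * js[1:] + shifted[:-1]

    tol = 1e-9
    state = int(np.argmax([M[m, n], X[m, n], Y[m, n]]))
    i, j = m, n
    steps: List[str] = []
    while i > 0 or j > 0:
        if i == 0:
            steps.append("Y"); j -= 1; continue
        if j == 0:
            steps.append("X"); i -= 1; continue
        if state == 0:
            steps.append("M")
            state = int(np.argmax(
                [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            i -= 1; j -= 1
        elif state == 1:
            steps.append("X")
            state = (
                0 if M[i - 1, j] + gap_open + gap_extend
                >= X[i - 1, j] + gap_extend - tol else 1
            )
            i -= 1
        else:
            steps.append("Y")
            state = (
                0 if M[i, j - 1] + gap_open + gap_extend
                >= Y[i, j - 1] + gap_extend - tol else 2
            )
            j -= 1
    steps.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for step in steps:
        if step in ("M", "X"):
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
        if step in ("M", "Y"):
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    k = min(k, len(a), len(b))
    if k == 0:
        return 1.0
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    denom = min(sum(ca.values()), sum(cb.values()))
    return 1.0 - shared / denom if denom else 1.0


def align_proteins(seqs: Mapping[str, str], gene: str = "") -> ProteinAlignment:
    """Progressive multiple alignment: k-mer distances -> UPGMA -> profile NW.

    Scores are BLOSUM62 with affine gaps (open -10, extend -1). Within-species
    mitochondrial proteins are near-identical, so this reproduces what a
    heavier aligner would give; :func:`load_protein_alignment` is the escape
    hatch for externally computed alignments.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = sorted(seqs)
    if len(ids) == 1:
        return ProteinAlignment(gene=gene, rows={ids[0]: seqs[ids[0]]})

    nseq = len(ids)
    condensed = []
    for i, j in combinations(range(nseq), 2):
        condensed.append(_kmer_distance(seqs[ids[i]], seqs[ids[j]]))
    clusters: Dict[int, Tuple[List[int], List[str]]] = {
        i: ([i], [seqs[ids[i]]]) for i in range(nseq)
    }
    if nseq == 2:
        merges = [(0, 1)]
    else:
        z = linkage(np.asarray(condensed), method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in z]
    next_id = nseq
    for a, b in merges:
        idx_a, rows_a = clusters.pop(a)
        idx_b, rows_b = clusters.pop(b)
        new_a, new_b = _profile_align(rows_a, rows_b)
        clusters[next_id] = (idx_a + idx_b, new_a + new_b)
        next_id += 1
    (_, (order, rows)), = clusters.items()
    aligned = {ids[i]: row for i, row in zip(order, rows)}
    aln = ProteinAlignment(gene=gene, rows={rid: aligned[rid] for rid in ids})
    aln.validate()
    return aln


def load_protein_alignment(
    path: Path, expected: Mapping[str, str], gene: str = ""
) -> ProteinAlignment:
    """Import an externally computed protein alignment (FASTA) and verify it.

    Each record's degapped sequence must equal the corresponding input
    protein; extra or missing records are errors.
    """
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    extra = set(rows) - set(expected)
    missing = set(expected) - set(rows)
    if extra or missing:
        raise ValueError(
            f"alignment {path} record mismatch: extra={sorted(extra)} "
            f"missing={sorted(missing)}"
        )
    for rid, row in rows.items():
        if row.replace("-", "") != expected[rid]:
            raise ValueError(f"alignment row {rid} does not match its input protein")
    aln = ProteinAlignment(gene=gene, rows={rid: rows[rid] for rid in sorted(rows)})
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    gene: str
    rows: Dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        ncol = self.n_columns
        if ncol % 3:
            raise ValueError(f"codon alignment length {ncol} not divisible by 3")
        for rid, row in self.rows.items():
            if len(row) != ncol:
                raise ValueError(f"ragged codon alignment row {rid}")
            for i in range(0, ncol, 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(f"partially gapped codon {codon!r} in {rid}")


def backtranslate(
    cds_map: Mapping[str, str], prot_aln: ProteinAlignment
) -> CodonAlignment:
    """Thread cleaned CDS nucleotides onto the protein alignment columns."""
    rows: Dict[str, str] = {}
    for rid, prot_row in prot_aln.rows.items():
        if rid not in cds_map:
            raise ValueError(f"no CDS for aligned record {rid} ({prot_aln.gene})")
        cds = cds_map[rid]
        n_aa = len(prot_row) - prot_row.count("-")
        if n_aa * 3 != len(cds):
            raise ValueError(
                f"length mismatch for {rid} ({prot_aln.gene}): "
                f"{n_aa} aa vs {len(cds)} nt"
            )
        out = []
        pos = 0
        for aa in prot_row:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[pos : pos + 3])
                pos += 3
        rows[rid] = "".join(out)
    aln = CodonAlignment(gene=prot_aln.gene, rows=rows)
    aln.validate()
    return aln


def clean_codons(aln: CodonAlignment) -> CodonAlignment:
    """Mask every codon containing N or another ambiguity code to '---'.

    Masking is per row; downstream complete-site deletion removes the
    affected columns from all statistics.
    """
    rows: Dict[str, str] = {}
    for rid, row in aln.rows.items():
        out = []
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if codon != GAP_CODON and not set(codon) <= DNA:
                codon = GAP_CODON
            out.append(codon)
        rows[rid] = "".join(out)
    return CodonAlignment(gene=aln.gene, rows=rows)


# ---------------------------------------------------------------------------
# Supergene
# ---------------------------------------------------------------------------

@dataclass
class SupergeneAlignment:
    """Codon-faithful concatenation of the 12 heavy-strand gene alignments."""

    species: str
    rows: Dict[str, str]
    boundaries: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def record_ids(self) -> List[str]:
        return list(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    @classmethod
    def from_rows(
        cls, rows: Mapping[str, str], species: str = "unknown"
    ) -> "SupergeneAlignment":
        rows = {rid: rows[rid] for rid in sorted(rows)}
        ncol = len(next(iter(rows.values())))
        return cls(species=species, rows=rows, boundaries={"supergene": (0, ncol)})


def concatenate_supergene(
    gene_alns: Mapping[str, CodonAlignment], species: str = "unknown"
) -> SupergeneAlignment:
    """Concatenate the 12 heavy-strand codon alignments in fixed gene order."""
    if "ND6" in gene_alns:
        raise ValueError("ND6 is light-strand and excluded from the supergene")
    missing = [g for g in HEAVY_STRAND_GENES if g not in gene_alns]
    if missing:
        raise ValueError(f"missing gene alignments: {missing}")
    id_sets = {g: set(a.rows) for g, a in gene_alns.items()}
    reference = id_sets[HEAVY_STRAND_GENES[0]]
    for gene, ids in id_sets.items():
        if ids != reference:
            raise ValueError(
                f"record set mismatch between {HEAVY_STRAND_GENES[0]} and {gene}"
            )
    record_ids = sorted(reference)
    boundaries: Dict[str, Tuple[int, int]] = {}
    parts: Dict[str, List[str]] = {rid: [] for rid in record_ids}
    offset = 0
    for gene in HEAVY_STRAND_GENES:
        aln = gene_alns[gene]
        width = aln.n_columns
        boundaries[gene] = (offset, offset + width)
        offset += width
        for rid in record_ids:
            parts[rid].append(aln.rows[rid])
    rows = {rid: "".join(parts[rid]) for rid in record_ids}
    return SupergeneAlignment(species=species, rows=rows, boundaries=boundaries)


# ---------------------------------------------------------------------------
# FASTA / metadata I/O
# ---------------------------------------------------------------------------

def write_fasta(rows: Mapping[str, str], path: Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_supergene(aln: SupergeneAlignment, fasta_path: Path) -> None:
    fasta_path = Path(fasta_path)
    write_fasta(aln.rows, fasta_path)
    meta = {
        "species": aln.species,
        "boundaries": {g: list(iv) for g, iv in aln.boundaries.items()},
    }
    fasta_path.with_suffix(fasta_path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n"
    )


def read_supergene(fasta_path: Path) -> SupergeneAlignment:
    fasta_path = Path(fasta_path)
    rows = read_fasta(fasta_path)
    meta_path = fasta_path.with_suffix(fasta_path.suffix + ".meta.json")
    species = "unknown"
    boundaries: Dict[str, Tuple[int, int]] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        species = meta.get("species", species)
        boundaries = {g: tuple(iv) for g, iv in meta.get("boundaries", {}).items()}
    aln = SupergeneAlignment.from_rows(rows, species=species)
    if boundaries:
        aln.boundaries = boundaries
    return aln


def build_species_supergene(
    cds_by_gene: Mapping[str, Mapping[str, str]],
    species: str = "unknown",
    code: Optional[GeneticCode] = None,
    external_alignments: Optional[Mapping[str, Path]] = None,
) -> Tuple[SupergeneAlignment, List[str]]:
    """Translate, align, backtranslate, clean and concatenate one species.

    ``cds_by_gene`` maps gene -> record_id -> raw CDS. Records with an
    internal stop in any gene are excluded from every gene (returned in the
    second element). Only the 12 heavy-strand genes are used.
    """
    code = code or genetic_code(2)
    cleaned: Dict[str, Dict[str, str]] = {}
    proteins: Dict[str, Dict[str, str]] = {}
    bad_records: set = set()
    for gene in HEAVY_STRAND_GENES:
        cleaned[gene] = {}
        proteins[gene] = {}
        for rid, cds in cds_by_gene[gene].items():
            try:
                proteins[gene][rid] = translate(cds, code)
                cleaned[gene][rid] = clean_cds(cds, code)
            except InternalStopError:
                logger.warning("record %s excluded: internal stop in %s", rid, gene)
                bad_records.add(rid)
    gene_alns: Dict[str, CodonAlignment] = {}
    for gene in HEAVY_STRAND_GENES:
        prots = {r: p for r, p in proteins[gene].items() if r not in bad_records}
        cds_map = {r: c for r, c in cleaned[gene].items() if r not in bad_records}
        if len(prots) < 2:
            raise ValueError(f"fewer than 2 usable records for {gene}")
        if external_alignments and gene in external_alignments:
            prot_aln = load_protein_alignment(
                external_alignments[gene], prots, gene=gene
            )
        else:
            prot_aln = align_proteins(prots, gene=gene)
        gene_alns[gene] = clean_codons(backtranslate(cds_map, prot_aln))
    supergene = concatenate_supergene(gene_alns, species=species)
    return supergene, sorted(bad_records)
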