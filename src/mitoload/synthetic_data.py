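"""Self-contained test-data generation with known truth.

Samples a Kingman coalescent genealogy (optionally two demes with zero
migration joined at a split depth), mutates codon sequences along it with a
transition/transversion bias and acceptance-thinning of nonsynonymous
events (target dN/dS = omega), and emits GenBank-style flat files that
exercise the whole extraction/alignment/statistics pipeline offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import yaml

from .codon_alignment import (
    ALL_PROTEIN_GENES,
    HEAVY_STRAND_GENES,
    GeneticCode,
    genetic_code,
)
from .mitogenome_io import AnnotatedMitogenome, GeneFeature, write_flatfile

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Approximate mammalian mitochondrial gene sizes, in codons.
DEFAULT_GENE_CODONS: Dict[str, int] = {
    "ATP6": 226, "ATP8": 66, "COX1": 516, "COX2": 227, "COX3": 261,
    "CYTB": 379, "ND1": 318, "ND2": 347, "ND3": 115, "ND4": 459,
    "ND4L": 98, "ND5": 606, "ND6": 175,
}


def scaled_gene_codons(total_codons: int) -> Dict[str, int]:
    """Scale the default gene sizes to roughly ``total_codons`` overall."""
    base = sum(DEFAULT_GENE_CODONS.values())
    factor = total_codons / base
    return {
        gene: max(4, int(round(n * factor)))
        for gene, n in DEFAULT_GENE_CODONS.items()
    }


@dataclass
class SimulationParams:
    n_samples: int = 10  # per deme
    gene_codons: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_CODONS)
    )
    theta: float = 0.002
    omega: float = 0.2
    kappa: float = 8.0
    n_demes: int = 1
    split_depth: float = 5.0
    seed: int = 17
    species: str = "Synthetica exempli"
    table_id: int = 2

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples per deme")
        if self.n_demes not in (1, 2):
            raise ValueError("n_demes must be 1 or 2")
        missing = set(ALL_PROTEIN_GENES) - set(self.gene_codons)
        if missing:
            raise ValueError(f"gene_codons missing {sorted(missing)}")


# ---------------------------------------------------------------------------
# Coalescent genealogy
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """Binary coalescent tree: leaves are nodes 0..n-1 at time 0."""

    n_leaves: int
    parent: List[int]  # -1 for the root
    time: List[float]

    @property
    def root(self) -> int:
        return self.parent.index(-1)

    def children(self) -> Dict[int, List[int]]:
        out: Dict[int, List[int]] = {}
        for node, par in enumerate(self.parent):
            if par >= 0:
                out.setdefault(par, []).append(node)
        return out

    def branch_length(self, node: int) -> float:
        par = self.parent[node]
        return 0.0 if par < 0 else self.time[par] - self.time[node]

    def total_branch_length(self) -> float:
        return sum(self.branch_length(v) for v in range(len(self.parent)))

    def tmrca(self) -> float:
        return self.time[self.root]

    def mrca_time(self, leaves: List[int]) -> float:
        """Time of the most recent common ancestor of a leaf subset."""
        ancestors = None
        for leaf in leaves:
            chain = []
            v = leaf
            while v != -1:
                chain.append(v)
                v = self.parent[v]
            ancestors = set(chain) if ancestors is None else ancestors & set(chain)
        return min(self.time[v] for v in ancestors)


def simulate_genealogy(
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_demes: int = 1,
    split_depth: float = 5.0,
) -> Tuple[Genealogy, List[int]]:
    """Kingman coalescent; in two-deme mode each deme coalesces to its own
    MRCA independently and the deme MRCAs are joined at ``split_depth``
    (or just past the deeper deme MRCA if one exceeds it). Returns the tree
    and per-leaf deme labels.

    ``n`` is the number of samples per deme.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    total_leaves = n * n_demes
    parent = [-1] * total_leaves
    time = [0.0] * total_leaves
    deme_labels = [d for d in range(n_demes) for _ in range(n)]
    next_id = total_leaves

    def coalesce(active: List[int], t: float, t_max: Optional[float]):
        nonlocal next_id
        while len(active) > 1:
            k = len(active)
            wait = rng.exponential(2.0 / (k * (k - 1)))
            if t_max is not None and t + wait > t_max:
                return active, t_max
            t += wait
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = active[i], active[j]
            parent.append(-1)
            time.append(t)
            parent[a] = parent[b] = next_id
            active = [x for x in active if x not in (a, b)] + [next_id]
            next_id += 1
        return active, t

    if n_demes == 1:
        coalesce(list(range(n)), 0.0, None)
    else:
        roots: List[int] = []
        times: List[float] = []
        for d in range(n_demes):
            leaves = [d * n + i for i in range(n)]
            (root,), t_mrca = coalesce(leaves, 0.0, None)
            roots.append(root)
            times.append(t_mrca)
        join_time = max([split_depth] + times) + 1e-9
        parent.append(-1)
        time.append(join_time)
        for root in roots:
            parent[root] = next_id
        next_id += 1
    return Genealogy(n_leaves=total_leaves, parent=parent, time=time), deme_labels


# ---------------------------------------------------------------------------
# Codon mutation with selection thinning
# ---------------------------------------------------------------------------

def random_sense_codons(
    n_codons: int, rng: np.random.Generator, code: GeneticCode
) -> str:
    sense = code.sense_codons()
    idx = rng.integers(0, len(sense), size=n_codons)
    return "".join(sense[i] for i in idx)


def mutate_codons(
    tree: Genealogy,
    ancestral: str,
    theta: float,
    omega: float,
    kappa: float,
    code: GeneticCode,
    rng: np.random.Generator,
) -> List[str]:
    """Evolve ``ancestral`` down the tree; returns one sequence per leaf.

    Mutations arise as a Poisson process at rate theta/2 per site per unit
    branch length. Each event picks a uniform site and an alternative
    nucleotide with transition:transversion weights kappa:1:1; stop-creating
    events are discarded, synonymous events always accepted, nonsynonymous
    events accepted with probability omega.
    """
    if len(ancestral) % 3:
        raise ValueError("ancestral length must be divisible by 3")
    n_sites = len(ancestral)
    children = tree.children()
    sequences: Dict[int, List[str]] = {tree.root: list(ancestral)}
    leaves: List[str] = [""] * tree.n_leaves
    stack = [tree.root]
    while stack:
        node = stack.pop()
        seq = sequences.pop(node)
        if node < tree.n_leaves:
            leaves[node] = "".join(seq)
        for child in sorted(children.get(node, ())):
            child_seq = list(seq)
            blen = tree.branch_length(child)
            n_events = rng.poisson(theta / 2.0 * n_sites * blen)
            for _ in range(n_events):
                pos = int(rng.integers(0, n_sites))
                current = child_seq[pos]
                ts = _TS_PARTNER[current]
                tvs = [nt for nt in "ACGT" if nt not in (current, ts)]
                choices = [ts] + tvs
                weights = np.array([kappa, 1.0, 1.0])
                alt = choices[int(rng.choice(3, p=weights / weights.sum()))]
                cstart = 3 * (pos // 3)
                codon = child_seq[cstart : cstart + 3]
                new_codon = list(codon)
                new_codon[pos - cstart] = alt
                new_str = "".join(new_codon)
                if code.is_stop(new_str):
                    continue
                old_aa = code.aa("".join(codon))
                new_aa = code.aa(new_str)
                if old_aa != new_aa and rng.random() >= omega:
                    continue
                child_seq[pos] = alt
            sequences[child] = child_seq
            stack.append(child)
    return leaves


# ---------------------------------------------------------------------------
# Dataset assembly and emission
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    params: SimulationParams
    sample_ids: List[str]
    deme_labels: List[int]
    genes: Dict[str, List[str]]  # gene -> per-sample coding-sense CDS
    genealogy: Genealogy

    def truth(self) -> Dict[str, object]:
        return truth_table(self.params, deme_labels=self.deme_labels)


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Simulate one species: a single mitogenome genealogy (no recombination)
    shared by all 13 genes, each gene mutated independently along it.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    code = genetic_code(params.table_id)
    tree, deme_labels = simulate_genealogy(
        params.n_samples,
        rng=rng,
        n_demes=params.n_demes,
        split_depth=params.split_depth,
    )
    genes: Dict[str, List[str]] = {}
    for gene in ALL_PROTEIN_GENES:
        ancestral = random_sense_codons(params.gene_codons[gene], rng, code)
        genes[gene] = mutate_codons(
            tree, ancestral, params.theta, params.omega, params.kappa, code, rng
        )
    n_total = tree.n_leaves
    sample_ids = [f"SYN{params.seed % 1000:03d}S{i + 1:04d}" for i in range(n_total)]
    return SimulatedDataset(
        params=params,
        sample_ids=sample_ids,
        deme_labels=deme_labels,
        genes=genes,
        genealogy=tree,
    )


_SPACER = "ATTAATTAAT"  # inert inter-genic filler


def dataset_to_genomes(ds: SimulatedDataset) -> List[AnnotatedMitogenome]:
    """Assemble per-sample annotated genomes: 12 heavy-strand CDS plus ND6
    on the minus strand, separated by short spacers.
    """
    genomes: List[AnnotatedMitogenome] = []
    for i, sample_id in enumerate(ds.sample_ids):
        parts: List[str] = []
        features: Dict[str, GeneFeature] = {}
        offset = 0
        for gene in ALL_PROTEIN_GENES:
            cds = ds.genes[gene][i]
            genomic = (
                cds[::-1].translate(_COMPLEMENT) if gene == "ND6" else cds
            )
            start, end = offset, offset + len(genomic)
            parts.append(genomic)
            features[gene] = GeneFeature(
                canonical_name=gene,
                span=[(start, end)],
                strand="-" if gene == "ND6" else "+",
                nucleotide_sequence=cds,
            )
            parts.append(_SPACER)
            offset = end + len(_SPACER)
        sequence = "".join(parts)
        genomes.append(
            AnnotatedMitogenome(
                record_id=sample_id,
                species=ds.params.species,
                genome_length=len(sequence),
                circular=True,
                genes=features,
                genome_sequence=sequence,
            )
        )
    return genomes


def emit_flatfiles(ds: SimulatedDataset, out_dir: Path) -> List[Path]:
    """Write one GenBank flat file per sample plus truth.tsv and params.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    for genome in dataset_to_genomes(ds):
        path = out_dir / f"{genome.record_id}.gb"
        write_flatfile(genome, path)
        paths.append(path)
    truth = ds.truth()
    lines = ["sample_id\tdeme"]
    for sid, deme in zip(ds.sample_ids, ds.deme_labels):
        lines.append(f"{sid}\t{deme}")
    (out_dir / "truth.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / "params.yaml").write_text(
        yaml.safe_dump(
            {
                "species": ds.params.species,
                "n_samples": ds.params.n_samples,
                "n_demes": ds.params.n_demes,
                "split_depth": ds.params.split_depth,
                "theta": ds.params.theta,
                "omega": ds.params.omega,
                "kappa": ds.params.kappa,
                "seed": ds.params.seed,
                "expected_synonymous_diversity": truth["expected_synonymous_diversity"],
            },
            sort_keys=True,
        )
    )
    return paths


def truth_table(
    params: SimulationParams, deme_labels: Optional[List[int]] = None
) -> Dict[str, object]:
    """Expected values implied by the parameters (no simulation noise).

    Expected synonymous diversity per synonymous site follows from theta and
    the per-class acceptance rates, using uniform sense-codon composition:
    fourfold sites accept everything (rate theta), twofold sites accept the
    transition fraction kappa/(kappa+2).
    """
    params.validate()
    code = genetic_code(params.table_id)
    from .molevol_stats import _codon_class_counts  # shared degeneracy data

    counts = _codon_class_counts(params.table_id)
    sense = code.sense_codons()
    per_codon = np.mean([counts[c] for c in sense], axis=0)
    _, l2, l4 = per_codon
    ts_fraction = params.kappa / (params.kappa + 2.0)
    expected_syn = (
        params.theta * (l4 + l2 * ts_fraction) / (l4 + l2)
    )
    return {
        "theta": params.theta,
        "omega": params.omega,
        "kappa": params.kappa,
        "expected_synonymous_diversity": float(expected_syn),
        "n_demes": params.n_demes,
        "deme_labels": list(deme_labels) if deme_labels is not None else None,
    }
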