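"""Within-population molecular-evolution statistics.

Implements Nei-Li nucleotide diversity (uncorrected mean pairwise
p-distance) and the Pamilo-Bianchi-Li nonsynonymous/synonymous diversity
estimator with Kimura two-parameter correction, on complete-deletion codon
alignments, with codon-column bootstrap standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .codon_alignment import DNA, GeneticCode, SupergeneAlignment, genetic_code

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_CLASS_INDEX = {0: 0, 2: 1, 4: 2}  # degeneracy -> array slot


# ---------------------------------------------------------------------------
# Complete-site deletion
# ---------------------------------------------------------------------------

def complete_deletion(aln: SupergeneAlignment) -> SupergeneAlignment:
    """Drop every codon column with a gap or masked codon in any row.

    Columns are removed in whole-codon units and the gene boundary map is
    rebuilt to the surviving columns.
    """
    record_ids = sorted(aln.rows)
    ncod = aln.n_codons
    keep = np.ones(ncod, dtype=bool)
    for rid in record_ids:
        row = aln.rows[rid]
        for c in range(ncod):
            if keep[c] and not set(row[3 * c : 3 * c + 3]) <= DNA:
                keep[c] = False
    if not keep.any():
        raise ValueError("no usable sites after complete deletion")
    kept_idx = np.flatnonzero(keep)
    rows = {
        rid: "".join(aln.rows[rid][3 * c : 3 * c + 3] for c in kept_idx)
        for rid in record_ids
    }
    boundaries: Dict[str, Tuple[int, int]] = {}
    offset = 0
    for gene, (start, end) in aln.boundaries.items():
        n_kept = int(((kept_idx * 3 >= start) & (kept_idx * 3 < end)).sum())
        boundaries[gene] = (offset, offset + 3 * n_kept)
        offset += 3 * n_kept
    return SupergeneAlignment(species=aln.species, rows=rows, boundaries=boundaries)


# ---------------------------------------------------------------------------
# Nei-Li nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityEstimate:
    pi: float
    se: float
    n_sequences: int
    n_sites_used: int


def _encoded(aln: SupergeneAlignment) -> Tuple[List[str], np.ndarray]:
    record_ids = sorted(aln.rows)
    matrix = np.array(
        [np.frombuffer(aln.rows[r].encode(), dtype=np.uint8) for r in record_ids]
    )
    return record_ids, matrix


def nei_li_pi(
    aln: SupergeneAlignment, reps: int = 1000, seed: int = 17
) -> DiversityEstimate:
    """Mean pairwise p-distance per site with codon-column bootstrap SE.

    pi = 2 / (n(n-1)) * sum_{i<j} mismatches(i, j) / sites. The alignment
    must already be complete-deletion cleaned (pure ACGT rows).
    """
    record_ids, matrix = _encoded(aln)
    n, nsites = matrix.shape
    if n < 2:
        raise ValueError("need at least 2 sequences")
    npairs = n * (n - 1) // 2
    # per-site total mismatch count over all pairs
    mism_site = np.zeros(nsites)
    for i, j in combinations(range(n), 2):
        mism_site += matrix[i] != matrix[j]
    pi = float(mism_site.sum() / (npairs * nsites))
    ncod = nsites // 3
    mism_codon = mism_site.reshape(ncod, 3).sum(axis=1)
    rng = np.random.default_rng(seed)
    if reps < 2:
        raise ValueError("reps must be >= 2")
    estimates = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, ncod, size=ncod)
        weights = np.bincount(idx, minlength=ncod)
        estimates[r] = (mism_codon @ weights) / (npairs * nsites)
    se = float(np.std(estimates, ddof=1))
    return DiversityEstimate(pi=pi, se=se, n_sequences=n, n_sites_used=nsites)


# ---------------------------------------------------------------------------
# Site degeneracy and PBL pathway counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _degeneracy_table(table_id: int) -> Dict[str, Tuple[int, int, int]]:
    """Degeneracy class (0/2/4) of each position of all 64 codons.

    A position is 4-fold if all three single-nucleotide alternatives are
    synonymous, 0-fold if none is, else 2-fold. Alternatives creating stop
    codons count as nonsynonymous; for stop codons themselves (needed only
    on reinstated blocked pathways), stop->stop counts as synonymous.
    """
    code = genetic_code(table_id)
    table: Dict[str, Tuple[int, int, int]] = {}
    for codon in sorted(code.codon_to_aa):
        aa = code.codon_to_aa[codon]
        classes = []
        for pos in range(3):
            syn = 0
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if code.codon_to_aa[alt] == aa:
                    syn += 1
            classes.append({0: 0, 3: 4}.get(syn, 2))
        table[codon] = tuple(classes)
    return table


def site_degeneracy(codon: str, position: int, code: GeneticCode) -> int:
    """Degeneracy class (0, 2 or 4) of one position of a sense codon."""
    if not set(codon) <= DNA:
        raise ValueError(f"ambiguous codon {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no degeneracy class")
    return _degeneracy_table(code.table_id)[codon][position]


@lru_cache(maxsize=None)
def _codon_class_counts(table_id: int) -> Dict[str, np.ndarray]:
    """Per-codon counts of (0-fold, 2-fold, 4-fold) sites."""
    out: Dict[str, np.ndarray] = {}
    for codon, classes in _degeneracy_table(table_id).items():
        counts = np.zeros(3)
        for cls in classes:
            counts[_CLASS_INDEX[cls]] += 1.0
        out[codon] = counts
    return out


@lru_cache(maxsize=None)
def _pair_path_counts(c1: str, c2: str, table_id: int) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Fractional transition/transversion counts per degeneracy class for a
    codon pair, averaged over equally weighted single-step mutational
    pathways and over the two traversal directions (each step classifies at
    the degeneracy class of its source codon, which is direction-dependent;
    averaging keeps the counts symmetric in sequence order). Pathways
    passing through a stop codon are discarded unless all are blocked, in
    which case all are reinstated.
    """
    if c1 > c2:
        return _pair_path_counts(c2, c1, table_id)
    ts_f, tv_f = _directed_path_counts(c1, c2, table_id)
    ts_r, tv_r = _directed_path_counts(c2, c1, table_id)
    ts = tuple((a + b) / 2.0 for a, b in zip(ts_f, ts_r))
    tv = tuple((a + b) / 2.0 for a, b in zip(tv_f, tv_r))
    return ts, tv


def _directed_path_counts(c1: str, c2: str, table_id: int) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    code = genetic_code(table_id)
    deg = _degeneracy_table(table_id)
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    paths: List[Tuple[List[Tuple[int, bool]], bool]] = []
    for perm in permutations(diffs):
        cur = list(c1)
        steps: List[Tuple[int, bool]] = []
        blocked = False
        for p in perm:
            src = "".join(cur)
            cls = deg[src][p]
            is_ts = (cur[p], c2[p]) in _TRANSITIONS
            steps.append((cls, is_ts))
            cur[p] = c2[p]
            if code.is_stop("".join(cur)) and "".join(cur) != c2:
                blocked = True
        paths.append((steps, blocked))
    allowed = [steps for steps, blocked in paths if not blocked]
    if not allowed:
        allowed = [steps for steps, _ in paths]
    ts = np.zeros(3)
    tv = np.zeros(3)
    weight = 1.0 / len(allowed)
    for steps in allowed:
        for cls, is_ts in steps:
            (ts if is_ts else tv)[_CLASS_INDEX[cls]] += weight
    return tuple(ts), tuple(tv)


@dataclass
class SiteClassCounts:
    """Li-style per-class site counts and difference proportions for a pair.

    L = (L0, L2, L4) site counts averaged over the two sequences;
    P/Q = per-class transition/transversion difference proportions.
    """

    L: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    @property
    def L0(self) -> float: return float(self.L[0])
    @property
    def L2(self) -> float: return float(self.L[1])
    @property
    def L4(self) -> float: return float(self.L[2])


def pairwise_pbl_counts(
    row_i: str, row_j: str, code: Optional[GeneticCode] = None
) -> SiteClassCounts:
    """Class-specific site counts and difference proportions for one pair."""
    code = code or genetic_code(2)
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    if len(row_i) % 3:
        raise ValueError("row length not divisible by 3")
    class_counts = _codon_class_counts(code.table_id)
    L = np.zeros(3)
    ts = np.zeros(3)
    tv = np.zeros(3)
    for k in range(0, len(row_i), 3):
        c1, c2 = row_i[k : k + 3], row_j[k : k + 3]
        if not (set(c1) <= DNA and set(c2) <= DNA):
            raise ValueError("alignment must be complete-deletion cleaned")
        if code.is_stop(c1) or code.is_stop(c2):
            raise ValueError(f"stop codon in pair at column {k}")
        L += (class_counts[c1] + class_counts[c2]) / 2.0
        if c1 != c2:
            t, v = _pair_path_counts(c1, c2, code.table_id)
            ts += t
            tv += v
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, ts / L, 0.0)
        Q = np.where(L > 0, tv / L, 0.0)
    return SiteClassCounts(L=L, P=P, Q=Q)


# ---------------------------------------------------------------------------
# Kimura two-parameter components and PBL distances
# ---------------------------------------------------------------------------

@dataclass
class K2PComponents:
    a: float
    b: float
    defined: bool


def k2p_components(p: float, q: float) -> K2PComponents:
    """Kimura-corrected transitional (A) and transversional (B) distances.

    A = 1/2 ln(1/(1-2P-Q)) - 1/4 ln(1/(1-2Q)); B = 1/2 ln(1/(1-2Q)).
    Saturation (a log argument <= 0) yields defined=False, never an exception.
    """
    wa = 1.0 - 2.0 * p - q
    wb = 1.0 - 2.0 * q
    if wa <= 0.0 or wb <= 0.0:
        return K2PComponents(a=float("nan"), b=float("nan"), defined=False)
    a = 0.5 * np.log(1.0 / wa) - 0.25 * np.log(1.0 / wb)
    b = 0.5 * np.log(1.0 / wb)
    return K2PComponents(a=float(a), b=float(b), defined=True)


@dataclass
class PairDistance:
    dn: float
    ds: float
    defined: bool
    reason: str = ""


def pbl_pair_distance(counts: SiteClassCounts) -> PairDistance:
    """Pamilo-Bianchi-Li per-pair distances.

    dN = A0 + (L0 B0 + L2 B2) / (L0 + L2);
    dS = (L2 A2 + L4 A4) / (L2 + L4) + B4.
    """
    L0, L2, L4 = counts.L
    if L0 + L2 <= 0:
        return PairDistance(float("nan"), float("nan"), False, "L0+L2=0")
    if L2 + L4 <= 0:
        return PairDistance(float("nan"), float("nan"), False, "L2+L4=0")
    comps = [k2p_components(counts.P[i], counts.Q[i]) for i in range(3)]
    if not all(c.defined for c in comps):
        return PairDistance(float("nan"), float("nan"), False, "saturated")
    a = [c.a for c in comps]
    b = [c.b for c in comps]
    dn = a[0] + (L0 * b[0] + L2 * b[1]) / (L0 + L2)
    ds = (L2 * a[1] + L4 * a[2]) / (L2 + L4) + b[2]
    return PairDistance(dn=float(dn), ds=float(ds), defined=True)


# ---------------------------------------------------------------------------
# Population-level dN/dS with bootstrap
# ---------------------------------------------------------------------------

@dataclass
class DnDsEstimate:
    dn: float
    ds: float
    ratio: Optional[float]
    se_ratio: float
    n_pairs: int
    undefined_pairs: int
    reps: int
    seed: int
    dropped_replicates: int = 0


def _per_column_contributions(
    aln: SupergeneAlignment, code: GeneticCode
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair, per-codon-column L/ts/tv contributions (npairs, ncod, 3)."""
    record_ids = sorted(aln.rows)
    rows = [aln.rows[r] for r in record_ids]
    ncod = aln.n_codons
    pairs = list(combinations(range(len(rows)), 2))
    class_counts = _codon_class_counts(code.table_id)
    L = np.zeros((len(pairs), ncod, 3))
    TS = np.zeros((len(pairs), ncod, 3))
    TV = np.zeros((len(pairs), ncod, 3))
    for p, (i, j) in enumerate(pairs):
        ri, rj = rows[i], rows[j]
        for c in range(ncod):
            c1, c2 = ri[3 * c : 3 * c + 3], rj[3 * c : 3 * c + 3]
            if not (set(c1) <= DNA and set(c2) <= DNA):
                raise ValueError("alignment must be complete-deletion cleaned")
            L[p, c] = (class_counts[c1] + class_counts[c2]) / 2.0
            if c1 != c2:
                t, v = _pair_path_counts(c1, c2, code.table_id)
                TS[p, c] = t
                TV[p, c] = v
    return L, TS, TV


def _dnds_from_sums(
    L: np.ndarray, TS: np.ndarray, TV: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized PBL distances from per-pair class sums (npairs, 3)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, TS / L, 0.0)
        Q = np.where(L > 0, TV / L, 0.0)
        wa = 1.0 - 2.0 * P - Q
        wb = 1.0 - 2.0 * Q
        ok = (wa > 0).all(axis=1) & (wb > 0).all(axis=1)
        wa = np.where(wa > 0, wa, 1.0)
        wb = np.where(wb > 0, wb, 1.0)
        A = 0.5 * np.log(1.0 / wa) - 0.25 * np.log(1.0 / wb)
        B = 0.5 * np.log(1.0 / wb)
        denom_n = L[:, 0] + L[:, 1]
        denom_s = L[:, 1] + L[:, 2]
        ok &= (denom_n > 0) & (denom_s > 0)
        denom_n = np.where(denom_n > 0, denom_n, 1.0)
        denom_s = np.where(denom_s > 0, denom_s, 1.0)
        dn = A[:, 0] + (L[:, 0] * B[:, 0] + L[:, 1] * B[:, 1]) / denom_n
        ds = (L[:, 1] * A[:, 1] + L[:, 2] * A[:, 2]) / denom_s + B[:, 2]
    return dn, ds, ok


def population_dnds(
    aln: SupergeneAlignment,
    seed: int = 17,
    reps: int = 1000,
    code: Optional[GeneticCode] = None,
) -> DnDsEstimate:
    """Mean pairwise dN, dS and their ratio (ratio of means) with bootstrap SE.

    The bootstrap resamples codon columns with replacement; replicates whose
    mean dS is zero (or with no defined pairs) are dropped from the SE with
    a count reported.
    """
    code = code or genetic_code(2)
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 sequences")
    L, TS, TV = _per_column_contributions(aln, code)
    npairs, ncod, _ = L.shape

    def point(weights: Optional[np.ndarray]) -> Tuple[float, float, Optional[float], int]:
        if weights is None:
            ls, tss, tvs = L.sum(axis=1), TS.sum(axis=1), TV.sum(axis=1)
        else:
            ls = np.einsum("pck,c->pk", L, weights)
            tss = np.einsum("pck,c->pk", TS, weights)
            tvs = np.einsum("pck,c->pk", TV, weights)
        dn, ds, ok = _dnds_from_sums(ls, tss, tvs)
        n_ok = int(ok.sum())
        if n_ok == 0:
            return float("nan"), float("nan"), None, 0
        dn_mean = float(dn[ok].mean())
        ds_mean = float(ds[ok].mean())
        ratio = dn_mean / ds_mean if ds_mean > 0 else None
        return dn_mean, ds_mean, ratio, n_ok

    dn_mean, ds_mean, ratio, n_ok = point(None)
    if n_ok == 0:
        raise ValueError("all sequence pairs are saturated/undefined")

    rng = np.random.default_rng(seed)
    if reps < 2:
        raise ValueError("reps must be >= 2")
    ratios: List[float] = []
    dropped = 0
    for _ in range(reps):
        idx = rng.integers(0, ncod, size=ncod)
        weights = np.bincount(idx, minlength=ncod).astype(float)
        _, _, r, k = point(weights)
        if r is None or k == 0:
            dropped += 1
        else:
            ratios.append(r)
    se = float(np.std(ratios, ddof=1)) if len(ratios) >= 2 else float("nan")
    return DnDsEstimate(
        dn=dn_mean,
        ds=ds_mean,
        ratio=ratio,
        se_ratio=se,
        n_pairs=npairs,
        undefined_pairs=npairs - n_ok,
        reps=reps,
        seed=seed,
        dropped_replicates=dropped,
    )


def bootstrap_se(
    aln: SupergeneAlignment,
    estimator: Callable[[SupergeneAlignment], Optional[float]],
    reps: int = 1000,
    seed: int = 17,
) -> float:
    """Generic codon-column bootstrap SE of any alignment functional.

    Resampling unit is the codon column (codon-structure-safe for both the
    diversity and the dN/dS functionals); SE is the sample standard
    deviation across replicate estimates, skipping undefined replicates.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    record_ids = sorted(aln.rows)
    ncod = aln.n_codons
    codons = {
        rid: [aln.rows[rid][3 * c : 3 * c + 3] for c in range(ncod)]
        for rid in record_ids
    }
    rng = np.random.default_rng(seed)
    values: List[float] = []
    for _ in range(reps):
        idx = rng.integers(0, ncod, size=ncod)
        rows = {
            rid: "".join(codons[rid][i] for i in idx) for rid in record_ids
        }
        rep = SupergeneAlignment.from_rows(rows, species=aln.species)
        value = estimator(rep)
        if value is not None and np.isfinite(value):
            values.append(float(value))
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# Per-population driver
# ---------------------------------------------------------------------------

def population_stats_table(
    supergene: SupergeneAlignment,
    assignment: Mapping[str, str],
    reps: int = 1000,
    seed: int = 17,
    code: Optional[GeneticCode] = None,
) -> "pd.DataFrame":
    """Per-population pi and dN/dS over a species supergene.

    ``assignment`` maps record_id -> population label; records labelled as
    excluded (any label containing 'EXCLUDED') are skipped. Complete deletion
    is applied per population after subsetting.
    """
    import pandas as pd

    pops: Dict[str, List[str]] = {}
    for rid, label in assignment.items():
        if rid not in supergene.rows:
            raise ValueError(f"assignment references unknown record {rid}")
        if "EXCLUDED" in label.upper():
            continue
        pops.setdefault(label, []).append(rid)
    rows = []
    for label in sorted(pops):
        members = sorted(pops[label])
        if len(members) < 2:
            logger.warning(
                "population %s of %s has <2 members; skipped",
                label,
                supergene.species,
            )
            continue
        sub = SupergeneAlignment(
            species=supergene.species,
            rows={r: supergene.rows[r] for r in members},
            boundaries=dict(supergene.boundaries),
        )
        clean = complete_deletion(sub)
        div = nei_li_pi(clean, reps=reps, seed=seed)
        dnds = population_dnds(clean, seed=seed, reps=reps, code=code)
        rows.append(
            {
                "species": supergene.species,
                "population": label,
                "n": len(members),
                "sites_used": div.n_sites_used,
                "pi": div.pi,
                "pi_se": div.se,
                "dN": dnds.dn,
                "dS": dnds.ds,
                "dnds": dnds.ratio if dnds.ratio is not None else float("nan"),
                "dnds_se": dnds.se_ratio,
                "undefined_pairs": dnds.undefined_pairs,
                "bootstrap_reps": reps,
                "seed": seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "population", "n", "sites_used", "pi", "pi_se",
            "dN", "dS", "dnds", "dnds_se", "undefined_pairs",
            "bootstrap_reps", "seed",
        ],
    )
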