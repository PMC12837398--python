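"""Independent slow reference implementations used only by the tests.

These deliberately avoid the package's own data tables and code paths:
translation goes through Biopython, degeneracy and pathway counting are
re-derived from first principles with plain Python.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, permutations
from typing import Dict, List, Tuple

from Bio.Seq import Seq

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@lru_cache(maxsize=None)
def aa_of(codon: str) -> str:
    return str(Seq(codon).translate(table=2))


@lru_cache(maxsize=None)
def degeneracy_of(codon: str, pos: int) -> int:
    """0/2/4-fold classification by counting synonymous point alternatives.

    Stop-producing alternatives are nonsynonymous; for a stop codon source,
    stop-to-stop counts as synonymous (needed on reinstated blocked paths).
    """
    target = aa_of(codon)
    syn = 0
    for nt in "ACGT":
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if aa_of(alt) == target:
            syn += 1
    if syn == 0:
        return 0
    if syn == 3:
        return 4
    return 2


def codon_site_counts(codon: str) -> Tuple[float, float, float]:
    counts = [0.0, 0.0, 0.0]
    slot = {0: 0, 2: 1, 4: 2}
    for pos in range(3):
        counts[slot[degeneracy_of(codon, pos)]] += 1.0
    return tuple(counts)


def pathway_counts(c1: str, c2: str) -> Tuple[List[float], List[float]]:
    """Symmetrized per-class transition/transversion counts: the average of
    the two traversal directions of :func:`directed_pathway_counts`."""
    ts_f, tv_f = directed_pathway_counts(c1, c2)
    ts_r, tv_r = directed_pathway_counts(c2, c1)
    ts = [(a + b) / 2.0 for a, b in zip(ts_f, ts_r)]
    tv = [(a + b) / 2.0 for a, b in zip(tv_f, tv_r)]
    return ts, tv


def directed_pathway_counts(c1: str, c2: str) -> Tuple[List[float], List[float]]:
    """Per-class fractional transition/transversion counts over equally
    weighted mutational pathways, skipping stop-passing orderings (all
    reinstated when every ordering is blocked)."""
    slot = {0: 0, 2: 1, 4: 2}
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    all_paths = []
    for perm in permutations(diffs):
        cur = list(c1)
        steps = []
        blocked = False
        for p in perm:
            src = "".join(cur)
            cls = degeneracy_of(src, p)
            is_ts = (cur[p], c2[p]) in TRANSITIONS
            steps.append((cls, is_ts))
            cur[p] = c2[p]
            if aa_of("".join(cur)) == "*" and "".join(cur) != c2:
                blocked = True
        all_paths.append((steps, blocked))
    usable = [s for s, b in all_paths if not b]
    if not usable:
        usable = [s for s, _ in all_paths]
    ts = [0.0, 0.0, 0.0]
    tv = [0.0, 0.0, 0.0]
    w = 1.0 / len(usable)
    for steps in usable:
        for cls, is_ts in steps:
            (ts if is_ts else tv)[slot[cls]] += w
    return ts, tv


def pair_class_stats(row1: str, row2: str):
    """Full per-pair (L, P, Q) reference for codon-aligned rows."""
    L = [0.0, 0.0, 0.0]
    ts = [0.0, 0.0, 0.0]
    tv = [0.0, 0.0, 0.0]
    for k in range(0, len(row1), 3):
        c1, c2 = row1[k : k + 3], row2[k : k + 3]
        for s, v in zip((0, 1, 2), codon_site_counts(c1)):
            L[s] += v / 2.0
        for s, v in zip((0, 1, 2), codon_site_counts(c2)):
            L[s] += v / 2.0
        if c1 != c2:
            t, v = pathway_counts(c1, c2)
            for s in range(3):
                ts[s] += t[s]
                tv[s] += v[s]
    P = [ts[s] / L[s] if L[s] > 0 else 0.0 for s in range(3)]
    Q = [tv[s] / L[s] if L[s] > 0 else 0.0 for s in range(3)]
    return L, P, Q


def naive_pi(rows: Dict[str, str]) -> float:
    """All-pairs double-loop mean p-distance."""
    ids = sorted(rows)
    total = 0.0
    pairs = 0
    for a, b in combinations(ids, 2):
        sa, sb = rows[a], rows[b]
        mism = sum(1 for x, y in zip(sa, sb) if x != y)
        total += mism / len(sa)
        pairs += 1
    return total / pairs


def naive_ibs_distance(genotypes, missing=-1):
    """Brute-force pairwise mismatch proportion over shared sites."""
    n, m = genotypes.shape
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = mism = 0
            for s in range(m):
                a, b = genotypes[i, s], genotypes[j, s]
                if a == missing or b == missing:
                    continue
                shared += 1
                mism += a != b
            out[i][j] = mism / shared if shared else float("nan")
    return out
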