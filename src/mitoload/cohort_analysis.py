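"""Cohort-level summaries: fold-differences, diversity bins, diversity-load
correlation with a log fit, and IUCN risk-group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "species", "family", "population", "n",
    "pi", "pi_se", "dnds", "dnds_se", "iucn_status",
]

#: IUCN Red List category -> extinction-risk group. Data Deficient,
#: Not Evaluated and (absent from the study) EW/EX are excluded.
RISK_GROUPS: Dict[str, str] = {
    "LC": "low",
    "NT": "medium",
    "VU": "medium",
    "EN": "high",
    "CR": "high",
}
VALID_IUCN = {"NE", "DD", "LC", "NT", "VU", "EN", "CR", "EW", "EX"}


def build_cohort(
    stats: pd.DataFrame,
    taxonomy: Optional[Mapping[str, str]] = None,
    iucn: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Join the per-population stats table with taxonomy and IUCN status."""
    taxonomy = taxonomy or {}
    iucn = iucn or {}
    rows = []
    for _, row in stats.iterrows():
        species = row["species"]
        rows.append(
            {
                "species": species,
                "family": taxonomy.get(species, "Unknown"),
                "population": row["population"],
                "n": int(row["n"]),
                "pi": float(row["pi"]),
                "pi_se": float(row["pi_se"]),
                "dnds": float(row["dnds"]),
                "dnds_se": float(row["dnds_se"]),
                "iucn_status": iucn.get(species, ""),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# Fold differences
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold_all: float
    fold_all_1dp: float
    fold_all_int: int
    argmax: str
    argmin: str
    fold_excluded: Optional[float] = None
    fold_excluded_1dp: Optional[float] = None
    fold_excluded_int: Optional[int] = None
    argmax_excluded: Optional[str] = None
    argmin_excluded: Optional[str] = None


def fold_difference(
    values: Union[Mapping[str, float], Sequence[float]],
    exclusions: Iterable[str] = (),
) -> FoldResult:
    """max/min fold-difference, with and without named exclusions.

    Reported both to one decimal and as the nearest integer; every value
    must be strictly positive.
    """
    if not isinstance(values, Mapping):
        values = {str(i): v for i, v in enumerate(values)}
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if any(v <= 0 for v in values.values()):
        raise ValueError("fold differences require strictly positive values")
    exclusions = set(exclusions)
    unknown = exclusions - set(values)
    if unknown:
        raise ValueError(f"exclusions name unknown labels: {sorted(unknown)}")

    def summarize(vals: Mapping[str, float]) -> Tuple[float, str, str]:
        hi = max(sorted(vals), key=lambda k: vals[k])
        lo = min(sorted(vals), key=lambda k: vals[k])
        return vals[hi] / vals[lo], hi, lo

    fold, hi, lo = summarize(values)
    result = FoldResult(
        fold_all=fold,
        fold_all_1dp=round(fold, 1),
        fold_all_int=int(round(fold)),
        argmax=hi,
        argmin=lo,
    )
    if exclusions:
        remaining = {k: v for k, v in values.items() if k not in exclusions}
        if len(remaining) < 2:
            raise ValueError("fewer than 2 values remain after exclusions")
        fold_x, hi_x, lo_x = summarize(remaining)
        result.fold_excluded = fold_x
        result.fold_excluded_1dp = round(fold_x, 1)
        result.fold_excluded_int = int(round(fold_x))
        result.argmax_excluded = hi_x
        result.argmin_excluded = lo_x
    return result


# ---------------------------------------------------------------------------
# Diversity bins
# ---------------------------------------------------------------------------

def bin_by_diversity(
    table: pd.DataFrame, low_cut: float = 0.001, high_cut: float = 0.002
) -> pd.DataFrame:
    """Mean dN/dS per diversity bin: low (<low_cut), medium (closed interval
    [low_cut, high_cut]), high (>high_cut). SE is the standard error of the
    mean across populations; singleton bins report SE 0 with an n=1 flag.
    """
    if table.empty:
        raise ValueError("empty cohort table")

    def bin_of(pi: float) -> str:
        if pi < low_cut:
            return "low"
        if pi > high_cut:
            return "high"
        return "medium"

    rows = []
    assigned = table.assign(bin=table["pi"].map(bin_of))
    for name in ("low", "medium", "high"):
        group = assigned[assigned["bin"] == name]["dnds"].dropna()
        n = len(group)
        if n == 0:
            logger.warning("diversity bin %s is empty", name)
            mean = se = float("nan")
        else:
            mean = float(group.mean())
            se = float(group.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"bin": name, "n": n, "mean_dnds": mean, "se_dnds": se})
    return pd.DataFrame(rows, columns=["bin", "n", "mean_dnds", "se_dnds"])


# ---------------------------------------------------------------------------
# Correlation with log fit
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    n: int
    log_a: float  # y = a + b ln(x)
    log_b: float
    log_r2: float
    degenerate: bool = False


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson and Spearman correlation plus least-squares fit of
    y = a + b ln(x). Two-sided p-values use the t approximation with n-2 df.
    Rows with non-positive x are excluded from the log fit with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return CorrelationResult(
            pearson_r=float("nan"), pearson_p=float("nan"),
            spearman_r=float("nan"), spearman_p=float("nan"),
            n=n, log_a=float("nan"), log_b=float("nan"),
            log_r2=float("nan"), degenerate=True,
        )
    pearson = sps.pearsonr(x, y)
    spearman = sps.spearmanr(x, y)
    positive = x > 0
    if not positive.all():
        logger.warning("%d non-positive x values excluded from log fit",
                       int((~positive).sum()))
    lx, ly = np.log(x[positive]), y[positive]
    b, a = np.polyfit(lx, ly, 1)
    pred = a + b * lx
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CorrelationResult(
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman_r=float(spearman.statistic),
        spearman_p=float(spearman.pvalue),
        n=n,
        log_a=float(a),
        log_b=float(b),
        log_r2=r2,
    )


# ---------------------------------------------------------------------------
# IUCN risk groups
# ---------------------------------------------------------------------------

@dataclass
class RiskGroupSummary:
    group: str
    species: List[str]
    populations: List[str]
    n_populations: int
    mean_pi: float
    se_pi: float
    mean_dnds: float
    se_dnds: float


def group_by_risk(
    table: pd.DataFrame, status_map: Mapping[str, str]
) -> List[RiskGroupSummary]:
    """Population-weighted mean pi and dN/dS per extinction-risk group.

    LC -> low; NT, VU -> medium; EN, CR -> high. DD/NE (and EW/EX) species
    are excluded, as are species absent from the status map (warned).
    """
    for code in status_map.values():
        if code not in VALID_IUCN:
            raise ValueError(f"unknown IUCN code {code!r}")
    buckets: Dict[str, List[pd.Series]] = {"low": [], "medium": [], "high": []}
    for _, row in table.iterrows():
        species = row["species"]
        code = status_map.get(species)
        if code is None:
            logger.warning("species %s absent from status map; excluded", species)
            continue
        group = RISK_GROUPS.get(code)
        if group is None:
            logger.warning("species %s status %s excluded from risk groups",
                           species, code)
            continue
        buckets[group].append(row)
    out: List[RiskGroupSummary] = []
    for group in ("low", "medium", "high"):
        members = buckets[group]
        pis = np.array([m["pi"] for m in members], dtype=float)
        ratios = np.array([m["dnds"] for m in members], dtype=float)
        n = len(members)

        def mean_se(values: np.ndarray) -> Tuple[float, float]:
            if len(values) == 0:
                return float("nan"), float("nan")
            if len(values) == 1:
                return float(values[0]), 0.0
            return float(values.mean()), float(values.std(ddof=1) / np.sqrt(len(values)))

        mean_pi, se_pi = mean_se(pis)
        mean_dnds, se_dnds = mean_se(ratios)
        out.append(
            RiskGroupSummary(
                group=group,
                species=sorted({m["species"] for m in members}),
                populations=[f"{m['species']}|{m['population']}" for m in members],
                n_populations=n,
                mean_pi=mean_pi,
                se_pi=se_pi,
                mean_dnds=mean_dnds,
                se_dnds=se_dnds,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def load_iucn_table(path: Path) -> Dict[str, str]:
    """Read a species<TAB>IUCN-code table."""
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or parts[0].lower() == "species":
            continue
        out[parts[0]] = parts[1]
    return out


def render_report(
    table: pd.DataFrame,
    out_dir: Path,
    status_map: Optional[Mapping[str, str]] = None,
    exclude_outliers: Iterable[str] = (),
    plots: bool = False,
) -> Dict[str, Path]:
    """Write cohort.tsv, folds.tsv, risk_groups.tsv, correlation.tsv,
    diversity_bins.tsv (and optional PNG plots) for a cohort table.

    Outlier exclusion is explicit by population label ('species|population'),
    never automatic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    warnings = 0

    paths["cohort"] = out_dir / "cohort.tsv"
    table.to_csv(paths["cohort"], sep="\t", index=False)

    labels = {
        f"{r['species']}|{r['population']}": r for _, r in table.iterrows()
    }
    fold_rows = []
    exclude_outliers = [e for e in exclude_outliers if e in labels]
    for metric in ("pi", "dnds"):
        vals = {
            k: float(r[metric]) for k, r in labels.items()
            if np.isfinite(r[metric]) and r[metric] > 0
        }
        if len(vals) >= 2:
            fold = fold_difference(vals, exclusions=[
                e for e in exclude_outliers if e in vals
            ])
            fold_rows.append({
                "metric": metric,
                "fold_all": fold.fold_all,
                "fold_all_1dp": fold.fold_all_1dp,
                "fold_all_int": fold.fold_all_int,
                "argmax": fold.argmax,
                "argmin": fold.argmin,
                "fold_excluded_1dp": fold.fold_excluded_1dp,
                "fold_excluded_int": fold.fold_excluded_int,
            })
        else:
            warnings += 1
    paths["folds"] = out_dir / "folds.tsv"
    pd.DataFrame(fold_rows).to_csv(paths["folds"], sep="\t", index=False)

    usable = table[(table["pi"] > 0) & np.isfinite(table["dnds"])]
    paths["correlation"] = out_dir / "correlation.tsv"
    if len(usable) >= 3:
        corr = correlate(usable["pi"].to_numpy(), usable["dnds"].to_numpy())
        pd.DataFrame([vars(corr)]).to_csv(paths["correlation"], sep="\t", index=False)
    else:
        warnings += 1
        pd.DataFrame(
            columns=[f.name for f in CorrelationResult.__dataclass_fields__.values()]
        ).to_csv(paths["correlation"], sep="\t", index=False)

    paths["diversity_bins"] = out_dir / "diversity_bins.tsv"
    if not table.empty:
        bin_by_diversity(table).to_csv(paths["diversity_bins"], sep="\t", index=False)
    else:
        warnings += 1
        pd.DataFrame(columns=["bin", "n", "mean_dnds", "se_dnds"]).to_csv(
            paths["diversity_bins"], sep="\t", index=False
        )

    paths["risk_groups"] = out_dir / "risk_groups.tsv"
    if status_map:
        groups = group_by_risk(table, status_map)
        pd.DataFrame([
            {
                "group": g.group,
                "n_populations": g.n_populations,
                "n_species": len(g.species),
                "mean_pi": g.mean_pi,
                "se_pi": g.se_pi,
                "mean_dnds": g.mean_dnds,
                "se_dnds": g.se_dnds,
            }
            for g in groups
        ]).to_csv(paths["risk_groups"], sep="\t", index=False)
    else:
        pd.DataFrame(
            columns=["group", "n_populations", "n_species",
                     "mean_pi", "se_pi", "mean_dnds", "se_dnds"]
        ).to_csv(paths["risk_groups"], sep="\t", index=False)

    if plots and not table.empty:
        _render_plots(table, usable, out_dir, status_map)
    if warnings:
        logger.warning("report rendered with %d empty sections", warnings)
    return paths


def _render_plots(table, usable, out_dir: Path, status_map) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{r['species']}|{r['population']}" for _, r in table.iterrows()]
    for metric, err in (("pi", "pi_se"), ("dnds", "dnds_se")):
        fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(table)), 4))
        ax.bar(range(len(table)), table[metric], yerr=table[err], color="steelblue")
        ax.set_xticks(range(len(table)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(out_dir / f"{metric}_bars.png", dpi=120)
        plt.close(fig)
    if len(usable) >= 3:
        corr = correlate(usable["pi"].to_numpy(), usable["dnds"].to_numpy())
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(usable["pi"], usable["dnds"], s=12)
        grid = np.linspace(usable["pi"].min(), usable["pi"].max(), 200)
        ax.plot(grid, corr.log_a + corr.log_b * np.log(grid), color="firebrick")
        ax.set_xlabel("nucleotide diversity")
        ax.set_ylabel("dN/dS")
        fig.tight_layout()
        fig.savefig(out_dir / "diversity_vs_dnds.png", dpi=120)
        plt.close(fig)
    if status_map:
        groups = group_by_risk(table, status_map)
        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        names = [g.group for g in groups]
        axes[0].bar(names, [g.mean_pi for g in groups],
                    yerr=[g.se_pi for g in groups], color="seagreen")
        axes[0].set_ylabel("mean diversity")
        axes[1].bar(names, [g.mean_dnds for g in groups],
                    yerr=[g.se_dnds for g in groups], color="indianred")
        axes[1].set_ylabel("mean dN/dS")
        fig.tight_layout()
        fig.savefig(out_dir / "risk_groups.png", dpi=120)
        plt.close(fig)
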