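"""Repeated-run evaluation protocol and benchmark statistics.

Optimizer comparisons follow the standard metaheuristic benchmarking
protocol: every algorithm is run ``n_runs`` times (30 by default), run *i*
seeded with ``base_seed + i`` so runs are independent and reproducible;
each run's best objective value feeds per-algorithm summary rows
(best / worst / mean / median / std / var, population convention) and the
non-parametric test battery — Levene for homoscedasticity, Shapiro-Wilk
per group for normality, and paired Wilcoxon signed-rank tests of a
reference algorithm against every other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RunSummary",
    "StatTestReport",
    "run_repeated",
    "summarize_runs",
    "statistical_tests",
    "export_artifacts",
]


@dataclass
class RunSummary:
    """Six-number summary of one algorithm's repeated-run results."""

    best: float
    worst: float
    mean: float
    median: float
    std: float
    var: float

    def as_row(self) -> dict:
        return {
            "best": self.best, "worst": self.worst, "mean": self.mean,
            "median": self.median, "std": self.std, "var": self.var,
        }


@dataclass
class StatTestReport:
    levene_p: float
    shapiro_p: dict[str, float]
    wilcoxon_p: dict[str, float]
    degenerate_pairs: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "levene_p": self.levene_p,
            "shapiro_p": self.shapiro_p,
            "wilcoxon_p": self.wilcoxon_p,
            "degenerate_pairs": self.degenerate_pairs,
            "alpha": self.alpha,
        }


def run_repeated(
    algorithms: Mapping[str, Callable[[int], float]],
    n_runs: int,
    base_seed: int,
) -> pd.DataFrame:
    """Execute every algorithm ``n_runs`` times with seeds base_seed + i.

    ``algorithms`` maps a name to a callable taking the run seed and
    returning the run's objective value.  Returns a tidy DataFrame with
    columns (algorithm, run, seed, value) — full provenance for every cell.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for name, fn in algorithms.items():
        for i in range(n_runs):
            seed = base_seed + i
            rows.append(
                {"algorithm": name, "run": i, "seed": seed,
                 "value": float(fn(seed))}
            )
    return pd.DataFrame(rows)


def summarize_runs(values: Sequence[float], ddof: int = 0) -> RunSummary:
    """Best/worst/mean/median/std/var of one result vector (maximization
    convention; std/var are population statistics unless ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty results vector")
    std = float(v.std(ddof=ddof))
    return RunSummary(
        best=float(v.max()),
        worst=float(v.min()),
        mean=float(v.mean()),
        median=float(np.median(v)),
        std=std,
        var=std ** 2,
    )


def summary_table(results: pd.DataFrame, maximize: bool = True,
                  ddof: int = 0) -> pd.DataFrame:
    """One summary row per algorithm (Best/Worst/Mean/Median/Std/Var)."""
    rows = {}
    for name, grp in results.groupby("algorithm", sort=False):
        s = summarize_runs(grp["value"].to_numpy(), ddof=ddof)
        row = s.as_row()
        if not maximize:  # for error-rate style indicators, best = smallest
            row["best"], row["worst"] = row["worst"], row["best"]
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def statistical_tests(
    results: pd.DataFrame,
    reference: str,
    alpha: float = 0.05,
) -> StatTestReport:
    """Levene across groups, Shapiro-Wilk per group, paired Wilcoxon of the
    reference algorithm against every other.

    Runs are paired by seed.  A pair whose differences are all zero is
    degenerate for the signed-rank statistic and is reported with p = 1 and
    flagged.  scipy's sample-size convention decides exact vs normal
    approximation for the Wilcoxon statistic.
    """
    groups = {
        name: grp.sort_values("run")["value"].to_numpy()
        for name, grp in results.groupby("algorithm", sort=False)
    }
    if reference not in groups:
        raise ValueError(f"reference algorithm {reference!r} not in results")
    if len(groups) < 2:
        raise ValueError("need at least two algorithms")
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1 or min(sizes) < 5:
        raise ValueError("need equal group sizes of at least 5 runs")

    levene_p = float(stats.levene(*groups.values()).pvalue)
    shapiro_p = {
        name: float(stats.shapiro(v).pvalue) for name, v in groups.items()
    }
    ref = groups[reference]
    wilcoxon_p: dict[str, float] = {}
    degenerate: list[str] = []
    for name, v in groups.items():
        if name == reference:
            continue
        diff = ref - v
        if np.all(diff == 0):
            wilcoxon_p[name] = 1.0
            degenerate.append(name)
        else:
            wilcoxon_p[name] = float(stats.wilcoxon(ref, v).pvalue)
    return StatTestReport(levene_p, shapiro_p, wilcoxon_p, degenerate, alpha)


def export_artifacts(
    results: pd.DataFrame,
    out_dir,
    histories: Optional[Mapping[str, Sequence[Sequence[float]]]] = None,
    reference: Optional[str] = None,
    maximize: bool = True,
) -> dict[str, Path]:
    """Write results.csv, summary.csv, optional convergence.csv / stats.json.

    ``histories`` maps algorithm -> per-run best-fitness trajectories;
    convergence.csv holds one row per (algorithm, run, iteration).  Files are
    rewritten identically on rerun with the same inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["results"] = out / "results.csv"
    results.to_csv(paths["results"], index=False)
    paths["summary"] = out / "summary.csv"
    summary_table(results, maximize=maximize).to_csv(paths["summary"])
    if histories is not None:
        rows = []
        for name, runs in histories.items():
            for run, hist in enumerate(runs):
                for it, value in enumerate(hist, start=1):
                    rows.append(
                        {"algorithm": name, "run": run, "iteration": it,
                         "best_fitness": float(value)}
                    )
        paths["convergence"] = out / "convergence.csv"
        pd.DataFrame(rows).to_csv(paths["convergence"], index=False)
    if reference is not None:
        report = statistical_tests(results, reference)
        paths["stats"] = out / "stats.json"
        with open(paths["stats"], "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return paths
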