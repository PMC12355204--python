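"""Benchmark metrics and cost-function diagnostics.

Two complementary questions are answered here. First, *does guidance
help?* — :func:`run_benchmark` runs the constrained search over a set of
(target, sm*) problems under several cost settings and reports the
constrained solve rate at each expansion-budget checkpoint, the mean
number of expansions N̄ (unsolved problems contribute their full budget),
and mean route length over the subset solved by every compared setting.

Second, *why does it help?* — :func:`diagnostics` examines a cost
function's behaviour along ground-truth routes. Walking the path from a
route's root to sm*, each molecule has a known synthetic distance d to
sm*; a useful guidance cost should decrease with d (monotonicity,
measured by Spearman's rho and Kendall's tau-b), vary little among
molecules at the same distance (consistency, mean coefficient of
variation), and separate adjacent distances cleanly (granularity, mean
distribution overlap). Overlap between adjacent distance groups i, j is
the separation ratio (sigma_i + sigma_j) / |mu_i - mu_j| — below 1 the
groups are about a standard deviation apart; it can exceed 1 for badly
blurred costs. A histogram overlap coefficient is available as an
alternative.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PathError
from .expansion_policy import ExpansionPolicy
from .molecules import Molecule
from .search import Route, RouteNode, SearchConfig, search
from .tango_cost import CostWeights, TangoCost

PairwiseCost = Callable[[Molecule, Molecule], float]


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkProblem:
    """One constrained planning instance."""

    name: str
    target: Molecule
    sm: Molecule
    policy: ExpansionPolicy
    building_blocks: frozenset
    #: optional per-problem frontier cost factory: weights -> callable
    cost_factory: Optional[Callable[[CostWeights], Callable[[Molecule], float]]] = None


@dataclass
class PairRecord:
    name: str
    solved: bool
    solve_iteration: Optional[int]
    expansions_used: int
    route_length: Optional[int]
    wall_time_s: float


@dataclass
class BenchmarkReport:
    budgets: List[int]
    records: Dict[str, List[PairRecord]]

    def solve_rate(self, setting: str, budget: int) -> float:
        """Constrained solve rate (%) at an expansion-budget checkpoint."""
        recs = self.records[setting]
        n = len(recs)
        if n == 0:
            return 0.0
        solved = sum(1 for r in recs
                     if r.solved and r.solve_iteration is not None
                     and r.solve_iteration <= budget)
        return 100.0 * solved / n

    def n_bar(self, setting: str, budget: Optional[int] = None) -> float:
        """Mean expansions per target; unsolved problems count the full
        budget (an inefficient method pays for its failures)."""
        b = budget if budget is not None else max(self.budgets)
        vals = []
        for r in self.records[setting]:
            if r.solved and r.solve_iteration is not None and r.solve_iteration <= b:
                vals.append(r.solve_iteration)
            else:
                vals.append(b)
        return float(np.mean(vals))

    def median_expansions(self, setting: str) -> float:
        b = max(self.budgets)
        vals = [r.solve_iteration
                if (r.solved and r.solve_iteration is not None) else b
                for r in self.records[setting]]
        return float(np.median(vals))

    def common_solved(self) -> List[str]:
        """Problems solved by every setting (route-length comparisons are
        restricted to this subset)."""
        sets = [
            {r.name for r in recs if r.solved} for recs in self.records.values()
        ]
        common = set.intersection(*sets) if sets else set()
        return sorted(common)

    def mean_route_length(self, setting: str) -> Optional[float]:
        common = self.common_solved()
        vals = [r.route_length for r in self.records[setting]
                if r.name in common and r.route_length is not None]
        return float(np.mean(vals)) if vals else None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for setting, recs in self.records.items():
            for r in recs:
                rows.append({
                    "setting": setting, "name": r.name, "solved": r.solved,
                    "solve_iteration": r.solve_iteration,
                    "expansions_used": r.expansions_used,
                    "route_length": r.route_length,
                    "wall_time_s": r.wall_time_s,
                })
        return pd.DataFrame(rows)

    def aggregates(self) -> dict:
        out: dict = {"budgets": self.budgets, "settings": {}}
        for setting in self.records:
            out["settings"][setting] = {
                "solve_rate": {str(b): self.solve_rate(setting, b)
                               for b in self.budgets},
                "n_bar": {str(b): self.n_bar(setting, b) for b in self.budgets},
                "median_expansions": self.median_expansions(setting),
                "mean_route_length": self.mean_route_length(setting),
            }
        out["n_common_solved"] = len(self.common_solved())
        return out

    def save(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.aggregates(), fh, indent=2, sort_keys=True)
                fh.write("\n")


def run_benchmark(problems: Sequence[BenchmarkProblem], budgets: Sequence[int],
                  cost_settings: Dict[str, CostWeights], top_n: int = 50,
                  seed: int = 0) -> BenchmarkReport:
    """One search per problem per cost setting at the maximum budget;
    checkpoint metrics are recovered from the iteration at which each
    problem first solved. Per-problem failures are recorded, never raised."""
    budgets = sorted(budgets)
    if not problems:
        raise InsufficientDataError("no benchmark problems given")
    if not budgets:
        raise InsufficientDataError("no budgets given")
    max_budget = budgets[-1]
    records: Dict[str, List[PairRecord]] = {name: [] for name in cost_settings}
    for prob in problems:
        for setting, weights in cost_settings.items():
            t0 = time.perf_counter()
            try:
                config = SearchConfig(
                    expansion_budget=max_budget, top_n=top_n,
                    cost_weights=weights,
                    building_blocks=prob.building_blocks,
                    enforced_sm=prob.sm, seed=seed)
                cost = None
                if prob.cost_factory is not None:
                    cost = prob.cost_factory(weights)
                result = search(prob.target, prob.policy, config, cost=cost)
                rec = PairRecord(
                    name=prob.name, solved=result.solved,
                    solve_iteration=result.solve_iteration,
                    expansions_used=result.expansions_used,
                    route_length=result.route.length
                    if (result.solved and result.route) else None,
                    wall_time_s=time.perf_counter() - t0)
            except Exception:
                rec = PairRecord(name=prob.name, solved=False,
                                 solve_iteration=None,
                                 expansions_used=max_budget, route_length=None,
                                 wall_time_s=time.perf_counter() - t0)
            records[setting].append(rec)
    return BenchmarkReport(budgets=list(budgets), records=records)


# ---------------------------------------------------------------------------
# diagnostics


def route_node_costs(route: Route, sm: Molecule, cost: PairwiseCost
                     ) -> List[Tuple[int, float]]:
    """Walk the unique root -> sm leaf path of a route; for each molecule
    on it emit (synthetic distance to sm in reactions, cost(molecule, sm))."""
    path = _path_to_leaf(route.root, sm)
    if path is None:
        raise PathError(f"{sm.smiles!r} is not a leaf of the route")
    L = len(path) - 1
    return [(L - i, float(cost(node.molecule, sm)))
            for i, node in enumerate(path)]


def _path_to_leaf(root: RouteNode, sm: Molecule) -> Optional[List[RouteNode]]:
    if root.is_leaf:
        return [root] if root.molecule == sm else None
    for child in root.children:
        sub = _path_to_leaf(child, sm)
        if sub is not None:
            return [root] + sub
    return None


def tango_pairwise_cost(weights: CostWeights = CostWeights()) -> PairwiseCost:
    """The TANGO node cost as a generic molecule-pair cost callable."""
    cache: Dict[str, TangoCost] = {}

    def cost(m: Molecule, sm: Molecule) -> float:
        tc = cache.get(sm.smiles)
        if tc is None:
            tc = TangoCost(sm, weights)
            cache[sm.smiles] = tc
        return tc.pairwise(m, sm)

    return cost


@dataclass
class DiagnosticsReport:
    spearman_rho: float
    kendall_tau: float
    mean_cv: float
    mean_overlap: float
    n_records: int
    group_stats: pd.DataFrame            # columns: distance, n, mean, std
    cv_excluded_groups: int = 0          # near-zero-mean groups left out of CV
    overlap_method: str = "separation_ratio"

    def to_json_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "kendall_tau": self.kendall_tau,
            "mean_cv": self.mean_cv,
            "mean_overlap": self.mean_overlap,
            "n_records": self.n_records,
            "cv_excluded_groups": self.cv_excluded_groups,
            "overlap_method": self.overlap_method,
            "groups": self.group_stats.to_dict(orient="records"),
        }


def diagnostics(records: Sequence[Tuple[float, float]],
                overlap_method: str = "separation_ratio",
                min_group_size: int = 1) -> DiagnosticsReport:
    """Monotonicity / consistency / granularity metrics for a cost
    function evaluated along ground-truth routes.

    ``records`` are (distance, cost) pairs pooled over routes. Kendall's
    tau uses the tau-b tie correction since distances are heavily tied.
    Groups whose mean cost is ~0 are excluded from the CV average (their
    CV is undefined); the count of exclusions is reported.
    """
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 records")
    dist = np.asarray([d for d, _ in records], dtype=float)
    cost = np.asarray([c for _, c in records], dtype=float)
    if np.unique(dist).size < 2:
        raise InsufficientDataError("need at least 2 distinct distances")

    rho = float(stats.spearmanr(dist, cost).statistic)
    tau = float(stats.kendalltau(dist, cost, variant="b").statistic)

    df = pd.DataFrame({"distance": dist, "cost": cost})
    grouped = df.groupby("distance")["cost"]
    gstats = grouped.agg(n="size", mean="mean",
                         std=lambda x: float(np.std(x, ddof=0))).reset_index()
    gstats = gstats[gstats["n"] >= min_group_size].sort_values("distance")
    if len(gstats) < 2:
        raise InsufficientDataError("need at least 2 usable distance groups")

    eps = 1e-12
    usable = gstats[np.abs(gstats["mean"]) > eps]
    excluded = len(gstats) - len(usable)
    mean_cv = float((usable["std"] / usable["mean"].abs()).mean()) \
        if len(usable) else float("nan")

    if overlap_method == "separation_ratio":
        overlaps = []
        rows = gstats.to_dict(orient="records")
        for a, b in zip(rows[:-1], rows[1:]):
            dmu = abs(a["mean"] - b["mean"])
            overlaps.append((a["std"] + b["std"]) / max(dmu, eps))
        mean_overlap = float(np.mean(overlaps))
    elif overlap_method == "histogram":
        mean_overlap = _mean_histogram_overlap(df)
    else:
        raise ValueError(f"unknown overlap method {overlap_method!r}")

    return DiagnosticsReport(
        spearman_rho=rho, kendall_tau=tau, mean_cv=mean_cv,
        mean_overlap=mean_overlap, n_records=len(records),
        group_stats=gstats.reset_index(drop=True),
        cv_excluded_groups=excluded, overlap_method=overlap_method)


def _mean_histogram_overlap(df: pd.DataFrame, bins: int = 20) -> float:
    """Classic overlap coefficient (in [0,1]) between adjacent distance
    groups, averaged; offered as an alternative to the separation ratio."""
    distances = sorted(df["distance"].unique())
    lo, hi = df["cost"].min(), df["cost"].max()
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    out = []
    for a, b in zip(distances[:-1], distances[1:]):
        pa, _ = np.histogram(df.loc[df["distance"] == a, "cost"],
                             bins=edges, density=False)
        pb, _ = np.histogram(df.loc[df["distance"] == b, "cost"],
                             bins=edges, density=False)
        pa = pa / pa.sum() if pa.sum() else pa.astype(float)
        pb = pb / pb.sum() if pb.sum() else pb.astype(float)
        out.append(float(np.minimum(pa, pb).sum()))
    return float(np.mean(out))


def plot_cost_by_distance(records: Sequence[Tuple[float, float]], path) -> None:
    """Best-effort strip/violin plot of cost grouped by distance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist = np.asarray([d for d, _ in records], dtype=float)
    cost = np.asarray([c for _, c in records], dtype=float)
    groups = sorted(set(dist))
    data = [cost[dist == g] for g in groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, positions=range(len(groups)), showmeans=True)
    for i, vals in enumerate(data):
        jitter = (np.arange(len(vals)) - len(vals) / 2) * 0.01
        ax.plot(np.full(len(vals), i) + jitter, vals, ".", ms=3, alpha=0.5)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([f"{g:g}" for g in groups])
    ax.set_xlabel("synthetic distance to sm*")
    ax.set_ylabel("node cost")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
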