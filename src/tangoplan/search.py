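"""Best-first AND-OR retrosynthesis search with pluggable node costs.

The engine is the classic value-guided best-first scheme: molecules are
OR nodes (solved by any one child reaction), reactions are AND nodes
(solved only when every precursor is solved). Each iteration

1. selects the unexpanded frontier molecule lying on the cheapest
   estimated route through the graph,
2. asks the single-step policy for disconnections (one call = one unit of
   the expansion budget E),
3. grafts the proposals into the graph (molecules deduplicated by
   canonical SMILES, ancestor-creating proposals dropped), and
4. re-evaluates route estimates.

Frontier molecules are priced by an injected cost callable. With the
TANGO cost that price is ``base(m) + k*(1 - tango(m, sm*))`` — the pull
toward the enforced starting material; with ``k = 0`` the search reduces
to plain unconstrained best-first planning. The search succeeds in the
*constrained* sense only when a solved route exists whose leaves are all
purchasable and include sm*.

Route cost is the sum of reaction costs, each ``-log(score)`` clamped to
[1e-3, 10]; with uniform template priors this makes cost a proxy for
reaction count.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import ParseError
from .expansion_policy import ExpansionPolicy, SingleStepProposal
from .molecules import Molecule, canonicalize
from .tango_cost import CostWeights, TangoCost

INF = math.inf

REACTION_COST_MIN = 1e-3
REACTION_COST_MAX = 10.0


def reaction_cost(score: float) -> float:
    """-log(confidence), clamped so costs stay positive and finite."""
    if score <= 0:
        return REACTION_COST_MAX
    return min(REACTION_COST_MAX, max(REACTION_COST_MIN, -math.log(score)))


# ---------------------------------------------------------------------------
# graph


@dataclass
class MolNode:
    molecule: Molecule
    purchasable: bool
    insertion_order: int
    expanded: bool = False
    dead: bool = False  # expanded and produced no proposals
    reactions: List[int] = field(default_factory=list)  # child reaction ids
    parents: List[int] = field(default_factory=list)    # parent reaction ids
    frontier_cost: float = 0.0  # cached injected-cost value


@dataclass
class RxnNode:
    rid: int
    product: str                      # canonical SMILES
    precursors: Tuple[str, ...]
    cost: float
    template_id: Optional[str]


class AndOrGraph:
    """Bipartite molecule/reaction search graph, molecules deduplicated
    by canonical SMILES."""

    def __init__(self, root: Molecule, building_blocks: FrozenSet[str]):
        self.mols: Dict[str, MolNode] = {}
        self.rxns: List[RxnNode] = []
        self.building_blocks = building_blocks
        self.root = root.smiles
        self._counter = 0
        self._add_mol(root)

    def _add_mol(self, m: Molecule) -> MolNode:
        node = self.mols.get(m.smiles)
        if node is None:
            node = MolNode(
                molecule=m,
                purchasable=m.smiles in self.building_blocks,
                insertion_order=self._counter,
            )
            self._counter += 1
            self.mols[m.smiles] = node
        return node

    def is_ancestor(self, candidate: str, of: str) -> bool:
        """True if ``candidate`` appears on some reaction path from the
        root down to ``of`` (used to reject loop-forming proposals)."""
        seen: Set[str] = set()
        stack = [of]
        while stack:
            s = stack.pop()
            if s == candidate:
                return True
            if s in seen:
                continue
            seen.add(s)
            for rid in self.mols[s].parents:
                stack.append(self.rxns[rid].product)
        return False

    def add_proposal(self, product: str, prop: SingleStepProposal) -> Optional[RxnNode]:
        for p in prop.precursors:
            if self.is_ancestor(p.smiles, product):
                return None
        rid = len(self.rxns)
        rxn = RxnNode(
            rid=rid,
            product=product,
            precursors=tuple(m.smiles for m in prop.precursors),
            cost=reaction_cost(prop.score),
            template_id=prop.template_id,
        )
        self.rxns.append(rxn)
        self.mols[product].reactions.append(rid)
        for m in prop.precursors:
            self._add_mol(m).parents.append(rid)
        return rxn

    # -- value estimates ---------------------------------------------------

    def values(self) -> Dict[str, float]:
        """Cost-to-solve estimate per molecule: 0 if purchasable, the
        injected frontier cost if unexpanded, else min over child
        reactions of (reaction cost + sum of precursor values)."""
        memo: Dict[str, float] = {}

        def visit(s: str, visiting: frozenset) -> float:
            if s in memo:
                return memo[s]
            if s in visiting:
                return INF  # cycle through shared subgraphs: unusable
            node = self.mols[s]
            if node.purchasable:
                val = 0.0
            elif not node.expanded:
                val = node.frontier_cost
            elif not node.reactions:
                val = INF
            else:
                visiting = visiting | {s}
                val = INF
                for rid in node.reactions:
                    rxn = self.rxns[rid]
                    total = rxn.cost
                    for p in rxn.precursors:
                        total += visit(p, visiting)
                        if total == INF:
                            break
                    val = min(val, total)
            memo[s] = val
            return val

        for s in self.mols:
            visit(s, frozenset())
        return memo

    def route_estimates(self, values: Dict[str, float]) -> Dict[str, float]:
        """Total cost of the cheapest route estimate passing through each
        molecule (the best-first selection key). Computed top-down from
        the root by Dijkstra-style relaxation; estimates only grow as they
        descend, so the heap order is safe."""
        est: Dict[str, float] = {self.root: values[self.root]}
        heap = [(est[self.root], self.root)]
        done: Set[str] = set()
        while heap:
            t, s = heapq.heappop(heap)
            if s in done or t > est.get(s, INF):
                continue
            done.add(s)
            node = self.mols[s]
            for rid in node.reactions:
                rxn = self.rxns[rid]
                branch = rxn.cost + sum(values[p] for p in rxn.precursors)
                through = t - values[s] + branch
                for p in rxn.precursors:
                    if through < est.get(p, INF):
                        est[p] = through
                        heapq.heappush(heap, (through, p))
        return est


# ---------------------------------------------------------------------------
# routes


@dataclass(frozen=True)
class RouteNode:
    """One molecule in a solution tree; leaves have no children."""

    molecule: Molecule
    template_id: Optional[str] = None
    children: Tuple["RouteNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def sort_key(self):
        return (self.molecule.smiles, self.template_id or "",
                tuple(c.sort_key() for c in self.children))


@dataclass(frozen=True)
class Route:
    """A solution tree: reactions from the target down to purchasable
    leaves, with the summed reaction cost."""

    root: RouteNode
    cost: float

    def leaves(self) -> Set[Molecule]:
        out: Set[Molecule] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.molecule)
            else:
                stack.extend(n.children)
        return out

    def molecules(self) -> List[Molecule]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n.molecule)
            stack.extend(n.children)
        return out

    def contains(self, m: Molecule) -> bool:
        return any(m == x for x in self.molecules())

    @property
    def length(self) -> int:
        """Number of reactions on the longest root-to-leaf path."""

        def depth(n: RouteNode) -> int:
            if n.is_leaf:
                return 0
            return 1 + max(depth(c) for c in n.children)

        return depth(self.root)

    @property
    def n_reactions(self) -> int:
        def count(n: RouteNode) -> int:
            if n.is_leaf:
                return 0
            return 1 + sum(count(c) for c in n.children)

        return count(self.root)

    def reaction_smiles(self) -> List[str]:
        """Flat '.'-joined precursor>>product strings, preorder."""
        out: List[str] = []

        def walk(n: RouteNode):
            if n.is_leaf:
                return
            out.append(
                ".".join(sorted(c.molecule.smiles for c in n.children))
                + ">>" + n.molecule.smiles)
            for c in sorted(n.children, key=lambda x: x.molecule.smiles):
                walk(c)

        walk(self.root)
        return out

    def to_json_dict(self) -> dict:
        def node_dict(n: RouteNode) -> dict:
            d = {"product": n.molecule.smiles}
            if n.template_id is not None:
                d["template_id"] = n.template_id
            d["precursors"] = [node_dict(c) for c in n.children]
            return d

        return {"cost": self.cost, "tree": node_dict(self.root)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "Route":
        def parse(nd: dict) -> RouteNode:
            return RouteNode(
                molecule=canonicalize(nd["product"]),
                template_id=nd.get("template_id"),
                children=tuple(parse(c) for c in nd.get("precursors", [])),
            )

        return cls(root=parse(d["tree"]), cost=float(d["cost"]))


def route_length(route: Route) -> int:
    return route.length


# ---------------------------------------------------------------------------
# configuration & result


@dataclass
class SearchConfig:
    expansion_budget: int = 500
    top_n: int = 50
    cost_weights: CostWeights = field(default_factory=CostWeights)
    building_blocks: FrozenSet[str] = frozenset()
    enforced_sm: Optional[Molecule] = None
    seed: int = 0
    tie_break: str = "cost_insertion_smiles"
    stop_on_first_solve: bool = True

    def __post_init__(self):
        if self.expansion_budget < 1:
            raise ValueError("expansion_budget must be >= 1")
        bbs = set(self.building_blocks)
        if self.enforced_sm is not None:
            bbs.add(self.enforced_sm.smiles)  # sm* is purchasable by definition
        self.building_blocks = frozenset(bbs)


@dataclass
class SearchResult:
    solved: bool                    # constrained sense
    route: Optional[Route]
    expansions_used: int
    graph: AndOrGraph
    trace: List[str]
    solve_iteration: Optional[int] = None  # expansions used when first solved
    unconstrained_solved: bool = False


# ---------------------------------------------------------------------------
# route extraction


_TieKey = Tuple[float, tuple]


def _min_key(cost: float, node: RouteNode) -> _TieKey:
    return (round(cost, 9), node.sort_key())


def extract_route(graph: AndOrGraph, prefer_sm: Optional[Molecule] = None
                  ) -> Optional[Route]:
    """Minimum-cost solved route from the root; if ``prefer_sm`` is given
    and some solved route contains it as a leaf, the cheapest such route
    is returned even when a cheaper route without it exists. Cost ties
    break on the lexicographically smallest serialized tree."""
    best = _best_solved(graph)
    if prefer_sm is not None:
        best_sm = _best_solved_with(graph, prefer_sm.smiles, best)
        hit = best_sm.get(graph.root)
        if hit is not None:
            return Route(root=hit[1], cost=hit[0])
    hit = best.get(graph.root)
    if hit is None:
        return None
    return Route(root=hit[1], cost=hit[0])


def _best_solved(graph: AndOrGraph) -> Dict[str, Tuple[float, RouteNode]]:
    """Per molecule: (cost, tree) of its cheapest fully-purchasable route."""
    memo: Dict[str, Optional[Tuple[float, RouteNode]]] = {}

    def visit(s: str, visiting: frozenset) -> Optional[Tuple[float, RouteNode]]:
        if s in memo:
            return memo[s]
        if s in visiting:
            return None
        node = graph.mols[s]
        if node.purchasable:
            memo[s] = (0.0, RouteNode(molecule=node.molecule))
            return memo[s]
        visiting = visiting | {s}
        best: Optional[Tuple[float, RouteNode]] = None
        for rid in node.reactions:
            rxn = graph.rxns[rid]
            cost = rxn.cost
            children = []
            ok = True
            for p in rxn.precursors:
                sub = visit(p, visiting)
                if sub is None:
                    ok = False
                    break
                cost += sub[0]
                children.append(sub[1])
            if not ok:
                continue
            cand = (cost, RouteNode(molecule=node.molecule,
                                    template_id=rxn.template_id,
                                    children=tuple(children)))
            if best is None or _min_key(*cand) < _min_key(*best):
                best = cand
        memo[s] = best
        return best

    for s in graph.mols:
        visit(s, frozenset())
    return {s: v for s, v in memo.items() if v is not None}


def _best_solved_with(graph: AndOrGraph, sm: str,
                      best: Dict[str, Tuple[float, RouteNode]]
                      ) -> Dict[str, Tuple[float, RouteNode]]:
    """Per molecule: cheapest fully-purchasable route having ``sm`` as a
    leaf. Exactly one precursor branch per reaction carries sm (a leaf
    can of course be sm itself)."""
    memo: Dict[str, Optional[Tuple[float, RouteNode]]] = {}

    def visit(s: str, visiting: frozenset) -> Optional[Tuple[float, RouteNode]]:
        if s in memo:
            return memo[s]
        if s in visiting:
            return None
        node = graph.mols[s]
        if s == sm:
            memo[s] = (0.0, RouteNode(molecule=node.molecule))
            return memo[s]
        visiting = visiting | {s}
        out: Optional[Tuple[float, RouteNode]] = None
        for rid in node.reactions:
            rxn = graph.rxns[rid]
            plain = [best.get(p) for p in rxn.precursors]
            if any(v is None for v in plain):
                continue
            for j, p in enumerate(rxn.precursors):
                carrier = visit(p, visiting)
                if carrier is None:
                    continue
                cost = rxn.cost + carrier[0] + sum(
                    plain[i][0] for i in range(len(plain)) if i != j)
                children = tuple(
                    carrier[1] if i == j else plain[i][1]
                    for i in range(len(plain)))
                cand = (cost, RouteNode(molecule=node.molecule,
                                        template_id=rxn.template_id,
                                        children=children))
                if out is None or _min_key(*cand) < _min_key(*out):
                    out = cand
        memo[s] = out
        return out

    for s in graph.mols:
        visit(s, frozenset())
    return {s: v for s, v in memo.items() if v is not None}


def is_constrained_solved(route: Optional[Route], config: SearchConfig,
                          target: Optional[Molecule] = None) -> bool:
    """Constrained-solve criterion: the route solves the target, every
    leaf is purchasable, and the enforced starting material is a leaf."""
    if route is None or config.enforced_sm is None:
        return False
    if target is not None and route.root.molecule != target:
        return False
    leaves = route.leaves()
    if not all(m.smiles in config.building_blocks for m in leaves):
        return False
    return any(m == config.enforced_sm for m in leaves)


# ---------------------------------------------------------------------------
# the search loop


def search(target: Molecule, policy: ExpansionPolicy, config: SearchConfig,
           cost: Optional[Callable[[Molecule], float]] = None) -> SearchResult:
    """Run the constrained best-first search.

    ``cost`` prices frontier molecules; when omitted, a cached TANGO cost
    bound to ``config.enforced_sm`` is used (or a zero cost when no
    starting material is enforced). Returns after the first constrained
    solve unless ``config.stop_on_first_solve`` is False, in which case
    the budget is exhausted and the best route extracted at the end.
    """
    sm = config.enforced_sm
    if cost is None:
        if sm is not None and config.cost_weights.k > 0:
            cost = TangoCost(sm, config.cost_weights)
        else:
            cost = lambda m: 0.0  # noqa: E731 - unguided fallback

    graph = AndOrGraph(target, config.building_blocks)

    # degenerate case: the target is the enforced starting material
    if sm is not None and target == sm:
        route = Route(root=RouteNode(molecule=target), cost=0.0)
        return SearchResult(solved=True, route=route, expansions_used=0,
                            graph=graph, trace=[], solve_iteration=0,
                            unconstrained_solved=True)

    graph.mols[target.smiles].frontier_cost = float(cost(target))

    trace: List[str] = []
    expansions = 0
    solve_iteration: Optional[int] = None

    def constrained_route() -> Optional[Route]:
        if sm is None:
            return None
        r = extract_route(graph, prefer_sm=sm)
        if r is not None and is_constrained_solved(r, config, target=target):
            return r
        return None

    while expansions < config.expansion_budget:
        values = graph.values()
        estimates = graph.route_estimates(values)
        frontier = [
            node for s, node in graph.mols.items()
            if not node.expanded and not node.dead
            and not node.purchasable and s in estimates
        ]
        # a purchasable root still needs expansion when it is not sm*
        root_node = graph.mols[graph.root]
        if (root_node.purchasable and not root_node.expanded
                and not root_node.dead):
            frontier.append(root_node)
        if not frontier:
            break
        pick = min(frontier, key=lambda n: (
            round(estimates.get(n.molecule.smiles, INF), 9),
            n.insertion_order, n.molecule.smiles))

        proposals = policy.propose(pick.molecule, config.top_n)
        expansions += 1
        trace.append(pick.molecule.smiles)
        pick.expanded = True
        if not proposals:
            pick.dead = True
            continue
        for prop in proposals:
            rxn = graph.add_proposal(pick.molecule.smiles, prop)
            if rxn is None:
                continue
            for p in prop.precursors:
                node = graph.mols[p.smiles]
                if not node.expanded and not node.purchasable:
                    node.frontier_cost = float(cost(p))

        if config.stop_on_first_solve:
            route = constrained_route()
            if route is not None:
                return SearchResult(
                    solved=True, route=route, expansions_used=expansions,
                    graph=graph, trace=trace, solve_iteration=expansions,
                    unconstrained_solved=True)
        elif solve_iteration is None and constrained_route() is not None:
            solve_iteration = expansions

    route = extract_route(graph, prefer_sm=sm)
    solved = is_constrained_solved(route, config, target=target)
    if solved and solve_iteration is None:
        solve_iteration = expansions
    return SearchResult(
        solved=solved, route=route, expansions_used=expansions, graph=graph,
        trace=trace, solve_iteration=solve_iteration if solved else None,
        unconstrained_solved=route is not None)


# ---------------------------------------------------------------------------
# I/O helpers


def save_route(route: Route, path) -> None:
    with open(path, "w") as fh:
        json.dump(route.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_route(path) -> Route:
    with open(path) as fh:
        return Route.from_json_dict(json.load(fh))


def load_pairs(path) -> List[Tuple[Molecule, Molecule]]:
    """(target, sm*) pairs from a CSV with columns target_smiles, sm_smiles."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"target_smiles", "sm_smiles"} - set(df.columns)
    if missing:
        raise ParseError(f"pair file missing columns: {sorted(missing)}")
    return [(canonicalize(t), canonicalize(s))
            for t, s in zip(df["target_smiles"], df["sm_smiles"])]
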