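"""Independent oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: the Tanimoto
oracle counts fingerprint bits with Python sets, the MCS oracle
enumerates connected bond subsets exhaustively, the route enumerator
walks the whole finite network, and the plain best-first reference is a
from-scratch reimplementation of the unguided search loop.
"""

from __future__ import annotations

import itertools
import math
from itertools import combinations
from typing import Dict, List, Optional, Set, Tuple

from rdkit import Chem

from tangoplan import Molecule
from tangoplan.search import reaction_cost

INF = math.inf


# ---------------------------------------------------------------------------
# similarity oracles


def brute_tanimoto(a: Molecule, b: Molecule) -> float:
    """Jaccard index computed from explicit on-bit sets."""
    bits_a = set(a.fingerprint().GetOnBits())
    bits_b = set(b.fingerprint().GetOnBits())
    union = bits_a | bits_b
    if not union:
        return 0.0
    return len(bits_a & bits_b) / len(union)


def _connected_atoms(mol, bond_ids) -> Tuple[bool, Set[int]]:
    parent: Dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    atoms: Set[int] = set()
    for bid in bond_ids:
        b = mol.GetBondWithIdx(bid)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        atoms |= {i, j}
        parent[find(i)] = find(j)
    roots = {find(a) for a in atoms}
    return len(roots) == 1, atoms


def brute_mcs_atoms(a: Molecule, b: Molecule) -> int:
    """Maximum heavy-atom count over all connected common subgraphs,
    found by exhaustive enumeration of bond subsets of the smaller
    molecule (feasible for <= ~8 heavy atoms)."""
    ma, mb = a.rdkit_mol, b.rdkit_mol
    if ma.GetNumBonds() > mb.GetNumBonds():
        ma, mb = mb, ma
    best = 0
    bond_ids = list(range(ma.GetNumBonds()))
    for r in range(1, len(bond_ids) + 1):
        for sub in combinations(bond_ids, r):
            ok, atoms = _connected_atoms(ma, sub)
            if not ok:
                continue
            frag = Chem.MolFragmentToSmiles(ma, atomsToUse=sorted(atoms),
                                            bondsToUse=list(sub))
            query = Chem.MolFromSmarts(frag)
            if query is not None and mb.HasSubstructMatch(query):
                best = max(best, len(atoms))
    return best


# ---------------------------------------------------------------------------
# exhaustive route enumeration over a finite synthetic network


def enumerate_routes(network) -> List[Tuple[float, frozenset]]:
    """Every solved route from the network target: (cost, leaf set)."""
    bb = network.building_blocks
    memo: Dict[str, List[Tuple[float, frozenset]]] = {}

    def expand(s: str) -> List[Tuple[float, frozenset]]:
        if s in memo:
            return memo[s]
        memo[s] = []  # cycle guard; networks are acyclic
        out: List[Tuple[float, frozenset]] = []
        if s in bb:
            out.append((0.0, frozenset([s])))
        for prec, score, _rid in network.reactions.get(s, []):
            sub = [expand(p) for p in prec]
            if any(not lst for lst in sub):
                continue
            for combo in itertools.product(*sub):
                cost = reaction_cost(score) + sum(c for c, _ in combo)
                leaves = frozenset().union(*(l for _, l in combo))
                out.append((cost, leaves))
        memo[s] = out
        return out

    return expand(network.target.smiles)


def min_route_cost(network) -> Optional[float]:
    routes = enumerate_routes(network)
    return min((c for c, _ in routes), default=None)


def constrained_route_exists(network) -> bool:
    sm = network.enforced_sm.smiles
    return any(sm in leaves for _, leaves in enumerate_routes(network))


# ---------------------------------------------------------------------------
# plain unguided best-first reference (the k=0 baseline)


def plain_best_first_trace(target: Molecule, policy, building_blocks,
                           budget: int, top_n: int = 50) -> List[str]:
    """Expansion order of an unguided best-first AND-OR search with zero
    frontier values, written independently of the package's engine.
    Tie-break: (rounded route estimate, insertion order, SMILES)."""
    nodes: Dict[str, dict] = {}
    counter = [0]

    def add(mol: Molecule):
        if mol.smiles not in nodes:
            nodes[mol.smiles] = {
                "mol": mol, "purch": mol.smiles in building_blocks,
                "expanded": False, "dead": False, "order": counter[0],
                "rxns": [],  # (cost, precursor smiles tuple)
            }
            counter[0] += 1

    add(target)
    root = target.smiles
    trace: List[str] = []

    def value(s: str, seen: frozenset) -> float:
        n = nodes[s]
        if n["purch"]:
            return 0.0
        if not n["expanded"]:
            return 0.0
        if not n["rxns"] or s in seen:
            return INF
        seen = seen | {s}
        best = INF
        for cost, precs in n["rxns"]:
            tot = cost + sum(value(p, seen) for p in precs)
            best = min(best, tot)
        return best

    for _ in range(budget):
        vals = {s: value(s, frozenset()) for s in nodes}
        # through-route estimates by relaxation until fixpoint
        est = {root: vals[root]}
        changed = True
        while changed:
            changed = False
            for s, n in nodes.items():
                if s not in est:
                    continue
                for cost, precs in n["rxns"]:
                    through = est[s] - vals[s] + cost + sum(vals[p] for p in precs)
                    for p in precs:
                        if through < est.get(p, INF) - 1e-15:
                            est[p] = through
                            changed = True
        frontier = [n for s, n in nodes.items()
                    if not n["expanded"] and not n["dead"] and not n["purch"]
                    and s in est]
        if not frontier:
            break
        pick = min(frontier, key=lambda n: (round(est[n["mol"].smiles], 9),
                                            n["order"], n["mol"].smiles))
        proposals = policy.propose(pick["mol"], top_n)
        trace.append(pick["mol"].smiles)
        pick["expanded"] = True
        if not proposals:
            pick["dead"] = True
            continue
        for prop in proposals:
            for m in prop.precursors:
                add(m)
            pick["rxns"].append(
                (reaction_cost(prop.score), tuple(m.smiles for m in prop.precursors)))
    return trace


class CountingPolicy:
    """Wraps a policy and counts propose() calls for budget accounting."""

    def __init__(self, inner):
        self.inner = inner
        self.calls = 0

    def propose(self, product, top_n):
        self.calls += 1
        return self.inner.propose(product, top_n)
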