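"""Finite synthetic reaction networks with a planted ground-truth route.

Benchmarking a constrained planner needs (target, sm*) pairs whose answer
is known. This module manufactures them: a linear planted route is grown
*forward* from a chosen starting material by repeatedly attaching small
fragments, so that reading it backwards gives a retrosynthesis whose
deepest, heaviest leaf is sm* — the same extraction rule used on real
route datasets (longest root-to-leaf path, then the leaf with the most
heavy atoms). Decoy disconnections are grafted onto every intermediate:
some terminate immediately in purchasable decoy leaves (solvable, but
*unconstrained* — they never contain sm*), the rest are dead ends. An
unguided search therefore solves the unconstrained problem easily but
must wade through decoys to reach sm*; a starting-material-guided cost
should find it with fewer expansions.

Two modes:

* ``"real"`` — molecules are genuine RDKit structures grown from a
  fragment grammar, so fingerprint and MCS similarity to sm* increases
  monotonically along the planted route. This is the regime where TANGO
  guidance is provably informative.
* ``"abstract"`` — structure-less token molecules plus an oracle cost
  equal to the planted synthetic distance; fast, chemistry-free search
  logic testing.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from rdkit import Chem

from .errors import ParameterError
from .expansion_policy import TabularPolicy
from .molecules import Molecule, canonicalize
from .search import Route, RouteNode

# fragment grammar: small growable pieces; planted-route leaves come from here
FRAGMENT_POOL = ["C", "O", "N", "CC", "CO", "CN", "CCO", "C=O", "CCN"]

# candidate starting materials: heavier than any fragment so the deepest
# leaf with the most heavy atoms is always sm*
SM_POOL = ["Oc1ccccc1", "Nc1ccccc1", "OC(=O)c1ccccc1", "c1ccncc1",
           "OC1CCCCC1", "Cc1ccccc1"]

# purchasable decoy leaves, disjoint from the fragment pool
DECOY_POOL = ["CC(C)O", "CCCN", "CCS", "C1CCOC1", "CC#N", "CCCl", "C1CCNC1",
              "CCOC", "CC(C)N", "C1CCCCC1"]

# one shared confidence for every reaction: route costs then scale with
# reaction count, and neither arm of a guided-vs-unguided comparison can
# read the planted route off the scores
REACTION_SCORE = 0.8

#: decoy side chains are 1..MAX_DECOY_DEPTH reactions deep
MAX_DECOY_DEPTH = 3


@dataclass
class SyntheticNetwork:
    """A finite reaction universe with one planted constrained route."""

    mode: str
    molecules: Dict[str, Molecule]
    #: product smiles -> [(precursor smiles tuple, score, reaction id)]
    reactions: Dict[str, List[Tuple[Tuple[str, ...], float, str]]]
    building_blocks: frozenset
    planted_route: Route
    target: Molecule
    enforced_sm: Molecule
    #: planted synthetic distance to sm* for molecules on the planted route
    planted_distance: Dict[str, int]
    params: dict = field(default_factory=dict)

    def policy(self) -> TabularPolicy:
        return TabularPolicy(self.reactions, self.molecules)

    def oracle_cost(self, off_route_penalty: Optional[float] = None
                    ) -> Callable[[Molecule], float]:
        """Frontier cost equal to the planted distance to sm* (the perfect
        guidance signal); off-route molecules pay a flat penalty."""
        depth = self.params.get("depth", max(self.planted_distance.values(), default=0))
        penalty = off_route_penalty if off_route_penalty is not None else depth + 2.0

        def cost(m: Molecule) -> float:
            return float(self.planted_distance.get(m.smiles, penalty))

        return cost

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "params": self.params,
            "molecules": [
                {"smiles": m.smiles, "heavy_atoms": m.heavy_atom_count}
                for m in sorted(self.molecules.values())
            ],
            "reactions": {
                prod: [[list(prec), score, rid] for prec, score, rid in entries]
                for prod, entries in sorted(self.reactions.items())
            },
            "building_blocks": sorted(self.building_blocks),
            "planted_route": self.planted_route.to_json_dict(),
            "target": self.target.smiles,
            "enforced_sm": self.enforced_sm.smiles,
            "planted_distance": self.planted_distance,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticNetwork":
        mols = {}
        for entry in d["molecules"]:
            s = entry["smiles"]
            m = (Molecule.token(s, entry["heavy_atoms"])
                 if s.startswith("tok:") else canonicalize(s))
            mols[m.smiles] = m
        return cls(
            mode=d["mode"],
            molecules=mols,
            reactions={
                prod: [(tuple(prec), float(score), rid)
                       for prec, score, rid in entries]
                for prod, entries in d["reactions"].items()
            },
            building_blocks=frozenset(d["building_blocks"]),
            planted_route=Route.from_json_dict(d["planted_route"]),
            target=mols[d["target"]],
            enforced_sm=mols[d["enforced_sm"]],
            planted_distance={k: int(v) for k, v in d["planted_distance"].items()},
            params=d.get("params", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SyntheticNetwork":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def extract_pair(network: SyntheticNetwork) -> Tuple[Molecule, Molecule]:
    """(target, sm*) by the route-dataset rule: walk the planted route,
    keep the leaves at maximal depth, pick the one with the most heavy
    atoms (ties: lexicographically smallest SMILES)."""
    leaves: List[Tuple[int, Molecule]] = []

    def walk(node: RouteNode, depth: int):
        if node.is_leaf:
            leaves.append((depth, node.molecule))
        for c in node.children:
            walk(c, depth + 1)

    walk(network.planted_route.root, 0)
    max_depth = max(d for d, _ in leaves)
    deepest = [m for d, m in leaves if d == max_depth]
    sm = max(deepest, key=lambda m: (m.heavy_atom_count, ), default=None)
    # explicit tie-break on smiles for equal heavy-atom counts
    best_ha = max(m.heavy_atom_count for m in deepest)
    sm = sorted([m for m in deepest if m.heavy_atom_count == best_ha])[0]
    return network.planted_route.root.molecule, sm


# ---------------------------------------------------------------------------
# real-molecule construction helpers


def _join(a: Chem.Mol, b: Chem.Mol, rng: random.Random) -> Optional[Chem.Mol]:
    """Attach ``b`` to ``a`` with one single bond between atoms that have
    spare valence; None if no valid attachment exists."""
    combined = Chem.RWMol(Chem.CombineMols(a, b))
    na = a.GetNumAtoms()

    def attachable(indices):
        out = []
        for i in indices:
            at = combined.GetAtomWithIdx(i)
            if at.GetTotalNumHs() > 0:
                out.append(i)
        return out

    left = attachable(range(na))
    right = attachable(range(na, combined.GetNumAtoms()))
    if not left or not right:
        return None
    for _ in range(8):
        i = rng.choice(left)
        j = rng.choice(right)
        trial = Chem.RWMol(combined)
        trial.AddBond(i, j, Chem.BondType.SINGLE)
        mol = trial.GetMol()
        try:
            Chem.SanitizeMol(mol)
            return mol
        except Exception:
            continue
    return None


def _grow(base: Molecule, frag_smiles: str, rng: random.Random) -> Optional[Molecule]:
    frag = Chem.MolFromSmiles(frag_smiles)
    joined = _join(base.rdkit_mol, frag, rng)
    if joined is None:
        return None
    return canonicalize(Chem.MolToSmiles(joined))


# ---------------------------------------------------------------------------
# generation


def generate(depth: int, branching: int = 2, decoy_rate: float = 0.3,
             seed: int = 0, mode: str = "real") -> SyntheticNetwork:
    """Generate a network whose planted route has longest path ``depth``.

    ``branching`` reactions leave every planted intermediate: one is the
    planted disconnection, the rest are decoys. A decoy is a dead end
    with probability ``decoy_rate``, otherwise it terminates in
    purchasable decoy leaves. Fully deterministic per seed.
    """
    if depth < 1:
        raise ParameterError(f"depth must be >= 1, got {depth}")
    if branching < 1:
        raise ParameterError(f"branching must be >= 1, got {branching}")
    if not 0.0 <= decoy_rate < 1.0:
        raise ParameterError(f"decoy_rate must be in [0, 1), got {decoy_rate}")
    if mode not in ("real", "abstract"):
        raise ParameterError(f"mode must be 'real' or 'abstract', got {mode!r}")
    rng = random.Random(seed)
    builder = _build_real if mode == "real" else _build_abstract
    return builder(depth, branching, decoy_rate, seed, rng)


def _build_real(depth: int, branching: int, decoy_rate: float, seed: int,
                rng: random.Random) -> SyntheticNetwork:
    sm = canonicalize(rng.choice(SM_POOL))
    molecules: Dict[str, Molecule] = {sm.smiles: sm}
    reactions: Dict[str, List[Tuple[Tuple[str, ...], float, str]]] = {}
    building_blocks = {sm.smiles}
    planted_distance = {sm.smiles: 0}
    forbidden = {canonicalize(s).smiles for s in FRAGMENT_POOL + DECOY_POOL + SM_POOL}

    # grow the planted chain sm -> ... -> target; each step must strictly
    # lower fingerprint similarity to sm* so the planted route carries a
    # monotone guidance signal (the regime similarity guidance assumes)
    from .molecules import tanimoto as _tanimoto

    chain = [sm]
    frag_leaves: List[Molecule] = []
    cur = sm
    sim_cur = 1.0
    for i in range(1, depth + 1):
        grown = None
        for _ in range(80):
            frag = canonicalize(rng.choice(FRAGMENT_POOL))
            cand = _grow(cur, frag.smiles, rng)
            if cand is not None and cand.smiles not in molecules \
                    and cand.smiles not in forbidden \
                    and _tanimoto(cand, sm) < sim_cur:
                grown, used_frag = cand, frag
                sim_cur = _tanimoto(cand, sm)
                break
        if grown is None:  # pragma: no cover - grammar is permissive
            raise ParameterError(f"could not grow planted chain at step {i}")
        molecules[grown.smiles] = grown
        molecules.setdefault(used_frag.smiles, used_frag)
        building_blocks.add(used_frag.smiles)
        frag_leaves.append(used_frag)
        rid = f"planted-{i}"
        reactions.setdefault(grown.smiles, []).append(
            ((cur.smiles, used_frag.smiles), REACTION_SCORE, rid))
        planted_distance[grown.smiles] = i
        chain.append(grown)
        cur = grown
    target = cur

    # decoy side chains off every planted intermediate (not sm itself):
    # 1..MAX_DECOY_DEPTH reactions deep, ending purchasable or dead
    decoy_idx = 0
    for node in chain[1:]:
        for _ in range(branching - 1):
            decoy_idx += 1
            chain_len = rng.randint(1, MAX_DECOY_DEPTH)
            is_dead = rng.random() < decoy_rate
            parent = node
            ok = True
            for step in range(chain_len):
                last = step == chain_len - 1
                rid = f"decoy-{decoy_idx}-{step + 1}"
                if last and not is_dead:
                    leaf = canonicalize(rng.choice(DECOY_POOL))
                    molecules.setdefault(leaf.smiles, leaf)
                    building_blocks.add(leaf.smiles)
                    reactions.setdefault(parent.smiles, []).append(
                        ((leaf.smiles,), REACTION_SCORE, rid))
                else:
                    mid = _make_decoy_mol(molecules, forbidden,
                                          building_blocks, rng)
                    if mid is None:
                        ok = False
                        break
                    molecules[mid.smiles] = mid
                    reactions.setdefault(parent.smiles, []).append(
                        ((mid.smiles,), REACTION_SCORE, rid))
                    parent = mid
            if not ok:
                continue

    route = _linear_route(chain, frag_leaves)
    return SyntheticNetwork(
        mode="real", molecules=molecules, reactions=reactions,
        building_blocks=frozenset(building_blocks), planted_route=route,
        target=target, enforced_sm=sm, planted_distance=planted_distance,
        params={"depth": depth, "branching": branching,
                "decoy_rate": decoy_rate, "seed": seed})


def _make_decoy_mol(molecules, forbidden, building_blocks, rng) -> Optional[Molecule]:
    """A fresh non-purchasable decoy intermediate (or dead end)."""
    for _ in range(40):
        base = canonicalize(rng.choice(FRAGMENT_POOL))
        cand = base
        for _ in range(2):
            nxt = _grow(cand, rng.choice(FRAGMENT_POOL), rng)
            if nxt is not None:
                cand = nxt
        if cand.smiles not in molecules and cand.smiles not in forbidden \
                and cand.smiles not in building_blocks:
            return cand
    return None


def _build_abstract(depth: int, branching: int, decoy_rate: float, seed: int,
                    rng: random.Random) -> SyntheticNetwork:
    sm = Molecule.token("SM", heavy_atom_count=12)
    molecules = {sm.smiles: sm}
    reactions: Dict[str, List[Tuple[Tuple[str, ...], float, str]]] = {}
    building_blocks = {sm.smiles}
    planted_distance = {sm.smiles: 0}

    chain = [sm]
    frag_leaves: List[Molecule] = []
    for i in range(1, depth + 1):
        node = Molecule.token(f"R{i}", heavy_atom_count=12 + i)
        frag = Molecule.token(f"F{i}", heavy_atom_count=2)
        molecules[node.smiles] = node
        molecules[frag.smiles] = frag
        building_blocks.add(frag.smiles)
        frag_leaves.append(frag)
        reactions.setdefault(node.smiles, []).append(
            ((chain[-1].smiles, frag.smiles), REACTION_SCORE, f"planted-{i}"))
        planted_distance[node.smiles] = i
        chain.append(node)
    target = chain[-1]

    decoy_idx = 0
    for node in chain[1:]:
        for _ in range(branching - 1):
            decoy_idx += 1
            chain_len = rng.randint(1, MAX_DECOY_DEPTH)
            is_dead = rng.random() < decoy_rate
            parent = node
            for step in range(chain_len):
                last = step == chain_len - 1
                rid = f"decoy-{decoy_idx}-{step + 1}"
                if last and not is_dead:
                    leaf = Molecule.token(f"D{decoy_idx}", heavy_atom_count=3)
                    molecules[leaf.smiles] = leaf
                    building_blocks.add(leaf.smiles)
                    reactions.setdefault(parent.smiles, []).append(
                        ((leaf.smiles,), REACTION_SCORE, rid))
                else:
                    mid = Molecule.token(f"X{decoy_idx}-{step + 1}",
                                         heavy_atom_count=5)
                    molecules[mid.smiles] = mid
                    reactions.setdefault(parent.smiles, []).append(
                        ((mid.smiles,), REACTION_SCORE, rid))
                    parent = mid

    route = _linear_route(chain, frag_leaves)
    return SyntheticNetwork(
        mode="abstract", molecules=molecules, reactions=reactions,
        building_blocks=frozenset(building_blocks), planted_route=route,
        target=target, enforced_sm=sm, planted_distance=planted_distance,
        params={"depth": depth, "branching": branching,
                "decoy_rate": decoy_rate, "seed": seed})


def _linear_route(chain, frag_leaves) -> Route:
    """Route tree for the planted chain, read retrosynthetically."""
    from .search import reaction_cost

    node = RouteNode(molecule=chain[0])  # sm* leaf
    cost = 0.0
    for i in range(1, len(chain)):
        frag_leaf = RouteNode(molecule=frag_leaves[i - 1])
        node = RouteNode(molecule=chain[i], template_id=f"planted-{i}",
                         children=tuple(sorted((node, frag_leaf),
                                               key=lambda n: n.molecule.smiles)))
        cost += reaction_cost(REACTION_SCORE)
    return Route(root=node, cost=cost)
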