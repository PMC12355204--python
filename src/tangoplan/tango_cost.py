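"""The TANGO similarity score and the node cost it induces on a search.

TANGO measures how close a candidate precursor is to an enforced starting
material sm* as a weighted sum of two complementary signals:

* Tanimoto similarity of circular fingerprints (global, fine-grained), and
* FMS — fuzzy matching substructure — the heavy-atom count of the maximum
  common substructure divided by the heavy-atom count of the candidate
  precursor (local, interpretable as "fraction of the candidate already
  explained by shared substructure").

With FMS weight ``c`` the score is ``(1-c)*tanimoto + c*fms``, in [0, 1].
The induced node cost is ``base(m) + k*(1 - tango)``: a non-negative
penalty that vanishes exactly when the candidate *is* sm*, scaled by the
guidance strength ``k`` and added to an unconstrained synthesizability
estimate ``base`` (the role a value network plays in Retro*). ``k=0``
recovers plain unconstrained guidance; the defaults ``k=25, c=0``
correspond to pure-Tanimoto guidance, and ``c=0.3`` to the blended
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Literal, Optional, Tuple

from .errors import DegenerateMoleculeError
from .molecules import (
    DEFAULT_FP_BITS,
    DEFAULT_FP_RADIUS,
    McsSettings,
    Molecule,
    mcs,
    tanimoto,
)

#: callable estimating the unconstrained cost-to-solve of a molecule
ValueFunction = Callable[[Molecule], float]

FmsDenominator = Literal["candidate", "sm", "max"]


@dataclass(frozen=True)
class CostWeights:
    """Hyperparameters of the TANGO node cost.

    k : guidance scale balancing starting-material pull against the base
        value function; 25 is the tuned default.
    c : FMS weight in [0, 1]; the Tanimoto weight is 1 - c. c=0 is the
        pure-Tanimoto configuration, c=0.3 the blended one.
    fms_denominator : which heavy-atom count normalises the MCS size;
        "candidate" (the precursor being scored) is the default reading.
    """

    k: float = 25.0
    c: float = 0.0
    fp_radius: int = DEFAULT_FP_RADIUS
    fp_bits: int = DEFAULT_FP_BITS
    mcs_settings: McsSettings = field(default_factory=McsSettings)
    fms_denominator: FmsDenominator = "candidate"

    def __post_init__(self):
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must be in [0, 1], got {self.c}")


@dataclass(frozen=True)
class CostBreakdown:
    """All intermediate terms of one node-cost evaluation, for diagnostics."""

    tanimoto_term: float
    fms_term: float
    tango_score: float
    guidance_cost: float
    base_value: float
    total: float


def constant_value(value: float = 0.0) -> ValueFunction:
    """Base value function that ignores the molecule (pure TANGO guidance)."""

    def fn(m: Molecule) -> float:
        return value

    return fn


def heavy_atom_value(atoms_per_reaction: float = 6.0) -> ValueFunction:
    """Crude reaction-count proxy: heavy atoms / atoms-per-reaction.

    Stands in for a trained synthesizability value network: bigger
    molecules are assumed to need proportionally more steps.
    """

    def fn(m: Molecule) -> float:
        return m.heavy_atom_count / atoms_per_reaction

    return fn


def fms_score(candidate: Molecule, target_sm: Molecule,
              weights: CostWeights = CostWeights()) -> float:
    """MCS heavy atoms normalised by the configured denominator, in [0, 1]."""
    if candidate.heavy_atom_count <= 0:
        raise DegenerateMoleculeError(
            f"candidate {candidate.smiles!r} has no heavy atoms")
    res = mcs(candidate, target_sm, weights.mcs_settings)
    if weights.fms_denominator == "candidate":
        denom = candidate.heavy_atom_count
    elif weights.fms_denominator == "sm":
        denom = target_sm.heavy_atom_count
    else:
        denom = max(candidate.heavy_atom_count, target_sm.heavy_atom_count)
    if denom <= 0:
        raise DegenerateMoleculeError("denominator molecule has no heavy atoms")
    return min(1.0, res.heavy_atom_count / denom)


def tango_score(candidate: Molecule, target_sm: Molecule,
                weights: CostWeights = CostWeights()) -> float:
    """Weighted Tanimoto/FMS similarity to the enforced starting material."""
    tan = tanimoto(candidate, target_sm, weights.fp_radius, weights.fp_bits)
    if weights.c == 0.0:
        return tan  # skip the (expensive) MCS entirely
    fms = fms_score(candidate, target_sm, weights)
    return (1.0 - weights.c) * tan + weights.c * fms


def tango_node_cost(candidate: Molecule, target_sm: Molecule,
                    weights: CostWeights = CostWeights(),
                    base: Optional[ValueFunction] = None) -> CostBreakdown:
    """Full node cost ``base(candidate) + k * (1 - tango_score)``."""
    if base is None:
        base = constant_value(0.0)
    tan = tanimoto(candidate, target_sm, weights.fp_radius, weights.fp_bits)
    fms = fms_score(candidate, target_sm, weights) if weights.c > 0.0 else 0.0
    score = (1.0 - weights.c) * tan + weights.c * fms
    guidance = weights.k * (1.0 - score)
    base_value = float(base(candidate))
    return CostBreakdown(
        tanimoto_term=tan,
        fms_term=fms,
        tango_score=score,
        guidance_cost=guidance,
        base_value=base_value,
        total=base_value + guidance,
    )


class TangoCost:
    """Cached TANGO node-cost callable bound to one starting material.

    Usable both as a unary frontier cost (``cost(m)``) inside a search
    bound to sm*, and as a generic pairwise cost (``cost.pairwise(m, sm)``)
    so it can be dropped into frameworks expecting a molecule-pair distance.
    Breakdowns are cached on the canonical-SMILES pair; the cache lives for
    the duration of one search (call :meth:`clear_cache` between searches).
    """

    def __init__(self, target_sm: Molecule, weights: CostWeights = CostWeights(),
                 base: Optional[ValueFunction] = None):
        self.target_sm = target_sm
        self.weights = weights
        self.base = base if base is not None else constant_value(0.0)
        self._cache: Dict[Tuple[str, str], CostBreakdown] = {}

    def breakdown(self, candidate: Molecule,
                  target_sm: Optional[Molecule] = None) -> CostBreakdown:
        sm = target_sm if target_sm is not None else self.target_sm
        key = (candidate.smiles, sm.smiles)
        hit = self._cache.get(key)
        if hit is None:
            hit = tango_node_cost(candidate, sm, self.weights, self.base)
            self._cache[key] = hit
        return hit

    def __call__(self, candidate: Molecule) -> float:
        return self.breakdown(candidate).total

    def pairwise(self, candidate: Molecule, target_sm: Molecule) -> float:
        return self.breakdown(candidate, target_sm).total

    def clear_cache(self) -> None:
        self._cache.clear()


def base_only_cost(base: Optional[ValueFunction] = None) -> Callable[[Molecule], float]:
    """Unguided frontier cost (the k=0 limit): just the base value function."""
    fn = base if base is not None else constant_value(0.0)

    def cost(m: Molecule) -> float:
        return float(fn(m))

    return cost
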