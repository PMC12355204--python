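"""Chemical primitives: molecule identity, fingerprints, and MCS.

A :class:`Molecule` is keyed by its canonical SMILES; equality and hashing
use that key only. Fingerprints (binary Morgan/circular) are computed
lazily and cached on the instance. Maximum-common-substructure (MCS)
computation is wrapped so that a timeout yields the best count found so
far, flagged rather than raised — a search loop must never stall on a
pathological molecule pair.

Molecules normally wrap an RDKit ``Mol``. A second, chemistry-free flavour
("token" molecules) exists for abstract synthetic networks used in search
logic tests; token molecules carry an explicit heavy-atom count and no
structure, and any structural operation on them raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator, rdFMCS

from .errors import ParseError

RDLogger.DisableLog("rdApp.*")

#: prefix marking abstract token "molecules" that have no chemical structure
TOKEN_PREFIX = "tok:"

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 2048


@dataclass(frozen=True)
class McsSettings:
    """Atom/bond comparison rules for MCS computation.

    The defaults are strict (element- and bond-order-sensitive, ring bonds
    match only ring bonds). The ``fuzzy_*`` flags relax atom typing or bond
    orders for a looser notion of shared substructure.
    """

    fuzzy_atoms: bool = False
    fuzzy_bonds: bool = False
    ring_matches_ring_only: bool = True
    timeout_s: float = 1.0


@dataclass(frozen=True)
class McsResult:
    """Heavy-atom count of an MCS; ``timed_out`` marks a lower bound."""

    heavy_atom_count: int
    timed_out: bool = False


class Molecule:
    """A molecule keyed by canonical SMILES.

    Instances are immutable value objects: two molecules are equal iff
    their canonical SMILES are equal. Construct via :func:`canonicalize`
    (real molecules) or :meth:`Molecule.token` (abstract ones).
    """

    __slots__ = ("smiles", "heavy_atom_count", "_mol", "_fp")

    def __init__(self, smiles: str, heavy_atom_count: int, mol: Optional[Chem.Mol]):
        object.__setattr__(self, "smiles", smiles)
        object.__setattr__(self, "heavy_atom_count", heavy_atom_count)
        object.__setattr__(self, "_mol", mol)
        object.__setattr__(self, "_fp", None)

    def __setattr__(self, name, value):  # pragma: no cover - guard
        raise AttributeError("Molecule is immutable")

    @classmethod
    def token(cls, name: str, heavy_atom_count: int = 1) -> "Molecule":
        """An abstract structure-less molecule (for synthetic networks)."""
        smiles = name if name.startswith(TOKEN_PREFIX) else TOKEN_PREFIX + name
        return cls(smiles, heavy_atom_count, None)

    @property
    def is_token(self) -> bool:
        return self._mol is None

    @property
    def rdkit_mol(self) -> Chem.Mol:
        if self._mol is None:
            raise ValueError(f"token molecule {self.smiles!r} has no structure")
        return self._mol

    def fingerprint(self, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS):
        """Binary circular fingerprint, cached per (radius, n_bits)."""
        cached = self._fp
        if cached is not None and cached[0] == (radius, n_bits):
            return cached[1]
        gen = _fp_generator(radius, n_bits)
        fp = gen.GetFingerprint(self.rdkit_mol)
        object.__setattr__(self, "_fp", ((radius, n_bits), fp))
        return fp

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    def __lt__(self, other: "Molecule") -> bool:
        return self.smiles < other.smiles

    def __repr__(self) -> str:
        return f"Molecule({self.smiles!r}, heavy_atoms={self.heavy_atom_count})"


@lru_cache(maxsize=8)
def _fp_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def canonicalize(smiles: str) -> Molecule:
    """Parse a raw SMILES string into a canonical :class:`Molecule`.

    Raises :class:`ParseError` on anything RDKit cannot sanitize; the
    search layer treats that as bad input to skip, never a crash.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(f"empty or non-string SMILES: {smiles!r}")
    smiles = smiles.strip()
    if smiles.startswith(TOKEN_PREFIX):
        # token identity is its own canonical form
        return Molecule.token(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return Molecule(Chem.MolToSmiles(mol), mol.GetNumHeavyAtoms(), mol)


def tanimoto(a: Molecule, b: Molecule, radius: int = DEFAULT_FP_RADIUS,
             n_bits: int = DEFAULT_FP_BITS) -> float:
    """Tanimoto (Jaccard) similarity of binary circular fingerprints."""
    from rdkit import DataStructs

    return DataStructs.TanimotoSimilarity(
        a.fingerprint(radius, n_bits), b.fingerprint(radius, n_bits)
    )


def mcs(a: Molecule, b: Molecule, settings: McsSettings = McsSettings()) -> McsResult:
    """Heavy-atom count of the maximum common substructure of ``a`` and ``b``.

    Hitting the per-call timeout returns the best-so-far count with
    ``timed_out=True`` (a valid lower bound) instead of failing.
    """
    if settings.timeout_s <= 0:
        raise ValueError("timeout_s must be positive")
    params = rdFMCS.MCSParameters()
    params.MaximizeBonds = False  # the score counts atoms, so maximize atoms
    params.AtomCompareParameters.RingMatchesRingOnly = settings.ring_matches_ring_only
    params.BondCompareParameters.RingMatchesRingOnly = settings.ring_matches_ring_only
    params.AtomTyper = (
        rdFMCS.AtomCompare.CompareAny if settings.fuzzy_atoms
        else rdFMCS.AtomCompare.CompareElements
    )
    params.BondTyper = (
        rdFMCS.BondCompare.CompareAny if settings.fuzzy_bonds
        else rdFMCS.BondCompare.CompareOrder
    )
    params.Timeout = max(1, int(round(settings.timeout_s)))
    res = rdFMCS.FindMCS([a.rdkit_mol, b.rdkit_mol], params)
    return McsResult(heavy_atom_count=res.numAtoms, timed_out=res.canceled)


def read_smiles_file(path) -> Iterator[Molecule]:
    """Yield molecules from a .smi file (one SMILES per line, optional
    whitespace-separated name, '#' comments). Unparseable lines raise."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smi = line.split()[0]
            try:
                yield canonicalize(smi)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def load_building_blocks(path) -> set:
    """Canonical-SMILES membership set from a plain-text SMILES file."""
    return {m.smiles for m in read_smiles_file(path)}
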