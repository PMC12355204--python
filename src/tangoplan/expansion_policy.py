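"""Single-step retrosynthesis policies.

A policy answers one question: given a product molecule, which precursor
sets could it have been made from, and with what confidence? The contract
(:class:`ExpansionPolicy`) is deliberately minimal so a served neural
model can be wrapped the same way: product in, ordered scored precursor
sets out. One ``propose`` call is one "model call" for expansion-budget
accounting, regardless of how many proposals it returns.

Two offline implementations are provided:

* :class:`TemplatePolicy` — applies retro reaction templates (SMARTS
  transformations, product pattern on the left) to real molecules with
  RDKit. Scores are template priors; no learned ranking.
* :class:`TabularPolicy` — a lookup over an explicit reaction table, used
  with generated synthetic networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import rdChemReactions

from .errors import TemplateParseError
from .molecules import Molecule, canonicalize


@dataclass(frozen=True)
class SingleStepProposal:
    """One retrosynthetic disconnection: product -> precursors.

    ``score`` in (0, 1] plays the role of model confidence; the search
    converts it to a reaction cost via -log(score).
    """

    precursors: Tuple[Molecule, ...]
    score: float
    template_id: Optional[str] = None

    def precursor_key(self) -> Tuple[str, ...]:
        return tuple(sorted(m.smiles for m in self.precursors))


class ExpansionPolicy(Protocol):
    def propose(self, product: Molecule, top_n: int) -> List[SingleStepProposal]:
        """At most ``top_n`` proposals, sorted by descending score then
        lexicographic precursor key; [] signals a dead end."""
        ...


@dataclass(frozen=True)
class ReactionTemplate:
    smarts: str
    id: str
    prior: float = 1.0


def _sort_proposals(props: List[SingleStepProposal]) -> List[SingleStepProposal]:
    return sorted(props, key=lambda p: (-p.score, p.precursor_key()))


def load_templates(path) -> List[ReactionTemplate]:
    """Read templates from a text file: ``SMARTS<TAB>id<TAB>prior`` per
    line, later fields optional, '#' comments. Malformed SMARTS raise
    :class:`TemplateParseError` with the offending line number."""
    templates: List[ReactionTemplate] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smarts = parts[0].strip()
            tid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"T{lineno}"
            try:
                prior = float(parts[2]) if len(parts) > 2 else 1.0
            except ValueError:
                raise TemplateParseError(
                    f"bad prior on line {lineno}", line=line, lineno=lineno)
            _compile_template(smarts, lineno, line)
            templates.append(ReactionTemplate(smarts=smarts, id=tid, prior=prior))
    return templates


def _compile_template(smarts: str, lineno: int = 0, line: str = ""):
    try:
        rxn = rdChemReactions.ReactionFromSmarts(smarts)
    except Exception:
        rxn = None
    if rxn is None:
        raise TemplateParseError(
            f"invalid reaction SMARTS on line {lineno}: {smarts!r}",
            line=line, lineno=lineno)
    if rxn.GetNumReactantTemplates() != 1:
        raise TemplateParseError(
            f"template on line {lineno} must have exactly one product-side "
            f"pattern, got {rxn.GetNumReactantTemplates()}",
            line=line, lineno=lineno)
    return rxn


class TemplatePolicy:
    """Retro-template expansion over real molecules.

    Each template is a one-reactant SMARTS transformation applied to the
    product; every run of the transformation yields one candidate
    precursor set. Fragments that fail sanitization invalidate the whole
    proposal. Proposals are deduplicated by canonical precursor set and
    ordered by (descending prior, lexicographic precursor SMILES) so the
    output is bit-reproducible.
    """

    def __init__(self, templates: Sequence[ReactionTemplate]):
        self.templates = list(templates)
        self._compiled = [_compile_template(t.smarts) for t in self.templates]

    def propose(self, product: Molecule, top_n: int) -> List[SingleStepProposal]:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        seen: Dict[Tuple[str, ...], SingleStepProposal] = {}
        for tmpl, rxn in zip(self.templates, self._compiled):
            try:
                outcomes = rxn.RunReactants((product.rdkit_mol,))
            except Exception:
                continue
            for frags in outcomes:
                precursors = []
                ok = True
                for frag in frags:
                    try:
                        Chem.SanitizeMol(frag)
                        m = canonicalize(Chem.MolToSmiles(frag))
                    except Exception:
                        ok = False
                        break
                    precursors.append(m)
                if not ok or not precursors:
                    continue
                if any(p == product for p in precursors):
                    continue  # no self-loops
                prop = SingleStepProposal(
                    precursors=tuple(sorted(precursors)),
                    score=tmpl.prior,
                    template_id=tmpl.id,
                )
                key = prop.precursor_key()
                prev = seen.get(key)
                if prev is None or prop.score > prev.score:
                    seen[key] = prop
        return _sort_proposals(list(seen.values()))[:top_n]


class TabularPolicy:
    """Lookup policy over an explicit reaction table.

    ``table`` maps product canonical SMILES to a list of
    ``(precursor_smiles_tuple, score, reaction_id)`` entries; the policy
    returns exactly those entries (up to ``top_n``) in score order.
    """

    def __init__(self, table: Dict[str, List[Tuple[Tuple[str, ...], float, str]]],
                 molecules: Dict[str, Molecule]):
        self.table = table
        self.molecules = molecules

    def propose(self, product: Molecule, top_n: int) -> List[SingleStepProposal]:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        entries = self.table.get(product.smiles, [])
        props = []
        for prec_smiles, score, rid in entries:
            precursors = tuple(sorted(self.molecules[s] for s in prec_smiles))
            if any(p == product for p in precursors):
                continue
            props.append(SingleStepProposal(precursors=precursors, score=score,
                                            template_id=rid))
        return _sort_proposals(props)[:top_n]
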