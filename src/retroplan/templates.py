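"""Named-reaction retro-templates (SMIRKS) and their application.

A retro-template is a SMIRKS transformation written in the retrosynthetic
direction, ``product >> reactant(s)``, with one product pattern on the left
and one or two reactant patterns on the right.  The same string, with its
sides swapped, is the forward transformation — every shipped template is
valid in both directions, which is what makes the round-trip property
(forward o retro recovers the product) testable.

The shipped library is a representative set of general medicinal-chemistry
transformations (couplings, alkylations, protections, reductions, ...) in a
diff-friendly TSV; users extend it by appending rows.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import rdChemReactions

from .core import canonicalize

ReactantSet = Tuple[str, ...]  # canonical SMILES, in template reactant-pattern order


class TemplateError(ValueError):
    """Raised for malformed template files or SMIRKS."""


def _reverse_smirks(smirks: str) -> str:
    lhs, rhs = smirks.split(">>")
    return f"{rhs}>>{lhs}"


@dataclass
class RetroTemplate:
    """A named reaction transformation applied retrosynthetically."""

    template_id: str
    reaction_name: str
    smirks: str
    n_reactants: int
    classifier_id: Optional[str] = None

    _retro_rxn: rdChemReactions.ChemicalReaction = field(
        init=False, repr=False, compare=False, default=None
    )
    _forward_rxn: rdChemReactions.ChemicalReaction = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        if self.n_reactants not in (1, 2):
            raise TemplateError(
                f"template {self.template_id}: n_reactants must be 1 or 2, "
                f"got {self.n_reactants}"
            )
        if ">>" not in self.smirks:
            raise TemplateError(f"template {self.template_id}: not a transformation")
        try:
            retro = rdChemReactions.ReactionFromSmarts(self.smirks)
            forward = rdChemReactions.ReactionFromSmarts(_reverse_smirks(self.smirks))
        except Exception as exc:  # rdkit raises bare RuntimeError on bad SMARTS
            raise TemplateError(
                f"template {self.template_id}: SMIRKS does not parse: {exc}"
            ) from exc
        if retro is None or forward is None:
            raise TemplateError(f"template {self.template_id}: SMIRKS does not parse")
        if retro.GetNumReactantTemplates() != 1:
            raise TemplateError(
                f"template {self.template_id}: retro side must have exactly one "
                "product pattern"
            )
        if retro.GetNumProductTemplates() != self.n_reactants:
            raise TemplateError(
                f"template {self.template_id}: SMIRKS has "
                f"{retro.GetNumProductTemplates()} reactant pattern(s) but "
                f"n_reactants={self.n_reactants}"
            )
        self._retro_rxn = retro
        self._forward_rxn = forward

    @property
    def product_pattern(self) -> Chem.Mol:
        return self._retro_rxn.GetReactantTemplate(0)

    def matches(self, product_smiles: str) -> bool:
        """True iff the product pattern substructure-matches the molecule."""
        mol = Chem.MolFromSmiles(product_smiles)
        if mol is None:
            return False
        return mol.HasSubstructMatch(self.product_pattern)


def _run_reaction(
    rxn: rdChemReactions.ChemicalReaction, mols: Sequence[Chem.Mol]
) -> List[Tuple[str, ...]]:
    """Run an RDKit reaction, sanitize outputs, return canonical tuples in order."""
    results: List[Tuple[str, ...]] = []
    seen = set()
    try:
        product_sets = rxn.RunReactants(tuple(mols))
    except Exception:
        return results
    for prods in product_sets:
        smis = []
        for p in prods:
            try:
                Chem.SanitizeMol(p)
            except Exception:
                break
            smis.append(Chem.MolToSmiles(p))
        else:
            tup = tuple(smis)
            if tup not in seen:
                seen.add(tup)
                results.append(tup)
    return results


def apply_retro(template: RetroTemplate, product_smiles: str) -> List[ReactantSet]:
    """One-step retrosynthesis: all distinct reactant sets for ``product_smiles``.

    Each distinct substructure match of the product pattern yields one
    reactant set; sets identical as canonical multisets are deduplicated.
    Unsanitizable reactant structures are discarded.  A non-matching product
    gives an empty list (not an error).  Order is deterministic (RDKit match
    order, first occurrence kept).
    """
    mol = Chem.MolFromSmiles(canonicalize(product_smiles))
    if mol is None:
        return []
    out: List[ReactantSet] = []
    seen_multisets = set()
    for rset in _run_reaction(template._retro_rxn, (mol,)):
        key = tuple(sorted(rset))
        if key not in seen_multisets:
            seen_multisets.add(key)
            out.append(rset)
    return out


def apply_forward(template: RetroTemplate, reactants: Sequence[str]) -> List[str]:
    """Forward application: all products obtainable from ``reactants``.

    ``reactants`` must match the template arity and be given in the
    template's reactant-pattern order.
    """
    if len(reactants) != template.n_reactants:
        raise TemplateError(
            f"template {template.template_id} expects {template.n_reactants} "
            f"reactant(s), got {len(reactants)}"
        )
    mols = []
    for smi in reactants:
        m = Chem.MolFromSmiles(smi)
        if m is None:
            raise TemplateError(f"unparsable reactant SMILES: {smi!r}")
        mols.append(m)
    out: List[str] = []
    seen = set()
    for ptup in _run_reaction(template._forward_rxn, mols):
        for psmi in ptup:
            if psmi not in seen:
                seen.add(psmi)
                out.append(psmi)
    return out


class TemplateLibrary:
    """An ordered, validated collection of retro-templates."""

    def __init__(self, templates: Iterable[RetroTemplate] = ()) -> None:
        self._templates: List[RetroTemplate] = []
        self._by_id = {}
        for t in templates:
            self.add(t)

    def add(self, template: RetroTemplate) -> None:
        if template.template_id in self._by_id:
            raise TemplateError(f"duplicate template_id {template.template_id}")
        self._by_id[template.template_id] = template
        self._templates.append(template)

    def __len__(self) -> int:
        return len(self._templates)

    def __iter__(self):
        return iter(self._templates)

    def __getitem__(self, template_id: str) -> RetroTemplate:
        return self._by_id[template_id]

    def __contains__(self, template_id: str) -> bool:
        return template_id in self._by_id

    def applicable(self, product_smiles: str) -> List[RetroTemplate]:
        """Templates whose product pattern matches the molecule, in file order."""
        return [t for t in self._templates if t.matches(product_smiles)]


def applicable_templates(
    library: TemplateLibrary, product_smiles: str
) -> List[RetroTemplate]:
    return library.applicable(product_smiles)


def load_templates(path) -> TemplateLibrary:
    """Load and validate a template TSV (template_id, reaction_name, smirks, n_reactants)."""
    path = Path(path)
    lib = TemplateLibrary()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"template_id", "reaction_name", "smirks", "n_reactants"}
        if reader.fieldnames is None:
            return lib
        missing = required - set(reader.fieldnames)
        if missing:
            raise TemplateError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            try:
                n = int(row["n_reactants"])
            except (TypeError, ValueError):
                raise TemplateError(
                    f"{path}: template {row.get('template_id')}: bad n_reactants "
                    f"{row.get('n_reactants')!r}"
                ) from None
            lib.add(
                RetroTemplate(
                    template_id=row["template_id"],
                    reaction_name=row["reaction_name"],
                    smirks=row["smirks"],
                    n_reactants=n,
                )
            )
    return lib


def default_template_path() -> Path:
    """Path of the shipped template library."""
    return Path(resources.files("retroplan.data") / "templates.tsv")


def load_default_templates() -> TemplateLibrary:
    return load_templates(default_template_path())
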