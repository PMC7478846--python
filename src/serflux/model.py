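"""Constraint-based metabolic model container, GPR logic, and model edits.

The model container is deliberately minimal: a stoichiometric network with
flux bounds, boolean gene-protein-reaction (GPR) rules and a single objective
reaction (biomass).  Sign convention throughout: for exchange reactions a
negative flux is uptake into the cell and a positive flux is secretion, so
user-facing uptake magnitudes are nonnegative and converted internally.

Two dialects are supported: SBML Level 3 with the FBC package (the format
genome-scale models such as yeast-GEM are distributed in) and a small JSON
dialect for toy networks used in testing and teaching.
"""

from __future__ import annotations

import copy as _copy
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumDefinition",
    "GprExpression",
    "ModelError",
    "GprParseError",
    "parse_gpr",
    "load_model",
    "write_model",
    "apply_gene_deletions",
    "apply_medium",
    "set_exchange_bound",
    "load_medium",
    "genotype_deletions",
    "SEY6210_DELETIONS",
]


class ModelError(ValueError):
    """Raised for malformed or inconsistent metabolic models."""


class GprParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprExpression:
    """Boolean tree over gene ids.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"true"`` (the empty
    rule, unconditionally available).  Evaluation against a set of *deleted*
    genes is deterministic: a gene node is true iff its gene is not deleted.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = ()

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        if self.op == "true":
            return True
        if self.op == "gene":
            return self.gene not in deleted
        values = (c.evaluate(deleted) for c in self.children)
        return all(values) if self.op == "and" else any(values)

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_text(self) -> str:
        if self.op == "true":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            t = c.to_text()
            if c.op in ("and", "or") and c.op != self.op:
                t = f"({t})"
            parts.append(t)
        return sep.join(parts)


GPR_TRUE = GprExpression("true")


def _tokenize_gpr(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append((low, word, i))
        elif low in ("&", "&&"):
            tokens.append(("and", word, i))
        elif low in ("|", "||"):
            tokens.append(("or", word, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string into a boolean expression tree.

    Accepts gene ids, ``and`` / ``or`` (case-insensitive, also ``&``/``|``)
    and parentheses.  The empty string parses to the always-true expression.
    ``and`` binds tighter than ``or``.
    """
    tokens = _tokenize_gpr(text or "")
    if not tokens:
        return GPR_TRUE
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GprExpression:
        nonlocal pos
        node = parse_and()
        children = [node]
        while (tk := peek()) is not None and tk[0] == "or":
            pos += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else GprExpression("or", children=tuple(children))

    def parse_and() -> GprExpression:
        nonlocal pos
        node = parse_atom()
        children = [node]
        while (tk := peek()) is not None and tk[0] == "and":
            pos += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else GprExpression("and", children=tuple(children))

    def parse_atom() -> GprExpression:
        nonlocal pos
        tk = peek()
        if tk is None:
            raise GprParseError("unexpected end of rule", len(text))
        kind, word, at = tk
        if kind == "gene":
            pos += 1
            return GprExpression("gene", gene=word)
        if kind == "paren" and word == "(":
            pos += 1
            node = parse_or()
            tk2 = peek()
            if tk2 is None or tk2[1] != ")":
                raise GprParseError("unbalanced parentheses", at)
            pos += 1
            return node
        raise GprParseError(f"unexpected token {word!r}", at)

    expr = parse_or()
    if pos < len(tokens):
        raise GprParseError(f"stray token {tokens[pos][1]!r}", tokens[pos][2])
    return expr


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A reaction with stoichiometry (negative coefficient = consumed),
    flux bounds in mmol·gDW⁻¹·h⁻¹ and an optional GPR rule."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GprExpression = GPR_TRUE
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            name=self.name,
        )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: set[str]
    objective_reaction: str

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: r for r in self.reactions}
        self._met_index = {m.id: m for m in self.metabolites}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise ModelError(f"unknown reaction id {rid!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_index[mid]
        except KeyError:
            raise ModelError(f"unknown metabolite id {mid!r}") from None

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            objective_reaction=self.objective_reaction,
        )

    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            if not r.stoichiometry:
                raise ModelError(f"reaction {r.id!r} has empty stoichiometry")
            for mid in r.stoichiometry:
                if mid not in met_ids:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelError(
                    f"reaction {r.id!r} has lower bound {r.lower_bound} > "
                    f"upper bound {r.upper_bound}"
                )
            unknown = r.gpr.genes() - self.genes
            if unknown:
                raise ModelError(
                    f"reaction {r.id!r} GPR references genes not in the gene "
                    f"set: {sorted(unknown)}"
                )
        if self.objective_reaction not in self._rxn_index:
            raise ModelError(
                f"objective reaction {self.objective_reaction!r} is not in the model"
            )


@dataclass(frozen=True)
class MediumDefinition:
    """Named growth medium: maximum uptake rate per exchange reaction.

    Bounds are nonnegative magnitudes in mmol·gDW⁻¹·h⁻¹; applying the medium
    sets each listed exchange's lower bound to minus the magnitude.
    """

    name: str
    uptake_bounds: Mapping[str, float]

    def __post_init__(self) -> None:
        for ex, b in self.uptake_bounds.items():
            if b < 0 or not math.isfinite(b):
                raise ModelError(f"medium {self.name!r}: bound for {ex!r} must be >= 0")


# ---------------------------------------------------------------------------
# IO: toy JSON dialect
# ---------------------------------------------------------------------------


def _model_from_toy_json(doc: dict) -> MetabolicModel:
    mets: list[Metabolite] = []
    for m in doc.get("metabolites", []):
        if isinstance(m, str):
            mets.append(Metabolite(id=m))
        else:
            mets.append(
                Metabolite(
                    id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "")
                )
            )
    rxns: list[Reaction] = []
    genes: set[str] = set()
    for r in doc.get("reactions", []):
        try:
            gpr = parse_gpr(r.get("gpr", ""))
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r["lb"]),
                upper_bound=float(r["ub"]),
                gpr=gpr,
                name=r.get("name", ""),
            )
        except KeyError as e:
            raise ModelError(f"reaction entry missing field {e} in {r!r}") from None
        genes |= gpr.genes()
        rxns.append(rxn)
    if "objective" not in doc:
        raise ModelError("toy-json model is missing an 'objective' entry")
    genes |= set(doc.get("genes", []))
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes, objective_reaction=doc["objective"]
    )
    model.validate()
    return model


def _model_to_toy_json(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr.to_text(),
                "name": r.name,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_reaction,
    }


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the toy JSON dialect (round-trips with load_model)."""
    Path(path).write_text(json.dumps(_model_to_toy_json(model), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# IO: SBML Level 3 + FBC
# ---------------------------------------------------------------------------


def _gpr_from_fbc_association(assoc) -> GprExpression:
    import libsbml

    if assoc is None:
        return GPR_TRUE
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return GprExpression("gene", gene=assoc.getGeneProduct())
    if code == libsbml.SBML_FBC_AND:
        children = tuple(
            _gpr_from_fbc_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        return GprExpression("and", children=children)
    if code == libsbml.SBML_FBC_OR:
        children = tuple(
            _gpr_from_fbc_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        return GprExpression("or", children=children)
    raise ModelError(f"unsupported FBC association element (type code {code})")


def _model_from_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(f"SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelError("SBML file contains no model element")
    fbc = sm.getPlugin("fbc")

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    mets = [
        Metabolite(
            id=sp.getId(),
            name=sp.getName(),
            compartment=sp.getCompartment(),
        )
        for sp in (sm.getSpecies(i) for i in range(sm.getNumSpecies()))
        if not sp.getBoundaryCondition()
    ]
    internal = {m.id for m in mets}

    rxns: list[Reaction] = []
    genes: set[str] = set()
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in internal:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in internal:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rfbc = sr.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = params[rfbc.getLowerFluxBound()]
            ub = params[rfbc.getUpperFluxBound()]
        else:
            lb = -1000.0 if sr.getReversible() else 0.0
            ub = 1000.0
        gpr = GPR_TRUE
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            gpr = _gpr_from_fbc_association(rfbc.getGeneProductAssociation().getAssociation())
        genes |= gpr.genes()
        rxns.append(
            Reaction(
                id=sr.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                name=sr.getName(),
            )
        )

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = obj.getFluxObjective(0).getReaction()
    if objective is None:
        raise ModelError("SBML model has no FBC objective (biomass) reaction")

    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            genes.add(fbc.getGeneProduct(i).getIdAttribute())

    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes, objective_reaction=objective
    )
    model.validate()
    return model


def load_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load and validate a metabolic model.

    Parameters
    ----------
    path : file path
    dialect : ``"sbml-fbc"`` or ``"toy-json"``; inferred from the file
        extension (``.xml``/``.sbml`` vs ``.json``) when omitted.

    Exchange reactions are auto-detected as single-metabolite boundary
    reactions; they are not stored separately but exposed through
    :attr:`MetabolicModel.exchange_reactions`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "sbml-fbc" if path.suffix.lower() in (".xml", ".sbml") else "toy-json"
    if dialect == "sbml-fbc":
        return _model_from_sbml(path)
    if dialect == "toy-json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ModelError(f"malformed toy-json model: {e}") from None
        return _model_from_toy_json(doc)
    raise ValueError(f"unknown model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Model edits
# ---------------------------------------------------------------------------


def apply_gene_deletions(model: MetabolicModel, deleted: Iterable[str]) -> MetabolicModel:
    """Knock out reactions whose GPR evaluates false under the deletions.

    Returns a copy; every reaction whose rule is unsatisfiable with the given
    genes removed has both bounds set to zero, all other bounds are untouched.
    Deleting a gene unknown to the model warns and is otherwise a no-op.
    """
    deleted = frozenset(deleted)
    unknown = deleted - model.genes
    if unknown:
        warnings.warn(
            f"deleted genes not present in the model: {sorted(unknown)}", stacklevel=2
        )
    out = model.copy()
    for r in out.reactions:
        if not r.gpr.evaluate(deleted):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def apply_medium(
    model: MetabolicModel, medium: MediumDefinition, closed_default: bool = True
) -> MetabolicModel:
    """Constrain exchange lower bounds to a growth medium.

    For each exchange listed in the medium the lower bound becomes minus the
    uptake magnitude.  With ``closed_default`` every *unlisted* exchange has
    its lower bound raised to zero (no uptake); secretion upper bounds are
    never touched.  Idempotent for a fixed medium.
    """
    missing = [ex for ex in medium.uptake_bounds if not model.has_reaction(ex)]
    missing += [
        ex
        for ex in medium.uptake_bounds
        if model.has_reaction(ex) and not model.reaction(ex).is_exchange
    ]
    if missing:
        raise ModelError(f"medium {medium.name!r}: unresolvable exchange ids {missing}")
    out = model.copy()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        if r.id in medium.uptake_bounds:
            r.lower_bound = -float(medium.uptake_bounds[r.id])
        elif closed_default:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


def set_exchange_bound(
    model: MetabolicModel, exchange_id: str, uptake: float, mode: str = "fixed"
) -> MetabolicModel:
    """Set an exchange reaction's uptake.

    ``mode="fixed"`` pins the flux to exactly ``-uptake`` (both bounds);
    ``mode="max"`` only lowers the lower bound to ``-uptake``, leaving the
    upper bound untouched.  ``uptake`` is a nonnegative magnitude.
    """
    if uptake < 0:
        raise ValueError("uptake must be a nonnegative magnitude")
    rxn = model.reaction(exchange_id)
    if not rxn.is_exchange:
        raise ModelError(f"reaction {exchange_id!r} is not an exchange reaction")
    if mode not in ("fixed", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    out = model.copy()
    r = out.reaction(exchange_id)
    if mode == "fixed":
        r.lower_bound = -uptake
        r.upper_bound = -uptake
    else:
        r.lower_bound = -uptake
    return out


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------

#: Auxotrophy / marker deletions of the SEY6210 laboratory background.
SEY6210_DELETIONS = frozenset({"LEU2", "URA3", "HIS3", "TRP1", "LYS2", "SUC2"})

_GENOTYPES = {"sey6210": SEY6210_DELETIONS}


def genotype_deletions(name: str) -> frozenset[str]:
    """Named deletion-set presets (currently: ``sey6210``)."""
    try:
        return _GENOTYPES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown genotype preset {name!r}") from None


def load_medium(source: str | Path, name: str | None = None) -> MediumDefinition:
    """Load a medium from a YAML file mapping exchange ids to uptake bounds.

    The file holds either a flat ``{exchange_id: bound}`` mapping or named
    media ``{medium_name: {exchange_id: bound}}`` (pick one with ``name``).
    Shipped presets (``serflux/config/sdc.yaml``, ``ypd.yaml``) use editable
    placeholder exchange ids and the documented default bounds of
    1 mmol·gDW⁻¹·h⁻¹ per amino acid/nucleobase and 10 for glucose; edit the
    ids to match the loaded genome-scale model before applying.
    """
    doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, dict):
        raise ModelError(f"medium file {source} must be a mapping")
    if name is not None:
        if name not in doc:
            raise KeyError(f"medium {name!r} not found in {source}")
        doc = doc[name]
        return MediumDefinition(name=name, uptake_bounds={k: float(v) for k, v in doc.items()})
    if all(isinstance(v, (int, float)) for v in doc.values()):
        return MediumDefinition(
            name=Path(source).stem, uptake_bounds={k: float(v) for k, v in doc.items()}
        )
    raise ModelError("medium file holds multiple media; pass name=")
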