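"""Stoichiometric model data structures and I/O.

A :class:`MetabolicModel` is a plain in-memory container for a metabolic
network: metabolites with elemental formulas, reactions with flux bounds,
and a single linear objective.  Two on-disk dialects are supported:

* a COBRA-style JSON document (``metabolites`` / ``reactions`` lists with
  ``objective_coefficient`` markers), and
* a TSV reaction table (columns ``id``, ``equation``, ``lower_bound``,
  ``upper_bound``, ``subsystem``) whose equations use the
  ``"a A + b B -> c C"`` / ``"<=>"`` syntax.

All fluxes are in mmol/gDW/h throughout; no unit handling happens here.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

ELEMENTS = ("C", "H", "O", "N", "P", "S")

#: default bounds for irreversible / reversible reactions
IRREVERSIBLE_BOUNDS = (0.0, 1000.0)
REVERSIBLE_BOUNDS = (-1000.0, 1000.0)

COMPARTMENTS = ("cytosol", "mitochondrion", "peroxisome", "extracellular")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, bad bounds...)."""


class ModelParseError(ValueError):
    """An on-disk model file could not be parsed."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string (``"C4H6O5"``) into an element map."""
    if not text:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(text):
        if match.start() != pos:
            raise ModelParseError(f"malformed formula {text!r} at position {pos}")
        pos = match.end()
        element = match.group(1)
        n = int(match.group(2) or 1)
        if n < 0:
            raise ModelParseError(f"negative count in formula {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text):
        raise ModelParseError(f"malformed formula {text!r} at position {pos}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render an element map as a Hill-style string with C, H first."""
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    parts = []
    for element in order:
        n = counts.get(element, 0)
        if n == 0:
            continue
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            for element, n in self.formula.items():
                if not isinstance(n, int) or n < 0:
                    raise ModelValidationError(
                        f"metabolite {self.id}: formula count {element}={n} "
                        "must be a non-negative integer"
                    )


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoich: dict[str, float] = field(default_factory=dict)
    lower_bound: float = IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = IRREVERSIBLE_BOUNDS[1]
    subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.is_exchange and len(self.stoich) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id} must touch exactly one metabolite"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """Metabolites, reactions and one linear objective."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: tuple[str, str] | None = None  # (reaction id, "maximize"|"minimize")
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup helpers -------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_by_id[mid]
        except KeyError:
            raise KeyError(f"no metabolite {mid!r} in model {self.id}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_by_id[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.id}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_by_id

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- structure ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ModelValidationError(f"duplicate {label} id {i!r}")
                seen.add(i)
        self._met_by_id = {m.id: m for m in self.metabolites}
        self._rxn_by_id = {r.id: r for r in self.reactions}
        for rxn in self.reactions:
            for mid in rxn.stoich:
                if mid not in self._met_by_id:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {mid!r}"
                    )
        if self.objective is not None:
            rid, direction = self.objective
            if rid not in self._rxn_by_id:
                raise ModelValidationError(f"objective reaction {rid!r} not in model")
            if direction not in ("maximize", "minimize"):
                raise ModelValidationError(f"bad objective direction {direction!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m, formula=dict(m.formula) if m.formula else None)
                         for m in self.metabolites],
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            objective=self.objective,
            id=self.id,
        )

    def remove_reaction(self, rid: str) -> None:
        self.reaction(rid)
        self.reactions = [r for r in self.reactions if r.id != rid]
        if self.objective and self.objective[0] == rid:
            self.objective = None
        self.validate()


@dataclass
class FluxSolution:
    """Outcome of one LP solve over a model."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rid: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"solution has status {self.status!r}, no fluxes")
        return self.fluxes[rid]


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
    """Assemble S (metabolites x reactions) plus row/column index maps."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for rxn in model.reactions:
        j = rxn_index[rxn.id]
        for mid, coef in rxn.stoich.items():
            S[met_index[mid], j] = coef
    return S, met_index, rxn_index


# ---------------------------------------------------------------------------
# elemental balance
# ---------------------------------------------------------------------------

def validate_mass_balance(
    model: MetabolicModel, atol: float = 1e-9
) -> dict[str, dict[str, float]]:
    """Per-reaction element residuals for every unbalanced non-exchange reaction.

    Exchange reactions are exempt (they are the system boundary).  A missing
    formula on a metabolite used by a non-exchange reaction is an error: the
    balance of that reaction would be unknowable, not merely unbalanced.
    """
    report: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        residual = {e: 0.0 for e in ELEMENTS}
        for mid, coef in rxn.stoich.items():
            met = model.metabolite(mid)
            if met.formula is None:
                raise ModelValidationError(
                    f"metabolite {mid} (in reaction {rxn.id}) has no formula"
                )
            for element, n in met.formula.items():
                residual[element] = residual.get(element, 0.0) + coef * n
        nonzero = {e: v for e, v in residual.items() if abs(v) > atol}
        if nonzero:
            report[rxn.id] = nonzero
    return report


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_KNOWN_MET_KEYS = {"id", "name", "compartment", "formula", "charge"}
_KNOWN_RXN_KEYS = {
    "id", "name", "metabolites", "lower_bound", "upper_bound",
    "subsystem", "objective_coefficient", "is_exchange",
}


def _model_to_dict(model: MetabolicModel) -> dict:
    obj_rid, obj_dir = model.objective if model.objective else (None, "maximize")
    mets = []
    for met in sorted(model.metabolites, key=lambda m: m.id):
        entry: dict = {"id": met.id, "name": met.name, "compartment": met.compartment}
        if met.formula is not None:
            entry["formula"] = format_formula(met.formula)
        if met.charge is not None:
            entry["charge"] = met.charge
        mets.append(entry)
    rxns = []
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        entry = {
            "id": rxn.id,
            "name": rxn.name,
            "metabolites": {mid: rxn.stoich[mid] for mid in sorted(rxn.stoich)},
            "lower_bound": rxn.lower_bound,
            "upper_bound": rxn.upper_bound,
            "subsystem": rxn.subsystem,
            "is_exchange": rxn.is_exchange,
            "objective_coefficient": 1.0 if obj_rid == rxn.id else 0.0,
        }
        rxns.append(entry)
    return {
        "id": model.id,
        "metabolites": mets,
        "reactions": rxns,
        "objective_direction": obj_dir,
    }


def _model_from_dict(doc: dict, source: str = "<json>") -> MetabolicModel:
    if not isinstance(doc, dict) or "reactions" not in doc or "metabolites" not in doc:
        raise ModelParseError(f"{source}: not a model document "
                              "(missing 'metabolites'/'reactions')")
    metabolites = []
    for entry in doc["metabolites"]:
        unknown = set(entry) - _KNOWN_MET_KEYS
        if unknown:
            logger.warning("%s: metabolite %s: ignoring unknown keys %s",
                           source, entry.get("id"), sorted(unknown))
        formula = entry.get("formula")
        metabolites.append(Metabolite(
            id=entry["id"],
            name=entry.get("name", ""),
            compartment=entry.get("compartment", "cytosol"),
            formula=parse_formula(formula) if formula is not None else None,
            charge=entry.get("charge"),
        ))
    reactions = []
    objective: tuple[str, str] | None = None
    direction = doc.get("objective_direction", "maximize")
    for entry in doc["reactions"]:
        unknown = set(entry) - _KNOWN_RXN_KEYS
        if unknown:
            logger.warning("%s: reaction %s: ignoring unknown keys %s",
                           source, entry.get("id"), sorted(unknown))
        stoich = {k: float(v) for k, v in entry["metabolites"].items()}
        rxn = Reaction(
            id=entry["id"],
            name=entry.get("name", ""),
            stoich=stoich,
            lower_bound=float(entry.get("lower_bound", IRREVERSIBLE_BOUNDS[0])),
            upper_bound=float(entry.get("upper_bound", IRREVERSIBLE_BOUNDS[1])),
            subsystem=entry.get("subsystem", ""),
            is_exchange=bool(entry.get("is_exchange", len(stoich) == 1)),
        )
        reactions.append(rxn)
        if float(entry.get("objective_coefficient", 0.0)) != 0.0:
            objective = (rxn.id, direction)
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions,
        objective=objective, id=doc.get("id", "model"),
    )


# -- TSV reaction-table dialect ---------------------------------------------

_TSV_COLUMNS = ["id", "equation", "lower_bound", "upper_bound", "subsystem"]


def format_equation(rxn: Reaction) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in items:
            coef_txt = "" if coef == 1 else f"{repr(coef)} "
            parts.append(f"{coef_txt}{mid}")
        return " + ".join(parts)

    lhs = sorted((m, -c) for m, c in rxn.stoich.items() if c < 0)
    rhs = sorted((m, c) for m, c in rxn.stoich.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def parse_equation(text: str, rid: str = "?") -> dict[str, float]:
    for arrow in ("<=>", "<->", "-->", "->", "="):
        if arrow in text:
            lhs_txt, rhs_txt = text.split(arrow, 1)
            break
    else:
        raise ModelParseError(f"reaction {rid}: no arrow in equation {text!r}")
    stoich: dict[str, float] = {}

    def absorb(side_txt: str, sign: float) -> None:
        side_txt = side_txt.strip()
        if not side_txt:
            return
        for term in side_txt.split("+"):
            term = term.strip()
            if not term:
                raise ModelParseError(f"reaction {rid}: empty term in {text!r}")
            tokens = term.split()
            if len(tokens) == 1:
                coef, mid = 1.0, tokens[0]
            elif len(tokens) == 2:
                try:
                    coef = float(tokens[0])
                except ValueError:
                    raise ModelParseError(
                        f"reaction {rid}: bad coefficient {tokens[0]!r}") from None
                mid = tokens[1]
            else:
                raise ModelParseError(f"reaction {rid}: bad term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    absorb(lhs_txt, -1.0)
    absorb(rhs_txt, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}


_COMPARTMENT_SUFFIX = {"c": "cytosol", "m": "mitochondrion",
                       "p": "peroxisome", "e": "extracellular"}


def _compartment_from_id(mid: str) -> str:
    suffix = mid.rsplit("_", 1)[-1]
    return _COMPARTMENT_SUFFIX.get(suffix, "cytosol")


def _model_to_tsv(model: MetabolicModel) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        lines.append("\t".join([
            rxn.id, format_equation(rxn),
            repr(rxn.lower_bound), repr(rxn.upper_bound), rxn.subsystem,
        ]))
    return "\n".join(lines) + "\n"


def _model_from_tsv(text: str, source: str = "<tsv>") -> MetabolicModel:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ModelParseError(f"{source}: empty file")
    header = lines[0].split("\t")
    if header != _TSV_COLUMNS:
        raise ModelParseError(f"{source}: bad header {header!r}")
    reactions = []
    met_ids: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(_TSV_COLUMNS):
            raise ModelParseError(f"{source}:{lineno}: expected "
                                  f"{len(_TSV_COLUMNS)} columns, got {len(cells)}")
        rid, equation, lb, ub, subsystem = cells
        stoich = parse_equation(equation, rid)
        reactions.append(Reaction(
            id=rid, stoich=stoich,
            lower_bound=float(lb), upper_bound=float(ub),
            subsystem=subsystem, is_exchange=len(stoich) == 1,
        ))
        met_ids.update(stoich)
    metabolites = [Metabolite(id=mid, compartment=_compartment_from_id(mid))
                   for mid in sorted(met_ids)]
    return MetabolicModel(metabolites=metabolites, reactions=reactions)


# -- public I/O --------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "tsv"):
            raise ValueError(f"unknown model format {format!r}")
        return format
    return "tsv" if path.suffix.lower() in (".tsv", ".txt") else "json"


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from COBRA-style JSON or the TSV reaction table."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        if not text.strip():
            raise ModelParseError(f"{path}: empty file")
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_dict(doc, source=str(path))
    return _model_from_tsv(text, source=str(path))


def save_model(model: MetabolicModel, path: str | Path,
               format: str | None = None) -> None:
    """Write a model deterministically (ids sorted, repr-precision floats)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1,
                                   sort_keys=True) + "\n")
    else:
        path.write_text(_model_to_tsv(model))


def models_equal(a: MetabolicModel, b: MetabolicModel,
                 check_metabolite_metadata: bool = True) -> bool:
    """Field-wise equality of two models (order-insensitive)."""
    if sorted(a.metabolite_ids) != sorted(b.metabolite_ids):
        return False
    if sorted(a.reaction_ids) != sorted(b.reaction_ids):
        return False
    if check_metabolite_metadata:
        for mid in a.metabolite_ids:
            ma, mb = a.metabolite(mid), b.metabolite(mid)
            if (ma.compartment, ma.formula, ma.charge, ma.name) != \
                    (mb.compartment, mb.formula, mb.charge, mb.name):
                return False
    for rid in a.reaction_ids:
        ra, rb = a.reaction(rid), b.reaction(rid)
        if ra.stoich != rb.stoich:
            return False
        if (ra.lower_bound, ra.upper_bound, ra.subsystem, ra.is_exchange) != \
                (rb.lower_bound, rb.upper_bound, rb.subsystem, rb.is_exchange):
            return False
    return a.objective == b.objective
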