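"""Pathway scenarios: bound edits probing alternative flux routes.

Five named scenarios are analysed for each product:

* ``Ref``    - the unconstrained reference (methanol uptake 10 mmol/gDW/h,
  objective = product exchange; this shared setup underlies all scenarios),
* ``TCA-``   - circular TCA flux blocked (upper bound 0 on PDH, citrate
  synthase, citrate export, ATP-citrate lyase and AKG dehydrogenase),
* ``TCA+``   - flux forced into the circular TCA (lower bound on the AKG
  dehydrogenase at its maximum feasible flux),
* ``GlxStd`` - flux forced through the glyoxylate shunt (lower bound on
  isocitrate lyase at its maximum feasible flux),
* ``GlxVar`` - the glyoxylate forcing with mitochondrial MDH additionally
  restricted to its minimum feasible flux.

The forced bounds are calibrated on the model itself: the extreme
feasible flux of the aliased reaction is found by flux variability (no
objective fixing) and backed off by a relative slack of 1e-6 so the
forced model stays feasible.  The published full-model calibrations
(lower bound 7.8 for the AKG dehydrogenase, 10 for isocitrate lyase,
-10/2.85 for mitochondrial MDH) are model-specific vertices and are kept
only as reference metadata, never imposed on the core model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .fba import (
    InfeasibleModelError,
    compute_yield,
    flux_variability,
    solve_fba,
)
from .model import FluxSolution, MetabolicModel
from .network import (
    DEFAULT_UPTAKE,
    METHANOL_EXCHANGE,
    PRODUCTS,
    UNMAPPED,
    ProductTarget,
    ReactionAliasMap,
    reference_reaction_aliases,
)

logger = logging.getLogger(__name__)

SCENARIO_NAMES = ("Ref", "TCA-", "TCA+", "GlxStd", "GlxVar")

#: published full-model calibrations, reference metadata only (mmol/gDW/h)
REFERENCE_CALIBRATIONS = {"AKGDam": 7.8, "ICL": 10.0, "MDHm": (-10.0, 2.85)}

CALIBRATION_SLACK = 1e-6


class ScenarioConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BoundEdit:
    alias: str
    which: str  # "lower" | "upper" | "both"
    value: float | str  # number, "calibrate:max" or "calibrate:min"

    def __post_init__(self) -> None:
        if self.which not in ("lower", "upper", "both"):
            raise ScenarioConfigurationError(
                f"bad bound selector {self.which!r} for alias {self.alias}")
        if isinstance(self.value, str) and self.value not in (
                "calibrate:max", "calibrate:min"):
            raise ScenarioConfigurationError(
                f"bad edit value {self.value!r} for alias {self.alias}")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    edits: tuple[BoundEdit, ...] = ()
    description: str = ""


def default_scenarios() -> list[ScenarioSpec]:
    """The five scenario definitions bundled with the package."""
    with resources.files("methyloflux.data").joinpath("scenarios.yaml").open() as fh:
        return _parse_scenarios(yaml.safe_load(fh))


def load_scenarios(path: str | Path) -> list[ScenarioSpec]:
    """Read scenario definitions from a YAML/JSON config file."""
    with open(path) as fh:
        return _parse_scenarios(yaml.safe_load(fh))


def _parse_scenarios(doc: dict) -> list[ScenarioSpec]:
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ScenarioConfigurationError("config must contain a 'scenarios' list")
    specs = []
    for entry in doc["scenarios"]:
        edits = tuple(
            BoundEdit(alias=e["alias"], which=e["which"], value=e["value"])
            for e in entry.get("edits", [])
        )
        specs.append(ScenarioSpec(name=entry["name"], edits=edits,
                                  description=entry.get("description", "")))
    return specs


def calibrate_forced_bound(model: MetabolicModel, reaction: str,
                           direction: str) -> float:
    """Extreme feasible flux of a reaction, backed off by a small slack.

    ``direction="max"`` returns the maximum feasible flux minus a relative
    slack of 1e-6 (for use as a forcing lower bound); ``"min"`` returns the
    minimum plus the slack (for use as a restricting upper bound).
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    lo, hi = flux_variability(model, reaction, fix_objective_fraction=None)
    if direction == "max":
        return hi - CALIBRATION_SLACK * max(1.0, abs(hi))
    return lo + CALIBRATION_SLACK * max(1.0, abs(lo))


def apply_scenario(
    model: MetabolicModel,
    spec: ScenarioSpec,
    aliases: ReactionAliasMap | None = None,
    product: ProductTarget | str | None = None,
    uptake: float = DEFAULT_UPTAKE,
) -> MetabolicModel:
    """Return a copy of the model with the scenario's bound edits applied.

    The shared setup (methanol uptake, product objective) is applied first;
    calibrated edits are resolved sequentially on the partially edited
    model, so a later edit sees the forcings of earlier ones (as required
    by the variant glyoxylate scenario).
    """
    if aliases is None:
        aliases = reference_reaction_aliases(model)
    if isinstance(product, str):
        product = PRODUCTS[product]
    work = model.copy()
    meoh = work.reaction(METHANOL_EXCHANGE)
    meoh.lower_bound = -abs(uptake)
    if product is not None:
        work.reaction(product.exchange_reaction)
        work.objective = (product.exchange_reaction, "maximize")
    for edit in spec.edits:
        rid = aliases.resolve(edit.alias)
        if rid == UNMAPPED:
            raise ScenarioConfigurationError(
                f"scenario {spec.name}: alias {edit.alias!r} has no "
                "core-model analog")
        rxn = work.reaction(rid)
        if isinstance(edit.value, str):
            _kind, direction = edit.value.split(":")
            value = calibrate_forced_bound(work, rid, direction)
        else:
            value = float(edit.value)
        if edit.which in ("lower", "both"):
            rxn.lower_bound = value
        if edit.which in ("upper", "both"):
            rxn.upper_bound = value
        if rxn.lower_bound > rxn.upper_bound:
            raise ScenarioConfigurationError(
                f"scenario {spec.name}: edit on {rid} leaves lower bound "
                f"{rxn.lower_bound} above upper bound {rxn.upper_bound}")
    work.validate()
    return work


@dataclass
class YieldTable:
    """Product x scenario grid of molar yields with per-cell LP status."""

    yields: pd.DataFrame   # rows: products, columns: scenarios
    status: pd.DataFrame   # same shape, LP status strings
    solutions: dict[tuple[str, str], FluxSolution] = field(default_factory=dict)

    def to_markdown(self, printed_decimals: int = 2) -> str:
        """Markdown rendering of the yield grid (mol product / mol methanol)."""
        rows = [
            "| Yield (mol/mol) | " + " | ".join(self.yields.columns) + " |",
            "|---" * (len(self.yields.columns) + 1) + "|",
        ]
        for product, row in self.yields.iterrows():
            cells = [f"{v:.{printed_decimals}f}" for v in row]
            rows.append(f"| {product} | " + " | ".join(cells) + " |")
        return "\n".join(rows)


def run_scenario_matrix(
    model: MetabolicModel,
    products: Sequence[ProductTarget | str] | None = None,
    scenarios: Sequence[ScenarioSpec] | None = None,
    uptake: float = DEFAULT_UPTAKE,
) -> YieldTable:
    """Maximize each product under each scenario and collect molar yields.

    Infeasible cells are reported with yield 0 and a warning rather than
    silently dropped; with the shipped calibration slack every cell is
    feasible and forced scenarios reach an (effectively) zero optimum.
    """
    if products is None:
        products = list(PRODUCTS.values())
    products = [PRODUCTS[p] if isinstance(p, str) else p for p in products]
    if scenarios is None:
        scenarios = default_scenarios()
    aliases = reference_reaction_aliases(model)
    names = [s.name for s in scenarios]
    yields = pd.DataFrame(0.0, index=[p.name for p in products], columns=names)
    status = pd.DataFrame("", index=[p.name for p in products], columns=names)
    solutions: dict[tuple[str, str], FluxSolution] = {}
    for product in products:
        for spec in scenarios:
            constrained = apply_scenario(model, spec, aliases,
                                         product=product, uptake=uptake)
            sol = solve_fba(constrained)
            status.loc[product.name, spec.name] = sol.status
            if sol.optimal:
                yields.loc[product.name, spec.name] = compute_yield(
                    sol, product.exchange_reaction, METHANOL_EXCHANGE)
                solutions[(product.name, spec.name)] = sol
            else:
                warnings.warn(
                    f"scenario cell ({product.name}, {spec.name}) is "
                    f"{sol.status}; reporting yield 0", stacklevel=2)
    return YieldTable(yields=yields, status=status, solutions=solutions)
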