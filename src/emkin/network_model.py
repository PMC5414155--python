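"""Stoichiometric network container, I/O and core-model extraction.

The in-memory model is a plain dataclass triple (metabolites, reactions,
network) that mirrors the COBRA view of a metabolic network: a sparse
stoichiometric matrix S (rows = metabolites, columns = reactions), flux
bounds in mmol/gDW/h, optional gene-protein-reaction (GPR) boolean strings,
and the two maintenance parameters GAM (growth-associated, embedded in the
biomass reaction's ATP hydrolysis stoichiometry) and NGAM (non-growth
associated, imposed as a fixed flux on a dedicated ATP-maintenance
reaction).

Two dialects are supported on disk: COBRA-flavored SBML (through cobrapy /
libsbml) and an internal tab-separated reaction table with columns
``id, equation, lb, ub, gpr`` where equations use text arrows ``->`` /
``<=>`` and metabolite ids carry a compartment suffix such as ``glc(c)`` or
``nh4(e)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ImbalanceReport",
    "NetworkFormatError",
    "NetworkValidationError",
    "CoreExtractionError",
    "parse_formula",
    "load_network",
    "write_network",
    "check_balance",
    "extract_core",
]

DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class NetworkFormatError(ValueError):
    """A file could not be parsed under the requested dialect."""


class NetworkValidationError(ValueError):
    """The parsed network violates a structural invariant."""


class CoreExtractionError(ValueError):
    """Core extraction produced a biomass-infeasible subnetwork."""

    def __init__(self, message: str, blocked_precursors: Sequence[str] = ()):
        super().__init__(message)
        self.blocked_precursors = list(blocked_precursors)


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula string (e.g. ``C6H12O6``) into a count map."""
    if formula is None or formula == "":
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise NetworkFormatError(f"unparseable formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        n = float(num) if num else 1.0
        counts[element] = counts.get(element, 0.0) + n
    if pos != len(formula):
        raise NetworkFormatError(f"unparseable formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, float]) -> str:
    parts = []
    for element in sorted(counts):
        n = counts[element]
        if n == 0:
            continue
        if n == int(n):
            n = int(n)
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, float] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            raise NetworkValidationError(f"metabolite {self.id}: empty compartment")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """A boundary reaction: exactly one metabolite crosses the system edge."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str | None = None
    gam: float = 0.0  # mmol ATP/gDCW per gDCW of biomass, in the biomass column
    ngam: float = 0.0  # mmol ATP/gDCW/h, fixed on the maintenance reaction
    atp_maintenance_id: str | None = None

    def __post_init__(self) -> None:
        self.validate()
        if self.atp_maintenance_id is not None and self.ngam:
            rxn = self.reaction(self.atp_maintenance_id)
            rxn.lower_bound = self.ngam
            rxn.upper_bound = self.ngam

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index()[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index()[rxn_id]

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise NetworkValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise NetworkValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        known = set(met_ids)
        for rxn in self.reactions:
            dangling = set(rxn.stoichiometry) - known
            if dangling:
                raise NetworkValidationError(
                    f"reaction {rxn.id} references unknown metabolites "
                    f"{sorted(dangling)}"
                )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in set(
            rxn_ids
        ):
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in network"
            )

    # -- numerics ----------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with rows ordered like ``metabolites`` and columns like
        ``reactions``."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=[replace(m, formula=dict(m.formula) if m.formula else None)
                         for m in self.metabolites],
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry))
                       for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            gam=self.gam,
            ngam=self.ngam,
            atp_maintenance_id=self.atp_maintenance_id,
        )


# ---------------------------------------------------------------------------
# Internal reaction-table dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "->", "=>")
_TERM = re.compile(r"^(?:(\d*\.?\d+(?:[eE][+-]?\d+)?)\s+)?(\S+)$")


def _parse_side(text: str, sign: float, stoich: dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _TERM.match(term)
        if m is None:
            raise NetworkFormatError(f"unparseable equation term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coeff


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``a + 2 b -> c`` style text into a stoichiometry map.

    Returns the map and whether the arrow was the reversible ``<=>``.
    """
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            stoich: dict[str, float] = {}
            _parse_side(left, -1.0, stoich)
            _parse_side(right, +1.0, stoich)
            stoich = {k: v for k, v in stoich.items() if v != 0}
            return stoich, arrow in ("<=>", "<->")
    raise NetworkFormatError(f"no reaction arrow found in equation {equation!r}")


def format_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    def side(items: Iterable[tuple[str, float]]) -> str:
        parts = []
        for met, coeff in items:
            coeff = abs(coeff)
            parts.append(met if coeff == 1 else f"{coeff:g} {met}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in stoich.items() if c < 0]
    prods = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}"


def _compartment_of(met_id: str) -> str:
    m = re.search(r"\(([a-z])\)$", met_id)
    return m.group(1) if m else "c"


def _load_reaction_table(path: Path) -> MetabolicNetwork:
    try:
        table = pd.read_csv(path, sep="\t", dtype={"id": str, "equation": str,
                                                   "gpr": str}, comment="#")
    except Exception as exc:  # noqa: BLE001 - re-raise as a format error
        raise NetworkFormatError(f"cannot read reaction table {path}: {exc}") from exc
    required = {"id", "equation", "lb", "ub"}
    missing = required - set(table.columns)
    if missing:
        raise NetworkFormatError(
            f"reaction table {path} missing columns {sorted(missing)}"
        )
    reactions: list[Reaction] = []
    met_ids: dict[str, None] = {}
    for row in table.itertuples(index=False):
        try:
            stoich, _ = parse_equation(row.equation)
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"reaction {row.id}: {exc}") from exc
        gpr = getattr(row, "gpr", None)
        if isinstance(gpr, float) and np.isnan(gpr):
            gpr = None
        reactions.append(
            Reaction(str(row.id), stoich, float(row.lb), float(row.ub), gpr=gpr)
        )
        for met in stoich:
            met_ids.setdefault(met)
    metabolites = [
        Metabolite(met, compartment=_compartment_of(met)) for met in met_ids
    ]
    biomass = next((r.id for r in reactions if "biomass" in r.id.lower()), None)
    return MetabolicNetwork(metabolites, reactions, biomass_reaction_id=biomass)


def _write_reaction_table(path: Path, network: MetabolicNetwork) -> None:
    rows = [
        {
            "id": r.id,
            "equation": format_equation(r.stoichiometry, r.reversible),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "gpr": r.gpr if r.gpr is not None else "",
        }
        for r in network.reactions
    ]
    pd.DataFrame(rows, columns=["id", "equation", "lb", "ub", "gpr"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SBML dialect (COBRA flavor, via cobrapy)
# ---------------------------------------------------------------------------

def _from_cobra(model) -> MetabolicNetwork:
    metabolites = []
    for met in model.metabolites:
        formula = parse_formula(met.formula) if met.formula else None
        metabolites.append(
            Metabolite(
                met.id,
                name=met.name or "",
                compartment=met.compartment or "c",
                formula=formula,
                charge=met.charge,
            )
        )
    reactions = []
    for rxn in model.reactions:
        stoich = {m.id: coeff for m, coeff in rxn.metabolites.items()}
        gpr = rxn.gene_reaction_rule or None
        reactions.append(
            Reaction(rxn.id, stoich, rxn.lower_bound, rxn.upper_bound, gpr=gpr)
        )
    biomass = None
    try:
        objective_ids = [
            v.name for v in model.objective.variables if not v.name.endswith("_reverse")
        ]
    except Exception:  # noqa: BLE001 - objective introspection is best-effort
        objective_ids = []
    for rid in objective_ids:
        if rid in {r.id for r in reactions}:
            biomass = rid
            break
    if biomass is None:
        biomass = next(
            (r.id for r in reactions if "biomass" in r.id.lower()), None
        )
    return MetabolicNetwork(metabolites, reactions, biomass_reaction_id=biomass)


def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("emkin")
    cobra_mets = {}
    for met in network.metabolites:
        m = cobra.Metabolite(
            met.id,
            name=met.name,
            compartment=met.compartment,
            formula=format_formula(met.formula) if met.formula else None,
            charge=met.charge,
        )
        cobra_mets[met.id] = m
    for rxn in network.reactions:
        r = cobra.Reaction(rxn.id)
        model.add_reactions([r])
        r.add_metabolites({cobra_mets[m]: c for m, c in rxn.stoichiometry.items()})
        r.bounds = (rxn.lower_bound, rxn.upper_bound)
        if rxn.gpr:
            r.gene_reaction_rule = rxn.gpr
    if network.biomass_reaction_id:
        model.objective = network.biomass_reaction_id
    return model


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    return "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "reaction-table"


def load_network(path: str | Path, dialect: str | None = None) -> MetabolicNetwork:
    """Load a network from SBML or the internal TSV reaction table.

    Exchange reactions are recognized structurally (single-metabolite
    stoichiometry crossing the system boundary) rather than by id prefix.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        import cobra

        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # noqa: BLE001
            raise NetworkFormatError(f"cannot parse SBML {path}: {exc}") from exc
        return _from_cobra(model)
    if dialect == "reaction-table":
        return _load_reaction_table(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_network(
    path: str | Path, network: MetabolicNetwork, dialect: str | None = None
) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        import cobra

        cobra.io.write_sbml_model(_to_cobra(network), str(path))
    elif dialect == "reaction-table":
        _write_reaction_table(path, network)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Elemental / charge balance
# ---------------------------------------------------------------------------

@dataclass
class ImbalanceReport:
    reaction_id: str
    element_surplus: dict[str, float] = field(default_factory=dict)
    charge_surplus: float = 0.0
    skipped: bool = False  # exchange reactions are exempt
    unverifiable: list[str] = field(default_factory=list)  # metabolites w/o formula

    @property
    def balanced(self) -> bool:
        return (
            not self.skipped
            and not self.unverifiable
            and not self.element_surplus
            and self.charge_surplus == 0
        )

    @property
    def empty(self) -> bool:
        return not self.element_surplus and self.charge_surplus == 0

    def to_dict(self) -> dict:
        return {
            "reaction": self.reaction_id,
            "elements": dict(self.element_surplus),
            "charge": self.charge_surplus,
            "skipped": self.skipped,
            "unverifiable": list(self.unverifiable),
        }


def check_balance(
    reaction: Reaction,
    metabolite_info: Mapping[str, tuple[Mapping[str, float] | None, int | None]],
    tol: float = 1e-9,
) -> ImbalanceReport:
    """Per-element and charge surplus of a reaction (Σ coeff·formula).

    Exchange reactions move mass across the boundary by construction and are
    reported as skipped. Metabolites missing a formula make the reaction
    unverifiable (listed in the report) instead of raising.
    """
    report = ImbalanceReport(reaction.id)
    if reaction.is_exchange:
        report.skipped = True
        return report
    surplus: dict[str, float] = {}
    charge = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        formula, met_charge = metabolite_info.get(met_id, (None, None))
        if formula is None:
            report.unverifiable.append(met_id)
            continue
        for element, count in formula.items():
            surplus[element] = surplus.get(element, 0.0) + coeff * count
        charge += coeff * (met_charge or 0)
    report.element_surplus = {
        el: round(v, 12) for el, v in surplus.items() if abs(v) > tol
    }
    report.charge_surplus = charge if abs(charge) > tol else 0.0
    return report


def network_balance_report(network: MetabolicNetwork) -> list[ImbalanceReport]:
    info = {
        m.id: (m.formula, m.charge) for m in network.metabolites
    }
    return [check_balance(r, info) for r in network.reactions]


# ---------------------------------------------------------------------------
# Core extraction
# ---------------------------------------------------------------------------

def extract_core(
    network: MetabolicNetwork,
    keep_reactions: Sequence[str],
    lumping_rules: Sequence[tuple[Sequence[str], Reaction]] = (),
    check_biomass: bool = True,
    exchange_bound: float = DEFAULT_BOUND,
) -> MetabolicNetwork:
    """Carve the core subnetwork that scaffolds the kinetic layer.

    ``keep_reactions`` survive verbatim; each lumping rule replaces a group
    of removed reactions (typically parallel cofactor variants) with one
    replacement reaction. Metabolites orphaned by the cut are dropped, and
    metabolites that still occur in the core but lost all their other
    producers/consumers receive a reversible exchange so the core stays
    FBA-feasible.
    """
    rxn_index = network._rxn_index()
    missing = [r for r in keep_reactions if r not in rxn_index]
    if missing:
        raise NetworkValidationError(f"keep_reactions not in network: {missing}")
    removed_by_rule: set[str] = set()
    replacements: list[Reaction] = []
    for removed_ids, replacement in lumping_rules:
        for rid in removed_ids:
            if rid not in rxn_index:
                raise NetworkValidationError(f"lumping rule removes unknown {rid!r}")
            removed_by_rule.add(rid)
        replacements.append(replacement)

    kept = [rxn_index[r] for r in keep_reactions if r not in removed_by_rule]
    core_rxns = [replace(r, stoichiometry=dict(r.stoichiometry)) for r in kept]
    core_rxns.extend(replacements)

    kept_ids = {r.id for r in core_rxns}
    # lumped reactions are *replaced*, not cut: they do not define a boundary
    removed = [
        r
        for r in network.reactions
        if r.id not in kept_ids and r.id not in removed_by_rule
    ]

    used_mets: set[str] = set()
    for r in core_rxns:
        used_mets.update(r.stoichiometry)

    def _has_producer_and_consumer(met: str) -> bool:
        producer = consumer = False
        for r in core_rxns:
            coeff = r.stoichiometry.get(met)
            if coeff is None:
                continue
            if coeff > 0 and r.upper_bound > 0 or coeff < 0 and r.lower_bound < 0:
                producer = True
            if coeff < 0 and r.upper_bound > 0 or coeff > 0 and r.lower_bound < 0:
                consumer = True
            if producer and consumer:
                return True
        return False

    # boundary metabolites of the cut: still used by the core, lost their
    # only producers/consumers to removed reactions -> exchange them so the
    # core stays FBA-feasible; metabolites with both roles intact are left
    # alone (the cut then cannot change the optimum)
    has_exchange = {
        next(iter(r.stoichiometry)) for r in core_rxns if r.is_exchange
    }
    boundary: list[str] = []
    for r in removed:
        for met in r.stoichiometry:
            if (
                met in used_mets
                and met not in has_exchange
                and not _has_producer_and_consumer(met)
            ):
                boundary.append(met)
                has_exchange.add(met)
    for met in boundary:
        core_rxns.append(
            Reaction(
                f"EX_{met}",
                {met: -1.0},
                lower_bound=-exchange_bound,
                upper_bound=exchange_bound,
            )
        )

    metabolites = [
        replace(m, formula=dict(m.formula) if m.formula else None)
        for m in network.metabolites
        if m.id in used_mets
    ]
    biomass = (
        network.biomass_reaction_id
        if network.biomass_reaction_id in kept_ids
        else None
    )
    core = MetabolicNetwork(
        metabolites,
        core_rxns,
        biomass_reaction_id=biomass,
        gam=network.gam,
        ngam=network.ngam,
        atp_maintenance_id=(
            network.atp_maintenance_id
            if network.atp_maintenance_id in kept_ids
            else None
        ),
    )
    if check_biomass and biomass is not None:
        from .fba_core import fba  # deferred: fba_core depends on this module

        state = fba(core, biomass, sense="max")
        if state.status != "optimal" or state.objective_value <= 1e-9:
            blocked = _blocked_precursors(core, biomass)
            raise CoreExtractionError(
                "core network cannot produce biomass after extraction; "
                f"blocked precursors: {blocked}",
                blocked_precursors=blocked,
            )
    return core


def _blocked_precursors(network: MetabolicNetwork, biomass_id: str) -> list[str]:
    from .fba_core import fba

    blocked = []
    biomass = network.reaction(biomass_id)
    for met, coeff in biomass.stoichiometry.items():
        if coeff >= 0:
            continue
        probe = network.copy()
        probe.reactions.append(Reaction(f"__DM_{met}", {met: -1.0}, 0.0, DEFAULT_BOUND))
        state = fba(probe, f"__DM_{met}", sense="max")
        if state.status != "optimal" or state.objective_value <= 1e-9:
            blocked.append(met)
    return blocked
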