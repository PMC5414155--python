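"""Steady-state LP analysis: FBA, FVA, yield ranges, and elimination of
thermodynamically infeasible cycles (TICs).

A TIC is a closed set of internal reactions that can carry arbitrarily large
flux with all exchanges shut, violating energy conservation. Parallel
reactions that perform the same conversion with alternate cofactors (e.g.
several hydrogenases) are the typical culprits in fermentative networks.
Instead of deleting or restricting such reactions, the cycle constraint
implemented here bounds the absolute flux of every cycle member at a marker
metabolite ``i`` by the absolute net flux of all *non*-cycle reactions
involving that metabolite:

    | Σ_{j ∉ J_i^c} S_ij · v_j |  ≥  | v_{j*} |   for every j* in J_i^c.

With no hint about reaction directionality this is a disjunction on the
sign of the net term and is encoded as a MILP with one binary per marker
metabolite (big-M). When direction hints pin down the sign of every
non-cycle term the constraint collapses to a pure LP.

All LPs/MILPs are solved with HiGHS through :mod:`scipy.optimize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .network_model import MetabolicNetwork

__all__ = [
    "FluxState",
    "CycleSpec",
    "YieldRange",
    "FluxProblem",
    "InfeasibleError",
    "fba",
    "fva",
    "find_tics",
    "apply_cycle_constraint",
    "yield_range",
]

BIG_M = 1000.0  # mmol/gDW/h cap used both for unbounded fluxes and big-M rows
FEASIBILITY_TOL = 1e-9
FLUX_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """The LP/MILP was infeasible; ``binding`` names constraints implicated."""

    def __init__(self, message: str, binding: Sequence[str] = ()):
        super().__init__(message)
        self.binding = list(binding)


@dataclass
class FluxState:
    fluxes: dict[str, float]
    objective_id: str
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class CycleSpec:
    """The marker-metabolite sets feeding the cycle constraint.

    ``cycle_reactions[i]`` is the set J_i^c of alternate-cofactor reactions
    participating in the cycle marked by metabolite ``i``.
    """

    cycle_reactions: dict[str, list[str]]

    @property
    def marker_metabolites(self) -> list[str]:
        return list(self.cycle_reactions)

    def validate(self, network: MetabolicNetwork) -> None:
        for met, rxns in self.cycle_reactions.items():
            if not rxns:
                raise ValueError(f"empty cycle reaction set for marker {met!r}")
            network.metabolite(met)
            for rid in rxns:
                rxn = network.reaction(rid)
                if met not in rxn.stoichiometry:
                    raise ValueError(
                        f"cycle reaction {rid} does not involve marker {met}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "CycleSpec":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls({str(k): [str(r) for r in v] for k, v in data.items()})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as handle:
            yaml.safe_dump(self.cycle_reactions, handle)


@dataclass
class YieldRange:
    product_id: str
    substrate_id: str
    min_yield: float
    max_yield: float


@dataclass
class _Row:
    coeffs: dict[int, float]
    lb: float
    ub: float


class FluxProblem:
    """An LP/MILP over the flux cone of a network, with optional extra rows.

    Variables 0..n-1 are reaction fluxes in network order; auxiliary
    (possibly binary) variables may be appended by constraint builders.
    Bounds beyond ±``big_m`` are truncated and remembered in ``truncated``.
    """

    def __init__(self, network: MetabolicNetwork, big_m: float = BIG_M):
        self.network = network
        self.big_m = big_m
        self.rxn_ids = network.reaction_ids
        self.rxn_pos = {r: j for j, r in enumerate(self.rxn_ids)}
        self._S = csr_matrix(network.stoichiometric_matrix())
        lb, ub = network.bounds_arrays()
        self.truncated = [
            self.rxn_ids[j]
            for j in range(len(self.rxn_ids))
            if lb[j] < -big_m or ub[j] > big_m
        ]
        self.lb = np.clip(lb, -big_m, big_m)
        self.ub = np.clip(ub, -big_m, big_m)
        self.aux_lb: list[float] = []
        self.aux_ub: list[float] = []
        self.aux_integer: list[bool] = []
        self.rows: list[_Row] = []

    # -- construction ------------------------------------------------------
    @property
    def n_rxn(self) -> int:
        return len(self.rxn_ids)

    @property
    def n_var(self) -> int:
        return self.n_rxn + len(self.aux_lb)

    def add_aux(self, lb: float, ub: float, integer: bool = False) -> int:
        self.aux_lb.append(lb)
        self.aux_ub.append(ub)
        self.aux_integer.append(integer)
        return self.n_var - 1

    def add_row(self, coeffs: Mapping[int, float], lb: float, ub: float) -> None:
        self.rows.append(_Row(dict(coeffs), lb, ub))

    def set_bounds(self, rxn_id: str, lb: float, ub: float) -> None:
        j = self.rxn_pos[rxn_id]
        self.lb[j] = max(lb, -self.big_m)
        self.ub[j] = min(ub, self.big_m)
        if self.lb[j] > self.ub[j]:
            raise ValueError(
                f"contradictory bounds for {rxn_id}: [{lb}, {ub}] after clipping"
            )

    # -- solving -----------------------------------------------------------
    def _constraints(self):
        n = self.n_var
        S_full = csr_matrix(
            (self._S.data, self._S.indices, self._S.indptr),
            shape=(self._S.shape[0], n),
        )
        cons = [LinearConstraint(S_full, 0.0, 0.0)]
        if self.rows:
            data, indices, indptr = [], [], [0]
            lo, hi = [], []
            for row in self.rows:
                for j, c in row.coeffs.items():
                    indices.append(j)
                    data.append(c)
                indptr.append(len(indices))
                lo.append(row.lb)
                hi.append(row.ub)
            A = csr_matrix((data, indices, indptr), shape=(len(self.rows), n))
            cons.append(LinearConstraint(A, lo, hi))
        return cons

    def solve(
        self,
        objective: Mapping[str, float] | str,
        sense: str = "max",
        extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    ):
        if isinstance(objective, str):
            objective = {objective: 1.0}
        c = np.zeros(self.n_var)
        for rid, coef in objective.items():
            c[self.rxn_pos[rid]] = coef
        if sense == "max":
            c = -c
        elif sense != "min":
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        lv = np.concatenate([self.lb, np.array(self.aux_lb)])
        uv = np.concatenate([self.ub, np.array(self.aux_ub)])
        if extra_bounds:
            for rid, (blo, bhi) in extra_bounds.items():
                j = self.rxn_pos[rid]
                lv = lv.copy()
                uv = uv.copy()
                lv[j] = max(blo, -self.big_m)
                uv[j] = min(bhi, self.big_m)
        integrality = np.zeros(self.n_var)
        for k, is_int in enumerate(self.aux_integer):
            if is_int:
                integrality[self.n_rxn + k] = 1
        res = milp(
            c,
            constraints=self._constraints(),
            bounds=Bounds(lv, uv),
            integrality=integrality,
        )
        if res.status == 0:
            value = float(res.fun if sense == "min" else -res.fun)
            return "optimal", np.asarray(res.x), value
        if res.status == 2:
            return "infeasible", None, float("nan")
        if res.status == 3:
            return "unbounded", None, float("nan")
        return "infeasible", None, float("nan")

    def fba(
        self,
        objective: str,
        sense: str = "max",
        extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> FluxState:
        status, x, value = self.solve(objective, sense, extra_bounds)
        if status != "optimal":
            return FluxState({}, objective, float("nan"), status)
        fluxes = {
            rid: 0.0 if abs(x[j]) < FLUX_TOL else float(x[j])
            for rid, j in self.rxn_pos.items()
        }
        return FluxState(fluxes, objective, value, "optimal")

    def fva(
        self,
        target_reactions: Sequence[str] | None = None,
        fix_objective_fraction: float = 0.0,
        objective: str | None = None,
        extra_bounds: Mapping[str, tuple[float, float]] | None = None,
        keep_solutions: bool = False,
    ) -> dict[str, tuple[float, float]]:
        targets = list(target_reactions or self.rxn_ids)
        popped = None
        if fix_objective_fraction > 0:
            if objective is None:
                raise ValueError("fix_objective_fraction > 0 requires an objective")
            status, _, opt = self.solve(objective, "max", extra_bounds)
            if status != "optimal":
                raise InfeasibleError(
                    f"model {status} while fixing objective {objective}",
                    binding=[objective],
                )
            self.add_row(
                {self.rxn_pos[objective]: 1.0},
                fix_objective_fraction * opt,
                np.inf,
            )
            popped = self.rows[-1]
        ranges: dict[str, tuple[float, float]] = {}
        self._fva_solutions: dict[str, np.ndarray] = {}
        try:
            for rid in targets:
                lo_status, xlo, lo = self.solve(rid, "min", extra_bounds)
                hi_status, xhi, hi = self.solve(rid, "max", extra_bounds)
                if lo_status != "optimal" or hi_status != "optimal":
                    raise InfeasibleError(
                        f"FVA subproblem for {rid} was {lo_status}/{hi_status}",
                        binding=[rid],
                    )
                ranges[rid] = (lo, hi)
                if keep_solutions:
                    self._fva_solutions[rid] = (
                        xhi if abs(hi) >= abs(lo) else xlo
                    )
        finally:
            if popped is not None:
                self.rows.pop()
        return ranges


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def fba(
    network: MetabolicNetwork,
    objective: str,
    sense: str = "max",
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    cycle_spec: CycleSpec | None = None,
) -> FluxState:
    """LP optimum of a single flux subject to S·v = 0 and bounds."""
    problem = (
        apply_cycle_constraint(network, cycle_spec)
        if cycle_spec is not None
        else FluxProblem(network)
    )
    return problem.fba(objective, sense, extra_bounds)


def fva(
    network: MetabolicNetwork,
    target_reactions: Sequence[str] | None = None,
    fix_objective_fraction: float = 0.0,
    objective: str | None = None,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    cycle_spec: CycleSpec | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux min/max under shared constraints (two LPs each)."""
    problem = (
        apply_cycle_constraint(network, cycle_spec)
        if cycle_spec is not None
        else FluxProblem(network)
    )
    return problem.fva(
        target_reactions, fix_objective_fraction, objective, extra_bounds
    )


def _closed_exchange_problem(network: MetabolicNetwork) -> FluxProblem:
    problem = FluxProblem(network)
    for rxn in network.reactions:
        j = problem.rxn_pos[rxn.id]
        if rxn.is_exchange:
            problem.lb[j] = 0.0
            problem.ub[j] = 0.0
        else:
            # keep v = 0 feasible (e.g. fixed maintenance demands)
            problem.lb[j] = min(problem.lb[j], 0.0)
            problem.ub[j] = max(problem.ub[j], 0.0)
    return problem


def find_tics(
    network: MetabolicNetwork, tol: float = FLUX_TOL
) -> list[dict]:
    """Detect thermodynamically infeasible cycles.

    All exchanges are closed (bounds 0; positive demands relaxed so that the
    zero flux vector stays feasible) and an FVA is run: any internal
    reaction that can still carry flux belongs to a TIC. Participating
    reactions are grouped into cycles as connected components of the
    metabolite-sharing graph, and a consistent circulation (direction signs)
    is read off a feasible closed-exchange flux vector for each component.
    """
    problem = _closed_exchange_problem(network)
    internal = [r.id for r in network.reactions if not r.is_exchange]
    ranges = problem.fva(internal, keep_solutions=True)
    participating = [
        rid for rid, (lo, hi) in ranges.items() if max(abs(lo), abs(hi)) > tol
    ]
    if not participating:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(participating)
    part = set(participating)
    met_to_rxns: dict[str, list[str]] = {}
    for rid in participating:
        for met in network.reaction(rid).stoichiometry:
            met_to_rxns.setdefault(met, []).append(rid)
    for rxns in met_to_rxns.values():
        for a, b in zip(rxns, rxns[1:]):
            graph.add_edge(a, b)
    cycles = []
    for component in nx.connected_components(graph):
        comp = sorted(component & part)
        # a feasible circulation through this component, from the FVA argmax
        best = max(
            comp,
            key=lambda rid: max(abs(v) for v in ranges[rid]),
        )
        x = problem._fva_solutions[best]
        signs = {
            rid: int(np.sign(x[problem.rxn_pos[rid]]))
            if abs(x[problem.rxn_pos[rid]]) > tol
            else 0
            for rid in comp
        }
        cycles.append({"reactions": comp, "signs": signs})
    return cycles


def suggest_markers(network: MetabolicNetwork, cycles: Sequence[dict]) -> CycleSpec:
    """Heuristic marker choice: per cycle, the metabolite shared by every
    cycle reaction that appears in the fewest other reactions."""
    spec: dict[str, list[str]] = {}
    for cycle in cycles:
        rxns = cycle["reactions"]
        shared = None
        for rid in rxns:
            mets = set(network.reaction(rid).stoichiometry)
            shared = mets if shared is None else shared & mets
        if not shared:
            continue
        counts = {
            met: sum(
                1
                for r in network.reactions
                if met in r.stoichiometry and r.id not in rxns
            )
            for met in shared
        }
        marker = min(sorted(counts), key=lambda met: counts[met])
        spec[marker] = list(rxns)
    return CycleSpec(spec)


def apply_cycle_constraint(
    network: MetabolicNetwork,
    spec: CycleSpec | None,
    direction_hints: Mapping[str, int] | None = None,
    big_m: float = BIG_M,
) -> FluxProblem:
    """Build a flux problem carrying the TIC-elimination constraint.

    Returns a :class:`FluxProblem` whose ``fba``/``fva`` methods honor
    | Σ_{j∉J_i^c} S_ij v_j | ≥ |v_{j*}| for every cycle reaction j*. Pure LP
    when the sign of the non-cycle net term is deducible from direction
    hints (or from the model bounds); MILP with one binary per marker
    otherwise.
    """
    problem = FluxProblem(network, big_m=big_m)
    if direction_hints:
        for rid, sign in direction_hints.items():
            j = problem.rxn_pos[rid]
            if sign > 0:
                if problem.ub[j] < 0:
                    raise ValueError(f"hint +1 for {rid} contradicts bounds")
                problem.lb[j] = max(problem.lb[j], 0.0)
            elif sign < 0:
                if problem.lb[j] > 0:
                    raise ValueError(f"hint -1 for {rid} contradicts bounds")
                problem.ub[j] = min(problem.ub[j], 0.0)
    if spec is None or not spec.cycle_reactions:
        return problem
    spec.validate(network)
    S = network.stoichiometric_matrix()
    met_pos = {m: i for i, m in enumerate(network.metabolite_ids)}
    for marker, cycle_rxns in spec.cycle_reactions.items():
        i = met_pos[marker]
        cycle_set = set(cycle_rxns)
        term = {
            problem.rxn_pos[rid]: S[i, problem.rxn_pos[rid]]
            for rid in network.reaction_ids
            if rid not in cycle_set and S[i, problem.rxn_pos[rid]] != 0
        }
        sign = _net_term_sign(problem, term)
        if sign is not None:
            s = 1.0 if sign >= 0 else -1.0
            for rid in cycle_rxns:
                jstar = problem.rxn_pos[rid]
                for vsign in (+1.0, -1.0):
                    row = {j: s * c for j, c in term.items()}
                    row[jstar] = row.get(jstar, 0.0) - vsign
                    problem.add_row(row, 0.0, np.inf)
        else:
            w = problem.add_aux(0.0, big_m)
            y = problem.add_aux(0.0, 1.0, integer=True)
            # relaxation constant large enough to free either branch even
            # when |T| exceeds the per-flux cap
            relax = big_m * (1.0 + sum(abs(c) for c in term.values()))
            # w <= |T| via the disjunction on sign(T)
            row_pos = dict(term)
            row_pos[w] = -1.0  # T - w >= -relax*y  (y=0 picks the T>=0 branch)
            row_pos[y] = relax
            problem.add_row(row_pos, 0.0, np.inf)
            row_neg = {j: -c for j, c in term.items()}
            row_neg[w] = -1.0  # -T - w >= -relax*(1-y)
            row_neg[y] = -relax
            problem.add_row(row_neg, -relax, np.inf)
            for rid in cycle_rxns:
                jstar = problem.rxn_pos[rid]
                problem.add_row({w: 1.0, jstar: -1.0}, 0.0, np.inf)
                problem.add_row({w: 1.0, jstar: 1.0}, 0.0, np.inf)
    return problem


def _net_term_sign(problem: FluxProblem, term: Mapping[int, float]) -> int | None:
    """Sign of Σ S_ij v_j when deducible from variable bounds, else None."""
    signs = set()
    for j, coeff in term.items():
        lo = coeff * problem.lb[j]
        hi = coeff * problem.ub[j]
        lo, hi = min(lo, hi), max(lo, hi)
        if lo >= 0 and hi > 0:
            signs.add(+1)
        elif hi <= 0 and lo < 0:
            signs.add(-1)
        elif lo == hi == 0:
            continue
        else:
            return None
    if not signs:
        return +1
    if len(signs) > 1:
        return None
    return signs.pop()


def yield_range(
    network: MetabolicNetwork,
    product_exchange: str,
    substrate_exchange: str,
    measurement_bounds: Mapping[str, tuple[float, float]] | None = None,
    cycle_spec: CycleSpec | None = None,
) -> YieldRange:
    """Feasible [min, max] molar yield of a product per unit substrate.

    The substrate exchange is fixed at one unit of uptake (yields are
    invariant to this scaling under the LP), measurement bounds given as
    yields become flux bounds at that scale, and an FVA on the product
    exchange delivers the range.
    """
    problem = (
        apply_cycle_constraint(network, cycle_spec)
        if cycle_spec is not None
        else FluxProblem(network)
    )
    problem.set_bounds(substrate_exchange, -1.0, -1.0)
    bounds = dict(measurement_bounds or {})
    for rid, (lo, hi) in bounds.items():
        problem.set_bounds(rid, lo, hi)
    try:
        ranges = problem.fva([product_exchange])
    except InfeasibleError as exc:
        binding = _diagnose_measurements(
            network, product_exchange, substrate_exchange, bounds, cycle_spec
        )
        raise InfeasibleError(
            "measurement bounds are mass-imbalanced with the network; "
            f"relaxing any of {binding} restores feasibility",
            binding=binding,
        ) from exc
    lo, hi = ranges[product_exchange]
    return YieldRange(product_exchange, substrate_exchange, lo, hi)


def _diagnose_measurements(
    network, product_exchange, substrate_exchange, bounds, cycle_spec
) -> list[str]:
    binding = []
    for drop in bounds:
        reduced = {k: v for k, v in bounds.items() if k != drop}
        try:
            yield_range(
                network, product_exchange, substrate_exchange, reduced, cycle_spec
            )
            binding.append(drop)
        except InfeasibleError:
            continue
    return binding
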