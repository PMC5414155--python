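import itertools

import numpy as np
import pytest

from emkin.fba_core import (
    BIG_M,
    CycleSpec,
    FluxProblem,
    InfeasibleError,
    apply_cycle_constraint,
    fba,
    find_tics,
    fva,
    suggest_markers,
    yield_range,
)
from emkin.network_model import MetabolicNetwork, Metabolite, Reaction


def chain_network():
    mets = [Metabolite("a"), Metabolite("b")]
    rxns = [
        Reaction("EX_a", {"a": -1.0}, -1.0, 0.0),
        Reaction("R", {"a": -1.0, "b": 1.0}, 0.0, 10.0),
        Reaction("EX_b", {"b": -1.0}, 0.0, 10.0),
    ]
    return MetabolicNetwork(mets, rxns)


def branched_network():
    """Five reactions, rank-2 S: small enough for vertex enumeration."""
    mets = [Metabolite("a"), Metabolite("b")]
    rxns = [
        Reaction("EX_a", {"a": -1.0}, -3.0, 0.0),
        Reaction("R1", {"a": -1.0, "b": 1.0}, 0.0, 2.0),
        Reaction("R2", {"a": -1.0, "b": 1.0}, 0.0, 1.5),
        Reaction("WASTE", {"a": -1.0}, 0.0, 1.0),
        Reaction("EX_b", {"b": -1.0}, 0.0, 10.0),
    ]
    return MetabolicNetwork(mets, rxns)


def enumerate_vertices(network):
    """Brute-force extreme points of {v : S v = 0, l <= v <= u}.

    Every vertex has at least n - rank(S) variables at a bound; enumerate
    all such fixings and solve the remaining square system.
    """
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    vertices = []
    for fixed in itertools.combinations(range(n), n - rank):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < len(free):
            continue
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            if np.abs(S_free @ sol - rhs).max() > 1e-9:
                continue
            v = np.zeros(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(v)
    return vertices


class TestFBA:
    def test_linear_chain_optimum(self):
        state = fba(chain_network(), "EX_b", "max")
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(1.0)
        assert state.fluxes["R"] == pytest.approx(1.0)

    def test_matches_vertex_enumeration_oracle(self):
        net = branched_network()
        state = fba(net, "EX_b", "max")
        vertices = enumerate_vertices(net)
        assert vertices, "oracle produced no vertices"
        j = net.reaction_ids.index("EX_b")
        oracle = max(v[j] for v in vertices)
        assert state.objective_value == pytest.approx(oracle, abs=1e-9)

    def test_mass_balance_of_optimum(self):
        net = branched_network()
        state = fba(net, "EX_b", "max")
        S = net.stoichiometric_matrix()
        v = np.array([state.fluxes[r] for r in net.reaction_ids])
        assert np.abs(S @ v).max() < 1e-6

    def test_infeasible_status(self):
        net = chain_network()
        state = fba(net, "EX_b", "max", extra_bounds={"EX_b": (5.0, 10.0)})
        assert state.status == "infeasible"
        assert state.fluxes == {}

    def test_extra_bounds_override(self):
        state = fba(chain_network(), "EX_b", "max", extra_bounds={"R": (0.0, 0.25)})
        assert state.objective_value == pytest.approx(0.25)


class TestFVA:
    def test_fully_determined_network_min_equals_max(self):
        net = chain_network()
        net.reaction("EX_a").upper_bound = -1.0  # force uptake exactly 1
        ranges = fva(net)
        for rid, (lo, hi) in ranges.items():
            assert lo == pytest.approx(hi, abs=1e-9), rid

    def test_unconstrained_loop_hits_big_m(self):
        mets = [Metabolite("a"), Metabolite("b")]
        rxns = [
            Reaction("F", {"a": -1.0, "b": 1.0}, 0.0, np.inf),
            Reaction("B", {"b": -1.0, "a": 1.0}, 0.0, np.inf),
        ]
        net = MetabolicNetwork(mets, rxns)
        problem = FluxProblem(net)
        assert set(problem.truncated) == {"F", "B"}
        ranges = problem.fva()
        assert ranges["F"][1] == pytest.approx(BIG_M)
        assert ranges["B"][1] == pytest.approx(BIG_M)

    def test_monotone_under_bound_relaxation(self):
        net = branched_network()
        tight = fva(net, ["EX_b"])["EX_b"]
        net.reaction("R1").upper_bound = 3.0  # relax
        loose = fva(net, ["EX_b"])["EX_b"]
        assert loose[0] <= tight[0] + 1e-9
        assert loose[1] >= tight[1] - 1e-9

    def test_infeasible_measurement_constraints_diagnosed(self):
        net = branched_network()
        with pytest.raises(InfeasibleError) as excinfo:
            yield_range(
                net, "EX_b", "EX_a",
                measurement_bounds={"WASTE": (0.9, 1.0), "EX_b": (0.5, 1.0)},
            )
        assert excinfo.value.binding  # names at least one binding measurement


class TestTICs:
    def test_canonical_two_cycle(self):
        mets = [Metabolite("a"), Metabolite("b")]
        rxns = [
            Reaction("F", {"a": -1.0, "b": 1.0}, 0.0, 10.0),
            Reaction("B", {"b": -1.0, "a": 1.0}, 0.0, 10.0),
        ]
        net = MetabolicNetwork(mets, rxns)
        cycles = find_tics(net)
        assert len(cycles) == 1
        assert cycles[0]["reactions"] == ["B", "F"]
        assert cycles[0]["signs"] == {"B": 1, "F": 1}

    def test_loop_free_random_dags_are_clean(self):
        """50 random acyclic networks: no TIC is ever reported."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_met = int(rng.integers(4, 8))
            mets = [Metabolite(f"m{i}") for i in range(n_met)]
            rxns = [
                Reaction("EX_in", {"m0": -1.0}, -5.0, 0.0),
                Reaction("EX_out", {f"m{n_met-1}": -1.0}, 0.0, 5.0),
            ]
            k = 0
            for i in range(n_met - 1):
                for j in range(i + 1, n_met):
                    if rng.random() < 0.5:
                        rxns.append(
                            Reaction(
                                f"R{k}", {f"m{i}": -1.0, f"m{j}": 1.0}, 0.0, 5.0
                            )
                        )
                        k += 1
            if k == 0:
                continue
            net = MetabolicNetwork(mets, rxns)
            assert find_tics(net) == []

    def test_matches_closed_exchange_fva_definition(self, truth3):
        """The union of reported cycle reactions equals the set of reactions
        with nonzero closed-exchange FVA range (definitional equivalence)."""
        net = truth3.network
        from emkin.fba_core import _closed_exchange_problem

        problem = _closed_exchange_problem(net)
        internal = [r.id for r in net.reactions if not r.is_exchange]
        ranges = problem.fva(internal)
        by_fva = {
            rid for rid, (lo, hi) in ranges.items()
            if max(abs(lo), abs(hi)) > 1e-6
        }
        cycles = find_tics(net)
        by_tic = set().union(*[set(c["reactions"]) for c in cycles]) if cycles else set()
        assert by_tic == by_fva

    def test_planted_cofactor_pair_found_once(self, truth3):
        cycles = find_tics(truth3.network)
        assert len(cycles) == 1
        assert set(cycles[0]["reactions"]) == set(truth3.planted_tic)

    def test_marker_suggestion_involves_all_cycle_reactions(self, truth3):
        cycles = find_tics(truth3.network)
        spec = suggest_markers(truth3.network, cycles)
        assert spec.cycle_reactions
        for met, rxns in spec.cycle_reactions.items():
            for rid in rxns:
                assert met in truth3.network.reaction(rid).stoichiometry


def hydrogen_loop_network():
    """Two alternate-cofactor conversions sharing h2, plus an h2 exchange."""
    mets = [Metabolite("x"), Metabolite("y"), Metabolite("h2")]
    rxns = [
        Reaction("H1", {"x": -1.0, "y": 1.0, "h2": 1.0}, 0.0, 1000.0),
        Reaction("H2", {"y": -1.0, "h2": -1.0, "x": 1.0}, -1000.0, 1000.0),
        Reaction("EX_h2", {"h2": -1.0}, -1000.0, 1000.0),
        Reaction("EX_x", {"x": -1.0}, -1000.0, 1000.0),
        Reaction("EX_y", {"y": -1.0}, -1000.0, 1000.0),
    ]
    return MetabolicNetwork(mets, rxns)


class TestCycleConstraint:
    def test_empty_spec_is_noop(self):
        net = branched_network()
        plain = fva(net)
        constrained = apply_cycle_constraint(net, CycleSpec({})).fva()
        for rid in net.reaction_ids:
            assert constrained[rid] == pytest.approx(plain[rid], abs=1e-9)

    def test_hydrogen_loop_hand_lp(self):
        """Closed exchanges: the constraint zeroes the loop; open exchanges:
        both cofactor variants can still carry flux simultaneously."""
        net = hydrogen_loop_network()
        spec = CycleSpec({"h2": ["H1", "H2"]})
        # without the constraint the closed loop circulates freely
        closed_free = apply_cycle_constraint(net, None)
        for rid in ("EX_h2", "EX_x", "EX_y"):
            closed_free.set_bounds(rid, 0.0, 0.0)
        assert closed_free.fva(["H1"])["H1"][1] == pytest.approx(BIG_M)
        # with it the closed-exchange flux is pinned at zero
        closed = apply_cycle_constraint(net, spec)
        for rid in ("EX_h2", "EX_x", "EX_y"):
            closed.set_bounds(rid, 0.0, 0.0)
        ranges = closed.fva(["H1", "H2"])
        assert ranges["H1"] == pytest.approx((0.0, 0.0), abs=1e-6)
        assert ranges["H2"] == pytest.approx((0.0, 0.0), abs=1e-6)
        # open: both reactions active at once (H2 running in reverse, both
        # producing h2 that the exchange drains)
        open_problem = apply_cycle_constraint(net, spec)
        state = open_problem.fba(
            "H1", "max", extra_bounds={"H2": (-1000.0, -0.1), "EX_h2": (0.5, 1.0)}
        )
        assert state.status == "optimal"
        assert state.fluxes["H1"] > 0.05
        assert state.fluxes["H2"] <= -0.1

    def test_hint_contradicting_bounds_raises(self):
        net = hydrogen_loop_network()
        net.reaction("H1").upper_bound = 0.0
        net.reaction("H1").lower_bound = 0.0
        ok = apply_cycle_constraint(net, None, direction_hints={"H1": -1})
        assert ok is not None
        net.reaction("H1").lower_bound = 0.5
        net.reaction("H1").upper_bound = 1.0
        with pytest.raises(ValueError, match="contradicts"):
            apply_cycle_constraint(net, None, direction_hints={"H1": -1})

    @pytest.mark.parametrize("instance_seed", range(8))
    def test_lp_with_hints_equals_milp(self, instance_seed):
        """On random 8-reaction instances, fixing the directionality used by
        the MILP optimum and re-solving as an LP gives the same optimum."""
        rng = np.random.default_rng(100 + instance_seed)
        mets = [Metabolite(m) for m in ("p", "q", "h")]
        rxns = [
            Reaction("C1", {"p": -1.0, "h": 1.0}, 0.0, 10.0),
            Reaction("C2", {"h": -1.0, "p": 1.0}, -10.0, 10.0),
            Reaction("N1", {"q": -1.0, "h": 1.0}, 0.0, float(rng.uniform(1, 5))),
            Reaction("N2", {"h": -1.0, "q": 1.0}, 0.0, float(rng.uniform(1, 5))),
            Reaction("EX_p", {"p": -1.0}, -5.0, 5.0),
            Reaction("EX_q", {"q": -1.0}, -5.0, 5.0),
            Reaction("EX_h", {"h": -1.0}, float(rng.uniform(-5, -1)), 5.0),
            Reaction("S1", {"p": -1.0, "q": 1.0}, 0.0, float(rng.uniform(1, 5))),
        ]
        net = MetabolicNetwork(mets, rxns)
        spec = CycleSpec({"h": ["C1", "C2"]})
        objective = str(rng.choice(["C1", "N1", "EX_h", "S1"]))
        milp_state = apply_cycle_constraint(net, spec).fba(objective, "max")
        assert milp_state.status == "optimal"
        hints = {
            rid: (1 if milp_state.fluxes[rid] >= 0 else -1)
            for rid in net.reaction_ids
        }
        lp_state = apply_cycle_constraint(net, spec, direction_hints=hints).fba(
            objective, "max"
        )
        assert lp_state.status == "optimal"
        assert lp_state.objective_value == pytest.approx(
            milp_state.objective_value, abs=1e-6
        )

    def test_never_reduces_yield_on_loop_free_network(self):
        net = branched_network()
        spec = CycleSpec({"b": ["R2"]})  # R2 declared cyclic (it is not)
        plain = fba(net, "EX_b", "max").objective_value
        constrained = apply_cycle_constraint(net, spec).fba("EX_b", "max")
        # |T| at b from R1 covers R2's flux: optimum preserved
        assert constrained.objective_value == pytest.approx(plain, abs=1e-6)


class TestYieldRange:
    def test_stoichiometric_forcing(self):
        mets = [Metabolite("a"), Metabolite("b")]
        rxns = [
            Reaction("EX_a", {"a": -1.0}, -1.0, 0.0),
            Reaction("R", {"a": -1.0, "b": 2.0}, 0.0, 10.0),
            Reaction("WASTE", {"a": -1.0}, 0.0, 10.0),
            Reaction("EX_b", {"b": -1.0}, 0.0, 10.0),
        ]
        net = MetabolicNetwork(mets, rxns)
        yr = yield_range(net, "EX_b", "EX_a")
        # the product exchange can only drain what R makes: 2 per substrate
        assert yr.max_yield == pytest.approx(2.0)
        # min: the waste route lets all substrate bypass the product
        assert yr.min_yield == pytest.approx(0.0)

    def test_forced_chain_pins_min_and_max(self):
        mets = [Metabolite("a"), Metabolite("b")]
        rxns = [
            Reaction("EX_a", {"a": -1.0}, -1.0, 0.0),
            Reaction("R", {"a": -1.0, "b": 2.0}, 0.0, 10.0),
            Reaction("EX_b", {"b": -1.0}, 0.0, 10.0),
        ]
        net = MetabolicNetwork(mets, rxns)
        yr = yield_range(net, "EX_b", "EX_a")  # uptake fixed at 1 by the op
        assert (yr.min_yield, yr.max_yield) == pytest.approx((2.0, 2.0))

    def test_range_contains_fba_optimum_under_measurement_boxes(self, truth3):
        """Property: for random feasible measurement boxes, the FBA-optimal
        yield under the same box lies inside the reported range."""
        net = truth3.network
        rng = np.random.default_rng(7)
        products = ["EX_lac", "EX_etoh", "EX_ac"]
        checked = 0
        for _ in range(100):
            boxes = {}
            for rid in products:
                lo = float(rng.uniform(0.0, 0.4))
                hi = lo + float(rng.uniform(0.1, 1.0))
                if rng.random() < 0.7:
                    boxes[rid] = (lo, hi)
            target = str(rng.choice(products))
            boxes.pop(target, None)
            try:
                yr = yield_range(net, target, "EX_sub", boxes)
            except InfeasibleError:
                continue
            state = fba(
                net, target, "max",
                extra_bounds={**boxes, "EX_sub": (-1.0, -1.0)},
            )
            if state.status != "optimal":
                continue
            assert yr.min_yield - 1e-6 <= state.objective_value <= yr.max_yield + 1e-6
            checked += 1
        assert checked >= 30
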