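import numpy as np
import pytest
from scipy.optimize import brentq

from emkin.em_kinetics import (
    DecompositionError,
    _get_sim,
    anchored_parameter_set,
    apply_genotype,
    build_model,
    decompose,
    derive_km_kcat,
    reaction_forms,
    sample_ensemble,
    steady_state,
)
from emkin.fba_core import FluxState
from emkin.network_model import MetabolicNetwork, Metabolite, Reaction


def single_enzyme_network():
    mets = [Metabolite("a"), Metabolite("b")]
    rxns = [
        Reaction("EX_a", {"a": -1.0}, -10.0, 0.0),
        Reaction("CNV", {"a": -1.0, "b": 1.0}, -1000.0, 1000.0),
        Reaction("EX_b", {"b": -1.0}, 0.0, 10.0),
    ]
    net = MetabolicNetwork(mets, rxns)
    ref = FluxState(
        {"EX_a": -1.0, "CNV": 1.0, "EX_b": 1.0}, "EX_b", 1.0, "optimal"
    )
    return net, ref


class TestDecompose:
    def test_uni_uni_gives_three_steps(self):
        net, _ = single_enzyme_network()
        steps = [s for s in decompose(net) if s.parent_reaction == "CNV"]
        assert [s.kind for s in steps] == ["bind", "convert", "release"]

    def test_bi_bi_gives_five_steps(self):
        mets = [Metabolite(m) for m in "abcd"]
        net = MetabolicNetwork(
            mets,
            [Reaction("R", {"a": -1, "b": -1, "c": 1, "d": 1}, -10, 10)],
        )
        steps = decompose(net)
        assert len(steps) == 5
        assert [s.kind for s in steps] == [
            "bind", "bind", "convert", "release", "release",
        ]

    def test_competitive_inhibitor_adds_dead_end_step(self):
        net, _ = single_enzyme_network()
        base = [s for s in decompose(net) if s.parent_reaction == "CNV"]
        with_reg = [
            s
            for s in decompose(net, [("b", "CNV", "competitive")])
            if s.parent_reaction == "CNV"
        ]
        assert len(with_reg) == len(base) + 1
        assert with_reg[-1].kind == "regulatory"

    def test_oversized_reaction_rejected(self):
        mets = [Metabolite(f"m{i}") for i in range(6)]
        net = MetabolicNetwork(
            mets,
            [Reaction("BIG", {f"m{i}": -1.0 for i in range(5)} | {"m5": 1.0})],
        )
        with pytest.raises(DecompositionError, match="lump"):
            decompose(net)

    def test_enzyme_forms_count(self):
        net, _ = single_enzyme_network()
        steps = decompose(net)
        # uni-uni: free enzyme + substrate complex + product complex
        assert len(reaction_forms(steps, "CNV")) == 3


class TestSampling:
    def test_every_member_anchors_to_reference(self, truth3):
        members = sample_ensemble(
            truth3.templates, truth3.reference_flux, 25, seed=77
        )
        for member in members:
            model = build_model(
                truth3.network, truth3.templates, member,
                truth3.regulations, uptake_reaction="EX_sub",
            )
            state = steady_state(model)
            assert state.converged
            for rid, v in truth3.reference_flux.fluxes.items():
                assert state.fluxes[rid] == pytest.approx(v, abs=1e-8)

    def test_same_seed_is_bit_identical(self, truth3):
        a = sample_ensemble(truth3.templates, truth3.reference_flux, 3, seed=5)
        b = sample_ensemble(truth3.templates, truth3.reference_flux, 3, seed=5)
        for ma, mb in zip(a, b):
            assert ma.enzyme_fractions == mb.enzyme_fractions
            assert ma.rate_constants == mb.rate_constants
            assert ma.reversibilities == mb.reversibilities

    def test_fractions_sum_to_one(self, truth3):
        member = sample_ensemble(
            truth3.templates, truth3.reference_flux, 1, seed=9
        )[0]
        for rxn, fractions in member.enzyme_fractions.items():
            assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_json_round_trip(self, truth3, tmp_path):
        member = sample_ensemble(
            truth3.templates, truth3.reference_flux, 1, seed=3
        )[0]
        path = tmp_path / "params.json"
        member.to_json(path)
        from emkin.em_kinetics import ElementaryParameterSet

        back = ElementaryParameterSet.from_json(path)
        assert back.enzyme_fractions == member.enzyme_fractions
        assert back.rate_constants == {
            r: {i: tuple(v) for i, v in d.items()}
            for r, d in member.rate_constants.items()
        }


def mm_closed_form(k, etot, s):
    """Initial-rate Michaelis-Menten curve of the 3-step reversible
    mechanism E+S <-> ES <-> EP <-> E+P at P = 0 (King-Altman)."""
    k1, k_1 = k[0]
    k2, k_2 = k[1]
    k3, _ = k[2]
    denom = k2 + k_2 + k3
    vmax = k2 * k3 * etot / denom
    km = (k_1 * k_2 + k_1 * k3 + k2 * k3) / (k1 * denom)
    return vmax * s / (km + s), km, vmax


class TestMichaelisMenten:
    def test_ensemble_reproduces_closed_form_rate_curve(self):
        """500 sampled members of a single reversible enzyme: the lumped
        constants derived from the elementary chain match the closed-form
        initial-rate curve at ten substrate levels."""
        net, ref = single_enzyme_network()
        templates = decompose(net, reactions=["CNV"])
        members = sample_ensemble(templates, ref, 500, seed=123)
        s_grid = np.logspace(-2, 2, 10)
        for member in members[:: 1]:
            model = build_model(net, templates, member)
            k = [member.rate_constants["CNV"][i] for i in range(3)]
            kms, kcat = derive_km_kcat(model, "CNV")
            _, km_oracle, vmax_oracle = mm_closed_form(k, 1.0, 1.0)
            assert kms["a"] == pytest.approx(km_oracle, rel=1e-6)
            assert kcat == pytest.approx(vmax_oracle, rel=1e-6)
            from emkin.em_kinetics import _qss_rate

            for s in s_grid:
                v_oracle, _, _ = mm_closed_form(k, 1.0, s)
                v_num = _qss_rate(model, "CNV", {"a": s, "b": 0.0})
                assert v_num == pytest.approx(v_oracle, rel=1e-9, abs=1e-12)

    def test_symmetric_equilibrium_chain_has_symmetric_km(self):
        """Two mirror-image zero-flux reactions sampled at equilibrium with
        equal fractions carry identical lumped constants."""
        mets = [Metabolite("a"), Metabolite("b")]
        net = MetabolicNetwork(
            mets,
            [
                Reaction("F", {"a": -1.0, "b": 1.0}, -10, 10),
                Reaction("B", {"b": -1.0, "a": 1.0}, -10, 10),
            ],
        )
        ref = FluxState({"F": 0.0, "B": 0.0}, "F", 0.0, "optimal")
        templates = decompose(net)
        fractions = {
            r: {f: 1.0 for f in reaction_forms(templates, r)} for r in ("F", "B")
        }
        params = anchored_parameter_set(templates, ref, fractions, {})
        model = build_model(net, templates, params)
        km_f, kcat_f = derive_km_kcat(model, "F")
        km_b, kcat_b = derive_km_kcat(model, "B")
        assert km_f["a"] == pytest.approx(km_b["b"], rel=1e-9)
        assert kcat_f == pytest.approx(kcat_b, rel=1e-9)


def two_step_chain_rate(k1, k_1, k2, k_2, etot, a):
    """Net consumption rate of the 2-step exchange chain E+A <-> EA <-> E
    at enzyme quasi-steady state (exact at steady state)."""
    return etot * (k1 * k2 * a - k_1 * k_2) / (k1 * a + k_1 + k2 + k_2)


class TestSteadyState:
    def test_reference_levels_return_reference_state(self, truth3):
        state = steady_state(truth3.model)
        assert state.converged
        for met, fold in state.concentrations.items():
            assert fold == pytest.approx(1.0, abs=1e-9)
        for rid, v in truth3.reference_flux.fluxes.items():
            assert state.fluxes[rid] == pytest.approx(v, abs=1e-9)

    def test_knockout_zeroes_flux_and_rebalances(self, truth3):
        model = apply_genotype(truth3.model, [("LDH", "knockout")])
        state = steady_state(model)
        assert state.converged
        assert state.fluxes["LDH"] == pytest.approx(0.0, abs=1e-9)
        S = truth3.network.stoichiometric_matrix()
        v = np.array([state.fluxes[r] for r in truth3.network.reaction_ids])
        assert np.abs(S @ v).max() < 1e-6

    def test_two_reaction_chain_matches_analytic_solution(self):
        """Producer/consumer pair: the steady state solves a scalar equation
        in [a] whose enzyme distribution is known in closed form."""
        mets = [Metabolite("a")]
        net = MetabolicNetwork(
            mets,
            [
                Reaction("PRD", {"a": -1.0}, -10, 0),
                Reaction("CNS", {"a": -1.0}, 0, 10),
            ],
        )
        ref = FluxState({"PRD": -1.0, "CNS": 1.0}, "CNS", 1.0, "optimal")
        templates = decompose(net)
        fractions = {
            r: {f: 1.0 for f in reaction_forms(templates, r)}
            for r in ("PRD", "CNS")
        }
        revs = {"PRD": {0: 0.3, 1: 0.3}, "CNS": {0: 0.6, 1: 0.6}}
        params = anchored_parameter_set(templates, ref, fractions, revs)
        model = build_model(net, templates, params, uptake_reaction="PRD")
        level = 1.7  # upregulate the producer

        def k_of(rxn, idx):
            return params.rate_constants[rxn][idx]

        def net_consumption(a):
            total = 0.0
            for rxn, lam in (("PRD", level), ("CNS", 1.0)):
                (k1, k_1), (k2, k_2) = k_of(rxn, 0), k_of(rxn, 1)
                total += two_step_chain_rate(k1, k_1, k2, k_2, lam, a)
            return total

        a_star = brentq(net_consumption, 1e-9, 1e6, xtol=1e-14)
        state = steady_state(model, enzyme_levels={"PRD": level})
        assert state.converged
        assert state.concentrations["a"] == pytest.approx(a_star, rel=1e-6)
        (k1, k_1), (k2, k_2) = k_of("CNS", 0), k_of("CNS", 1)
        v_cns = two_step_chain_rate(k1, k_1, k2, k_2, 1.0, a_star)
        assert state.fluxes["CNS"] == pytest.approx(v_cns, rel=1e-6)

    def test_enzyme_totals_conserved(self, truth3):
        model = apply_genotype(truth3.model, [("GLY", "down", 0.5)])
        state, x = steady_state(model, return_state=True)
        sim = _get_sim(model)
        for rxn in truth3.network.reaction_ids:
            total = sum(
                x[i]
                for s, i in sim.pos.items()
                if ":" in s and s.split(":", 1)[0] == rxn
            )
            expected = 0.5 if rxn == "GLY" else 1.0
            assert total == pytest.approx(expected, abs=1e-10)

    def test_flux_monotone_in_own_enzyme_level(self, truth3):
        levels = [0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
        fluxes = []
        for lvl in levels:
            state = steady_state(truth3.model, enzyme_levels={"LDH": lvl})
            assert state.converged
            fluxes.append(state.fluxes["LDH"])
        assert all(b >= a - 1e-9 for a, b in zip(fluxes, fluxes[1:]))


class TestGenotypes:
    def test_knockout_directive(self, truth3):
        model = apply_genotype(truth3.model, [("LDH", "knockout")])
        assert model.enzyme_levels["LDH"] == 0.0

    def test_twofold_downregulation(self, truth3):
        model = apply_genotype(truth3.model, [("LDH", "down", 0.5)])
        assert model.enzyme_levels["LDH"] == 0.5

    def test_empty_genotype_is_identity(self, truth3):
        model = apply_genotype(truth3.model, [])
        assert model.enzyme_levels == truth3.model.enzyme_levels
        assert model.level_bounds == truth3.model.level_bounds

    def test_free_band_registration(self, truth3):
        model = apply_genotype(truth3.model, [("LDH", "down"), ("AC", "up")])
        assert model.level_bounds["LDH"] == (0.1, 1.0)
        assert model.level_bounds["AC"] == (1.0, 10.0)

    def test_level_outside_band_rejected(self, truth3):
        with pytest.raises(ValueError, match="outside band"):
            apply_genotype(truth3.model, [("LDH", "down", 1.5)])
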