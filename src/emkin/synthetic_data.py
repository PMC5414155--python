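"""Ground-truth generators with the statistical shape of real fermentation
training data.

The toy network is a branched anaerobic fermentation: a sugar uptake
backbone (one lumped glycolysis reaction producing pyruvate and NADH),
two to four competing terminal product branches with different redox
demands (lactate-, ethanol-, acetate- and butanol-like), an amino-acid
branch fed by a nitrogen uptake transporter and NADPH, a biomass drain, and
a transhydrogenase pair with swapped cofactor specificity that deliberately
forms a thermodynamically infeasible cycle (for exercising TIC detection
and the cycle constraint). Metabolites carry synthetic but elementally
balanced formulas (cofactor scaffolds use the placeholder elements R/Q).

Mutant libraries are simulated from the true kinetics and dressed with
multiplicative lognormal noise, unbiased in log space, tagged with the
generating CV — mirroring yield datasets where measurement error is on the
order of 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .em_kinetics import (
    ElementaryParameterSet,
    ElementaryStep,
    KineticModel,
    KineticSteadyState,
    apply_genotype,
    build_model,
    decompose,
    derive_km_kcat,
    sample_ensemble,
    steady_state,
)
from .fba_core import CycleSpec, FluxState
from .network_model import MetabolicNetwork, Metabolite, Reaction, parse_formula
from .parameterization import Measurement, MutantDataset

__all__ = ["GroundTruth", "generate_toy_network", "generate_mutant_library"]

_BRANCHES = ["lac", "etoh", "ac", "but"]  # nadh stoichiometries 1, 2, 0, 3
_BRANCH_NADH = {"lac": 1.0, "etoh": 2.0, "ac": 0.0, "but": 3.0}
_BRANCH_RXN = {"lac": "LDH", "etoh": "ETOH", "ac": "AC", "but": "BUT"}
# reference flux split among product branches, per branch count; solves the
# pyruvate (Σ = 1.4) and NADH (Σ nadh_i·v_i = 1.6) balances of the backbone
_BRANCH_SPLIT = {
    2: {"etoh": 0.2, "lac": 1.2},
    3: {"etoh": 0.5, "lac": 0.6, "ac": 0.3},
    4: {"etoh": 0.4, "lac": 0.5, "ac": 0.4, "but": 0.1},
}

_FORMULAS = {
    "sub": "C6H12O6",
    "pyr": "C3H4O3",
    "lac": "C3H6O3",
    "etoh": "C3H8O3",
    "ac": "C3H4O3",
    "but": "C3H10O3",
    "aa": "C3H9NO3",
    "n": "NH3",
    "nad": "R",
    "nadh": "RH2",
    "nadp": "Q",
    "nadph": "QH2",
}


@dataclass
class GroundTruth:
    network: MetabolicNetwork
    templates: list[ElementaryStep]
    regulations: list[tuple[str, str, str]]
    cycle_spec: CycleSpec
    planted_tic: list[str]
    reference_flux: FluxState
    true_params: ElementaryParameterSet
    model: KineticModel  # the true kinetic model (ẽ_tot ≡ 1 reproduces reference)
    seed: int
    n_branches: int
    true_steady_states: dict[str, KineticSteadyState] = field(default_factory=dict)

    @property
    def uptake_reaction(self) -> str:
        return "EX_sub"


def _toy_network(n_branches: int) -> tuple[MetabolicNetwork, FluxState]:
    if n_branches < 2:
        raise ValueError("need at least two product branches")
    if n_branches > len(_BRANCHES):
        raise ValueError(f"at most {len(_BRANCHES)} product branches supported")
    branches = _BRANCHES[:n_branches]
    mets = ["sub", "pyr", "nad", "nadh", "nadp", "nadph", "n", "aa"] + branches
    metabolites = [
        Metabolite(m, compartment="c", formula=parse_formula(_FORMULAS[m]), charge=0)
        for m in mets
    ]
    reactions = [
        Reaction("EX_sub", {"sub": -1.0}, -10.0, 0.0),
        Reaction("GLY", {"sub": -1.0, "nad": -2.0, "pyr": 2.0, "nadh": 2.0}, 0.0, 1000.0),
        Reaction("THD1", {"nadh": -1.0, "nadp": -1.0, "nad": 1.0, "nadph": 1.0}, 0.0, 1000.0),
        Reaction("THD2", {"nadph": -1.0, "nad": -1.0, "nadp": 1.0, "nadh": 1.0}, 0.0, 1000.0),
        Reaction("AADH", {"pyr": -1.0, "n": -1.0, "nadph": -1.0, "aa": 1.0, "nadp": 1.0}, 0.0, 1000.0),
        Reaction("EX_n", {"n": -1.0}, -1000.0, 0.0),
        Reaction("BIOMASS", {"pyr": -0.5, "aa": -0.5}, 0.0, 1000.0),
        Reaction("EX_aa", {"aa": -1.0}, 0.0, 1000.0),
    ]
    flux = {
        "EX_sub": -1.0,
        "GLY": 1.0,
        "THD1": 0.4,
        "THD2": 0.0,
        "AADH": 0.4,
        "EX_n": -0.4,
        "BIOMASS": 0.4,
        "EX_aa": 0.2,
    }
    split = _BRANCH_SPLIT[n_branches]
    for product in branches:
        rxn_id = _BRANCH_RXN[product]
        nadh = _BRANCH_NADH[product]
        stoich = {"pyr": -1.0, product: 1.0}
        if nadh:
            stoich.update({"nadh": -nadh, "nad": nadh})
        reactions.append(Reaction(rxn_id, stoich, 0.0, 1000.0))
        reactions.append(Reaction(f"EX_{product}", {product: -1.0}, 0.0, 1000.0))
        flux[rxn_id] = split[product]
        flux[f"EX_{product}"] = split[product]
    network = MetabolicNetwork(metabolites, reactions, biomass_reaction_id="BIOMASS")
    # the generator must hand out a consistent reference: S·v = 0
    S = network.stoichiometric_matrix()
    v = np.array([flux[r] for r in network.reaction_ids])
    if np.abs(S @ v).max() > 1e-12:
        raise AssertionError("reference flux split violates mass balance")
    reference = FluxState(flux, "BIOMASS", flux["BIOMASS"], "optimal")
    return network, reference


_REGULATIONS = [
    ("aa", "AADH", "product-inhibition"),
    ("nadph", "THD1", "product-inhibition"),
    ("lac", "LDH", "product-inhibition"),
]


def generate_toy_network(
    n_branches: int = 4,
    seed: int = 0,
    max_resample: int = 10,
    verify_genotypes: Sequence[tuple[str, list[tuple]]] | None = None,
) -> GroundTruth:
    """Build a branched fermentation network with known true kinetics.

    The true parameter set is sampled with the ensemble machinery and the
    reference steady state is verified to be dynamically stable (resampling
    with a deterministically derived seed on the rare unstable draw). With
    ``verify_genotypes``, draws whose true steady state diverges for any of
    the listed genotypes are likewise resampled, guaranteeing a viable
    mutant library for those genotypes.
    """
    network, reference = _toy_network(n_branches)
    regulations = [r for r in _REGULATIONS if r[1] in set(network.reaction_ids)]
    templates = decompose(network, regulations)
    from .em_kinetics import _get_sim, _is_stable  # internal stability probe

    for attempt in range(max_resample):
        draw_seed = seed + 1_000_003 * attempt
        params = sample_ensemble(templates, reference, 1, draw_seed)[0]
        model = build_model(
            network, templates, params, regulations, uptake_reaction="EX_sub"
        )
        sim = _get_sim(model)
        x_ref = sim.initial_state({})
        if not _is_stable(sim, x_ref):
            continue
        if verify_genotypes and not all(
            steady_state(apply_genotype(model, g)).converged
            for _, g in verify_genotypes
        ):
            continue
        break
    else:
        raise RuntimeError("could not sample a stable reference state")
    cycle_spec = CycleSpec({"nadph": ["THD1", "THD2"]})
    truth = GroundTruth(
        network=network,
        templates=templates,
        regulations=regulations,
        cycle_spec=cycle_spec,
        planted_tic=["THD1", "THD2"],
        reference_flux=reference,
        true_params=params,
        model=model,
        seed=seed,
        n_branches=n_branches,
    )
    wild_type = steady_state(model)
    if not wild_type.converged:
        raise RuntimeError("reference state did not converge (anchoring broken)")
    truth.true_steady_states["reference"] = wild_type
    return truth


def default_genotypes(truth: GroundTruth) -> list[tuple[str, list[tuple]]]:
    """A 19-mutant design: single/double knockouts plus up/downregulations
    concentrated around the pyruvate node, with two unique-phenotype
    mutants (transhydrogenase and amino-acid-branch deletions) whose
    information is not replicated elsewhere."""
    rxns = set(truth.network.reaction_ids)
    branch_rxns = [
        _BRANCH_RXN[b] for b in _BRANCHES if _BRANCH_RXN[b] in rxns
    ]
    genotypes: list[tuple[str, list[tuple]]] = []
    for rxn in branch_rxns:
        genotypes.append((f"d_{rxn.lower()}", [(rxn, "knockout")]))
    # unique phenotypes: only these mutants exercise THD2 / starve the aa branch
    genotypes.append(("d_thd1", [("THD1", "knockout")]))
    genotypes.append(("d_aadh", [("AADH", "knockout")]))
    for rxn in branch_rxns:
        genotypes.append((f"{rxn.lower()}_down", [(rxn, "down", 0.5)]))
        genotypes.append((f"{rxn.lower()}_up", [(rxn, "up", 2.0)]))
    genotypes.append(("gly_down", [("GLY", "down", 0.5)]))
    genotypes.append(("exn_down", [("EX_n", "down", 0.5)]))
    genotypes.append(("aadh_down", [("AADH", "down", 0.5)]))
    if len(branch_rxns) >= 2:
        a, b = branch_rxns[0], branch_rxns[1]
        genotypes.append(
            (f"d_{a.lower()}_{b.lower()}_up", [(a, "knockout"), (b, "up", 2.0)])
        )
        genotypes.append(
            (f"d_{b.lower()}_{a.lower()}_down", [(b, "knockout"), (a, "down", 0.5)])
        )
    if len(branch_rxns) >= 3:
        genotypes.append(
            (
                f"d_{branch_rxns[0].lower()}_d_{branch_rxns[2].lower()}",
                [(branch_rxns[0], "knockout"), (branch_rxns[2], "knockout")],
            )
        )
    genotypes.append(("thd1_down", [("THD1", "down", 0.5)]))
    genotypes.append(("biomass_down", [("BIOMASS", "down", 0.5)]))
    return genotypes[:19]


def _yield_targets(truth: GroundTruth) -> list[str]:
    rxns = truth.network.reaction_ids
    targets = [r for r in rxns if r.startswith("EX_") and r != "EX_sub"]
    targets.append("BIOMASS")
    return targets


def _concentration_targets(truth: GroundTruth) -> list[str]:
    return truth.network.metabolite_ids


def generate_mutant_library(
    truth: GroundTruth,
    genotypes: Sequence[tuple[str, list[tuple]]] | None = None,
    cv: float = 0.5,
    seed: int = 0,
    include_concentration_dataset: bool = False,
    include_km_dataset: bool = False,
    km_reactions: Sequence[str] = ("GLY", "LDH", "ETOH"),
    km_cv: float = 0.3,
) -> list[MutantDataset]:
    """Simulate mutant genotypes and emit noisy training datasets.

    Each mutant dataset tags every measurement with the generating CV. With
    the flags on, two companion datasets are appended: a normalized
    intracellular concentration vector for one downregulation mutant and a
    noisy Km/kcat table for a few enzymes (per-parameter SD noise).
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    if genotypes is None:
        genotypes = default_genotypes(truth)
    yield_targets = _yield_targets(truth)
    conc_targets = _concentration_targets(truth)

    def noisy(value: float, sd_log: float) -> float:
        return float(value * np.exp(sd_log * rng.standard_normal()))

    datasets: list[MutantDataset] = []
    for name, genotype in genotypes:
        mutant = apply_genotype(truth.model, genotype)
        state = steady_state(mutant)
        if not state.converged:
            raise RuntimeError(f"true steady state for genotype {name} diverged")
        truth.true_steady_states[name] = state
        measurements = [
            Measurement("yield", rxn, noisy(state.normalized_fluxes[rxn], sigma), cv)
            for rxn in yield_targets
        ]
        measurements.extend(
            Measurement(
                "concentration-fold",
                met,
                noisy(state.concentrations[met], sigma),
                cv,
            )
            for met in conc_targets
        )
        datasets.append(MutantDataset(name, list(genotype), measurements))

    if include_concentration_dataset:
        genotype = [("AADH", "down", 0.5)]
        mutant = apply_genotype(truth.model, genotype)
        state = steady_state(mutant)
        truth.true_steady_states["conc_aadh_down"] = state
        measurements = [
            Measurement(
                "concentration-fold", met, noisy(state.concentrations[met], sigma), cv
            )
            for met in conc_targets
        ]
        datasets.append(MutantDataset("conc_aadh_down", genotype, measurements))

    if include_km_dataset:
        km_sigma = float(np.sqrt(np.log1p(km_cv**2)))
        measurements = []
        for rxn in km_reactions:
            if rxn not in set(truth.network.reaction_ids):
                continue
            kms, kcat = derive_km_kcat(truth.model, rxn)
            for substrate, km in kms.items():
                measurements.append(
                    Measurement("km", f"{rxn}:{substrate}", noisy(km, km_sigma), km_cv)
                )
            measurements.append(
                Measurement("kcat", rxn, noisy(kcat, km_sigma), km_cv)
            )
        datasets.append(MutantDataset("kinetic_constants", [], measurements))

    return datasets
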