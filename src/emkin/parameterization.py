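"""Model training: the relative-deviation objective, GA selection over
sampled elementary parameters, and leave-one-out cross-validation.

The objective normalizes each residual by the experimental value and by the
measurement's coefficient of variation, averages within a dataset and then
across datasets:

    D = (1/M) Σ_m (1/N_m) Σ_i (1/CV_i) · |v_i − v_i^exp| / |v_i^exp|

The magnitude convention (|·|) is the default so that signed residuals
cannot cancel; the signed variant is available for fidelity experiments.

The genetic algorithm does not mutate kinetic constants directly: each
chromosome picks, per reaction, one member of that reaction's sampled
parameter pool (anchoring is per reaction, so recombining pools across
members preserves the reference steady state), plus a free ẽ_tot gene for
every up/down-regulated enzyme whose level was not reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import em_kinetics as emk
from .em_kinetics import (
    ElementaryParameterSet,
    ElementaryStep,
    KineticModel,
    apply_genotype,
    build_model,
    derive_km_kcat,
    steady_state,
)
from .fba_core import FluxState
from .network_model import MetabolicNetwork

__all__ = [
    "Measurement",
    "MutantDataset",
    "DeviationReport",
    "GAConfig",
    "GAFitResult",
    "relative_deviation",
    "predict_dataset",
    "ga_fit",
    "cross_validate",
    "save_datasets",
    "load_datasets",
]

QUANTITIES = {"yield", "concentration-fold", "km", "kcat"}
NONCONVERGENCE_PENALTY = 1e3
DEFAULT_CV = 0.5  # the mutant-library measurements carry ~50% error


@dataclass
class Measurement:
    quantity: str  # yield | concentration-fold | km | kcat
    target: str  # reaction id, metabolite id, or "reaction:substrate" for km
    value: float
    cv: float = DEFAULT_CV

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if not self.cv > 0:
            raise ValueError("cv must be positive")
        if not np.isfinite(self.value):
            raise ValueError("measurement value must be finite")

    @property
    def key(self) -> tuple[str, str]:
        return (self.quantity, self.target)


@dataclass
class MutantDataset:
    name: str
    genotype: list[tuple]  # apply_genotype directives
    measurements: list[Measurement]

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError(f"dataset {self.name}: no measurements")


@dataclass
class DeviationReport:
    per_dataset: dict[str, float]
    overall: float
    residuals: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    flagged_zero_reference: list[tuple[str, tuple[str, str]]] = field(
        default_factory=list
    )


def relative_deviation(
    predictions: Mapping[str, Mapping[tuple[str, str], float]],
    datasets: Sequence[MutantDataset],
    signed: bool = False,
) -> DeviationReport:
    """Score predictions against measured datasets.

    Measurements with a zero experimental value are scored on the absolute
    difference scaled by CV (the relative form is undefined) and flagged.
    """
    per_dataset: dict[str, float] = {}
    residuals: dict[str, dict[tuple[str, str], float]] = {}
    flagged: list[tuple[str, tuple[str, str]]] = []
    for ds in datasets:
        preds = predictions[ds.name]
        terms = []
        res: dict[tuple[str, str], float] = {}
        for meas in ds.measurements:
            if meas.key not in preds:
                raise KeyError(
                    f"dataset {ds.name}: no prediction for {meas.key}"
                )
            v = preds[meas.key]
            if meas.value == 0.0:
                raw = v - meas.value
                flagged.append((ds.name, meas.key))
            else:
                raw = (v - meas.value) / meas.value
            term = raw / meas.cv
            if not signed:
                term = abs(term)
            res[meas.key] = term
            terms.append(term)
        per_dataset[ds.name] = float(np.mean(terms))
        residuals[ds.name] = res
    overall = float(np.mean(list(per_dataset.values())))
    return DeviationReport(per_dataset, overall, residuals, flagged)


# ---------------------------------------------------------------------------
# Prediction of one dataset from a kinetic model
# ---------------------------------------------------------------------------

def predict_dataset(
    model: KineticModel,
    dataset: MutantDataset,
    free_levels: Mapping[str, float] | None = None,
    km_cache: dict | None = None,
    t_max: float = emk.T_MAX,
) -> tuple[dict[tuple[str, str], float] | None, bool]:
    """Simulate a mutant genotype and read off the measured quantities.

    Returns (predictions, converged); predictions are None when the steady
    state did not converge.
    """
    mutant = apply_genotype(model, dataset.genotype)
    if free_levels:
        levels = dict(mutant.enzyme_levels)
        for rxn, level in free_levels.items():
            if rxn in mutant.level_bounds:
                lo, hi = mutant.level_bounds[rxn]
                levels[rxn] = float(np.clip(level, lo, hi))
        mutant = mutant.with_updates(enzyme_levels=levels)
    needs_state = any(
        m.quantity in ("yield", "concentration-fold") for m in dataset.measurements
    )
    state = steady_state(mutant, t_max=t_max) if needs_state else None
    if state is not None and not state.converged:
        return None, False
    preds: dict[tuple[str, str], float] = {}
    for meas in dataset.measurements:
        if meas.quantity == "yield":
            preds[meas.key] = state.normalized_fluxes[meas.target]
        elif meas.quantity == "concentration-fold":
            preds[meas.key] = state.concentrations[meas.target]
        elif meas.quantity in ("km", "kcat"):
            if meas.quantity == "km":
                rxn_id, substrate = meas.target.split(":", 1)
            else:
                rxn_id, substrate = meas.target, None
            cache_key = rxn_id
            if km_cache is not None and cache_key in km_cache:
                kms, kcat = km_cache[cache_key]
            else:
                kms, kcat = derive_km_kcat(model, rxn_id)
                if km_cache is not None:
                    km_cache[cache_key] = (kms, kcat)
            preds[meas.key] = kms[substrate] if substrate else kcat
    return preds, True


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    seed: int = 0
    elitism: int = 2
    tournament: int = 3
    stagnation: int = 20  # stop after this many stale generations
    signed_objective: bool = False
    # memetic refinement: when the best-so-far stalls, run a coordinate-
    # descent sweep over its pool indices (one gene at a time); strongly
    # accelerates convergence on near-separable landscapes
    local_search: bool = True
    local_search_after: int = 3  # stale generations that trigger a sweep
    # iterated restart: after this many stale generations the non-elite
    # population is re-randomized (escape from local optima); the incumbent
    # is preserved by elitism so the best-so-far stays monotone
    restart_after: int = 12
    # integration horizon for fitness evaluations; members that have not
    # settled by then count as non-convergent (penalized)
    fitness_t_max: float = 1e4


@dataclass
class GAFitResult:
    best_params: ElementaryParameterSet
    best_model: KineticModel
    report: DeviationReport
    trace: list[float]  # best objective per generation (monotone)
    pool_indices: dict[str, int]
    free_levels: dict[tuple[str, str], float]  # (dataset, reaction) -> ẽ_tot


def _hybrid_parameter_set(
    pool: Sequence[ElementaryParameterSet], indices: Sequence[int], rxn_ids: Sequence[str]
) -> ElementaryParameterSet:
    base = pool[0]
    fractions, revs, consts = {}, {}, {}
    for rxn, idx in zip(rxn_ids, indices):
        member = pool[idx]
        fractions[rxn] = member.enzyme_fractions[rxn]
        revs[rxn] = member.reversibilities[rxn]
        consts[rxn] = member.rate_constants[rxn]
    return ElementaryParameterSet(
        fractions, revs, consts, base.reference_flux, base.reference_concentrations
    )


def _free_level_genes(
    network: MetabolicNetwork, datasets: Sequence[MutantDataset]
) -> list[tuple[str, str, tuple[float, float]]]:
    genes = []
    for ds in datasets:
        for entry in ds.genotype:
            rxn, directive = entry[0], entry[1]
            level = entry[2] if len(entry) > 2 else None
            if directive in ("down", "up") and level is None:
                band = emk.DOWN_BAND if directive == "down" else emk.UP_BAND
                genes.append((ds.name, rxn, band))
    return genes


def ga_fit(
    templates: Sequence[ElementaryStep],
    datasets: Sequence[MutantDataset],
    pool: Sequence[ElementaryParameterSet],
    network: MetabolicNetwork,
    regulations: Sequence[tuple[str, str, str]] = (),
    uptake_reaction: str | None = None,
    config: GAConfig | None = None,
    progress: Callable[[int, float], None] | None = None,
) -> GAFitResult:
    """Select the best per-reaction combination of sampled parameters.

    Fitness is the overall relative deviation; every evaluation simulates
    the steady state of each dataset's genotype. Non-convergent members
    receive a large penalty instead of being excluded so fitness stays
    total. Elitism makes the best-so-far monotone non-increasing. Fully
    deterministic for a fixed config seed.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    if not pool:
        raise ValueError("empty parameter pool")
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    rxn_ids = network.reaction_ids
    n_rxn = len(rxn_ids)
    level_genes = _free_level_genes(network, datasets)
    n_pool = len(pool)

    cache: dict[tuple, tuple[float, DeviationReport | None]] = {}

    def evaluate(chrom_int: np.ndarray, chrom_flt: np.ndarray):
        key = (tuple(int(i) for i in chrom_int), tuple(np.round(chrom_flt, 9)))
        if key in cache:
            return cache[key]
        params = _hybrid_parameter_set(pool, chrom_int, rxn_ids)
        model = build_model(
            network, templates, params, regulations, uptake_reaction
        )
        km_cache: dict = {}
        predictions = {}
        all_converged = True
        for ds in datasets:
            free = {
                rxn: chrom_flt[g]
                for g, (ds_name, rxn, _band) in enumerate(level_genes)
                if ds_name == ds.name
            }
            preds, converged = predict_dataset(
                model, ds, free, km_cache, t_max=config.fitness_t_max
            )
            if not converged:
                all_converged = False
                break
            predictions[ds.name] = preds
        if not all_converged:
            result = (NONCONVERGENCE_PENALTY, None)
        else:
            report = relative_deviation(
                predictions, datasets, signed=config.signed_objective
            )
            result = (report.overall, report)
        cache[key] = result
        return result

    def random_individual():
        ints = rng.integers(0, n_pool, size=n_rxn)
        flts = np.array([rng.uniform(lo, hi) for (_, _, (lo, hi)) in level_genes])
        return ints, flts

    # seed the population with the column-pure individuals (each pool
    # member as a whole model): coherent anchored models are better
    # starting points than arbitrary per-reaction hybrids
    population = [
        (np.full(n_rxn, k, dtype=int),
         np.array([rng.uniform(lo, hi) for (_, _, (lo, hi)) in level_genes]))
        for k in range(min(n_pool, config.population))
    ]
    while len(population) < config.population:
        population.append(random_individual())
    fitness = [evaluate(*ind)[0] for ind in population]
    if all(f >= NONCONVERGENCE_PENALTY for f in fitness):
        raise RuntimeError(
            "no individual of generation 0 produced a convergent steady "
            "state; the parameter pool is probably not anchored to the "
            "reference flux"
        )

    def tournament_pick():
        contenders = rng.integers(0, len(population), size=config.tournament)
        return min(contenders, key=lambda i: fitness[i])

    def coordinate_sweep(ind, value, max_passes: int = 4):
        """Greedy one-gene-at-a-time improvement, iterated to a fixpoint."""
        ints, flts = ind[0].copy(), ind[1].copy()
        for _ in range(max_passes):
            improved = False
            for g in rng.permutation(n_rxn):
                current = ints[g]
                for alt in range(n_pool):
                    if alt == current:
                        continue
                    trial = ints.copy()
                    trial[g] = alt
                    trial_value = evaluate(trial, flts)[0]
                    if trial_value < value - 1e-15:
                        ints, value = trial, trial_value
                        improved = True
            if not improved:
                break
        return (ints, flts), value

    best_value = min(fitness)
    best_ind = population[int(np.argmin(fitness))]
    trace = [best_value]
    stale = 0
    for gen in range(1, config.generations + 1):
        order = np.argsort(fitness)
        elites = [population[i] for i in order[: config.elitism]]
        offspring = [
            (e[0].copy(), e[1].copy()) for e in elites
        ]
        while len(offspring) < config.population:
            p1 = population[tournament_pick()]
            p2 = population[tournament_pick()]
            c_int, c_flt = p1[0].copy(), p1[1].copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(n_rxn) < 0.5
                c_int[mask] = p2[0][mask]
                if len(level_genes):
                    fmask = rng.random(len(level_genes)) < 0.5
                    c_flt[fmask] = p2[1][fmask]
            mut = rng.random(n_rxn) < config.mutation_rate
            c_int[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
            for g, (_, _, (lo, hi)) in enumerate(level_genes):
                if rng.random() < config.mutation_rate:
                    c_flt[g] = rng.uniform(lo, hi)
            offspring.append((c_int, c_flt))
        population = offspring
        fitness = [evaluate(*ind)[0] for ind in population]
        gen_best = min(fitness)
        if gen_best < best_value - 1e-15:
            best_value = gen_best
            best_ind = population[int(np.argmin(fitness))]
            stale = 0
        else:
            stale += 1
        if (
            config.local_search
            and stale >= config.local_search_after
            and best_value > 0
        ):
            # refine the *generation's* best: a fresh basin once the
            # incumbent's neighborhood is exhausted (its sweep is cached)
            gen_idx = int(np.argmin(fitness))
            seed_ind = population[gen_idx]
            seed_value = fitness[gen_idx]
            swept_ind, swept = coordinate_sweep(seed_ind, seed_value)
            if swept < best_value - 1e-15:
                best_value = swept
                best_ind = swept_ind
                stale = 0
            # reinject the refined individual over the current worst
            worst = int(np.argmax(fitness))
            population[worst] = swept_ind
            fitness[worst] = swept
        if stale and stale % config.restart_after == 0:
            order2 = np.argsort(fitness)
            keep = {int(i) for i in order2[: config.elitism]}
            for i in range(len(population)):
                if i not in keep:
                    population[i] = random_individual()
                    fitness[i] = evaluate(*population[i])[0]
        trace.append(best_value)
        if progress is not None:
            progress(gen, best_value)
        if stale >= config.stagnation:
            break

    _, report = evaluate(*best_ind)
    if report is None:  # best was penalized (should not happen past gen 0)
        raise RuntimeError("best individual is non-convergent")
    best_params = _hybrid_parameter_set(pool, best_ind[0], rxn_ids)
    best_model = build_model(
        network, templates, best_params, regulations, uptake_reaction
    )
    free = {
        (ds_name, rxn): float(best_ind[1][g])
        for g, (ds_name, rxn, _) in enumerate(level_genes)
    }
    return GAFitResult(
        best_params,
        best_model,
        report,
        trace,
        dict(zip(rxn_ids, (int(i) for i in best_ind[0]))),
        free,
    )


def cross_validate(
    templates: Sequence[ElementaryStep],
    datasets: Sequence[MutantDataset],
    pool: Sequence[ElementaryParameterSet],
    network: MetabolicNetwork,
    regulations: Sequence[tuple[str, str, str]] = (),
    uptake_reaction: str | None = None,
    config: GAConfig | None = None,
) -> dict[str, tuple[float, float]]:
    """Leave-one-out cross-validation.

    For each fold the model is refit on the remaining datasets (same seed
    and config for comparability) and the held-out dataset is scored with
    the fold's best model; the full-fit deviation of the same dataset is
    reported alongside, so held-out − full-fit is the accuracy reduction
    attributable to removing that dataset.
    """
    if len(datasets) < 2:
        raise ValueError("cross-validation needs at least two datasets")
    config = config or GAConfig()
    full = ga_fit(
        templates, datasets, pool, network, regulations, uptake_reaction, config
    )
    results: dict[str, tuple[float, float]] = {}
    for held in datasets:
        rest = [d for d in datasets if d.name != held.name]
        try:
            fold = ga_fit(
                templates, rest, pool, network, regulations, uptake_reaction, config
            )
        except RuntimeError as exc:
            import warnings

            warnings.warn(f"fold {held.name} skipped: {exc}", stacklevel=2)
            continue
        preds, converged = predict_dataset(fold.best_model, held, km_cache={})
        if not converged:
            held_dev = NONCONVERGENCE_PENALTY
        else:
            held_dev = relative_deviation(
                {held.name: preds}, [held], signed=config.signed_objective
            ).overall
        results[held.name] = (held_dev, full.report.per_dataset[held.name])
    return results


# ---------------------------------------------------------------------------
# Dataset I/O (TSV + genotype YAML)
# ---------------------------------------------------------------------------

def save_datasets(path, datasets: Sequence[MutantDataset], genotype_path=None) -> None:
    rows = []
    for ds in datasets:
        for meas in ds.measurements:
            rows.append(
                {
                    "dataset": ds.name,
                    "genotype": ds.name,
                    "quantity": meas.quantity,
                    "target": meas.target,
                    "value": meas.value,
                    "cv": meas.cv,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if genotype_path is not None:
        import yaml

        payload = {
            ds.name: [list(entry) for entry in ds.genotype] for ds in datasets
        }
        with open(genotype_path, "w") as handle:
            yaml.safe_dump(payload, handle)


def load_datasets(path, genotype_path) -> list[MutantDataset]:
    import yaml

    table = pd.read_csv(path, sep="\t")
    with open(genotype_path) as handle:
        genotypes = yaml.safe_load(handle)
    datasets = []
    for name, group in table.groupby("dataset", sort=False):
        measurements = [
            Measurement(row.quantity, row.target, float(row.value), float(row.cv))
            for row in group.itertuples(index=False)
        ]
        genotype = [tuple(entry) for entry in genotypes.get(name, [])]
        datasets.append(MutantDataset(str(name), genotype, measurements))
    return datasets
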