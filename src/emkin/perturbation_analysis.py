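"""Case-study drivers: enzyme-level scans (nitrogen-limitation style),
stress profiles (proteome fold-changes plus clamped cofactor pools), and
robustness analysis locating non-robust kinetic parameters through
divergent metabolite accumulation or depletion (the EMRA signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .em_kinetics import (
    KineticModel,
    KineticSteadyState,
    steady_state,
)

__all__ = [
    "StressProfile",
    "RobustnessReport",
    "scan_enzyme_level",
    "apply_stress_profile",
    "robustness_scan",
]


@dataclass
class StressProfile:
    """Multiplicative enzyme-level changes plus boundary pool scalings.

    ``pool_scalings`` entries clamp the metabolite at ``multiplier ×
    reference`` as a fixed boundary condition for the solve.
    """

    enzyme_fold_changes: dict[str, float] = field(default_factory=dict)
    pool_scalings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, mapping in (
            ("enzyme", self.enzyme_fold_changes),
            ("pool", self.pool_scalings),
        ):
            for key, mult in mapping.items():
                if not mult > 0:
                    raise ValueError(f"{label} multiplier for {key} must be > 0")

    @classmethod
    def from_percent_changes(
        cls,
        enzyme_percent: Mapping[str, float] | None = None,
        pool_percent: Mapping[str, float] | None = None,
        percent_is_increase: bool = True,
    ) -> "StressProfile":
        """Build a profile from percent changes (e.g. −38 → ×0.62, +140 →
        ×2.4). ``percent_is_increase=False`` reads "+670%" as ×6.7 instead
        of the default ×7.7 (i.e. as a ratio rather than an increment)."""
        offset = 1.0 if percent_is_increase else 0.0
        enzymes = {
            k: offset + v / 100.0 if percent_is_increase else v / 100.0
            for k, v in (enzyme_percent or {}).items()
        }
        pools = {
            k: offset + v / 100.0 if percent_is_increase else v / 100.0
            for k, v in (pool_percent or {}).items()
        }
        return cls(enzymes, pools)

    @classmethod
    def from_yaml(cls, path) -> "StressProfile":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(
            dict(data.get("enzymes", {})),
            dict(data.get("pools", {})),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as handle:
            yaml.safe_dump(
                {"enzymes": self.enzyme_fold_changes, "pools": self.pool_scalings},
                handle,
            )


@dataclass
class RobustnessReport:
    perturbed_reaction: str
    fold: float
    converged: bool
    non_robust_reactions: list[tuple[str, str]] = field(default_factory=list)
    # (adjacent reaction, accumulating-or-depleting species)


def scan_enzyme_level(
    model: KineticModel,
    reaction: str,
    levels: Sequence[float],
) -> dict[float, KineticSteadyState]:
    """Steady states along a ladder of ẽ_tot values for one reaction.

    Each level starts from the previous level's state (numerical
    continuation) which stabilizes convergence on steep response curves;
    level 0 is a knockout and is allowed.
    """
    from .em_kinetics import _get_sim

    model.network.reaction(reaction)
    sim = _get_sim(model)
    form_idx = [
        i for s, i in sim.pos.items()
        if ":" in s and s.split(":", 1)[0] == reaction
    ]
    results: dict[float, KineticSteadyState] = {}
    x_prev = None
    prev_level = None
    for level in levels:
        if level < 0:
            raise ValueError("enzyme levels must be >= 0")
        x0 = None
        if x_prev is not None:
            x0 = x_prev.copy()
            # conservation pins the enzyme total, so the warm start must
            # carry the new level explicitly
            if prev_level and prev_level > 0:
                x0[form_idx] *= level / prev_level
            else:
                frac = model.param_set.enzyme_fractions[reaction]
                for s, i in sim.pos.items():
                    if i in set(form_idx):
                        x0[i] = level * frac[s]
        state, x = steady_state(
            model, enzyme_levels={reaction: float(level)}, x0=x0,
            return_state=True,
        )
        results[float(level)] = state
        x_prev = x if state.converged else None
        prev_level = float(level)
    return results


def apply_stress_profile(
    model: KineticModel, profile: StressProfile
) -> KineticSteadyState:
    """Scale enzyme levels multiplicatively and clamp the listed pools as
    fixed boundary species, then solve to steady state."""
    levels = dict(model.enzyme_levels)
    for rxn, fold in profile.enzyme_fold_changes.items():
        model.network.reaction(rxn)
        levels[rxn] = levels.get(rxn, 1.0) * fold
    clamped = dict(model.clamped)
    for met, mult in profile.pool_scalings.items():
        model.network.metabolite(met)
        if mult == 1.0:  # x1 requests no change: leave the pool dynamic
            continue
        clamped[met] = model.param_set.ref_conc(met) * mult
    stressed = model.with_updates(enzyme_levels=levels, clamped=clamped)
    return steady_state(stressed)


def robustness_scan(
    model: KineticModel,
    folds: Sequence[float] = (0.5, 2.0),
    reactions: Sequence[str] | None = None,
) -> list[RobustnessReport]:
    """Perturb each reaction's ẽ_tot by each fold and flag divergence.

    A non-converged solve names the runaway species together with the
    adjacent reaction (a consumer for accumulation, a producer for
    depletion) — the non-robust node.
    """
    targets = list(reactions) if reactions is not None else [
        r.id for r in model.network.reactions
    ]
    reports: list[RobustnessReport] = []
    for rxn_id in targets:
        base = model.level(rxn_id)
        for fold in folds:
            state = steady_state(model, enzyme_levels={rxn_id: base * fold})
            non_robust: list[tuple[str, str]] = []
            if not state.converged:
                for species in state.divergent_species:
                    if ":" in species:  # enzyme form, not a metabolite node
                        continue
                    accumulating = state.concentrations.get(species, 0.0) > 1.0
                    adjacent = _adjacent_reaction(
                        model, species, consumer=accumulating
                    )
                    if adjacent is not None:
                        non_robust.append((adjacent, species))
            reports.append(
                RobustnessReport(rxn_id, float(fold), state.converged, non_robust)
            )
    return reports


def _adjacent_reaction(
    model: KineticModel, species: str, consumer: bool
) -> str | None:
    candidates = []
    for rxn in model.network.reactions:
        coeff = rxn.stoichiometry.get(species)
        if coeff is None:
            continue
        if (consumer and coeff < 0) or (not consumer and coeff > 0):
            candidates.append(rxn.id)
    if not candidates:
        return None
    # prefer the non-exchange neighbor: the saturated enzyme node
    internal = [r for r in candidates if not model.network.reaction(r).is_exchange]
    return (internal or candidates)[0]
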