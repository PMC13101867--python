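"""Core constraint-based data model.

A :class:`MetabolicModel` is a stoichiometric network with bounded reactions,
a set of exchange (boundary) reactions and a biomass objective, in the usual
genome-scale-model conventions: fluxes in mmol gDW⁻¹ h⁻¹, reversible reactions
bounded in [−1000, 1000], exchange reactions touching exactly one metabolite
with negative flux denoting uptake.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: Default magnitude bound for reversible reactions.
FLUX_BOUND = 1000.0

#: Fluxes (and growth rates) below this magnitude are treated as zero.
GROWTH_EPS = 1e-6


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id → signed coefficient (negative =
    consumed, positive = produced).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = FLUX_BOUND

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass
class MetabolicModel:
    """Stoichiometric network with exchanges and a biomass objective.

    ``metabolites`` maps metabolite id → compartment (``"e"`` external,
    ``"c"`` cytosolic by convention).
    """

    id: str
    metabolites: dict[str, str]
    reactions: list[Reaction]
    exchange_ids: list[str]
    biomass_id: str

    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- access ----------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._index[rid]]
        except KeyError:
            raise ValidationError(f"unknown reaction {rid!r}") from None

    def exchange_compound(self, exchange_id: str) -> str:
        """Compound id transported by a boundary exchange.

        The sole external metabolite of the exchange, with a trailing ``_e``
        compartment tag stripped when present.
        """
        rxn = self.reaction(exchange_id)
        if len(rxn.stoichiometry) != 1:
            raise ValidationError(
                f"exchange {exchange_id!r} touches {len(rxn.stoichiometry)} metabolites"
            )
        (met,) = rxn.stoichiometry
        return met[:-2] if met.endswith("_e") else met

    def exchange_compounds(self) -> dict[str, str]:
        """Mapping exchange reaction id → compound id for all exchanges."""
        return {ex: self.exchange_compound(ex) for ex in self.exchange_ids}

    # -- matrix form -----------------------------------------------------

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense S matrix (metabolites × reactions) and its row labels."""
        mets = sorted(self.metabolites)
        mindex = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                S[mindex[met], j] = coeff
        return S, mets

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- lifecycle -------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=list(self.reactions),
            exchange_ids=list(self.exchange_ids),
            biomass_id=self.biomass_id,
        )

    def validate(self) -> None:
        """Check model invariants; raise :class:`ValidationError` on failure."""
        if self.biomass_id not in self._index:
            raise ValidationError(f"biomass reaction {self.biomass_id!r} not in model")
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            if rxn.lower_bound > rxn.upper_bound:
                raise ValidationError(f"{rxn.id}: lower bound above upper bound")
            if abs(rxn.lower_bound) > FLUX_BOUND or abs(rxn.upper_bound) > FLUX_BOUND:
                raise ValidationError(f"{rxn.id}: bounds exceed ±{FLUX_BOUND:g}")
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValidationError(f"{rxn.id}: unknown metabolite {met!r}")
        for ex in self.exchange_ids:
            self.exchange_compound(ex)  # raises if not a 1-metabolite boundary


@dataclass(frozen=True)
class MediaSpec:
    """Maximum allowed uptake magnitude per exchange reaction.

    Exchanges absent from ``uptake_bounds`` default to zero uptake (secretion
    is always free). Values are magnitudes — the sign convention (uptake =
    negative exchange flux) stays internal to the solver.
    """

    uptake_bounds: dict[str, float]

    def __post_init__(self) -> None:
        for ex, cap in self.uptake_bounds.items():
            if cap < 0:
                raise ValidationError(f"negative uptake cap for {ex!r}")

    def cap(self, exchange_id: str) -> float:
        return self.uptake_bounds.get(exchange_id, 0.0)

    def active_imports(self) -> set[str]:
        return {ex for ex, cap in self.uptake_bounds.items() if cap > GROWTH_EPS}


@dataclass(frozen=True)
class FluxSolution:
    """Result of a flux optimization.

    ``mu`` is the biomass objective value; ``fluxes`` maps reaction id → flux.
    """

    status: str  # "optimal" | "infeasible"
    mu: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def uptake(self, exchange_id: str) -> float:
        """Uptake magnitude through an exchange (0 when secreting)."""
        return max(0.0, -self.fluxes.get(exchange_id, 0.0))

    def grows(self, eps: float = GROWTH_EPS) -> bool:
        return self.optimal and self.mu > eps
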