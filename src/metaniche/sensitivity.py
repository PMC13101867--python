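"""Compound-class growth-sensitivity profiling.

For each ensemble member: maximize growth on replete media (every exchange at
the full flux bound), find the minimal media sustaining that growth rate,
then for each of the 11 organic compound classes re-run FBA with that class's
minimal-media exchanges capped at a fraction ``f`` (default 0.5) of their
replete uptake and the class's other exchanges closed (so the model cannot
route around the limitation through an unused isomer). The growth sensitivity

    S = (1/f) · (1 − μ_n/μ)

is 0 when growth is unaffected and 1 when growth drops proportionally to the
limitation; values are clipped to [0, 1]. A member is *substantially*
sensitive to a class when S ≥ 0.8.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classes import ALL_CLASSES, ORGANIC_CLASSES, CompoundClassMap
from .ensembles import Ensemble, instantiate_member
from .errors import ValidationError
from .fba import minimal_media, optimize_growth, replete_media
from .model import FLUX_BOUND, GROWTH_EPS, FluxSolution, MediaSpec, MetabolicModel

SUBSTANTIAL_S = 0.8
VARIANCE_CUTOFF = 0.1
MIN_MODELS_DEFAULT = 10
LIMITATION_FRACTION = 0.5


@dataclass(frozen=True)
class SensitivityProfile:
    """Per-member 11-vector of class growth sensitivities."""

    genome_id: str
    member_index: int
    values: tuple[float, ...]  # ordered by ORGANIC_CLASSES

    def __post_init__(self) -> None:
        if len(self.values) != len(ORGANIC_CLASSES):
            raise ValidationError(f"profile needs {len(ORGANIC_CLASSES)} values")
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValidationError("sensitivities must lie in [0, 1]")

    @property
    def substantial_flags(self) -> tuple[bool, ...]:
        return tuple(v >= SUBSTANTIAL_S for v in self.values)


def growth_sensitivity(mu: float, mu_n: float, f: float = LIMITATION_FRACTION) -> float:
    """S = (1/f)(1 − μ_n/μ), clipped to [0, 1].

    ``mu`` is the replete growth rate, ``mu_n`` the growth rate under the
    class limitation, ``f`` the fraction of replete uptake still allowed.
    """
    if not 0.0 < f < 1.0:
        raise ValidationError("limitation fraction f must lie in (0, 1)")
    if mu <= 0:
        raise ValidationError("growth sensitivity undefined for mu ≤ 0")
    return float(np.clip((1.0 / f) * (1.0 - mu_n / mu), 0.0, 1.0))


def select_substrates(
    solutions: Iterable[FluxSolution],
    min_models: int = MIN_MODELS_DEFAULT,
    exchange_compounds: Mapping[str, str] | None = None,
) -> set[str]:
    """Compounds imported for growth by at least ``min_models`` solutions.

    ``exchange_compounds`` maps exchange reaction id → compound id; when
    omitted, exchange ids double as compound ids.
    """
    if min_models < 1:
        raise ValidationError("min_models must be ≥ 1")
    counts: dict[str, int] = {}
    for sol in solutions:
        imported = set()
        for rid, flux in sol.fluxes.items():
            if exchange_compounds is not None:
                if rid not in exchange_compounds:
                    continue
                cpd = exchange_compounds[rid]
            else:
                cpd = rid
            if -flux > GROWTH_EPS:
                imported.add(cpd)
        for cpd in imported:
            counts[cpd] = counts.get(cpd, 0) + 1
    return {cpd for cpd, n in counts.items() if n >= min_models}


def import_flux_coverage(
    solution: FluxSolution,
    classified: set[str],
    exchange_compounds: Mapping[str, str],
) -> float:
    """Fraction of total uptake flux magnitude carried by classified compounds.

    Returns 1 by convention when the solution imports nothing.
    """
    if not solution.optimal:
        raise ValidationError("coverage requires an optimal solution")
    total = 0.0
    covered = 0.0
    for ex, cpd in exchange_compounds.items():
        up = solution.uptake(ex)
        total += up
        if cpd in classified:
            covered += up
    return covered / total if total > GROWTH_EPS else 1.0


def limitation_media(
    model: MetabolicModel,
    replete_solution: FluxSolution,
    minimal: MediaSpec,
    class_name: str,
    class_map: CompoundClassMap,
    f: float = LIMITATION_FRACTION,
) -> MediaSpec:
    """Media limiting one compound class to a fraction of its replete uptake.

    Exchanges of ``class_name`` that belong to the minimal media are capped at
    ``f`` times their replete uptake magnitude; the class's remaining
    exchanges are closed so flux cannot be rerouted through substitutes the
    model did not originally need; every other exchange is fully open.
    """
    if class_name not in ALL_CLASSES:
        raise ValidationError(f"unknown compound class {class_name!r}")
    if not 0.0 < f < 1.0:
        raise ValidationError("limitation fraction f must lie in (0, 1)")
    minimal_imports = minimal.active_imports()
    caps: dict[str, float] = {}
    for ex in model.exchange_ids:
        cpd = model.exchange_compound(ex)
        if class_map.class_of(cpd) == class_name:
            caps[ex] = f * replete_solution.uptake(ex) if ex in minimal_imports else 0.0
        else:
            caps[ex] = FLUX_BOUND
    return MediaSpec(caps)


def build_profile(
    ensemble: Ensemble,
    class_map: CompoundClassMap,
    f: float = LIMITATION_FRACTION,
    members: Iterable[int] | None = None,
) -> tuple[list[SensitivityProfile], list[int]]:
    """Sensitivity profiles for every ensemble member.

    Per member: replete FBA → minimal media at the replete growth rate → one
    limitation FBA per organic class → 11 clipped S values. Members with no
    replete growth are excluded and reported in the second return value.
    """
    profiles: list[SensitivityProfile] = []
    failed: list[int] = []
    member_ids = list(members) if members is not None else range(ensemble.n_members)
    for m in member_ids:
        model = instantiate_member(ensemble, m)
        replete = replete_media(model)
        sol = optimize_growth(model, replete)
        if not sol.grows():
            failed.append(m)
            continue
        minimal, _ = minimal_media(model, sol.mu)
        values = []
        for cls in ORGANIC_CLASSES:
            media_n = limitation_media(model, sol, minimal, cls, class_map, f)
            sol_n = optimize_growth(model, media_n)
            mu_n = sol_n.mu if sol_n.optimal else 0.0
            values.append(growth_sensitivity(sol.mu, mu_n, f))
        profiles.append(SensitivityProfile(ensemble.genome_id, m, tuple(values)))
    return profiles, failed


def profiles_to_frame(profiles: Iterable[SensitivityProfile]) -> pd.DataFrame:
    """One row per (genome, member) with the 11 class columns."""
    rows = [(p.genome_id, p.member_index, *p.values) for p in profiles]
    return pd.DataFrame(rows, columns=["genome_id", "member", *ORGANIC_CLASSES])


def variance_filter(
    profiles: pd.DataFrame, cutoff: float = VARIANCE_CUTOFF
) -> set[str]:
    """Genomes whose cumulative across-member sensitivity variance exceeds ``cutoff``.

    The statistic is the sum over the 11 classes of the population variance of
    member sensitivities; genomes above the cutoff have unstable profiles and
    are excluded before clustering. Single-member genomes have variance 0 and
    are never excluded.
    """
    if cutoff <= 0:
        raise ValidationError("variance cutoff must be positive")
    cum_var = (
        profiles.groupby("genome_id")[list(ORGANIC_CLASSES)]
        .var(ddof=0)
        .fillna(0.0)
        .sum(axis=1)
    )
    return set(cum_var.index[cum_var > cutoff])
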