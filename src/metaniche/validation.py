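"""Model-versus-experiment validation protocol.

Each (strain, substrate) pair from a binary experimental growth matrix is
compared with an in-silico sole-carbon growth call on the strain's model
ensemble. Disagreements are retried with trace amounts (< 1% of the maximum
flux) of one or two rescue compounds, then assigned one of five outcomes:

  i    perfect agreement (growth or no-growth);
  ii   agreement once one or two rescue compounds are supplied;
  iii  experimental growth, no model growth, but the catabolic pathway is
       topologically present in the model;
  iv   experimental growth, no model growth, pathway absent;
  v    model growth but no experimental growth.

Accuracy is (i + ii) / total; precision treats growth as the positive class.
A permuted-matrix bootstrap (row sums preserved) provides the null agreement
level that random predictions would reach.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import ORGANIC_CLASSES, CompoundClassMap
from .ensembles import Ensemble, instantiate_member
from .errors import ValidationError
from .fba import optimize_growth
from .model import FLUX_BOUND, MediaSpec, MetabolicModel

SOLE_CARBON_CAP = 10.0
TRACE_FRACTION = 0.005
GROWTH_CALL_MAJORITY = 0.5

CATEGORIES = ("i", "ii", "iii", "iv", "v")


@dataclass(frozen=True)
class OutcomeRecord:
    strain: str
    substrate: str
    category: str  # one of CATEGORIES
    experiment: int  # observed growth bit
    model_call: str  # growth | no_growth | indeterminate

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown outcome category {self.category!r}")


def load_growth_matrix(path) -> pd.DataFrame:
    """Read a strains × substrates binary TSV (index column = strain)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_growth_matrix(df)
    return df


def validate_growth_matrix(matrix: pd.DataFrame) -> None:
    if not matrix.isin([0, 1]).all().all():
        raise ValidationError("growth matrix must be strictly binary")
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValidationError("growth matrix labels must be unique")


def sole_carbon_media(
    model: MetabolicModel,
    substrate: str,
    class_map: CompoundClassMap,
    extra_trace: dict[str, float] | None = None,
    cap: float = SOLE_CARBON_CAP,
) -> MediaSpec:
    """Media with one organic carbon source open and the rest closed.

    The target substrate's exchange is capped at ``cap``; other organic-class
    exchanges are closed; exchanges of inorganic/other compounds (the
    non-carbon essentials) stay fully open. ``extra_trace`` adds rescue
    compounds at their trace caps.
    """
    caps: dict[str, float] = {}
    target_found = False
    for ex in model.exchange_ids:
        cpd = model.exchange_compound(ex)
        if cpd == substrate:
            caps[ex] = cap
            target_found = True
        elif class_map.class_of(cpd) in ORGANIC_CLASSES:
            caps[ex] = 0.0
        else:
            caps[ex] = FLUX_BOUND
    if not target_found:
        raise ValidationError(f"substrate {substrate!r} has no exchange in the model")
    for cpd, trace_cap in (extra_trace or {}).items():
        for ex in model.exchange_ids:
            if model.exchange_compound(ex) == cpd:
                caps[ex] = max(caps[ex], trace_cap)
    return MediaSpec(caps)


def call_ensemble_growth(
    ensemble: Ensemble,
    substrate: str,
    class_map: CompoundClassMap,
    extra_trace: dict[str, float] | None = None,
    members: Iterable[int] | None = None,
) -> str:
    """Aggregate sole-carbon growth call over ensemble members.

    ``no_growth`` if no member grows, ``growth`` if more than half do, and
    ``indeterminate`` for fractions in (0, 0.5] — the gap the aggregation
    rule leaves open.
    """
    member_ids = list(members) if members is not None else range(ensemble.n_members)
    grew = 0
    for m in member_ids:
        model = instantiate_member(ensemble, m)
        media = sole_carbon_media(model, substrate, class_map, extra_trace)
        if optimize_growth(model, media).grows():
            grew += 1
    frac = grew / len(member_ids)
    if frac == 0.0:
        return "no_growth"
    if frac > GROWTH_CALL_MAJORITY:
        return "growth"
    return "indeterminate"


def pathway_present(
    model: MetabolicModel, substrate: str, member_reactions: set[str] | None = None
) -> bool:
    """Topological reachability from a substrate's exchange to biomass.

    Breadth-first search over the member's reaction hypergraph: a reaction
    fires once any of its consumed metabolites is reachable (both directions
    for reversible reactions); the pathway counts as present when the biomass
    reaction itself becomes fireable. Stoichiometric feasibility is
    deliberately ignored — this only splits "pathway missing" from "pathway
    present but numerically unable to grow".
    """
    start = None
    for ex in model.exchange_ids:
        if model.exchange_compound(ex) == substrate:
            (met,) = model.reaction(ex).stoichiometry
            start = met
            break
    if start is None:
        raise ValidationError(f"substrate {substrate!r} has no exchange in the model")
    usable = member_reactions if member_reactions is not None else set(model.reaction_ids)
    reachable = {start}
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions:
            if rxn.id not in usable or rxn.id == model.biomass_id:
                continue
            if rxn.lower_bound == 0 and rxn.upper_bound == 0:
                continue
            consumed = {m for m, c in rxn.stoichiometry.items() if c < 0}
            produced = {m for m, c in rxn.stoichiometry.items() if c > 0}
            if rxn.upper_bound > 0 and consumed & reachable:
                new = produced - reachable
                if new:
                    reachable |= new
                    changed = True
            if rxn.lower_bound < 0 and produced & reachable:
                new = consumed - reachable
                if new:
                    reachable |= new
                    changed = True
    biomass_inputs = {
        m for m, c in model.reaction(model.biomass_id).stoichiometry.items() if c < 0
    }
    return bool(biomass_inputs & reachable)


def rescue_and_classify(
    ensemble: Ensemble,
    substrate: str,
    experiment: int,
    class_map: CompoundClassMap,
    rescue_pool: Sequence[str] = (),
    trace_fraction: float = TRACE_FRACTION,
    members: Iterable[int] | None = None,
) -> OutcomeRecord:
    """Assign the five-outcome category for one (strain, substrate) pair.

    Rescue subsets (all 1- then 2-element combinations of ``rescue_pool``, in
    deterministic order) are tried only when the primary call disagrees with
    the experiment; the first subset restoring agreement yields category ii.
    """
    if not trace_fraction < 0.01:
        raise ValidationError("trace_fraction must stay below 1% of the flux bound")
    call = call_ensemble_growth(ensemble, substrate, class_map, members=members)
    predicted_growth = call == "growth"
    if experiment not in (0, 1):
        raise ValidationError("experiment bit must be 0 or 1")

    if (experiment == 1) == predicted_growth:
        return OutcomeRecord(ensemble.genome_id, substrate, "i", experiment, call)

    if experiment == 0:
        # model grows, experiment does not
        return OutcomeRecord(ensemble.genome_id, substrate, "v", experiment, call)

    # experiment grows, model does not: try rescues, then the pathway split
    trace_cap = trace_fraction * FLUX_BOUND
    subsets = [
        *combinations(sorted(rescue_pool), 1),
        *combinations(sorted(rescue_pool), 2),
    ]
    for subset in subsets:
        rescued = call_ensemble_growth(
            ensemble,
            substrate,
            class_map,
            extra_trace={c: trace_cap for c in subset},
            members=members,
        )
        if rescued == "growth":
            return OutcomeRecord(ensemble.genome_id, substrate, "ii", experiment, call)

    # split iii/iv on whether a majority of members carry the pathway
    member_ids = list(members) if members is not None else range(ensemble.n_members)
    with_pathway = sum(
        pathway_present(instantiate_member(ensemble, m), substrate)
        for m in member_ids
    )
    category = "iii" if with_pathway > len(member_ids) / 2 else "iv"
    return OutcomeRecord(ensemble.genome_id, substrate, category, experiment, call)


def score_agreement(
    records: Sequence[OutcomeRecord],
    exclude_indeterminate: bool = True,
    exclude_substrates: Sequence[str] = (),
) -> dict:
    """Accuracy, precision and category shares over outcome records.

    Accuracy = (i + ii) / total; precision = true growth predictions over all
    growth predictions. Pairs with an indeterminate ensemble call are
    reported separately and excluded by default; ``exclude_substrates``
    drops chemically confounded substrates before scoring.
    """
    kept = [r for r in records if r.substrate not in set(exclude_substrates)]
    indeterminate = [r for r in kept if r.model_call == "indeterminate"]
    if exclude_indeterminate:
        kept = [r for r in kept if r.model_call != "indeterminate"]
    if not kept:
        raise ValidationError("no records to score")
    counts = Counter(r.category for r in kept)
    total = len(kept)
    tp = sum(
        1 for r in kept if r.category in ("i", "ii") and r.experiment == 1
    )
    fp = counts.get("v", 0)
    return {
        "accuracy": (counts.get("i", 0) + counts.get("ii", 0)) / total,
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "counts": {c: counts.get(c, 0) for c in CATEGORIES},
        "shares": {c: counts.get(c, 0) / total for c in CATEGORIES},
        "n_scored": total,
        "n_indeterminate": len(indeterminate),
    }


def matrix_agreement(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Element-wise agreement fraction between two aligned binary matrices."""
    if not a.shape == b.shape:
        raise ValidationError("matrices must share shape")
    return float((a.to_numpy() == b.to_numpy()).mean())


def permutation_null(
    experimental: pd.DataFrame,
    predictions: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Row-sum-preserving permutation null for prediction accuracy.

    Each bootstrap redistributes every strain's positive substrates to random
    positions and scores the permuted matrix against the observed data. The
    real prediction accuracy is declared significant when it exceeds the null
    mean by more than two null standard deviations.
    """
    validate_growth_matrix(experimental)
    if n_boot < 2:
        raise ValidationError("n_boot must be ≥ 2")
    obs = experimental.to_numpy(dtype=np.uint8)
    n_strains, n_subs = obs.shape
    row_sums = obs.sum(axis=1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for b in range(n_boot):
        # rank-of-random trick: mark each row's row_sum smallest random draws
        r = rng.random((n_strains, n_subs))
        ranks = r.argsort(axis=1).argsort(axis=1)
        permuted = ranks < row_sums[:, None]
        null[b] = (permuted == obs).mean()
    real = matrix_agreement(
        predictions.loc[experimental.index, experimental.columns], experimental
    )
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    return {
        "null": null,
        "null_mean": mean,
        "null_sd": sd,
        "real_accuracy": real,
        "significant": bool(real > mean + 2 * sd),
    }
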