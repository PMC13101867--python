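"""Synthetic-data generators for every pipeline input.

Emulates, at desk scale, the five inputs the analysis consumes: toy
stoichiometric models with planted limiting compound classes (stand-ins for
automatically reconstructed genome-scale models), ensembles with stochastic
reaction dropout, member sensitivity profiles drawn around cluster
archetypes, per-genome codon-usage growth proxies (dCUB), region-structured
site × genome abundance tables, and strain × substrate growth matrices tied
to a reference toy model's true capabilities.

One global seed fans out to per-generator streams through
:func:`numpy.random.SeedSequence` spawning, so adding a generator never
perturbs the draws of another.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classes import ORGANIC_CLASSES, CompoundClassMap
from .ensembles import Ensemble
from .errors import ValidationError
from .fba import optimize_growth
from .model import FLUX_BOUND, MediaSpec, MetabolicModel, Reaction

N_MEMBERS_DEFAULT = 60


def split_seed(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one integer seed out into ``n`` independent generator streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Toy stoichiometric networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Blueprint for a toy growth network.

    Each substrate gets an exchange → transport → conversion chain feeding a
    single biomass reaction. Substrates of *limiting* classes convert into a
    class-specific biomass precursor that nothing else can supply; substrates
    of other classes feed one interchangeable carbon pool, so losing part of
    one non-limiting class can be compensated by the others (the toy analogue
    of organisms able to synthesize or substitute essential metabolites).
    """

    classes: tuple[str, ...] = ORGANIC_CLASSES
    limiting_classes: frozenset[str] = frozenset()
    n_substrates_per_class: int = 1
    biomass_yields: Mapping[str, float] = field(default_factory=dict)
    uptake_bound: float | Mapping[str, float] = 10.0
    default_yield: float = 0.5
    limiting_stoich: float = 0.01
    biomass_cap: float = FLUX_BOUND

    def __post_init__(self) -> None:
        if self.n_substrates_per_class < 1:
            raise ValidationError("n_substrates_per_class must be ≥ 1")
        if not set(self.limiting_classes) <= set(self.classes):
            missing = set(self.limiting_classes) - set(self.classes)
            raise ValidationError(f"limiting classes without substrates: {sorted(missing)}")
        if self.default_yield <= 0 or any(y <= 0 for y in self.biomass_yields.values()):
            raise ValidationError("biomass yields must be strictly positive")
        if self.limiting_stoich <= 0:
            raise ValidationError("limiting_stoich must be positive")

    def substrates_of(self, class_name: str) -> list[str]:
        return [f"{class_name}__s{i}" for i in range(self.n_substrates_per_class)]

    def all_substrates(self) -> list[str]:
        return [s for c in self.classes for s in self.substrates_of(c)]

    def yield_of(self, compound: str) -> float:
        return float(self.biomass_yields.get(compound, self.default_yield))

    def uptake_of(self, compound: str) -> float:
        if isinstance(self.uptake_bound, Mapping):
            return float(self.uptake_bound.get(compound, 10.0))
        return float(self.uptake_bound)


def make_toy_model(spec: ToyNetworkSpec, model_id: str = "toy") -> MetabolicModel:
    """Build the mass-balanced toy network described by ``spec``.

    Per substrate ``s``: ``EX_s`` (boundary, bounds ±1000), ``T_s`` (uptake
    transport, capacity = the spec's per-substrate uptake bound) and a
    conversion into either the shared carbon pool or the limiting class's
    precursor with the substrate's biomass yield. The biomass reaction drains
    one unit of pool plus ``limiting_stoich`` of every limiting-class
    precursor per unit growth.
    """
    metabolites: dict[str, str] = {}
    reactions: list[Reaction] = []
    exchange_ids: list[str] = []
    nonlimiting = [c for c in spec.classes if c not in spec.limiting_classes]

    if nonlimiting:
        metabolites["pool_c"] = "c"
    for cls in spec.limiting_classes:
        metabolites[f"prec_{cls}_c"] = "c"

    for cls in spec.classes:
        target = "pool_c" if cls in nonlimiting else f"prec_{cls}_c"
        for s in spec.substrates_of(cls):
            ext, cyt = f"{s}_e", f"{s}_c"
            metabolites[ext] = "e"
            metabolites[cyt] = "c"
            ex_id = f"EX_{s}"
            exchange_ids.append(ex_id)
            reactions.append(Reaction(ex_id, {ext: -1.0}, -FLUX_BOUND, FLUX_BOUND))
            reactions.append(
                Reaction(f"T_{s}", {ext: -1.0, cyt: 1.0}, 0.0, spec.uptake_of(s))
            )
            reactions.append(
                Reaction(f"CONV_{s}", {cyt: -1.0, target: spec.yield_of(s)}, 0.0, FLUX_BOUND)
            )

    biomass_stoich: dict[str, float] = {}
    if nonlimiting:
        biomass_stoich["pool_c"] = -1.0
    for cls in spec.limiting_classes:
        biomass_stoich[f"prec_{cls}_c"] = -spec.limiting_stoich
    if not biomass_stoich:
        raise ValidationError("toy network needs at least one substrate class")
    reactions.append(Reaction("BIOMASS", biomass_stoich, 0.0, spec.biomass_cap))

    model = MetabolicModel(model_id, metabolites, reactions, exchange_ids, "BIOMASS")
    model.validate()
    return model


def toy_class_map(spec: ToyNetworkSpec) -> CompoundClassMap:
    """Compound → class mapping for a toy network's substrates."""
    return CompoundClassMap(
        {s: cls for cls in spec.classes for s in spec.substrates_of(cls)}
    )


# ---------------------------------------------------------------------------
# Ensemble dropout
# ---------------------------------------------------------------------------


def perturb_ensemble(
    model: MetabolicModel,
    dropout: float,
    n_models: int,
    seed: int,
) -> Ensemble:
    """Ensemble of ``n_models`` members with Bernoulli reaction dropout.

    Emulates stochastic ensemble reconstruction: each non-core reaction is
    independently absent with probability ``dropout`` in each member; the
    biomass reaction and all exchanges (the core) are always retained.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValidationError("dropout must lie in [0, 1)")
    if n_models < 1:
        raise ValidationError("n_models must be ≥ 1")
    rng = np.random.default_rng(seed)
    core = set(model.exchange_ids) | {model.biomass_id}
    rids = model.reaction_ids
    presence = np.ones((n_models, len(rids)), dtype=np.uint8)
    noncore_cols = [j for j, r in enumerate(rids) if r not in core]
    if noncore_cols and dropout > 0:
        draws = rng.random((n_models, len(noncore_cols))) >= dropout
        presence[:, noncore_cols] = draws.astype(np.uint8)
    return Ensemble(model.id, list(rids), presence, base_model=model)


# ---------------------------------------------------------------------------
# Archetype sensitivity profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted niche cluster: mean sensitivity vector, noise and size."""

    cluster_id: int
    mean_sensitivity: tuple[float, ...]  # 11 entries, one per organic class
    sensitivity_sd: float
    mean_dcub: float
    dcub_sd: float
    n_genomes: int

    def __post_init__(self) -> None:
        if len(self.mean_sensitivity) != len(ORGANIC_CLASSES):
            raise ValidationError(
                f"mean_sensitivity needs {len(ORGANIC_CLASSES)} entries"
            )
        if any(not 0.0 <= v <= 1.0 for v in self.mean_sensitivity):
            raise ValidationError("mean sensitivities must lie in [0, 1]")
        if self.sensitivity_sd < 0 or self.dcub_sd < 0:
            raise ValidationError("standard deviations must be ≥ 0")
        if self.n_genomes < 1:
            raise ValidationError("n_genomes must be ≥ 1")

    def genome_ids(self) -> list[str]:
        return [f"g{self.cluster_id}_{i:03d}" for i in range(self.n_genomes)]


def simulate_profiles(
    archetypes: Sequence[ArchetypeSpec],
    seed: int,
    n_members: int = N_MEMBERS_DEFAULT,
) -> pd.DataFrame:
    """Member sensitivity profiles drawn around planted archetype means.

    Returns one row per (genome, member) with the 11 organic-class columns
    plus ``genome_id``, ``member`` and the planted ``true_cluster`` label
    kept for recovery tests. Noise is Gaussian clipped to [0, 1], preserving
    the sensitivity statistic's range.
    """
    if not archetypes:
        raise ValidationError("need at least one archetype")
    (rng,) = split_seed(seed, 1)
    rows = []
    for arch in archetypes:
        mean = np.asarray(arch.mean_sensitivity)
        for gid in arch.genome_ids():
            noise = rng.normal(0.0, arch.sensitivity_sd, size=(n_members, len(mean)))
            values = np.clip(mean + noise, 0.0, 1.0)
            for m in range(n_members):
                rows.append((gid, m, arch.cluster_id, *values[m]))
    return pd.DataFrame(
        rows, columns=["genome_id", "member", "true_cluster", *ORGANIC_CLASSES]
    )


def simulate_tables(
    archetypes: Sequence[ArchetypeSpec],
    regions: Sequence[str],
    seed: int,
    *,
    n_sites_per_region: int = 6,
    enrichment: Mapping[tuple[str, int], float] | None = None,
    region_categories: Mapping[str, str] | None = None,
    growth_spec: ToyNetworkSpec | None = None,
    growth_error_rate: float = 0.0,
) -> tuple[pd.DataFrame, "AbundanceTable", pd.DataFrame]:
    """Generate the dCUB, abundance and experimental-growth inputs.

    * dCUB table: one Gaussian draw per genome around its archetype mean.
    * Abundance table: lognormal per-genome RPKM baselines scaled by the
      region × cluster ``enrichment`` factor (default 1 everywhere), with a
      site metadata frame carrying region and category labels.
    * Growth matrix: each genome-strain inherits the reference toy model's
      true sole-substrate growth capabilities, bit-flipped at
      ``growth_error_rate``.
    """
    from .biogeo import AbundanceTable  # local import to avoid a cycle

    if not regions:
        raise ValidationError("need at least one region")
    if not 0.0 <= growth_error_rate <= 1.0:
        raise ValidationError("growth_error_rate must lie in [0, 1]")
    rng_dcub, rng_abund, rng_growth = split_seed(seed, 3)
    enrichment = enrichment or {}

    genomes, clusters, dcub = [], [], []
    for arch in archetypes:
        for gid in arch.genome_ids():
            genomes.append(gid)
            clusters.append(arch.cluster_id)
            dcub.append(rng_dcub.normal(arch.mean_dcub, arch.dcub_sd))
    dcub_table = pd.DataFrame({"genome_id": genomes, "dcub": dcub})

    sites, site_regions = [], []
    values = np.empty((len(regions) * n_sites_per_region, len(genomes)))
    row = 0
    for region in regions:
        for s in range(n_sites_per_region):
            sites.append(f"{region}_site{s}")
            site_regions.append(region)
            base = rng_abund.lognormal(mean=1.0, sigma=0.4, size=len(genomes))
            factors = np.array(
                [enrichment.get((region, c), 1.0) for c in clusters]
            )
            values[row] = base * factors
            row += 1
    metadata = pd.DataFrame(
        {
            "region": site_regions,
            "category": [
                (region_categories or {}).get(r, "Coastal") for r in site_regions
            ],
        },
        index=pd.Index(sites, name="site"),
    )
    abundance = AbundanceTable(
        pd.DataFrame(values, index=metadata.index, columns=genomes), metadata
    )

    # Default reference network: 4 classes × 2 substrates, the second
    # substrate of each class lacking transport capacity, so true growth
    # capability is a mixed 0/1 pattern rather than all-ones.
    spec = growth_spec or ToyNetworkSpec(
        classes=ORGANIC_CLASSES[:4],
        n_substrates_per_class=2,
        uptake_bound={f"{c}__s1": 0.0 for c in ORGANIC_CLASSES[:4]},
    )
    truth = true_growth_vector(spec)
    substrates = list(truth.index)
    bits = np.tile(truth.to_numpy(dtype=np.uint8), (len(genomes), 1))
    if growth_error_rate > 0:
        flips = rng_growth.random(bits.shape) < growth_error_rate
        bits = np.where(flips, 1 - bits, bits)
    growth = pd.DataFrame(
        bits, index=pd.Index(genomes, name="strain"), columns=substrates
    )
    return dcub_table, abundance, growth


def true_growth_vector(spec: ToyNetworkSpec) -> pd.Series:
    """Sole-substrate growth capability of the toy network, by FBA.

    For each substrate, only its exchange is opened (all others closed) and
    growth is called at the standard epsilon. Substrates of limiting classes
    cannot sustain growth alone whenever another requirement exists.
    """
    model = make_toy_model(spec)
    result = {}
    for s in spec.all_substrates():
        media = MediaSpec({f"EX_{s}": spec.uptake_of(s)})
        result[s] = int(optimize_growth(model, media).grows())
    return pd.Series(result, name="grows")
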