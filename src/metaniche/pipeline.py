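"""End-to-end pipeline orchestration.

Runs the stages in dependency order — simulate → qc → sensitivity → cluster
→ stats → validate → biogeo — on a synthetic study generated from the
bundled reference archetypes, writing per-stage TSV/JSON artifacts plus a
run manifest (config hash, seeds, per-stage outputs). Deterministic stages
reproduce identical artifacts for identical configs.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biogeo, clustering, datasets, ensembles, growth, sensitivity, simulate, som, validation
from .classes import ORGANIC_CLASSES
from .errors import ValidationError

STAGE_ORDER = ("simulate", "qc", "sensitivity", "cluster", "stats", "validate", "biogeo")


@dataclass
class PipelineConfig:
    """All thresholds, sizes and seeds for a pipeline run."""

    out_dir: str = "metaniche_run"
    seed: int = 0

    # study size (synthetic)
    n_genomes_per_cluster: int = 8
    n_members: int = 12
    ensemble_dropout: float = 0.1
    n_qc_genomes: int = 6
    sensitivity_sd: float = 0.02
    dcub_sd: float = 0.03
    regions: tuple[str, ...] = ("Estuarine", "Coastal", "Oligotrophic")

    # thresholds (the analysis constants)
    consensus_threshold: float = 0.8
    substantial_s: float = 0.8
    variance_cutoff: float = 0.1
    dcub_threshold: float = -0.08
    limitation_fraction: float = 0.5
    min_models: int = 10

    # SOM / k-means
    som_width: int = 10
    som_height: int = 10
    som_iterations: int = 150
    learning_rate_start: float = 0.025
    learning_rate_end: float = 0.01
    k: int = 8

    # bootstraps
    bootstrap_n_draw: int = 185
    bootstrap_n_boot: int = 2000
    permutation_n_boot: int = 1000
    recruit_n_iter: int = 200
    recruit_n_draw: int = 2000
    recruit_seed: int = 123

    def __post_init__(self) -> None:
        if not 0.0 <= self.consensus_threshold <= 1.0:
            raise ValidationError("consensus threshold outside [0, 1]")
        if not 0.0 < self.limitation_fraction < 1.0:
            raise ValidationError("limitation fraction outside (0, 1)")
        if self.variance_cutoff <= 0:
            raise ValidationError("variance cutoff must be positive")

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["regions"] = list(data["regions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        data = asdict(self)
        data["regions"] = list(data["regions"])
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] | None = None
) -> dict:
    """Execute the requested stages and return the run manifest."""
    requested = tuple(stages) if stages else STAGE_ORDER
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    todo = [s for s in STAGE_ORDER if s in requested]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest.update(json.loads(manifest_path.read_text()))
        manifest["config_hash"] = config.digest()
        manifest["seed"] = config.seed

    for stage in todo:
        t0 = time.perf_counter()
        artifacts = _STAGES[stage](config, out)
        manifest["stages"][stage] = {
            "artifacts": artifacts,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise ValidationError(
            f"missing artifact {name!r}; run the {stage!r} stage first"
        )
    return path


# -- stage implementations ------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    archetypes = datasets.reference_archetypes(
        sensitivity_sd=cfg.sensitivity_sd,
        dcub_sd=cfg.dcub_sd,
        n_genomes=cfg.n_genomes_per_cluster,
    )
    profiles = simulate.simulate_profiles(archetypes, cfg.seed, cfg.n_members)
    profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)

    dcub, abundance, growth_matrix = simulate.simulate_tables(
        archetypes,
        list(cfg.regions),
        cfg.seed + 1,
        enrichment={(cfg.regions[0], 6): 2.0, (cfg.regions[-1], 8): 2.0},
    )
    dcub.to_csv(out / "dcub.tsv", sep="\t", index=False)
    abundance.to_tsv(out / "abundance.tsv", out / "sites.tsv")
    growth_matrix.to_csv(out / "growth_matrix.tsv", sep="\t")

    spec = simulate.ToyNetworkSpec(
        classes=ORGANIC_CLASSES[:4],
        limiting_classes=frozenset({ORGANIC_CLASSES[0]}),
        n_substrates_per_class=1,
    )
    model = simulate.make_toy_model(spec)
    simulate.toy_class_map(spec).to_tsv(out / "class_map.tsv")
    rng_seeds = np.random.SeedSequence(cfg.seed + 2).generate_state(cfg.n_qc_genomes)
    for i, s in enumerate(rng_seeds):
        ens = simulate.perturb_ensemble(
            model, cfg.ensemble_dropout, cfg.n_members, int(s % (2**31))
        )
        ens.genome_id = f"toy_{i:02d}"
        ens.to_tsv(out / f"ensemble_toy_{i:02d}.tsv")
    from .sbml import write_sbml

    write_sbml(model, out / "toy_model.xml")
    return [
        "profiles.tsv", "dcub.tsv", "abundance.tsv", "sites.tsv",
        "growth_matrix.tsv", "class_map.tsv", "toy_model.xml",
    ]


def _load_toy_ensembles(cfg: PipelineConfig, out: Path):
    from .sbml import read_sbml

    model = read_sbml(_require(out, "toy_model.xml", "simulate"))
    ens = []
    for path in sorted(out.glob("ensemble_toy_*.tsv")):
        ens.append(ensembles.Ensemble.from_tsv(path, path.stem.replace("ensemble_", ""), model))
    if not ens:
        raise ValidationError("no ensembles found; run the 'simulate' stage first")
    return ens


def _stage_qc(cfg: PipelineConfig, out: Path) -> list[str]:
    ens = _load_toy_ensembles(cfg, out)
    scores = [ensembles.consensus_score(e) for e in ens]
    report = ensembles.consensus_report(scores)
    report["retained"] = report["consensus"] >= cfg.consensus_threshold
    report.to_csv(out / "consensus.tsv", sep="\t", index=False)
    curve = pd.DataFrame(
        ensembles.accumulation_curve(ens[0], cfg.seed),
        columns=["members", "distinct_reactions"],
    )
    curve.to_csv(out / "accumulation.tsv", sep="\t", index=False)
    return ["consensus.tsv", "accumulation.tsv"]


def _stage_sensitivity(cfg: PipelineConfig, out: Path) -> list[str]:
    from .classes import CompoundClassMap

    ens = _load_toy_ensembles(cfg, out)
    class_map = CompoundClassMap.from_tsv(_require(out, "class_map.tsv", "simulate"))
    consensus = pd.read_csv(_require(out, "consensus.tsv", "qc"), sep="\t")
    retained = set(consensus.loc[consensus["retained"], "genome_id"])
    all_profiles = []
    for e in ens:
        if e.genome_id not in retained:
            continue
        profiles, _failed = sensitivity.build_profile(
            e, class_map, cfg.limitation_fraction
        )
        all_profiles.extend(profiles)
    frame = sensitivity.profiles_to_frame(all_profiles)
    frame.to_csv(out / "toy_profiles.tsv", sep="\t", index=False)
    excluded = sensitivity.variance_filter(frame, cfg.variance_cutoff)
    (out / "variance_excluded.json").write_text(json.dumps(sorted(excluded)))
    return ["toy_profiles.tsv", "variance_excluded.json"]


def _stage_cluster(cfg: PipelineConfig, out: Path) -> list[str]:
    profiles = pd.read_csv(_require(out, "profiles.tsv", "simulate"), sep="\t")
    excluded = sensitivity.variance_filter(profiles, cfg.variance_cutoff)
    profiles = profiles[~profiles["genome_id"].isin(excluded)]
    cfg_som = som.TrainConfig(
        iterations=cfg.som_iterations,
        learning_rate_start=cfg.learning_rate_start,
        learning_rate_end=cfg.learning_rate_end,
        seed=cfg.seed,
    )
    grid = som.train_som(
        profiles[list(ORGANIC_CLASSES)].to_numpy(),
        cfg_som,
        cfg.som_width,
        cfg.som_height,
    )
    cm = clustering.cluster_nodes(grid, cfg.k, cfg.seed)
    clustering.assign_genomes(cm, grid, profiles)
    cm.report().to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(grid.codebooks, columns=list(ORGANIC_CLASSES)).to_csv(
        out / "codebooks.tsv", sep="\t", index=False
    )
    summary = {
        "quantization_error": som.quantization_error(
            grid, profiles[list(ORGANIC_CLASSES)].to_numpy()
        ),
    }
    if "true_cluster" in profiles.columns:
        truth = profiles.groupby("genome_id")["true_cluster"].first()
        summary["planted_ari"] = clustering.adjusted_rand_index(
            dict(truth), dict(cm.genome_assignment)
        )
    (out / "cluster_summary.json").write_text(json.dumps(summary, indent=2))
    return ["clusters.tsv", "codebooks.tsv", "cluster_summary.json"]


def _stage_stats(cfg: PipelineConfig, out: Path) -> list[str]:
    clusters = pd.read_csv(_require(out, "clusters.tsv", "cluster"), sep="\t")
    dcub = pd.read_csv(_require(out, "dcub.tsv", "simulate"), sep="\t")
    merged = clusters.merge(dcub, on="genome_id")
    profiles = pd.read_csv(out / "profiles.tsv", sep="\t")
    mean_sens = (
        profiles.groupby("genome_id")[list(ORGANIC_CLASSES)].mean().mean(axis=1)
    )
    summaries = growth.summarize_clusters(
        dict(zip(merged["genome_id"], merged["cluster"])),
        dict(zip(merged["genome_id"], merged["dcub"])),
        dict(mean_sens),
        cfg.dcub_threshold,
    )
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "cluster_stats.tsv", sep="\t", index=False
    )
    by_cluster = {
        int(c): grp["dcub"].to_numpy() for c, grp in merged.groupby("cluster")
    }
    pvals = growth.compare_clusters(by_cluster)
    pvals.to_csv(out / "pairwise_pvalues.tsv", sep="\t", index=False)
    boot = growth.bootstrap_fast_fraction(
        merged["dcub"].to_numpy(),
        {s.cluster_id: s.fast_fraction for s in summaries},
        cfg.bootstrap_n_draw,
        cfg.bootstrap_n_boot,
        cfg.seed,
        cfg.dcub_threshold,
    )
    boot.to_csv(out / "fast_fraction_bootstrap.tsv", sep="\t", index=False)
    slope, intercept, adj_r2 = growth.regress_sensitivity_vs_growth(summaries)
    (out / "regression.json").write_text(
        json.dumps({"slope": slope, "intercept": intercept, "adjusted_r2": adj_r2})
    )
    return [
        "cluster_stats.tsv", "pairwise_pvalues.tsv",
        "fast_fraction_bootstrap.tsv", "regression.json",
    ]


def _stage_validate(cfg: PipelineConfig, out: Path) -> list[str]:
    from .classes import CompoundClassMap

    matrix = validation.load_growth_matrix(_require(out, "growth_matrix.tsv", "simulate"))
    # model predictions: the reference network's true capabilities
    truth = simulate.true_growth_vector(
        simulate.ToyNetworkSpec(
            classes=ORGANIC_CLASSES[:4],
            n_substrates_per_class=2,
            uptake_bound={f"{c}__s1": 0.0 for c in ORGANIC_CLASSES[:4]},
        )
    )
    predictions = pd.DataFrame(
        np.tile(truth.to_numpy(dtype=np.uint8), (len(matrix), 1)),
        index=matrix.index,
        columns=truth.index,
    )[matrix.columns]
    null = validation.permutation_null(
        matrix, predictions, cfg.permutation_n_boot, cfg.seed
    )
    report = {
        "real_accuracy": null["real_accuracy"],
        "null_mean": null["null_mean"],
        "null_sd": null["null_sd"],
        "significant": null["significant"],
    }
    (out / "validation.json").write_text(json.dumps(report, indent=2))
    return ["validation.json"]


def _stage_biogeo(cfg: PipelineConfig, out: Path) -> list[str]:
    table = biogeo.AbundanceTable.from_tsv(
        _require(out, "abundance.tsv", "simulate"), out / "sites.tsv"
    )
    clusters = pd.read_csv(_require(out, "clusters.tsv", "cluster"), sep="\t")
    assignment = dict(zip(clusters["genome_id"], clusters["cluster"]))
    ca = biogeo.cluster_relative_abundance(table, assignment)
    ca.relative.to_csv(out / "cluster_abundance.tsv", sep="\t")
    ca.z_scores.to_csv(out / "cluster_abundance_z.tsv", sep="\t")
    recruit = biogeo.bootstrap_recruitment(
        table, assignment, cfg.recruit_n_iter, cfg.recruit_n_draw, cfg.recruit_seed
    )
    recruit.to_csv(out / "recruitment.tsv", sep="\t", index=False)
    coords, result = biogeo.ordinate_sites(ca.relative, seed=cfg.seed)
    coords.assign(stress=result.stress).to_csv(out / "nmds.tsv", sep="\t")
    Z = biogeo.hierarchical_regions(ca.relative)
    (out / "regions.nwk").write_text(
        biogeo.linkage_to_newick(Z, list(ca.relative.index))
    )
    return [
        "cluster_abundance.tsv", "cluster_abundance_z.tsv",
        "recruitment.tsv", "nmds.tsv", "regions.nwk",
    ]


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "sensitivity": _stage_sensitivity,
    "cluster": _stage_cluster,
    "stats": _stage_stats,
    "validate": _stage_validate,
    "biogeo": _stage_biogeo,
}
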