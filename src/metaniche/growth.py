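"""Growth-strategy statistics from codon-usage bias.

dCUB — the difference in codon usage bias between ribosomal proteins and the
genome background — proxies optimization for fast maximal growth: more
negative is faster, and values are only informative below −0.08 (above that
threshold organisms are indistinguishably slow). Clusters are compared by
pairwise rank-sum tests with Bonferroni correction, by bootstrapping the
fast-grower proportion against the pooled distribution, and by regressing
mean cluster sensitivity on mean cluster dCUB.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DCUB_THRESHOLD = -0.08
BOOTSTRAP_N_DRAW = 185
BOOTSTRAP_N_BOOT = 10_000


@dataclass(frozen=True)
class GrowthEstimate:
    genome_id: str
    dcub: float

    @property
    def is_fast(self) -> bool:
        return classify_growth(self.dcub)


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    n_genomes: int
    mean_dcub: float
    mean_sensitivity: float
    fast_fraction: float


def classify_growth(dcub: float, threshold: float = DCUB_THRESHOLD) -> bool:
    """True iff the genome is a fast grower (dcub strictly below threshold)."""
    if not np.isfinite(dcub):
        raise ValidationError("dcub must be finite")
    return bool(dcub < threshold)


def compare_clusters(dcub_by_cluster: Mapping[int, Sequence[float]]) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests with Bonferroni correction.

    Returns one row per cluster pair with raw and corrected p-values
    (correction factor = number of tested pairs, capped at 1). Pairs with a
    cluster of fewer than 2 genomes are skipped.
    """
    usable = {c: np.asarray(v, dtype=float) for c, v in dcub_by_cluster.items()}
    pairs = [
        (a, b)
        for a, b in combinations(sorted(usable), 2)
        if len(usable[a]) >= 2 and len(usable[b]) >= 2
    ]
    if not pairs:
        raise ValidationError("need at least two clusters with ≥ 2 genomes")
    rows = []
    for a, b in pairs:
        stat, p = stats.mannwhitneyu(
            usable[a], usable[b], alternative="two-sided", method="auto"
        )
        rows.append((a, b, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "statistic", "p_raw"])
    out["p_bonferroni"] = (out["p_raw"] * len(pairs)).clip(upper=1.0)
    return out


def bootstrap_fast_fraction(
    dcub_values: Sequence[float],
    cluster_fractions: Mapping[int, float],
    n_draw: int = BOOTSTRAP_N_DRAW,
    n_boot: int = BOOTSTRAP_N_BOOT,
    seed: int = 0,
    threshold: float = DCUB_THRESHOLD,
) -> pd.DataFrame:
    """Place each cluster's fast-grower fraction against a pooled null.

    Resamples ``n_draw`` genomes (with replacement) from the pooled dCUB
    values ``n_boot`` times, computes the fast fraction of each resample,
    and labels each cluster ``below`` / ``within`` / ``above`` the null mean
    ± 2 standard deviations.
    """
    pool = np.asarray(dcub_values, dtype=float)
    if len(pool) == 0:
        raise ValidationError("empty dCUB pool")
    if n_draw < 1 or n_boot < 2:
        raise ValidationError("need n_draw ≥ 1 and n_boot ≥ 2")
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_boot, n_draw), replace=True)
    fractions = (draws < threshold).mean(axis=1)
    mean, sd = float(fractions.mean()), float(fractions.std(ddof=0))
    lo, hi = mean - 2 * sd, mean + 2 * sd
    rows = []
    for cid, frac in sorted(cluster_fractions.items()):
        group = "below" if frac < lo else ("above" if frac > hi else "within")
        rows.append((cid, frac, mean, sd, group))
    return pd.DataFrame(
        rows,
        columns=["cluster", "fast_fraction", "null_mean", "null_sd", "group"],
    )


def regress_sensitivity_vs_growth(
    summaries: Sequence[ClusterSummary],
) -> tuple[float, float, float]:
    """OLS of mean cluster sensitivity on mean cluster dCUB.

    Returns (slope, intercept, adjusted R²) with
    adj R² = 1 − (1 − R²)(n − 1)/(n − 2). Zero response variance yields
    R² = 0 by convention.
    """
    if len(summaries) < 3:
        raise ValidationError("need at least 3 clusters to regress")
    x = np.array([s.mean_dcub for s in summaries])
    y = np.array([s.mean_sensitivity for s in summaries])
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in mean dCUB predictor")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(res.slope), float(res.intercept), float(adj)


def summarize_clusters(
    assignment: Mapping[str, int],
    dcub: Mapping[str, float],
    mean_sensitivity: Mapping[str, float],
    threshold: float = DCUB_THRESHOLD,
) -> list[ClusterSummary]:
    """Aggregate per-genome dCUB and mean sensitivity into cluster summaries."""
    by_cluster: dict[int, list[str]] = {}
    for gid, cid in assignment.items():
        by_cluster.setdefault(cid, []).append(gid)
    out = []
    for cid, gids in sorted(by_cluster.items()):
        d = np.array([dcub[g] for g in gids])
        s = np.array([mean_sensitivity[g] for g in gids])
        out.append(
            ClusterSummary(
                cluster_id=cid,
                n_genomes=len(gids),
                mean_dcub=float(d.mean()),
                mean_sensitivity=float(s.mean()),
                fast_fraction=float((d < threshold).mean()),
            )
        )
    return out


def taxon_enrichment(
    cluster_labels: Mapping[str, int], taxon_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Percent enrichment of each taxon within each cluster.

    100 · (in-cluster frequency / whole-dataset frequency − 1); a taxon at
    twice its dataset-wide frequency inside a cluster scores +100%.
    """
    genomes = sorted(set(cluster_labels) & set(taxon_labels))
    if not genomes:
        raise ValidationError("no genomes shared between label maps")
    df = pd.DataFrame(
        {
            "cluster": [cluster_labels[g] for g in genomes],
            "taxon": [taxon_labels[g] for g in genomes],
        }
    )
    overall = df["taxon"].value_counts(normalize=True)
    rows = []
    for cid, grp in df.groupby("cluster"):
        freqs = grp["taxon"].value_counts(normalize=True)
        for taxon, f in freqs.items():
            rows.append((cid, taxon, 100.0 * (f / overall[taxon] - 1.0)))
    return pd.DataFrame(rows, columns=["cluster", "taxon", "enrichment_pct"])
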