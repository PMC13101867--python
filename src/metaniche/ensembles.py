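"""Ensemble data model, consensus scoring and member instantiation.

An ensemble is a genome's reaction universe plus a binary members × reactions
presence matrix produced by stochastic reconstruction. The consensus score

    C = (1/R) Σ_r (1/M) Σ_m I(X_mr = 1)

— the mean over the reaction universe of the fraction of members carrying
each reaction — measures how consistently the reconstruction recovered the
same network; high-consensus ensembles (C ≥ 0.8 by default) are the ones
worth profiling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import MetabolicModel

CONSENSUS_THRESHOLD = 0.8


@dataclass
class Ensemble:
    """Reaction universe and presence matrix for one genome's model ensemble.

    The universe is the union of member reaction sets: columns that are absent
    from every member are unobservable from the ensemble and are dropped at
    construction. ``base_model`` (optional) carries the stoichiometry and
    bounds of every universe reaction and is required only for member
    instantiation.
    """

    genome_id: str
    reaction_ids: list[str]
    presence: np.ndarray  # M × R, uint8
    base_model: MetabolicModel | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.ndim != 2:
            raise ValidationError("presence matrix must be 2-D (members × reactions)")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("presence matrix must be strictly binary")
        if self.presence.shape[0] < 1:
            raise ValidationError("ensemble needs at least one member")
        if self.presence.shape[1] != len(self.reaction_ids):
            raise ValidationError("presence columns must match reaction_ids")
        keep = self.presence.any(axis=0)
        if not keep.all():
            self.presence = self.presence[:, keep]
            self.reaction_ids = [r for r, k in zip(self.reaction_ids, keep) if k]
        if not self.reaction_ids:
            raise ValidationError("empty reaction universe")
        self.presence = self.presence.astype(np.uint8)

    @property
    def n_members(self) -> int:
        return self.presence.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.presence.shape[1]

    # -- serialization ---------------------------------------------------

    def presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence,
            index=pd.RangeIndex(self.n_members, name="member"),
            columns=self.reaction_ids,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the presence matrix (rows = members, columns = reactions)."""
        self.presence_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        genome_id: str | None = None,
        base_model: MetabolicModel | None = None,
    ) -> "Ensemble":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gid = genome_id if genome_id is not None else Path(path).stem
        return cls(gid, list(df.columns), df.to_numpy(), base_model)


@dataclass(frozen=True)
class ConsensusScore:
    genome_id: str
    value: float
    n_members: int = 0
    n_reactions: int = 0


def consensus_score(ensemble: Ensemble) -> ConsensusScore:
    """Mean over reactions of the fraction of members containing each.

    Bounded in (0, 1]: the union convention guarantees every column has at
    least one presence, so C ≥ 1/M.
    """
    value = float(ensemble.presence.mean())
    return ConsensusScore(
        ensemble.genome_id, value, ensemble.n_members, ensemble.n_reactions
    )


def filter_ensembles(
    scores: Iterable[ConsensusScore], threshold: float = CONSENSUS_THRESHOLD
) -> set[str]:
    """Genome ids whose consensus is at or above ``threshold`` (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("consensus threshold must lie in [0, 1]")
    return {s.genome_id for s in scores if s.value >= threshold}


def instantiate_member(ensemble: Ensemble, index: int) -> MetabolicModel:
    """Materialize ensemble member ``index`` from the base model.

    Reactions the member lacks have both bounds set to zero (never removed),
    so every member shares the base model's shape; present reactions keep
    their original bounds and directionality.
    """
    if ensemble.base_model is None:
        raise ValidationError(
            f"ensemble {ensemble.genome_id!r} has no base model to instantiate from"
        )
    if not 0 <= index < ensemble.n_members:
        raise ValidationError(
            f"member index {index} out of range [0, {ensemble.n_members})"
        )
    present = {
        rid for rid, bit in zip(ensemble.reaction_ids, ensemble.presence[index]) if bit
    }
    base = ensemble.base_model
    member = base.copy()
    member.id = f"{base.id}__m{index}"
    member.reactions = [
        r if r.id in present else r.with_bounds(0.0, 0.0) for r in base.reactions
    ]
    member.__post_init__()
    return member


def accumulation_curve(
    ensemble: Ensemble, order_seed: int = 0
) -> list[tuple[int, int]]:
    """Cumulative distinct-reaction count over a seeded random member order.

    The saturation diagnostic behind choosing an ensemble size: the curve
    plateaus once additional members stop contributing new reactions, and its
    final value is the universe size R.
    """
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(ensemble.n_members)
    seen = np.zeros(ensemble.n_reactions, dtype=bool)
    curve = []
    for count, m in enumerate(order, start=1):
        seen |= ensemble.presence[m].astype(bool)
        curve.append((count, int(seen.sum())))
    return curve


def consensus_report(scores: Iterable[ConsensusScore]) -> pd.DataFrame:
    """Tabular consensus report (genome_id, C, M, R)."""
    return pd.DataFrame(
        [(s.genome_id, s.value, s.n_members, s.n_reactions) for s in scores],
        columns=["genome_id", "consensus", "n_members", "n_reactions"],
    )
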