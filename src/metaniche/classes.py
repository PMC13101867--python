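"""Compound-class vocabulary and compound → class mapping.

Imported growth substrates are grouped into 13 broad chemical categories —
11 organic classes used for sensitivity profiling plus ``inorganics`` and
``other``, which are excluded from profiling but stay open in limitation
media.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

#: The 11 organic substrate classes, in canonical profile order.
ORGANIC_CLASSES: tuple[str, ...] = (
    "carboxylic_acids",
    "amino_acids",
    "peptides",
    "nucleotides",
    "carbohydrates",
    "ketones_aldehydes",
    "organic_sulfur",
    "phospholipids",
    "alcohols",
    "amines_amides",
    "b_vitamins",
)

#: All 13 categories (11 organic + inorganics + other).
ALL_CLASSES: tuple[str, ...] = ORGANIC_CLASSES + ("inorganics", "other")


@dataclass(frozen=True)
class CompoundClassMap:
    """One-to-one mapping of compound ids to the fixed class vocabulary."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in ALL_CLASSES}
        if bad:
            raise ValidationError(f"unknown compound classes: {sorted(bad)}")

    def class_of(self, compound_id: str) -> str:
        """Class of a compound; unmapped compounds fall into ``other``."""
        return self.mapping.get(compound_id, "other")

    def compounds_in(self, class_name: str) -> set[str]:
        if class_name not in ALL_CLASSES:
            raise ValidationError(f"unknown compound class {class_name!r}")
        return {c for c, n in self.mapping.items() if n == class_name}

    def organic_compounds(self) -> set[str]:
        return {c for c, n in self.mapping.items() if n in ORGANIC_CLASSES}

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompoundClassMap":
        """Load a two-column TSV (compound_id, class_name) with a header."""
        df = pd.read_csv(path, sep="\t")
        if not {"compound_id", "class_name"} <= set(df.columns):
            raise ValidationError(
                "class map TSV needs 'compound_id' and 'class_name' columns"
            )
        dup = df["compound_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"compounds mapped twice: {sorted(df.loc[dup, 'compound_id'])}"
            )
        return cls(dict(zip(df["compound_id"], df["class_name"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"compound_id": list(self.mapping), "class_name": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)
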