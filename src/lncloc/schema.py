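"""Feature-family schema and the tiles x features table.

Features are organized into named families, each belonging to the *primary*
(sequence-derived) or *secondary* (cell-context) category.  Sequence is
causally upstream of context, so family-level importance is evaluated within
category: sequence-only model sets for primary families, sequence + context
sets for secondary ones.

``canonical_schema`` instantiates the ten-family layout used on the real
mouse data: 1280 primary features (512 canonical 5-mers, 701 motif-scan
proteins, 59 repeat families + repeat-pair, 4 triplex summary values, 3
shared-motif features) and 333 secondary features (2 accessibility, 1
methylation, 48 marks + chromatin-pair, 275 ChIP antigens + ChIP-pair, 5
transcription tracks), 1613 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import canonical_kmers

__all__ = ["Family", "FamilySchema", "FeatureTable", "canonical_schema"]

PRIMARY = "primary"
SECONDARY = "secondary"

#: feature-name prefixes flagged as lncRNA-specific (pair / per-lncRNA features)
LNCRNA_SPECIFIC_PREFIXES = (
    "triplex_", "repeat_pair", "tf_pair", "rbp_pair", "ppi_pair",
    "chip_pair", "chromatin_pair",
)


@dataclass(frozen=True)
class Family:
    name: str
    category: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in (PRIMARY, SECONDARY):
            raise ValueError(f"category must be primary/secondary, got {self.category!r}")


@dataclass(frozen=True)
class FamilySchema:
    """Ordered assignment of every feature to exactly one family."""

    families: tuple[Family, ...]
    _by_name: dict[str, Family] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            for f in fam.features:
                if f in seen:
                    raise ValueError(f"feature {f!r} assigned to more than one family")
                seen.add(f)
        object.__setattr__(self, "_by_name", {f.name: f for f in self.families})

    def __getitem__(self, name: str) -> Family:
        return self._by_name[name]

    def family_names(self, category: str | None = None) -> list[str]:
        return [f.name for f in self.families if category is None or f.category == category]

    def features_of(self, family_names) -> list[str]:
        out: list[str] = []
        for name in family_names:
            out.extend(self._by_name[name].features)
        return out

    @property
    def all_features(self) -> list[str]:
        return self.features_of(self.family_names())

    def n_features(self, category: str | None = None) -> int:
        return sum(len(f.features) for f in self.families
                   if category is None or f.category == category)

    def family_of(self, feature: str) -> str:
        for fam in self.families:
            if feature in fam.features:
                return fam.name
        raise KeyError(feature)

    def to_json_dict(self) -> dict:
        return {fam.name: {"category": fam.category, "features": list(fam.features)}
                for fam in self.families}


def canonical_schema(n_tfs: int = 623, n_rbps: int = 78, n_repeat_families: int = 59,
                     n_marks: int = 48, n_chip_antigens: int = 275) -> FamilySchema:
    """The full ten-family schema at the reference resource counts."""
    kmer = Family("kmer", PRIMARY, canonical_kmers(5))
    motif = Family("motif", PRIMARY,
                   tuple(f"tf_motif_{i:03d}" for i in range(n_tfs)) +
                   tuple(f"rbp_motif_{i:03d}" for i in range(n_rbps)))
    repeat = Family("repeat", PRIMARY,
                    tuple(f"repeat_{i:02d}" for i in range(n_repeat_families)) + ("repeat_pair",))
    triplex = Family("triplex", PRIMARY,
                     ("triplex_pairs", "triplex_total_len", "triplex_max_score", "triplex_coverage"))
    shared = Family("shared_motifs", PRIMARY, ("tf_pair", "rbp_pair", "ppi_pair"))
    accessibility = Family("accessibility", SECONDARY, ("dnase", "atac"))
    methylation = Family("methylation", SECONDARY, ("wgbs_sum",))
    chromatin = Family("chromatin", SECONDARY,
                       tuple(f"mark_{i:02d}" for i in range(n_marks)) + ("chromatin_pair",))
    chip = Family("tf_chip", SECONDARY,
                  tuple(f"chip_{i:03d}" for i in range(n_chip_antigens)) + ("chip_pair",))
    transcription = Family("transcription", SECONDARY,
                           ("gro_seq", "pro_seq", "rna_seq", "cage", "polii_chip"))
    return FamilySchema((kmer, motif, repeat, triplex, shared,
                         accessibility, methylation, chromatin, chip, transcription))


class FeatureTable:
    """Tiles x features matrix bound to a FamilySchema.

    Missing signal is 0 (never NaN); lncRNA-specific columns (pair and
    triplex features) are flagged so per-lncRNA materializations are
    explicit.
    """

    def __init__(self, values: pd.DataFrame, schema: FamilySchema):
        missing = [f for f in schema.all_features if f not in values.columns]
        if missing:
            raise ValueError(f"feature table lacks schema columns: {missing[:5]}...")
        values = values[schema.all_features]
        if values.isna().any().any():
            raise ValueError("feature table contains missing values; absent signal must be 0")
        self.values = values
        self.schema = schema

    @property
    def tile_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def matrix(self, family_names, tile_ids=None) -> pd.DataFrame:
        cols = self.schema.features_of(family_names)
        sub = self.values[cols]
        return sub if tile_ids is None else sub.loc[tile_ids]

    def lncrna_specific_columns(self) -> list[str]:
        return [c for c in self.values.columns
                if any(c.startswith(p) for p in LNCRNA_SPECIFIC_PREFIXES)]

    def to_tsv(self, path, schema_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="tile_id")
        if schema_path is not None:
            import json
            with open(schema_path, "w") as fh:
                json.dump(self.schema.to_json_dict(), fh, indent=1)

    @classmethod
    def from_tsv(cls, path, schema: FamilySchema) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="tile_id")
        df.index.name = None
        return cls(df, schema)
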