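"""Phenotype harmonization across germplasm collections, plus small derived-trait
formulas used by the source datasets (fruit-colour hue angle, pulp ratio).

Phenotypes are kept on their recorded scale: no per-collection standardization
is applied before multi-environment modelling, because environment-specific
variance terms in the prediction models absorb scale differences between
collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable", "hue_angle", "pulp_percentage", "harmonize"]

RECORD_COLUMNS = ["individual_id", "collection", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Long-format trait records: one row per (individual, collection, trait).

    ``covariates`` holds per-individual fixed effects (e.g. a dataset-ID
    one-hot), indexed by individual ID. ``clone_map`` lists ID pairs known to
    be the same genotype conserved in two collections.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame | None = None
    clone_map: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        dup = self.records.duplicated(subset=["individual_id", "collection", "trait"])
        if dup.any():
            raise ValueError("duplicate (individual, collection, trait) records")
        self.records = self.records.reset_index(drop=True)

    @property
    def collections(self) -> list:
        return sorted(self.records["collection"].unique().tolist())

    @property
    def traits(self) -> list:
        return sorted(self.records["trait"].unique().tolist())

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, collections=None, traits=None) -> "PhenotypeTable":
        rec = self.records
        if collections is not None:
            rec = rec[rec["collection"].isin(collections)]
        if traits is not None:
            rec = rec[rec["trait"].isin(traits)]
        return PhenotypeTable(
            rec.reset_index(drop=True), self.covariates, self.clone_map
        )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


def hue_angle(a_star, b_star):
    """Fruit-colour hue angle h = arctan(b*/a*) in degrees.

    ``b*`` is yellowness and ``a*`` redness from a colorimeter reading. The
    formula is undefined at a* = 0 and the plain (non two-argument) arctangent
    is used, so the result lies in (-90, 90) degrees.
    """
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any(a == 0):
        raise ValueError("hue angle undefined for a* = 0")
    out = np.degrees(np.arctan(b / a))
    return float(out) if out.ndim == 0 else out


def pulp_percentage(fruit_weight, stone_weight):
    """Pulp score as the ratio of fruit weight to stone weight.

    Note this ratio exceeds 1 for any fleshy fruit and is not a true
    percentage; it is implemented exactly as the source dataset defines it.
    """
    fw = np.asarray(fruit_weight, dtype=float)
    sw = np.asarray(stone_weight, dtype=float)
    if np.any(sw <= 0):
        raise ValueError("stone weight must be positive")
    out = fw / sw
    return float(out) if out.ndim == 0 else out


def harmonize(
    tables: dict,
    clone_map=None,
    clone_mode: str = "distinct",
    covariates: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """Stack per-collection wide trait tables into one long table.

    Parameters
    ----------
    tables : mapping of collection label -> wide DataFrame with an
        ``individual_id`` column and one column per trait; missing cells are
        dropped.
    clone_mode : 'distinct' treats clone pairs as unrelated IDs; 'merged'
        assigns the pair a single genetic ID (the first member of the pair)
        so the genotype appears as one individual recorded in two
        collections.
    """
    if clone_mode not in ("distinct", "merged"):
        raise ValueError("clone_mode must be 'distinct' or 'merged'")
    clone_map = list(clone_map or [])
    long_parts = []
    for collection in sorted(tables, key=str):
        wide = tables[collection]
        if "individual_id" not in wide.columns:
            raise ValueError(f"table for {collection!r} lacks individual_id")
        melted = wide.melt(
            id_vars="individual_id", var_name="trait", value_name="value"
        ).dropna(subset=["value"])
        melted.insert(1, "collection", collection)
        long_parts.append(melted)
    records = pd.concat(long_parts, ignore_index=True)
    if clone_mode == "merged":
        rename = {b: a for a, b in clone_map}
        records["individual_id"] = records["individual_id"].map(
            lambda i: rename.get(i, i)
        )
    return PhenotypeTable(records, covariates=covariates, clone_map=clone_map)
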