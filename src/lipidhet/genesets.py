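"""Gene-set collections, GMT IO and metabolic-set assembly.

The metabolic collection is built from a pathway -> (category, genes) mapping:
one global ALL METABOLISM set (union over all pathways), one set per named
category (Carbohydrate, Energy, Lipid, Nucleotide and Amino acid metabolism by
default), and an Other Metabolism set holding the metabolic genes present in
none of the category sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_pathway_mapping",
    "assemble_metabolic_sets",
    "DEFAULT_CATEGORIES",
    "ALL_METABOLISM",
    "OTHER_METABOLISM",
]

DEFAULT_CATEGORIES = (
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
)
ALL_METABOLISM = "ALL METABOLISM"
OTHER_METABOLISM = "Other Metabolism"


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            inter = genes & uni
            if inter:
                kept[name] = inter
            else:
                warnings.warn(
                    f"gene set {name!r} is empty after restriction; dropped",
                    stacklevel=2,
                )
        return GeneSetCollection(kept, dict(self.categories))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...); the description field
    is kept as the category tag."""
    sets, cats = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, desc, *genes = line.split("\t")
            sets[name] = frozenset(g for g in genes if g)
            if desc:
                cats[name] = desc
    return GeneSetCollection(sets, cats)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.categories.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_pathway_mapping(path) -> pd.DataFrame:
    """Read a TSV with columns (pathway, category, gene); category may be
    empty for uncategorized pathways."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pathway", "category", "gene"}
    if not required.issubset(df.columns):
        raise ValueError(f"pathway mapping must have columns {sorted(required)}")
    return df


def assemble_metabolic_sets(
    mapping: pd.DataFrame,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
) -> GeneSetCollection:
    """Build the metabolic gene-set collection from a pathway mapping.

    ``mapping`` has one row per (pathway, gene) with a ``category`` column
    (empty or unknown-category pathways contribute to ALL METABOLISM and thus
    to Other Metabolism only).  With all five categories populated and at
    least one uncategorized gene the result has seven sets.

    Raises ``ValueError`` for an empty mapping or duplicate categories.
    """
    if mapping.empty:
        raise ValueError("pathway mapping is empty")
    if len(set(categories)) != len(categories):
        raise ValueError("requested categories must be distinct")
    known = set(mapping["category"].unique()) - {""}
    unknown = known - set(categories)
    if unknown:
        raise ValueError(f"unknown categories in mapping: {sorted(unknown)}")

    all_genes = frozenset(mapping["gene"])
    sets: dict[str, frozenset[str]] = {ALL_METABOLISM: all_genes}
    cats = {ALL_METABOLISM: "global"}
    covered: set[str] = set()
    for cat in categories:
        genes = frozenset(mapping.loc[mapping["category"] == cat, "gene"])
        if not genes:
            warnings.warn(f"category {cat!r} has no genes; set dropped", stacklevel=2)
            continue
        sets[cat] = genes
        cats[cat] = "subcategory"
        covered |= genes
    other = all_genes - covered
    if other:
        sets[OTHER_METABOLISM] = frozenset(other)
        cats[OTHER_METABOLISM] = "remainder"
    else:
        warnings.warn("no uncategorized metabolic genes; Other Metabolism dropped",
                      stacklevel=2)
    return GeneSetCollection(sets, cats)
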