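"""Homoeologous groups: dyads, triads, tetrads.

A group is *monomorphic* when every member gene carries at least one TE
insertion in its gene body, *polymorphic* when some but not all do, and
*no_te* when none does — independent of TE type, count, or position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .annotations_io import MACRO_REGION, GeneRecord

logger = logging.getLogger(__name__)

CARDINALITY_NAMES = {2: "dyad", 3: "triad", 4: "tetrad"}

MONOMORPHIC = "monomorphic"
POLYMORPHIC = "polymorphic"
NO_TE = "no_te"


@dataclass
class HomoeologGroup:
    group_id: str
    members: list[tuple[str, str]]  # (subgenome, gene_id), duplicated slots allowed
    syntenic: bool = True
    morphism: str | None = None
    region_status: str | None = None
    expressed: bool | None = None

    def __post_init__(self) -> None:
        if not 2 <= len(self.members) <= 4:
            raise ValueError(
                f"group {self.group_id}: {len(self.members)} members; expected 2-4")

    @property
    def cardinality(self) -> int:
        return len(self.members)

    @property
    def cardinality_name(self) -> str:
        return CARDINALITY_NAMES[self.cardinality]

    @property
    def composition(self) -> str:
        return "".join(sorted(s for s, _ in self.members))

    @property
    def gene_ids(self) -> list[str]:
        return [g for _, g in self.members]


def build_groups(
    group_table: pd.DataFrame,
    genes: Mapping[str, GeneRecord],
) -> list[HomoeologGroup]:
    """Assemble groups from a membership table (``group_id, gene_id, subgenome``).

    Groups referencing genes absent from ``genes`` are dropped (count logged).
    Duplicate rows for a group_id/gene_id pair are an error.
    """
    dup = group_table.duplicated(["group_id", "gene_id"])
    if dup.any():
        bad = sorted(group_table.loc[dup, "group_id"].astype(str).unique())
        raise ValueError(f"duplicate gene ids in groups: {', '.join(bad)}")
    known = set(genes.keys())
    missing = ~group_table["gene_id"].isin(known)
    dropped_ids = set(group_table.loc[missing, "group_id"])
    if dropped_ids:
        logger.info("dropped %d groups referencing missing genes",
                    len(dropped_ids))
    df = group_table[~group_table["group_id"].isin(dropped_ids)]
    df = df.sort_values(["group_id"], kind="stable")
    has_syn = "syntenic" in df.columns
    groups: list[HomoeologGroup] = []
    members: list[tuple[str, str]] = []
    syn = True
    prev: str | None = None
    rows = zip(df["group_id"].astype(str), df["gene_id"].astype(str),
               df["subgenome"].astype(str),
               df["syntenic"] if has_syn else [True] * len(df))
    for gid, gene_id, sub, syntenic in rows:
        if gid != prev:
            if prev is not None:
                groups.append(HomoeologGroup(prev, members, syntenic=syn))
            members, syn, prev = [], True, gid
        members.append((sub, gene_id))
        syn = syn and bool(syntenic)
    if prev is not None:
        groups.append(HomoeologGroup(prev, members, syntenic=syn))
    return groups


def classify_polymorphism(group: HomoeologGroup,
                          has_te: Mapping[str, bool]) -> str:
    """Morphism label from per-gene TE presence flags."""
    flags = [bool(has_te[g]) for g in group.gene_ids]
    if all(flags):
        return MONOMORPHIC
    if any(flags):
        return POLYMORPHIC
    return NO_TE


def assign_group_region(group: HomoeologGroup,
                        regions: Mapping[str, str]) -> str:
    """``proximal``/``distal`` when all members share the macro-region, else ``mixed``."""
    macros = {MACRO_REGION[regions[g]] for g in group.gene_ids}
    return macros.pop() if len(macros) == 1 else "mixed"


def group_expressed(group: HomoeologGroup,
                    gene_expressed: Mapping[str, bool]) -> bool:
    """A group is expressed when one or more member genes is expressed."""
    return any(bool(gene_expressed[g]) for g in group.gene_ids)


def annotate_groups(
    groups: Iterable[HomoeologGroup],
    has_te: Mapping[str, bool],
    regions: Mapping[str, str] | None = None,
    gene_expressed: Mapping[str, bool] | None = None,
) -> list[HomoeologGroup]:
    """Populate morphism/region_status/expressed in place; returns the list."""
    groups = list(groups)
    for g in groups:
        g.morphism = classify_polymorphism(g, has_te)
        if regions is not None:
            g.region_status = assign_group_region(g, regions)
        if gene_expressed is not None:
            g.expressed = group_expressed(g, gene_expressed)
    return groups


def groups_to_frame(groups: Iterable[HomoeologGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        rows.append((g.group_id, g.cardinality, g.cardinality_name,
                     g.composition,
                     ";".join(f"{gid}:{s}" for s, gid in g.members),
                     g.syntenic, g.morphism, g.region_status, g.expressed))
    return pd.DataFrame(rows, columns=[
        "group_id", "cardinality", "cardinality_name", "composition",
        "members", "syntenic", "morphism", "region_status", "expressed"])


def te_gene_count(group: HomoeologGroup, has_te: Mapping[str, bool]) -> int:
    return sum(bool(has_te[g]) for g in group.gene_ids)
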