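"""Read and validate gene models, TE annotations, group tables and region partitions.

Coordinates are 1-based inclusive throughout (GFF3 convention). TSV dialects
accepted as a fallback for every input are documented on the reader functions.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")
REGIONS = ("R1", "R2a", "C", "R2b", "R3")

#: macro-region mapping: proximal = low-recombination interior, distal = chromosome ends
MACRO_REGION = {"R1": "distal", "R2a": "proximal", "C": "proximal",
                "R2b": "proximal", "R3": "distal"}

# --------------------------------------------------------------------------- #
# TE classification (three-letter code taxonomy)
# --------------------------------------------------------------------------- #

_CLASS_BY_LETTER = {"R": "I", "D": "II", "X": "unknown"}
_ORDER_BY_LETTER = {"L": "LTR", "I": "LINE", "S": "SINE", "T": "TIR",
                    "H": "Helitron", "X": "unknown"}

#: superfamily names for the 14 codes observed in the wheat annotation
SUPERFAMILY_NAMES = {
    "RLG": "Gypsy",
    "RLC": "Copia",
    "RLX": "unknown",
    "RIX": "unknown",
    "SIX": "unknown",
    "DTC": "CACTA",
    "DTM": "Mutator",
    "DTX": "unknown",
    "DTH": "Harbinger",
    "DTT": "Mariner",
    "DTA": "hAT",
    "DXX": "unknown",
    "DHH": "Helitron",
    "XXX": "unknown",
}


@dataclass(frozen=True)
class TEClassification:
    """Decomposition of a ClariTeRep-style subfamily name.

    The first three letters are the superfamily code (class, order,
    superfamily); the suffix after the underscore names the family and,
    after an optional dot, the subfamily.
    """

    class_: str
    order: str
    superfamily_code: str
    superfamily: str
    family: str
    subfamily: str | None = None

    @property
    def subfamily_name(self) -> str:
        """Full name, e.g. ``RLC_famc1.6``."""
        tail = f".{self.subfamily}" if self.subfamily is not None else ""
        return f"{self.superfamily_code}_{self.family}{tail}"


_NAME_RE = re.compile(r"^([A-Za-z]{3})[_-]?(.*)$")


def parse_te_code(subfamily_name: str) -> TEClassification:
    """Parse a ClariTeRep-style name into class/order/superfamily/family/subfamily.

    Total and idempotent: any non-empty string yields a classification.
    Unknown three-letter codes keep the code verbatim with class/order
    unknown; names without a leading three-letter code degrade to ``XXX``.
    """
    if not subfamily_name:
        raise ValueError("empty TE subfamily name")
    m = _NAME_RE.match(subfamily_name)
    if m is None:
        warnings.warn(f"unparseable TE name {subfamily_name!r}; using code XXX")
        return TEClassification("unknown", "unknown", "XXX", "unknown",
                                subfamily_name, None)
    code = m.group(1).upper()
    rest = m.group(2)
    family, _, sub = rest.partition(".")
    if code == "SIX":  # ClariTeRep's SINE code deviates from the R-prefix rule
        class_, order = "I", "SINE"
    else:
        class_ = _CLASS_BY_LETTER.get(code[0], "unknown")
        order = (_ORDER_BY_LETTER.get(code[1], "unknown")
                 if class_ != "unknown" else "unknown")
    if code == "DHH":
        order = "Helitron"
    superfamily = SUPERFAMILY_NAMES.get(code, "unknown")
    if class_ == "unknown":
        order = "unknown"
        superfamily = "unknown"
    return TEClassification(class_, order, code, superfamily,
                            family or "unknown", sub or None)


# --------------------------------------------------------------------------- #
# Domain records
# --------------------------------------------------------------------------- #

@dataclass
class GeneRecord:
    gene_id: str
    chromosome: str
    subgenome: str
    start: int
    stop: int
    strand: str = "."
    region: str | None = None
    confidence: str = "HC"

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > stop {self.stop}")
        if self.subgenome not in SUBGENOMES:
            raise ValueError(
                f"gene {self.gene_id}: subgenome {self.subgenome!r} not in {SUBGENOMES}")

    @property
    def midpoint(self) -> int:
        # floor midpoint keeps boundary-straddling genes in the left region
        return (self.start + self.stop) // 2


@dataclass
class GeneModel:
    """Exon and UTR intervals of one gene (1-based inclusive, normalized)."""

    gene_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = normalize_intervals(self.exons)
        self.utr5 = normalize_intervals(self.utr5)
        self.utr3 = normalize_intervals(self.utr3)


@dataclass
class TERepeat:
    te_id: str
    chromosome: str
    start: int
    stop: int
    status: str
    subfamily_name: str
    classification: TEClassification = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"TE {self.te_id}: start {self.start} > stop {self.stop}")
        if self.classification is None:
            self.classification = parse_te_code(self.subfamily_name)


def normalize_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    out: list[tuple[int, int]] = []
    for a, b in ivs:
        if a > b:
            raise ValueError(f"interval start {a} > stop {b}")
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def infer_subgenome(chromosome: str) -> str | None:
    """Subgenome from the chromosome name suffix (``chr5A`` / ``5A`` -> ``A``)."""
    suffix = chromosome.rstrip("0123456789")[-1:] or chromosome[-1:]
    last = chromosome[-1].upper()
    return last if last in SUBGENOMES else (suffix.upper() if suffix.upper() in SUBGENOMES else None)


# --------------------------------------------------------------------------- #
# Region partition
# --------------------------------------------------------------------------- #

class RegionPartition:
    """Per-chromosome ordered R1/R2a/C/R2b/R3 segments tiling the chromosome."""

    def __init__(self, segments: Mapping[str, Sequence[tuple[str, int, int]]]):
        self._segments: dict[str, list[tuple[str, int, int]]] = {}
        for chrom, segs in segments.items():
            segs = sorted(segs, key=lambda s: s[1])
            prev_stop = None
            for label, start, stop in segs:
                if label not in REGIONS:
                    raise ValueError(f"{chrom}: unknown region label {label!r}")
                if start > stop:
                    raise ValueError(f"{chrom} {label}: start {start} > stop {stop}")
                if prev_stop is not None and start != prev_stop + 1:
                    raise ValueError(
                        f"{chrom}: regions do not tile; gap/overlap at {start}")
                prev_stop = stop
            self._segments[chrom] = [(l, int(a), int(b)) for l, a, b in segs]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._segments)

    def region_at(self, chromosome: str, position: int) -> str:
        if chromosome not in self._segments:
            raise KeyError(f"chromosome {chromosome!r} absent from region partition")
        for label, start, stop in self._segments[chromosome]:
            if start <= position <= stop:
                return label
        raise ValueError(
            f"position {position} outside partition of {chromosome}")

    def macro(self, region: str) -> str:
        return MACRO_REGION[region]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, l, a, b) for c, segs in self._segments.items()
                for l, a, b in segs]
        return pd.DataFrame(rows, columns=["chrom", "region", "start", "stop"])


def assign_chromosomal_region(gene: GeneRecord, partition: RegionPartition) -> str:
    """Region containing the gene midpoint (floor; boundary genes go left)."""
    return partition.region_at(gene.chromosome, gene.midpoint)


def read_region_partition(path: str | Path) -> RegionPartition:
    """Read a region partition TSV with columns chrom, region, start, stop."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "region", "start", "stop"}
    if not required.issubset(df.columns):
        raise ValueError(f"partition table needs columns {sorted(required)}")
    segments: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        segments.setdefault(row.chrom, []).append((row.region, row.start, row.stop))
    return RegionPartition(segments)


# --------------------------------------------------------------------------- #
# Gene models
# --------------------------------------------------------------------------- #

class AnnotationValidationError(ValueError):
    """Raised with the list of offending record ids."""

    def __init__(self, message: str, record_ids: Sequence[str]):
        super().__init__(f"{message}: {', '.join(record_ids)}")
        self.record_ids = list(record_ids)


_GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "stop", "strand", "subgenome"]


def read_gene_models(
    source: str | Path,
    *,
    fmt: str | None = None,
    include_lc: bool = False,
) -> tuple[dict[str, GeneRecord], dict[str, GeneModel]]:
    """Read gene records (and models where exon/UTR features exist).

    ``source`` is a GFF3 file or a TSV with columns
    ``gene_id, chrom, start, stop, strand, subgenome[, confidence]``.
    Low-confidence genes (``confidence == LC``) are excluded unless
    ``include_lc`` is set.
    """
    path = Path(source)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".txt", ".csv"} else "gff3"
    if fmt == "tsv":
        return _read_gene_tsv(path, include_lc=include_lc)
    return _read_gene_gff3(path, include_lc=include_lc)


def _read_gene_tsv(path: Path, *, include_lc: bool):
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_GENE_TSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"gene TSV missing columns {sorted(missing)}")
    bad = df.loc[df["start"] > df["stop"], "gene_id"].astype(str).tolist()
    if bad:
        raise AnnotationValidationError("genes with start > stop", bad)
    records: dict[str, GeneRecord] = {}
    for row in df.itertuples(index=False):
        conf = getattr(row, "confidence", "HC")
        if conf == "LC" and not include_lc:
            continue
        sub = getattr(row, "subgenome", None) or infer_subgenome(row.chrom)
        if sub is None:
            raise AnnotationValidationError(
                "cannot infer subgenome from chromosome", [str(row.gene_id)])
        records[str(row.gene_id)] = GeneRecord(
            gene_id=str(row.gene_id), chromosome=str(row.chrom),
            subgenome=sub, start=int(row.start), stop=int(row.stop),
            strand=getattr(row, "strand", "."), confidence=conf)
    return records, {}


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}


def _read_gene_gff3(path: Path, *, include_lc: bool):
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    records: dict[str, GeneRecord] = {}
    bad: list[str] = []
    lc_excluded = 0
    for feat in db.features_of_type("gene"):
        gene_id = feat.id
        conf = (feat.attributes.get("confidence") or ["HC"])[0]
        if conf == "LC" and not include_lc:
            lc_excluded += 1
            continue
        if feat.start > feat.end:
            bad.append(gene_id)
            continue
        sub = (feat.attributes.get("subgenome") or [None])[0] \
            or infer_subgenome(feat.seqid)
        if sub is None:
            bad.append(gene_id)
            continue
        records[gene_id] = GeneRecord(
            gene_id=gene_id, chromosome=feat.seqid, subgenome=sub,
            start=feat.start, stop=feat.end, strand=feat.strand or ".",
            confidence=conf)
    if bad:
        raise AnnotationValidationError("invalid gene records", bad)
    if lc_excluded:
        logger.info("excluded %d LC genes", lc_excluded)

    models: dict[str, GeneModel] = {}
    part_types = {"exon"} | _UTR5_TYPES | _UTR3_TYPES
    for ftype in part_types:
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            continue
        for feat in feats:
            parents = [p.id for p in db.parents(feat, featuretype="gene")]
            if not parents:  # direct Parent attribute naming a gene
                parents = [p for p in feat.attributes.get("Parent", [])
                           if p in records]
            for gid in parents:
                if gid not in records:
                    continue
                model = models.setdefault(gid, GeneModel(gid))
                iv = (feat.start, feat.end)
                if ftype == "exon":
                    model.exons.append(iv)
                elif ftype in _UTR5_TYPES:
                    model.utr5.append(iv)
                else:
                    model.utr3.append(iv)
    for model in models.values():
        model.exons = normalize_intervals(model.exons)
        model.utr5 = normalize_intervals(model.utr5)
        model.utr3 = normalize_intervals(model.utr3)
    return records, models


def genes_to_frame(records: Mapping[str, GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.chromosome, g.start, g.stop, g.strand, g.subgenome,
          g.confidence, g.region)
         for g in records.values()],
        columns=["gene_id", "chrom", "start", "stop", "strand", "subgenome",
                 "confidence", "region"])


def write_gene_table(records: Mapping[str, GeneRecord], path: str | Path) -> None:
    genes_to_frame(records).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# TE annotations
# --------------------------------------------------------------------------- #

REPEAT_REGION = "repeat_region"


class TEAnnotations:
    """All parsed TE records plus a filter view on ``repeat_region`` status."""

    def __init__(self, records: Sequence[TERepeat]):
        self.all: list[TERepeat] = list(records)

    @property
    def repeat_regions(self) -> list[TERepeat]:
        return [t for t in self.all if t.status == REPEAT_REGION]

    @property
    def n_removed(self) -> int:
        return len(self.all) - len(self.repeat_regions)

    def to_frame(self, *, repeat_regions_only: bool = False) -> pd.DataFrame:
        recs = self.repeat_regions if repeat_regions_only else self.all
        return pd.DataFrame(
            [(t.te_id, t.chromosome, t.start, t.stop, t.status,
              t.subfamily_name, t.classification.superfamily_code)
             for t in recs],
            columns=["te_id", "chrom", "start", "stop", "status", "name",
                     "superfamily"])


def read_te_annotations(source: str | Path, *, fmt: str | None = None) -> TEAnnotations:
    """Read TE annotations from GFF3 (attributes ``ID``, ``status``, ``Name``)
    or TSV with columns ``te_id, chrom, start, stop, status, name``.
    """
    path = Path(source)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".txt", ".csv"} else "gff3"
    records: list[TERepeat] = []
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", comment="#")
        except pd.errors.EmptyDataError:
            return TEAnnotations([])
        for row in df.itertuples(index=False):
            records.append(TERepeat(str(row.te_id), str(row.chrom),
                                    int(row.start), int(row.stop),
                                    str(row.status), str(row.name)))
    else:
        if path.stat().st_size == 0:
            return TEAnnotations([])
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique", keep_order=True)
        for feat in db.all_features():
            status = (feat.attributes.get("status") or [feat.featuretype])[0]
            name = (feat.attributes.get("Name")
                    or feat.attributes.get("name") or [feat.id])[0]
            records.append(TERepeat(feat.id, feat.seqid, feat.start, feat.end,
                                    status, name))
    anns = TEAnnotations(records)
    logger.info("TE annotations: %d read, %d non-repeat_region removed from view",
                len(anns.all), anns.n_removed)
    return anns


def write_te_table(anns: TEAnnotations, path: str | Path) -> None:
    anns.to_frame().drop(columns=["superfamily"]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# Homoeolog group table
# --------------------------------------------------------------------------- #

def read_group_table(path: str | Path) -> pd.DataFrame:
    """Group membership TSV: ``group_id, gene_id, subgenome[, syntenic]``."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"group_id": str, "gene_id": str})
    required = {"group_id", "gene_id", "subgenome"}
    if not required.issubset(df.columns):
        raise ValueError(f"group table needs columns {sorted(required)}")
    if "syntenic" not in df.columns:
        df["syntenic"] = True
    return df
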