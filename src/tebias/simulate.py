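"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator samples TE presence per gene as independent Bernoulli draws
(region- and superfamily-specific p) and then materializes insertion
coordinates inside the gene body, so the independence assumption of the
conditional-binomial morphism null holds exactly unless an effect is
planted. Expression triplets are drawn around the chosen category centroid
with a Dirichlet concentration parameter. Every planted parameter is
recorded in a truth ledger.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
(PCG64), so a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import expression as expr
from . import groups as grp
from . import overlap as ovl
from . import stats as st
from .annotations_io import (MACRO_REGION, GeneModel, GeneRecord,
                             RegionPartition, TERepeat)
from .enrichment import map_triads_to_go, sea

DEFAULT_SUPERFAMILY_P = {
    "DTT": 0.30, "DTC": 0.20, "DTX": 0.14, "RLC": 0.10, "RIX": 0.10,
    "XXX": 0.09, "RLG": 0.08, "RLX": 0.035, "DTM": 0.030, "DTH": 0.030,
    "DXX": 0.008, "SIX": 0.004, "DTA": 0.001, "DHH": 0.0005,
}

DEFAULT_REGION_FRACTIONS = {"R1": 0.30, "R2a": 0.15, "C": 0.10,
                            "R2b": 0.15, "R3": 0.30}

DEFAULT_CONTEXT_PROBS = {"intron": 0.80, "exon": 0.08, "utr5": 0.04,
                         "utr3": 0.08}


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply the odds of TE presence (per gene) for groups whose planted
    category matches the comparison's in-set."""

    te_group: str  # superfamily code
    comparison: str  # one of stats.COMPARISONS
    odds_multiplier: float


@dataclass(frozen=True)
class PlantedGO:
    """Multiply a term's per-gene annotation probability inside the subset of
    triads that carry an insertion of ``superfamily``."""

    term: str
    superfamily: str
    factor: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_dyads: int = 300
    n_triads: int = 2000
    n_tetrads: int = 50
    n_chromosome_groups: int = 2
    chromosome_length: int = 20_000_000
    region_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_FRACTIONS))
    gene_length_range: tuple[int, int] = (2000, 4000)
    superfamily_p: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPERFAMILY_P))
    distal_multiplier: float = 0.7
    n_families_per_superfamily: int = 5
    context_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_PROBS))
    nested_fraction: float = 0.15
    category_weights: dict[str, float] = field(
        default_factory=lambda: {"balanced": 0.83, "suppressed": 0.14,
                                 "dominant": 0.03})
    concentration: float = 60.0
    not_expressed_fraction: float = 0.05
    low_breadth_fraction: float = 0.10  # groups expressed in few tissues
    n_tissues: int = 15
    syntenic_fraction: float = 0.97
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    go_n_terms: int = 30
    go_base_range: tuple[float, float] = (0.01, 0.08)
    planted_go: list[PlantedGO] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.region_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("region fractions must sum to 1")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            raise ValueError("category weights must sum to 1")
        for p in self.superfamily_p.values():
            if not 0 <= p <= 1:
                raise ValueError("superfamily probabilities must be in [0, 1]")
        if self.gene_length_range[1] >= self.chromosome_length // 10:
            raise ValueError("genes too long for chromosome layout")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: dict[str, GeneRecord]
    models: dict[str, GeneModel]
    tes: list[TERepeat]
    groups_table: pd.DataFrame
    expression: pd.DataFrame  # gene_id index, tissue sample columns
    gene_to_go: pd.DataFrame  # gene_id, go_id, domain
    partition: RegionPartition
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.gff3",
            "tes": outdir / "tes.gff3",
            "groups": outdir / "groups.tsv",
            "expression": outdir / "expression.tsv",
            "gene_to_go": outdir / "gene_to_go.tsv",
            "regions": outdir / "regions.tsv",
            "truth": outdir / "truth.json",
        }
        _write_gene_gff3(self.genes, self.models, paths["genes"])
        _write_te_gff3(self.tes, paths["tes"])
        self.groups_table.to_csv(paths["groups"], sep="\t", index=False)
        self.expression.to_csv(paths["expression"], sep="\t",
                               index_label="gene_id")
        self.gene_to_go.to_csv(paths["gene_to_go"], sep="\t", index=False)
        self.partition.to_frame().to_csv(paths["regions"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def _write_gene_gff3(genes: Mapping[str, GeneRecord],
                     models: Mapping[str, GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            g = genes[gid]
            fh.write(f"{g.chromosome}\ttebias\tgene\t{g.start}\t{g.stop}\t.\t"
                     f"{g.strand}\t.\tID={gid};confidence={g.confidence}\n")
            model = models.get(gid)
            if model is None:
                continue
            for ftype, ivs in (("exon", model.exons),
                               ("five_prime_UTR", model.utr5),
                               ("three_prime_UTR", model.utr3)):
                for i, (a, b) in enumerate(ivs, 1):
                    fh.write(f"{g.chromosome}\ttebias\t{ftype}\t{a}\t{b}\t.\t"
                             f"{g.strand}\t.\tID={gid}.{ftype}{i};Parent={gid}\n")


def _write_te_gff3(tes: Sequence[TERepeat], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tes:
            fh.write(f"{t.chromosome}\ttebias\trepeat\t{t.start}\t{t.stop}\t.\t"
                     f".\t.\tID={t.te_id};Name={t.subfamily_name};"
                     f"status={t.status}\n")


# --------------------------------------------------------------------------- #
# Generation
# --------------------------------------------------------------------------- #

def _make_partition(config: SimulationConfig) -> RegionPartition:
    segs: dict[str, list[tuple[str, int, int]]] = {}
    L = config.chromosome_length
    for i in range(1, config.n_chromosome_groups + 1):
        for s in ("A", "B", "D"):
            chrom = f"{i}{s}"
            pos = 0
            segs[chrom] = []
            items = list(config.region_fractions.items())
            for j, (label, frac) in enumerate(items):
                stop = L if j == len(items) - 1 else pos + int(round(frac * L))
                segs[chrom].append((label, pos + 1, stop))
                pos = stop
    return RegionPartition(segs)


def _sample_category(rng: np.random.Generator, config: SimulationConfig,
                     cardinality: int) -> str:
    tiers = list(config.category_weights)
    w = np.array([config.category_weights[t] for t in tiers])
    tier = tiers[rng.choice(len(tiers), p=w / w.sum())]
    k = cardinality
    if tier == "balanced":
        return "balanced"
    if k == 3:
        slot = "ABD"[rng.integers(3)]
        return f"{slot}_{'suppressed' if tier == 'suppressed' else 'dominant'}"
    if k == 2:  # dyads have no dominant tier; fold into suppressed
        return f"suppressed_{rng.integers(2)}"
    if tier == "dominant":
        return f"dominant_{rng.integers(4)}"
    if rng.random() < 0.5:
        i, j = sorted(rng.choice(4, size=2, replace=False))
        return f"suppressed_{i}_{j}"
    return f"suppressed_{rng.integers(4)}"


def _category_in_comparison(category: str, comparison: str) -> bool:
    if comparison == "balanced_vs_nonbalanced":
        return category == "balanced"
    if comparison == "suppressed_vs_notsuppressed":
        return expr.is_suppressed(category)
    if comparison == "dominant_vs_notdominant":
        return expr.is_dominant(category)
    raise ValueError(f"unknown comparison {comparison!r}")


def _gene_model(gid: str, start: int, stop: int) -> GeneModel:
    """Fixed three-exon structure with terminal UTRs."""
    L = stop - start + 1
    e1 = (start, start + int(0.25 * L))
    e2 = (start + int(0.45 * L), start + int(0.55 * L))
    e3 = (start + int(0.75 * L), stop)
    utr5 = (e1[0], e1[0] + max(1, int(0.05 * L)))
    utr3 = (e3[1] - max(1, int(0.08 * L)), e3[1])
    return GeneModel(gid, exons=[e1, e2, e3], utr5=[utr5], utr3=[utr3])


_DYAD_COMPS = ["AB", "AD", "BD"]
_TETRAD_COMPS = ["AABD", "ABBD", "ABDD"]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    partition = _make_partition(config)
    L = config.chromosome_length
    glo, ghi = config.gene_length_range

    genes: dict[str, GeneRecord] = {}
    models: dict[str, GeneModel] = {}
    group_rows: list[tuple[str, str, str, bool]] = []
    group_meta: list[dict] = []  # per group: id, cardinality, category, ...
    pending: list[tuple[str, int, int, str, str]] = []  # chrom, start, len, gid, sub

    specs = ([("dy", 2)] * config.n_dyads + [("tr", 3)] * config.n_triads
             + [("te", 4)] * config.n_tetrads)
    for idx, (prefix, k) in enumerate(specs):
        group_id = f"{prefix}{idx:06d}"
        if k == 3:
            comp = "ABD"
        elif k == 2:
            comp = _DYAD_COMPS[rng.integers(3)]
        else:
            comp = _TETRAD_COMPS[rng.integers(3)]
        chrom_group = int(rng.integers(1, config.n_chromosome_groups + 1))
        u = rng.random() * 0.96 + 0.01
        syntenic = bool(rng.random() < config.syntenic_fraction)
        category = _sample_category(rng, config, k)
        not_expressed = bool(rng.random() < config.not_expressed_fraction)
        if not_expressed:
            n_tissues_expr = 0
        elif rng.random() < config.low_breadth_fraction:
            n_tissues_expr = int(rng.integers(1, config.n_tissues + 1))
        else:
            n_tissues_expr = config.n_tissues
        member_gene_ids = []
        seen_sub: dict[str, int] = {}
        for slot_idx, sub in enumerate(comp):
            copy = seen_sub.get(sub, 0)
            seen_sub[sub] = copy + 1
            gid = f"g{group_id}{sub}{copy + 1}"
            glen = int(rng.integers(glo, ghi + 1))
            jitter = (rng.random() - 0.5) * 0.01 + copy * 0.002
            pos = min(max(u + jitter, 0.0), 1.0)
            start = 1 + int(pos * (L - glen - 1))
            chrom = f"{chrom_group}{sub}"
            pending.append((chrom, start, glen, gid, sub))
            group_rows.append((group_id, gid, sub, syntenic))
            member_gene_ids.append(gid)
        group_meta.append(dict(
            group_id=group_id, cardinality=k, composition=comp,
            category=category, syntenic=syntenic,
            n_tissues_expressed=n_tissues_expr,
            gene_ids=member_gene_ids))

    # ---- resolve placement: genes on a chromosome must not overlap --------
    # (a TE confined to one gene body must never touch a second gene, so the
    # per-gene Bernoulli presence model holds exactly)
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for chrom, start, glen, gid, sub in pending:
        by_chrom.setdefault(chrom, []).append((start, glen, gid, sub))
    min_gap = 200
    for chrom, items in by_chrom.items():
        items.sort()
        prev_stop = 0
        for start, glen, gid, sub in items:
            start = max(start, prev_stop + min_gap)
            stop = start + glen - 1
            if stop > L:
                raise ValueError(
                    f"infeasible layout: genes exceed chromosome {chrom}")
            prev_stop = stop
            rec = GeneRecord(gene_id=gid, chromosome=chrom, subgenome=sub,
                             start=start, stop=stop, strand="+")
            rec.region = partition.region_at(chrom, rec.midpoint)
            genes[gid] = rec
            models[gid] = _gene_model(gid, start, stop)

    # ---- TE presence and coordinates --------------------------------------
    tes: list[TERepeat] = []
    te_serial = 0
    sf_codes = sorted(config.superfamily_p)
    ctx_names = list(config.context_probs)
    ctx_p = np.array([config.context_probs[c] for c in ctx_names])
    ctx_p = ctx_p / ctx_p.sum()
    presence_by_gene: dict[str, set[str]] = {g: set() for g in genes}
    for meta in group_meta:
        effects = {
            e.te_group: e.odds_multiplier for e in config.planted_effects
            if _category_in_comparison(meta["category"], e.comparison)}
        for gid in meta["gene_ids"]:
            rec = genes[gid]
            macro = MACRO_REGION[rec.region]
            for sf in sf_codes:
                p = config.superfamily_p[sf]
                if macro == "distal":
                    p = p * config.distal_multiplier
                mult = effects.get(sf)
                if mult is not None and 0 < p < 1:
                    odds = mult * p / (1 - p)
                    p = odds / (1 + odds)
                if rng.random() >= p:
                    continue
                presence_by_gene[gid].add(sf)
                te_serial += 1
                fam = int(rng.integers(1, config.n_families_per_superfamily + 1))
                name = f"{sf}_famc{fam}"
                if rng.random() < 0.3:
                    name += f".{int(rng.integers(1, 4))}"
                ctx = ctx_names[rng.choice(len(ctx_names), p=ctx_p)]
                te_len = int(rng.integers(100, 501))
                model = models[gid]
                if ctx == "exon":
                    lo, hi = model.exons[1]
                elif ctx == "utr5":
                    lo, hi = model.utr5[0]
                elif ctx == "utr3":
                    lo, hi = model.utr3[0]
                else:  # intron between exon 1 and 2
                    lo, hi = model.exons[0][1] + 1, model.exons[1][0] - 1
                span = max(hi - lo, 1)
                t_start = lo + int(rng.integers(0, span))
                t_stop = min(t_start + te_len - 1, rec.stop)
                tes.append(TERepeat(f"te{te_serial:07d}", rec.chromosome,
                                    t_start, t_stop, "repeat_region", name))
                if rng.random() < config.nested_fraction:
                    te_serial += 1
                    status = "nested" if rng.random() < 0.5 else "fragment"
                    tes.append(TERepeat(f"te{te_serial:07d}", rec.chromosome,
                                        t_start, t_stop, status, name))

    # ---- expression -------------------------------------------------------
    samples = [f"tissue{t:02d}" for t in range(1, config.n_tissues + 1)]
    expr_matrix = pd.DataFrame(0.0, index=sorted(genes), columns=samples)
    kappa = config.concentration
    for meta in group_meta:
        n_expr = meta["n_tissues_expressed"]
        if n_expr == 0:
            continue
        k = meta["cardinality"]
        cents = expr.general_centroids(k)
        centroid = cents[meta["category"]]
        expressed_tissues = rng.choice(config.n_tissues, size=n_expr,
                                       replace=False)
        alpha = kappa * centroid + 0.3
        for t in sorted(expressed_tissues):
            total = float(rng.lognormal(mean=3.0, sigma=0.6))
            props = rng.dirichlet(alpha)
            for gid, tpm in zip(meta["gene_ids"], total * props):
                expr_matrix.at[gid, samples[t]] = round(float(tpm), 4)

    # ---- GO annotations ---------------------------------------------------
    go_terms = [f"GO:{i:07d}" for i in range(1, config.go_n_terms + 1)]
    domains = {t: ("BP", "MF", "CC")[i % 3] for i, t in enumerate(go_terms)}
    lo_f, hi_f = config.go_base_range
    base_freq = {t: float(rng.uniform(lo_f, hi_f)) for t in go_terms}
    planted_by_sf: dict[str, list[PlantedGO]] = {}
    for pg in config.planted_go:
        planted_by_sf.setdefault(pg.superfamily, []).append(pg)
    go_rows: list[tuple[str, str, str]] = []
    for meta in group_meta:
        sf_present = set()
        for gid in meta["gene_ids"]:
            sf_present |= presence_by_gene[gid]
        boost = {}
        for sf, plants in planted_by_sf.items():
            if sf in sf_present:
                for pg in plants:
                    boost[pg.term] = pg.factor
        for gid in meta["gene_ids"]:
            for term in go_terms:
                p = min(base_freq[term] * boost.get(term, 1.0), 0.95)
                if rng.random() < p:
                    go_rows.append((gid, term, domains[term]))
    gene_to_go = pd.DataFrame(go_rows, columns=["gene_id", "go_id", "domain"])

    groups_table = pd.DataFrame(group_rows,
                                columns=["group_id", "gene_id", "subgenome",
                                         "syntenic"])
    truth = {
        "seed": config.seed,
        "superfamily_p": dict(config.superfamily_p),
        "distal_multiplier": config.distal_multiplier,
        "category_weights": dict(config.category_weights),
        "planted_effects": [dataclasses.asdict(e)
                            for e in config.planted_effects],
        "planted_go": [dataclasses.asdict(p) for p in config.planted_go],
        "go_base_freq": base_freq,
        "group_category": {m["group_id"]: m["category"] for m in group_meta},
        "group_n_tissues": {m["group_id"]: m["n_tissues_expressed"]
                            for m in group_meta},
    }
    return SyntheticDataset(config, genes, models, tes, groups_table,
                            expr_matrix, gene_to_go, partition, truth)


# --------------------------------------------------------------------------- #
# Calibration and recovery
# --------------------------------------------------------------------------- #

def gof_calibration(
    n_replicates: int,
    n_groups: int,
    k: int,
    p: float,
    *,
    seed: int = 0,
    use_true_p: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Type-I calibration of the morphism goodness-of-fit test under the null.

    Each replicate draws ``n_groups`` TE-containing groups with per-gene
    presence Bernoulli(``p``) conditioned on at least one insertion, then
    tests observed (poly, mono) counts against the conditional-binomial
    expectation. With ``use_true_p`` the expectation uses the generating p
    (the test statistic is then asymptotically chi-square with 1 df). With
    ``use_true_p=False`` p is re-estimated with the pipeline's plug-in
    estimator (TE genes / total genes over TE-containing groups), which is
    upward-biased under the >=1-insertion truncation; the resulting test is
    anti-conservative and rejects a true null with probability approaching
    one as n grows.
    """
    rng = np.random.default_rng(seed)
    j = np.arange(1, k + 1)
    probs = np.array([_binom_pmf(jj, k, p) for jj in j])
    probs = probs / probs.sum()
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        counts = rng.multinomial(n_groups, probs)
        n_mono = int(counts[-1])
        n_poly = n_groups - n_mono
        if use_true_p:
            p_mono, p_poly = st.conditional_morphism_probabilities(p, k)
            model_expected = (p_poly * n_groups, p_mono * n_groups)
        else:
            total_genes = int(np.dot(j, counts))
            p_hat = total_genes / (k * n_groups)
            p_mono, p_poly = st.conditional_morphism_probabilities(p_hat, k)
            model_expected = (p_poly * n_groups, p_mono * n_groups)
        _, pv = st.goodness_of_fit([n_poly, n_mono], list(model_expected))
        pvals[r] = pv
    return {"p_values": pvals, "rejection_rate": float(np.mean(pvals <= alpha)),
            "alpha": alpha, "n_replicates": n_replicates}


def _binom_pmf(j: int, k: int, p: float) -> float:
    from math import comb
    return comb(k, j) * p ** j * (1 - p) ** (k - j)


def triad_te_presence(dataset: SyntheticDataset) -> pd.DataFrame:
    """Triad-by-superfamily boolean presence from the materialized annotations."""
    reps = [t for t in dataset.tes if t.status == "repeat_region"]
    overlaps = ovl.find_te_insertions(dataset.genes.values(), reps, "gene_body")
    te_lookup = {t.te_id: t for t in reps}
    sf_by_gene: dict[str, set[str]] = {g: set() for g in dataset.genes}
    for row in overlaps.itertuples(index=False):
        sf_by_gene[row.gene_id].add(
            te_lookup[row.te_id].classification.superfamily_code)
    members = dataset.groups_table.groupby("group_id")["gene_id"].apply(list)
    triad_ids = [g for g in members.index if g.startswith("tr")]
    sf_codes = sorted(dataset.config.superfamily_p)
    data = {sf: [any(sf in sf_by_gene[g] for g in members[gid])
                 for gid in triad_ids] for sf in sf_codes}
    return pd.DataFrame(data, index=pd.Index(triad_ids, name="group_id"))


def recover_parameters(dataset: SyntheticDataset, *, alpha: float = 0.05,
                       fdr: float = 0.05) -> dict:
    """Run the full pipeline on a synthetic dataset and compare with truth.

    Returns a report with (a) morphism GOF p-values per cardinality (fitted
    and true-p variants), (b) planted TE-by-category associations detected at
    q <= ``fdr`` with direction, (c) planted GO terms recovered by SEA.
    """
    config = dataset.config
    reps = [t for t in dataset.tes if t.status == "repeat_region"]
    overlaps = ovl.find_te_insertions(dataset.genes.values(), reps, "gene_body")
    has_te = {g: False for g in dataset.genes}
    for gid in overlaps["gene_id"].unique():
        has_te[gid] = True

    hgroups = grp.build_groups(dataset.groups_table, dataset.genes)
    regions = {g.gene_id: g.region for g in dataset.genes.values()}
    mean_tpm = dataset.expression.mean(axis=1)
    gene_expressed = {g: bool(mean_tpm[g] > 0.5) for g in dataset.genes}
    grp.annotate_groups(hgroups, has_te, regions, gene_expressed)
    expressed = [g for g in hgroups if g.expressed]
    gdf = grp.groups_to_frame(expressed)
    te_counts = {g.group_id: grp.te_gene_count(g, has_te) for g in expressed}
    morphism = st.morphism_report(gdf, te_counts)

    members = dataset.groups_table.groupby("group_id")["gene_id"].apply(list)
    slots = dataset.groups_table.groupby("group_id")["subgenome"].apply(list)

    gof_true = {}
    for k in sorted(gdf["cardinality"].unique()):
        sub = gdf[(gdf["cardinality"] == k)
                  & gdf["morphism"].isin(["monomorphic", "polymorphic"])]
        if sub.empty:
            continue
        # expectation under the *planted* per-gene probability, averaged over
        # the macro-regions and categories actually realized
        cache: dict[tuple[str, str], float] = {}

        def gene_p(gid: str, category: str) -> float:
            macro = MACRO_REGION[dataset.genes[gid].region]
            key = (macro, category)
            if key not in cache:
                cache[key] = _planted_gene_p(config, macro, category)
            return cache[key]

        p_true = float(np.mean([
            gene_p(g, dataset.truth["group_category"][gid])
            for gid in sub["group_id"] for g in members[gid]]))
        p_mono, p_poly = st.conditional_morphism_probabilities(p_true, int(k))
        n = len(sub)
        n_poly = int((sub["morphism"] == "polymorphic").sum())
        _, pv = st.goodness_of_fit(
            [n_poly, n - n_poly], [p_poly * n, p_mono * n])
        gof_true[int(k)] = pv

    # --- triad categories + screens ---------------------------------------
    triad_members = {
        gid: dict(zip(slots[gid], members[gid]))
        for gid in members.index if gid.startswith("tr")}
    syntenic = dict(dataset.groups_table.groupby("group_id")["syntenic"].all())
    cats = expr.categorize_triads(dataset.expression, triad_members,
                                  syntenic=syntenic)
    eligible = expr.select_analysis_triads(cats).set_index("group_id")
    presence = triad_te_presence(dataset).loc[eligible.index]
    screens = {}
    for comparison in st.COMPARISONS:
        screens[comparison] = st.screen_te_groups(
            presence, eligible["category"], comparison)
    detected = []
    for e in config.planted_effects:
        res = screens[e.comparison]
        row = res[res["te_group"] == e.te_group]
        if row.empty or not row.iloc[0]["included"]:
            detected.append((e, False, None))
            continue
        r = row.iloc[0]
        want = "positive" if e.odds_multiplier > 1 else "negative"
        detected.append((e, bool(r["q"] <= fdr and r["direction"] == want),
                         float(r["q"])))

    # --- GO recovery -------------------------------------------------------
    gene_to_go: dict[str, set[str]] = {}
    for row in dataset.gene_to_go.itertuples(index=False):
        gene_to_go.setdefault(row.gene_id, set()).add(row.go_id)
    domain_of = dict(zip(dataset.gene_to_go["go_id"],
                         dataset.gene_to_go["domain"]))
    term_sets = map_triads_to_go(
        {gid: members[gid] for gid in eligible.index}, gene_to_go)
    go_recovered = []
    background = list(eligible.index)
    for pg in config.planted_go:
        query = [gid for gid in background if presence.loc[gid, pg.superfamily]]
        res = sea(query, background, term_sets, domain_of=domain_of,
                  fdr_cutoff=fdr)
        hit = res[(res["go_id"] == pg.term) & res["significant"]]
        go_recovered.append((pg, not hit.empty))

    return {
        "morphism_report": morphism,
        "gof_pvalues_true_p": gof_true,
        "screens": screens,
        "planted_associations": detected,
        "planted_go": go_recovered,
        "n_eligible_triads": len(eligible),
    }


def _planted_gene_p(config: SimulationConfig, macro: str, category: str) -> float:
    """Planted marginal probability that a gene carries >=1 TE insertion."""
    none = 1.0
    for sf, base in config.superfamily_p.items():
        p = base * (config.distal_multiplier if macro == "distal" else 1.0)
        for e in config.planted_effects:
            if (e.te_group == sf
                    and _category_in_comparison(category, e.comparison)
                    and 0 < p < 1):
                odds = e.odds_multiplier * p / (1 - p)
                p = odds / (1 + odds)
        none *= 1 - p
    return 1 - none
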