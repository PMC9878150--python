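"""TE-in-gene overlap calling by interval intersection.

A TE "insertion within" a feature means the two 1-based inclusive intervals
share at least one base; a TE straddling a feature edge counts. Strand is
ignored. Contexts:

- ``gene_body``: the full [start, stop] span including introns
- ``exon`` / ``utr5`` / ``utr3``: the normalized intervals of the gene model
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
import pyranges as pr

from .annotations_io import GeneModel, GeneRecord, TERepeat

CONTEXTS = ("gene_body", "exon", "utr5", "utr3")

OVERLAP_COLUMNS = ["gene_id", "te_id", "context", "overlap_bp"]


def _feature_frame(genes: Iterable[GeneRecord],
                   models: Mapping[str, GeneModel] | None,
                   context: str) -> pd.DataFrame:
    rows = []
    if context == "gene_body":
        for g in genes:
            rows.append((g.chromosome, g.start, g.stop, g.gene_id))
    else:
        attr = {"exon": "exons", "utr5": "utr5", "utr3": "utr3"}[context]
        models = models or {}
        for g in genes:
            model = models.get(g.gene_id)
            if model is None:
                continue
            for a, b in getattr(model, attr):
                rows.append((g.chromosome, a, b, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "stop", "gene_id"])


def find_te_insertions(
    genes: Iterable[GeneRecord],
    tes: Iterable[TERepeat],
    context: str = "gene_body",
    models: Mapping[str, GeneModel] | None = None,
) -> pd.DataFrame:
    """All (gene, TE) pairs whose intervals intersect in the given context.

    Returns a frame with columns ``gene_id, te_id, context, overlap_bp``,
    sorted for deterministic output. ``overlap_bp`` sums over the gene's
    intervals for exon/UTR contexts.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    feat = _feature_frame(genes, models, context)
    te_rows = [(t.chromosome, t.start, t.stop, t.te_id) for t in tes]
    te_df = pd.DataFrame(te_rows, columns=["chrom", "start", "stop", "te_id"])
    if feat.empty or te_df.empty:
        return pd.DataFrame(columns=OVERLAP_COLUMNS)

    # 1-based inclusive -> 0-based half-open for pyranges
    gr = pr.PyRanges(pd.DataFrame({
        "Chromosome": feat["chrom"], "Start": feat["start"] - 1,
        "End": feat["stop"], "gene_id": feat["gene_id"]}))
    tr = pr.PyRanges(pd.DataFrame({
        "Chromosome": te_df["chrom"], "Start": te_df["start"] - 1,
        "End": te_df["stop"], "te_id": te_df["te_id"]}))
    joined = gr.join(tr).df
    if joined.empty:
        return pd.DataFrame(columns=OVERLAP_COLUMNS)
    joined["overlap_bp"] = (
        joined[["End", "End_b"]].min(axis=1) - joined[["Start", "Start_b"]].max(axis=1)
    )
    out = (joined.groupby(["gene_id", "te_id"], as_index=False)["overlap_bp"].sum())
    out["context"] = context
    out = out[OVERLAP_COLUMNS]
    return out.sort_values(["gene_id", "te_id"], ignore_index=True)


def find_all_contexts(
    genes: Iterable[GeneRecord],
    tes: Iterable[TERepeat],
    models: Mapping[str, GeneModel] | None = None,
) -> pd.DataFrame:
    """Concatenated overlap calls for every context with available intervals."""
    genes = list(genes)
    tes = list(tes)
    frames = [find_te_insertions(genes, tes, ctx, models) for ctx in CONTEXTS]
    return pd.concat(frames, ignore_index=True)


def summarize_gene_te_content(
    overlaps: pd.DataFrame,
    genes: Iterable[GeneRecord],
    te_lookup: Mapping[str, TERepeat],
) -> pd.DataFrame:
    """Per-gene TE content table.

    Columns: ``gene_id``, boolean ``has_te_gene_body/_exon/_utr5/_utr3``,
    ``superfamilies`` and ``subfamilies`` (comma-joined sorted sets, from
    gene-body overlaps).
    """
    gene_ids = [g.gene_id for g in genes]
    out = pd.DataFrame({"gene_id": gene_ids}).set_index("gene_id")
    for ctx in CONTEXTS:
        hit = overlaps.loc[overlaps["context"] == ctx, "gene_id"].unique()
        out[f"has_te_{ctx}" if ctx == "gene_body" else f"has_te_{ctx}"] = \
            out.index.isin(hit)
    sups: dict[str, set[str]] = {gid: set() for gid in gene_ids}
    subs: dict[str, set[str]] = {gid: set() for gid in gene_ids}
    body = overlaps[overlaps["context"] == "gene_body"]
    for row in body.itertuples(index=False):
        te = te_lookup[row.te_id]
        sups[row.gene_id].add(te.classification.superfamily_code)
        subs[row.gene_id].add(te.subfamily_name)
    out["superfamilies"] = [",".join(sorted(sups[g])) for g in out.index]
    out["subfamilies"] = [",".join(sorted(subs[g])) for g in out.index]
    return out.reset_index()
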