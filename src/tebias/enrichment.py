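"""GO Singular Enrichment Analysis (SEA) against an eligible-triad background.

One-sided Fisher's exact over-representation per term, BH FDR within each GO
domain. Triad term sets are the union of their member genes' annotations,
optionally propagated to ancestors via an OBO ``is_a`` hierarchy.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

DOMAINS = ("BP", "MF", "CC")

_NAMESPACE_TO_DOMAIN = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


def read_gene_to_go(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene->GO TSV (``gene_id, go_id[, domain]``).

    Returns (gene -> term set, term -> domain). Terms without a domain
    column default to BP.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "go_id"}.issubset(df.columns):
        raise ValueError("gene->GO table needs columns gene_id, go_id")
    gene_to_go: dict[str, set[str]] = {}
    domain_of: dict[str, str] = {}
    has_domain = "domain" in df.columns
    for row in df.itertuples(index=False):
        gene_to_go.setdefault(row.gene_id, set()).add(row.go_id)
        domain_of[row.go_id] = row.domain if has_domain else "BP"
    return gene_to_go, domain_of


def read_obo(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Minimal OBO parser: returns (term -> direct is_a parents, term -> domain)."""
    parents: dict[str, set[str]] = {}
    domain_of: dict[str, str] = {}
    term_id: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                term_id = None
            elif line.startswith("id: GO:"):
                term_id = line[4:]
                parents.setdefault(term_id, set())
            elif line.startswith("is_a:") and term_id:
                parents[term_id].add(line.split()[1])
            elif line.startswith("namespace:") and term_id:
                ns = line.split(":", 1)[1].strip()
                domain_of[term_id] = _NAMESPACE_TO_DOMAIN.get(ns, "BP")
    return parents, domain_of


def ancestor_closure(parents: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Transitive closure of the is_a graph (term -> all ancestors)."""
    cache: dict[str, set[str]] = {}

    def walk(term: str) -> set[str]:
        if term in cache:
            return cache[term]
        cache[term] = set()  # break cycles defensively
        anc: set[str] = set()
        for p in parents.get(term, ()):
            anc.add(p)
            anc |= walk(p)
        cache[term] = anc
        return anc

    for t in parents:
        walk(t)
    return cache


def map_triads_to_go(
    members: Mapping[str, Iterable[str]],
    gene_to_go: Mapping[str, set[str]],
    *,
    ancestors: Mapping[str, set[str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Term set per triad: union over member genes, optionally with ancestors."""
    out: dict[str, frozenset[str]] = {}
    for group_id, gene_ids in members.items():
        terms: set[str] = set()
        for g in gene_ids:
            terms |= gene_to_go.get(g, set())
        if ancestors is not None:
            extra: set[str] = set()
            for t in terms:
                extra |= ancestors.get(t, set())
            terms |= extra
        out[group_id] = frozenset(terms)
    return out


def sea(
    query: Iterable[str],
    background: Iterable[str],
    term_sets: Mapping[str, frozenset[str]],
    *,
    domain_of: Mapping[str, str] | None = None,
    fdr_cutoff: float = 0.05,
    min_query_terms: int = 2,
    terms: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Singular enrichment analysis of ``query`` triads vs ``background``.

    Per term T, one-sided Fisher's exact test (over-representation) on

        [[q_hits, q_size - q_hits], [b_hits - q_hits, b_out - (b_hits - q_hits)]]

    where b_out = bg_size - q_size. FDR is BH-adjusted across terms within
    each GO domain. By default the terms tested are the union of the query
    triads' annotations (SEA semantics); pass ``terms`` to test an explicit
    list instead (terms absent from the query then report p = 1). Returns
    all tested terms with a ``significant`` flag (fdr <= ``fdr_cutoff``);
    empty frame when the query maps to fewer than ``min_query_terms``
    distinct terms.
    """
    query = sorted(set(query))
    background = sorted(set(background))
    if not set(query).issubset(background):
        raise ValueError("query triads must be a subset of the background")
    q_terms: set[str] = set()
    for t in query:
        q_terms |= term_sets.get(t, frozenset())
    columns = ["go_id", "domain", "query_hits", "query_size",
               "background_hits", "background_size", "p_raw", "fdr",
               "significant"]
    if len(q_terms) < min_query_terms:
        return pd.DataFrame(columns=columns)
    tested = sorted(q_terms) if terms is None else sorted(set(terms))
    q_size, b_size = len(query), len(background)
    rows = []
    for term in tested:
        q_hits = sum(term in term_sets.get(t, frozenset()) for t in query)
        b_hits = sum(term in term_sets.get(t, frozenset()) for t in background)
        table = [[q_hits, q_size - q_hits],
                 [b_hits - q_hits, (b_size - q_size) - (b_hits - q_hits)]]
        _, p = sps.fisher_exact(table, alternative="greater")
        dom = domain_of.get(term, "BP") if domain_of else "BP"
        rows.append((term, dom, q_hits, q_size, b_hits, b_size, float(p)))
    df = pd.DataFrame(rows, columns=columns[:7])
    df["fdr"] = float("nan")
    for dom, idx in df.groupby("domain").groups.items():
        df.loc[idx, "fdr"] = bh_adjust(df.loc[idx, "p_raw"])
    df["significant"] = df["fdr"] <= fdr_cutoff
    return df.sort_values(["domain", "p_raw", "go_id"], ignore_index=True)
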