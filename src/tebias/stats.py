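"""Statistical core: conditional-binomial morphism null, contingency tests,
and the TE-type-by-expression-category association screen.

The null model assumes TE presence/absence is independent Bernoulli(p) per
gene. Conditioning on a group containing at least one insertion gives

    P(monomorphic | TE) = p^k / (1 - (1-p)^k)
    P(polymorphic | TE) = (1 - p^k - (1-p)^k) / (1 - (1-p)^k)

with k the group cardinality. p is estimated from TE-containing groups as
(number of member genes with a TE) / (k * number of groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import expression as _expr

COMPARISONS = ("balanced_vs_nonbalanced", "suppressed_vs_notsuppressed",
               "dominant_vs_notdominant")


# --------------------------------------------------------------------------- #
# Conditional binomial null for morphism
# --------------------------------------------------------------------------- #

def single_gene_te_probability(te_gene_counts: Sequence[int], k: int) -> float:
    """p = (genes with TE in TE-containing groups) / (k * number of groups).

    Every count must be between 1 and k (the groups are TE-containing).
    """
    counts = np.asarray(list(te_gene_counts), dtype=int)
    if counts.size == 0:
        raise ValueError("no TE-containing groups")
    if counts.min() < 1 or counts.max() > k:
        raise ValueError(f"per-group TE gene counts must lie in [1, {k}]")
    return float(counts.sum()) / (k * counts.size)


def conditional_morphism_probabilities(p: float, k: int) -> tuple[float, float]:
    """(P(monomorphic | >=1 TE), P(polymorphic | >=1 TE)) under Bernoulli(p)."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    denom = 1.0 - (1.0 - p) ** k
    p_mono = p ** k / denom
    p_poly = (1.0 - p ** k - (1.0 - p) ** k) / denom
    return p_mono, p_poly


@dataclass
class MorphismNullModel:
    p: float
    k: int
    n_groups: int
    expected_monomorphic: float
    expected_polymorphic: float

    @classmethod
    def fit(cls, te_gene_counts: Sequence[int], k: int) -> "MorphismNullModel":
        counts = list(te_gene_counts)
        p = single_gene_te_probability(counts, k)
        n = len(counts)
        p_mono, p_poly = conditional_morphism_probabilities(p, k)
        return cls(p, k, n, p_mono * n, p_poly * n)

    @classmethod
    def from_counts(cls, n_polymorphic: int, n_monomorphic: int, k: int,
                    te_gene_total: int | None = None) -> "MorphismNullModel":
        """Fit from aggregate counts. For k=2 the per-gene total is implied
        (1 per polymorphic group, 2 per monomorphic); for k>2 it must be given.
        """
        n = n_polymorphic + n_monomorphic
        if te_gene_total is None:
            if k != 2:
                raise ValueError("te_gene_total required for k > 2")
            te_gene_total = n_polymorphic + 2 * n_monomorphic
        p = te_gene_total / (k * n)
        p_mono, p_poly = conditional_morphism_probabilities(p, k)
        return cls(p, k, n, p_mono * n, p_poly * n)


def expected_morphism_counts(model: MorphismNullModel) -> tuple[float, float]:
    return model.expected_monomorphic, model.expected_polymorphic


def goodness_of_fit(observed: Sequence[float],
                    expected: Sequence[float]) -> tuple[float, float]:
    """Pearson chi-square goodness of fit, df = cells - 1, no correction."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected lengths differ")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    res = sps.chisquare(obs, exp)
    return float(res.statistic), float(res.pvalue)


def morphism_gof(n_polymorphic: int, n_monomorphic: int,
                 model: MorphismNullModel) -> tuple[float, float]:
    return goodness_of_fit(
        [n_polymorphic, n_monomorphic],
        [model.expected_polymorphic, model.expected_monomorphic])


# --------------------------------------------------------------------------- #
# Contingency tests
# --------------------------------------------------------------------------- #

def independence_test(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2xK table.

    Yates continuity correction is applied for 2x2 tables only (the default
    behaviour of ``scipy.stats.chi2_contingency``).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=True)
    return float(chi2), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini/Hochberg (non-negative) step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------- #
# TE-type association screen
# --------------------------------------------------------------------------- #

@dataclass
class AssociationResult:
    te_group: str
    comparison: str
    table: np.ndarray  # rows: TE present/absent; cols: category in/out
    chi2: float | None
    p_raw: float | None
    q: float | None
    direction: str | None
    included: bool


def _category_mask(categories: pd.Series, comparison: str) -> pd.Series:
    if comparison == "balanced_vs_nonbalanced":
        return categories == _expr.BALANCED
    if comparison == "suppressed_vs_notsuppressed":
        return categories.map(_expr.is_suppressed)
    if comparison == "dominant_vs_notdominant":
        return categories.map(_expr.is_dominant)
    raise ValueError(f"unknown comparison {comparison!r}")


def screen_te_groups(
    presence: pd.DataFrame,
    categories: pd.Series,
    comparison: str,
    *,
    min_cell: int = 5,
) -> pd.DataFrame:
    """Test each TE group's presence against one category comparison.

    ``presence`` is a boolean triad-by-TE-group frame (True when at least one
    member gene carries an insertion of that group); ``categories`` the
    per-triad category labels, same index. For each TE group a 2x2 table
    [[present & in, present & out], [absent & in, absent & out]] is built;
    groups with any cell below ``min_cell`` are excluded. Raw p-values of the
    included tests are BH-adjusted within this call (one family).

    Direction is ``positive`` when the (present, in-category) cell exceeds
    its independence expectation.
    """
    if presence.empty:
        raise ValueError("empty eligible triad set")
    if not presence.index.equals(categories.index):
        categories = categories.reindex(presence.index)
        if categories.isna().any():
            raise ValueError("categories missing for some triads")
    in_cat = _category_mask(categories, comparison).to_numpy(dtype=bool)
    results: list[AssociationResult] = []
    for te_group in presence.columns:
        pres = presence[te_group].to_numpy(dtype=bool)
        a = int(np.sum(pres & in_cat))
        b = int(np.sum(pres & ~in_cat))
        c = int(np.sum(~pres & in_cat))
        d = int(np.sum(~pres & ~in_cat))
        table = np.array([[a, b], [c, d]])
        if table.min() < min_cell:
            results.append(AssociationResult(te_group, comparison, table,
                                             None, None, None, None, False))
            continue
        chi2, p = independence_test(table)
        n = table.sum()
        expected_a = table.sum(axis=1)[0] * table.sum(axis=0)[0] / n
        direction = "positive" if a > expected_a else "negative"
        results.append(AssociationResult(te_group, comparison, table,
                                         chi2, p, None, direction, True))
    included = [r for r in results if r.included]
    if included:
        qs = bh_adjust([r.p_raw for r in included])
        for r, q in zip(included, qs):
            r.q = float(q)
    rows = []
    for r in results:
        a, b = r.table[0]
        c, d = r.table[1]
        rows.append((r.te_group, r.comparison, a, b, c, d, r.chi2, r.p_raw,
                     r.q, r.direction, r.included))
    return pd.DataFrame(rows, columns=[
        "te_group", "comparison", "present_in", "present_out", "absent_in",
        "absent_out", "chi2", "p_raw", "q", "direction", "included"])


def morphism_report(
    groups_df: pd.DataFrame,
    te_gene_counts: dict[str, int],
    *,
    stratify_region: bool = True,
) -> pd.DataFrame:
    """Observed vs expected morphism counts per cardinality (and macro-region).

    ``groups_df`` is the annotated group table (``groups_to_frame`` output)
    restricted upstream to expressed groups; ``te_gene_counts`` maps group_id
    to its number of TE-carrying member genes.
    """
    rows = []
    strata: list[tuple[str, pd.DataFrame]] = [("all", groups_df)]
    if stratify_region and "region_status" in groups_df.columns:
        for reg in ("proximal", "distal"):
            strata.append((reg, groups_df[groups_df["region_status"] == reg]))
    for stratum, df in strata:
        for k, sub in df.groupby("cardinality"):
            te_sub = sub[sub["morphism"].isin(["monomorphic", "polymorphic"])]
            if te_sub.empty:
                continue
            counts = [te_gene_counts[g] for g in te_sub["group_id"]]
            model = MorphismNullModel.fit(counts, int(k))
            n_poly = int((te_sub["morphism"] == "polymorphic").sum())
            n_mono = int((te_sub["morphism"] == "monomorphic").sum())
            if min(model.expected_monomorphic, model.expected_polymorphic) > 0:
                chi2, p = morphism_gof(n_poly, n_mono, model)
            else:  # degenerate fit (p = 1): the null predicts a single cell
                chi2, p = float("nan"), float("nan")
            rows.append((stratum, int(k), len(sub), len(te_sub), n_poly,
                         n_mono, model.p, model.expected_polymorphic,
                         model.expected_monomorphic, chi2, p))
    return pd.DataFrame(rows, columns=[
        "stratum", "cardinality", "n_groups", "n_te_groups", "observed_poly",
        "observed_mono", "p_single_gene", "expected_poly", "expected_mono",
        "chi2", "p_value"])
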