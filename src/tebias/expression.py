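"""Homoeolog expression-bias categories from relative expression proportions.

Triads are assigned to one of seven categories — balanced, A/B/D dominant,
A/B/D suppressed — by Euclidean nearest-centroid over per-triad mean
normalized expression proportions. Centroids (editable via the ``centroids``
argument):

- balanced: (1/3, 1/3, 1/3)
- X dominant: 1 at X, 0 elsewhere
- X suppressed: 0 at X, 1/2 elsewhere

Dyads and tetrads use analogously constructed centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SLOTS = ("A", "B", "D")

BALANCED = "balanced"

#: tie-break priority: balanced beats dominant beats suppressed, then A > B > D
CATEGORY_PRIORITY = [
    "balanced",
    "A_dominant", "B_dominant", "D_dominant",
    "A_suppressed", "B_suppressed", "D_suppressed",
]


def triad_centroids() -> dict[str, np.ndarray]:
    """The seven ideal normalized expression-bias points for (A, B, D)."""
    cents: dict[str, np.ndarray] = {"balanced": np.full(3, 1 / 3)}
    for i, slot in enumerate(SLOTS):
        dom = np.zeros(3)
        dom[i] = 1.0
        cents[f"{slot}_dominant"] = dom
        sup = np.full(3, 0.5)
        sup[i] = 0.0
        cents[f"{slot}_suppressed"] = sup
    return cents


def general_centroids(cardinality: int) -> dict[str, np.ndarray]:
    """Centroids for dyads (balanced / one suppressed) and tetrads
    (balanced / one suppressed / two suppressed / one dominant)."""
    k = cardinality
    if k == 3:
        return triad_centroids()
    if k not in (2, 4):
        raise ValueError(f"unsupported cardinality {k}")
    cents: dict[str, np.ndarray] = {"balanced": np.full(k, 1 / k)}
    for i in range(k):
        sup = np.full(k, 1 / (k - 1))
        sup[i] = 0.0
        cents[f"suppressed_{i}"] = sup
    if k == 4:
        for i in range(k):
            dom = np.zeros(k)
            dom[i] = 1.0
            cents[f"dominant_{i}"] = dom
        for i in range(k):
            for j in range(i + 1, k):
                two = np.full(k, 0.5)
                two[i] = two[j] = 0.0
                cents[f"suppressed_{i}_{j}"] = two
    return cents


def _general_priority(names: list[str]) -> list[str]:
    def rank(name: str) -> tuple:
        if name == "balanced":
            tier = 0
        elif name.startswith("dominant"):
            tier = 1
        elif name.count("_") == 1 and name.startswith("suppressed"):
            tier = 2
        else:  # two suppressed copies
            tier = 3
        return (tier, name)
    return sorted(names, key=rank)


@dataclass
class TriadExpression:
    """Per-triad normalized expression summary across qualifying samples."""

    group_id: str
    mean_proportions: np.ndarray | None
    n_samples_used: int
    n_tissues_expressed: int
    expressed: bool


def normalize_triad_expression(
    tpm: pd.DataFrame,
    *,
    group_id: str = "",
    floor: float = 0.5,
    tissue_of: dict[str, str] | None = None,
) -> TriadExpression:
    """Normalize a homoeolog-by-sample TPM block to per-sample proportions.

    ``tpm`` rows are the homoeolog copies (in slot order), columns samples.
    Samples whose summed TPM is at or below ``floor`` are excluded from the
    mean; if none qualifies the triad is flagged not-expressed.
    ``tissue_of`` maps sample name -> tissue; by default each sample is its
    own tissue.
    """
    values = tpm.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative TPM values")
    totals = values.sum(axis=0)
    keep = totals > floor
    n_used = int(keep.sum())
    samples = list(tpm.columns)
    tissues = {tissue_of.get(s, s) if tissue_of else s
               for s, k in zip(samples, keep) if k}
    if n_used == 0:
        return TriadExpression(group_id, None, 0, 0, expressed=False)
    props = values[:, keep] / totals[keep]
    mean = props.mean(axis=1)
    mean = mean / mean.sum()
    return TriadExpression(group_id, mean, n_used, len(tissues), expressed=True)


def assign_contribution_category(
    mean_proportions,
    centroids: dict[str, np.ndarray] | None = None,
    *,
    atol: float = 1e-6,
) -> tuple[str, float]:
    """Nearest-centroid category for a proportion vector summing to 1.

    Ties go to the highest-priority category (balanced > dominant >
    suppressed, then A > B > D). Returns ``(category, distance)``.
    """
    props = np.asarray(mean_proportions, dtype=float)
    if abs(props.sum() - 1.0) > atol:
        raise ValueError(f"proportions sum to {props.sum():.6f}, not 1")
    if centroids is None:
        centroids = triad_centroids()
    if set(centroids) == set(CATEGORY_PRIORITY):
        order = CATEGORY_PRIORITY
    else:
        order = _general_priority(list(centroids))
    best: tuple[str, float] | None = None
    for name in order:
        d = float(np.linalg.norm(props - centroids[name]))
        if best is None or d < best[1] - 1e-12:
            best = (name, d)
    assert best is not None
    return best


def assign_group_category_general(proportions, cardinality: int) -> tuple[str, float]:
    """Nearest-centroid assignment for dyads/tetrads (and triads)."""
    return assign_contribution_category(
        proportions, general_centroids(cardinality))


def categorize_triads(
    expression: pd.DataFrame,
    triad_members: dict[str, dict[str, str]],
    *,
    floor: float = 0.5,
    tissue_of: dict[str, str] | None = None,
    syntenic: dict[str, bool] | None = None,
    min_tissues: int = 6,
    centroids: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assign every triad a category and an eligibility flag.

    ``expression`` is a gene-by-sample TPM frame indexed by gene_id.
    ``triad_members`` maps group_id -> {slot: gene_id} with slots A/B/D.
    Eligible = syntenic and expressed in at least ``min_tissues`` tissues.
    """
    ids = sorted(triad_members)
    if not ids:
        return pd.DataFrame(columns=[
            "group_id", "prop_A", "prop_B", "prop_D", "category",
            "distance_to_centroid", "n_tissues_expressed", "syntenic",
            "eligible"])
    gene_pos = {g: i for i, g in enumerate(expression.index)}
    idx = np.array([[gene_pos[triad_members[g][s]] for s in SLOTS]
                    for g in ids])
    values = expression.to_numpy(dtype=float)
    X = values[idx]                      # (n_triads, 3, n_samples)
    totals = X.sum(axis=1)               # (n_triads, n_samples)
    keep = totals > floor
    n_used = keep.sum(axis=1)
    safe = np.where(keep, totals, 1.0)
    props = np.where(keep[:, None, :], X / safe[:, None, :], 0.0)
    with np.errstate(invalid="ignore"):
        mean = props.sum(axis=2) / np.where(n_used > 0, n_used, 1)[:, None]
        mean = mean / np.where(n_used > 0, mean.sum(axis=1), 1)[:, None]

    samples = list(expression.columns)
    tissue_names = sorted({tissue_of.get(s, s) if tissue_of else s
                           for s in samples})
    t_idx = {t: i for i, t in enumerate(tissue_names)}
    onehot = np.zeros((len(samples), len(tissue_names)), dtype=bool)
    for j, s in enumerate(samples):
        onehot[j, t_idx[tissue_of.get(s, s) if tissue_of else s]] = True
    n_tissues = ((keep @ onehot) > 0).sum(axis=1)

    cents = centroids if centroids is not None else triad_centroids()
    order = CATEGORY_PRIORITY if set(cents) == set(CATEGORY_PRIORITY) \
        else _general_priority(list(cents))
    C = np.stack([cents[name] for name in order])
    D = np.linalg.norm(mean[:, None, :] - C[None, :, :], axis=2)
    dmin = D.min(axis=1)
    choice = (D <= dmin[:, None] + 1e-12).argmax(axis=1)  # first in priority

    rows = []
    for i, gid in enumerate(ids):
        is_syntenic = True if syntenic is None else bool(syntenic.get(gid, True))
        if n_used[i] == 0:
            cat, dist = "not_expressed", float("nan")
            pa = pb = pd_ = float("nan")
        else:
            cat, dist = order[choice[i]], float(dmin[i])
            pa, pb, pd_ = mean[i]
        eligible = bool(is_syntenic and n_tissues[i] >= min_tissues
                        and n_used[i] > 0)
        rows.append((gid, pa, pb, pd_, cat, dist, int(n_tissues[i]),
                     is_syntenic, eligible))
    return pd.DataFrame(rows, columns=[
        "group_id", "prop_A", "prop_B", "prop_D", "category",
        "distance_to_centroid", "n_tissues_expressed", "syntenic", "eligible"])


def select_analysis_triads(assignments: pd.DataFrame,
                           *, min_tissues: int = 6) -> pd.DataFrame:
    """Eligible triads: syntenic and expressed in >= ``min_tissues`` tissues."""
    mask = (assignments["syntenic"]
            & (assignments["n_tissues_expressed"] >= min_tissues)
            & (assignments["category"] != "not_expressed"))
    return assignments[mask].reset_index(drop=True)


def is_suppressed(category: str) -> bool:
    return category.endswith("_suppressed") or category.startswith("suppressed")


def is_dominant(category: str) -> bool:
    return category.endswith("_dominant") or category.startswith("dominant")
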