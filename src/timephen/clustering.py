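"""Immune-phenotype discovery: hierarchical clustering of core profiles.

Cores are clustered by Ward linkage on Euclidean distance over z-scaled
per-compartment immune densities, cut into ``k`` groups (k=5 in the
reference configuration).  Cluster robustness is quantified clusterboot-style:
rows are resampled with replacement, reclustered, each original cluster is
matched to the bootstrap cluster maximizing the Jaccard coefficient over the
resampled points, and the per-cluster mean over B replicates is reported.

Clusters are then given semantic names by ranking their overall median
densities (OMDs): the cluster with the highest CD8 OMD is TIL-rich; among
the rest, highest CK&PD-L1 OMD is immune-exclusion, highest CD68 OMD is
macrophage-rich, highest FOXP3 OMD is FOXP3-rich; the remainder is
immune-desert provided it also has the lowest total immune OMD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .features import cluster_omd_table


def scale_features(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise z-scaling (population SD, ddof=0); constant columns -> zeros."""
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to scale")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance columns mapped to zeros")
    scaled = np.where(zero, 0.0, (values - mean) / np.where(zero, 1.0, sd))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
    return scaled


@dataclass
class ClusteringReport:
    k: int
    linkage_tree: np.ndarray
    sizes: dict[int, int]
    jaccard: dict[int, float] = field(default_factory=dict)
    omd: pd.DataFrame | None = None


def hierarchical_cluster(
    scaled: pd.DataFrame | np.ndarray, k: int
) -> tuple[np.ndarray, ClusteringReport]:
    """Ward/Euclidean agglomerative clustering cut into ``k`` clusters.

    Returns 1-based labels (aligned with the input rows) and a report with
    the linkage tree and cluster sizes.
    """
    values = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    n = values.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must be in [2, {n}]")
    tree = linkage(values, method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust")
    sizes = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    return labels, ClusteringReport(k=k, linkage_tree=tree, sizes=sizes)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def bootstrap_jaccard(
    scaled: pd.DataFrame | np.ndarray,
    k: int,
    B: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict[int, float]:
    """Per-cluster mean Jaccard stability over B bootstrap reclusterings.

    For each resample the original clusters are restricted to the resampled
    positions and matched to the bootstrap cluster with maximal Jaccard; a
    cluster absent from a resample contributes 0 for that replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    n = values.shape[0]
    base_labels, _ = hierarchical_cluster(values, k)
    clusters = np.unique(base_labels)

    sums = {int(c): 0.0 for c in clusters}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot_labels, _ = hierarchical_cluster(values[idx], k)
        orig_at = base_labels[idx]
        for c in clusters:
            a = orig_at == c
            if not a.any():
                continue  # contributes 0
            best = max(_jaccard(a, boot_labels == bc) for bc in np.unique(boot_labels))
            sums[int(c)] += best
    return {c: s / B for c, s in sums.items()}


def name_clusters(
    labels: np.ndarray, features: pd.DataFrame, core_ids=None
) -> tuple[dict[int, str], pd.DataFrame]:
    """Attach semantic phenotype names to cluster indices via OMD ranking.

    Rule order: TIL-rich = max CD8 OMD; immune-exclusion = max CK&PD-L1 OMD
    among the rest; macrophage-rich = max CD68; FOXP3-rich = max FOXP3; the
    remainder is immune-desert only if it also has the minimal total immune
    OMD, otherwise ``unnamed``.  Ties go to the larger cluster.
    """
    core_ids = list(features.index) if core_ids is None else list(core_ids)
    assignments = pd.DataFrame({"core_id": core_ids, "cluster_index": labels})
    omd = cluster_omd_table(features, assignments)
    omd["total_immune"] = omd[["cd8", "cd68", "foxp3"]].sum(axis=1)
    sizes = assignments.groupby("cluster_index").size()

    names: dict[int, str] = {}
    remaining = list(omd.index)

    def _take(column: str) -> int | None:
        sub = omd.loc[remaining, column]
        top = sub.max()
        cands = [c for c in remaining if sub[c] == top]
        if len(cands) > 1:
            warnings.warn(f"OMD tie on {column}; broken by cluster size")
            cands.sort(key=lambda c: (-sizes.get(c, 0), c))
        winner = cands[0]
        remaining.remove(winner)
        return winner

    if (omd.nunique() == 1).all():  # every column constant: clusters indistinguishable
        warnings.warn("all clusters have identical OMD profiles; nothing nameable")
        return {int(c): "unnamed" for c in omd.index}, omd

    # specialist names in rule order; the last remaining cluster is always
    # the immune-desert candidate (partial naming when k < 5)
    for column, name in (
        ("cd8", "til_rich"),
        ("ck_pdl1", "immune_exclusion"),
        ("cd68", "macrophage_rich"),
        ("foxp3", "foxp3_rich"),
    ):
        if len(remaining) <= 1:
            break
        names[_take(column)] = name

    for c in remaining:
        if omd.loc[c, "total_immune"] == omd["total_immune"].min():
            names[int(c)] = "immune_desert"
        else:
            warnings.warn(
                f"residual cluster {c} lacks the minimal total immune OMD; left unnamed"
            )
            names[int(c)] = "unnamed"
    return {int(c): v for c, v in names.items()}, omd


def assign_phenotypes(
    features: pd.DataFrame,
    k: int = 5,
    B: int = 100,
    rng: np.random.Generator | int | None = None,
    variables: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, ClusteringReport]:
    """End-to-end phenotype assignment for a feature matrix.

    Scales the clustering variables, clusters, names clusters by OMD rules,
    and attaches per-cluster bootstrap Jaccard stability.  Returns the
    assignment table (core_id, cluster_index, semantic_name,
    jaccard_stability) and the clustering report.
    """
    from .features import CLUSTER_VARIABLES

    variables = variables or CLUSTER_VARIABLES
    scaled = scale_features(features[list(variables)])
    labels, report = hierarchical_cluster(scaled, k)
    jac = bootstrap_jaccard(scaled, k, B=B, rng=rng) if B else {}
    names, omd = name_clusters(labels, features)
    report.jaccard = jac
    report.omd = omd
    assignments = pd.DataFrame(
        {
            "core_id": list(features.index),
            "cluster_index": labels,
            "semantic_name": [names[int(c)] for c in labels],
            "jaccard_stability": [jac.get(int(c), np.nan) for c in labels],
        }
    )
    return assignments, report


def choose_k(
    scaled: pd.DataFrame | np.ndarray,
    k_range=range(2, 9),
    B: int = 0,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick k maximizing mean silhouette; bootstrap Jaccard as diagnostics.

    Never overrides a user-pinned k: callers who fix k simply do not call
    this.  Returns ``(best_k, diagnostics)``.
    """
    values = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    rows = []
    for k in k_range:
        if not 2 <= k <= values.shape[0] - 1:
            continue
        labels, _ = hierarchical_cluster(values, k)
        sil = float(silhouette_score(values, labels)) if len(np.unique(labels)) > 1 else float("nan")
        row = {"k": k, "silhouette": sil}
        if B:
            jac = bootstrap_jaccard(values, k, B=B, rng=rng)
            row["mean_jaccard"] = float(np.mean(list(jac.values())))
        rows.append(row)
    diag = pd.DataFrame(rows)
    if diag.empty:
        raise ValueError("empty k range")
    if diag["silhouette"].max() < 0.25:
        diag.attrs["note"] = "no support for k>1 (all silhouettes weak)"
    best = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    return best, diag
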