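"""Projection clustering, composition tables, motifs and motif enrichment.

Two complementary views of projection structure:

* continuous — hierarchical clustering of per-cell projection profiles
  (log1p of row-relative intensity) into clusters and coarser classes;
* binary — each distinct nonzero 0/1 target combination is a *projection
  motif*; observed motif counts are compared with the expectation under
  target independence, ``E[S] = N * prod_{t in S} p_t * prod_{t not in S}
  (1 - p_t)``, via a two-sided exact binomial test with
  Benjamini-Hochberg correction across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import binomtest, false_discovery_control

from .barcode_processing import ProjectionProfileSet, normalize_intensity

__all__ = [
    "ProjectionClustering",
    "cluster_projections",
    "cluster_summary",
    "composition_table",
    "enumerate_motifs",
    "motif_enrichment",
    "motif_expected",
    "motif_to_signature",
]


@dataclass
class ProjectionClustering:
    cell_ids: list[str]
    cluster_id: np.ndarray  # 1..K per projecting cell
    class_id: np.ndarray  # 1..n_classes per projecting cell
    method: str
    metric: str
    merge_heights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster_id": self.cluster_id, "class_id": self.class_id},
            index=pd.Index(self.cell_ids, name="cell_id"),
        )


def cluster_projections(
    profiles: ProjectionProfileSet,
    n_clusters: int,
    n_classes: int,
    method: str = "ward",
    metric: str = "euclidean",
) -> ProjectionClustering:
    """Agglomerative clustering of projecting cells' projection profiles.

    Rows are log1p(row-relative intensity); the dendrogram is cut at
    ``n_clusters`` (fine projection clusters) and ``n_classes`` (coarse
    projection classes). Classes partition clusters because both cuts come
    from the same tree. Deterministic given inputs.
    """
    proj = profiles.projecting()
    n = len(proj.cell_ids)
    if not 1 <= n_classes <= n_clusters <= n:
        raise ValueError(
            f"need 1 <= n_classes ({n_classes}) <= n_clusters ({n_clusters}) <= cells ({n})"
        )
    rel = normalize_intensity(proj, "relative")
    X = np.log1p(rel)
    Z = linkage(X, method=method, metric=metric)
    cluster_id = fcluster(Z, t=n_clusters, criterion="maxclust")
    class_id = fcluster(Z, t=n_classes, criterion="maxclust")
    return ProjectionClustering(
        cell_ids=list(proj.cell_ids),
        cluster_id=cluster_id,
        class_id=class_id,
        method=method,
        metric=metric,
        merge_heights=Z[:, 2].copy(),
    )


def cluster_summary(clustering: ProjectionClustering, profiles: ProjectionProfileSet) -> pd.DataFrame:
    """Cluster x target table of z-scored mean relative intensity and cell %.

    The z-score is across clusters within each target (the dot-plot color);
    the percentage is the share of the cluster's cells with binary == 1
    (the dot size). With a single cluster the z is undefined and reported
    as 0 with a flag column.
    """
    proj = profiles.projecting()
    if list(proj.cell_ids) != list(clustering.cell_ids):
        raise ValueError("clustering is not aligned to the projecting cells of profiles")
    rel = normalize_intensity(proj, "relative")
    clusters = np.unique(clustering.cluster_id)
    means = np.zeros((len(clusters), len(proj.target_ids)))
    pct = np.zeros_like(means)
    for i, k in enumerate(clusters):
        mask = clustering.cluster_id == k
        means[i] = rel[mask].mean(axis=0)
        pct[i] = 100.0 * proj.binary[mask].mean(axis=0)

    single = len(clusters) < 2
    if single:
        z = np.zeros_like(means)
    else:
        mu = means.mean(axis=0)
        sd = means.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (means - mu) / np.where(sd == 0, 1.0, sd), 0.0)

    rows = []
    for i, k in enumerate(clusters):
        for j, t in enumerate(proj.target_ids):
            rows.append(
                {
                    "cluster_id": int(k),
                    "target": t,
                    "mean_relative_intensity": means[i, j],
                    "intensity_zscore": z[i, j],
                    "cell_percentage": pct[i, j],
                    "single_cluster": single,
                }
            )
    return pd.DataFrame(rows)


def composition_table(labels_a, labels_b) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulated counts and row-normalized proportions of two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length ({len(a)} vs {len(b)})")
    counts = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return counts, proportions


def motif_to_signature(row: np.ndarray, target_ids: list[str]) -> str:
    """Human-readable motif name: '+'-joined targets of the 1-entries."""
    return "+".join(t for t, v in zip(target_ids, row) if v)


def enumerate_motifs(binary: np.ndarray, target_ids: list[str], top_n: int | None = None) -> pd.DataFrame:
    """Count distinct nonzero binary row patterns (projection motifs).

    Sorted by count descending, ties broken lexicographically on the
    signature tuple; all-zero rows are excluded (their count is reported in
    the ``n_nonprojecting`` attribute of the frame).
    """
    binary = np.asarray(binary)
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    nonzero = binary[binary.sum(axis=1) > 0]
    n_zero = len(binary) - len(nonzero)
    if len(nonzero) == 0:
        out = pd.DataFrame(columns=["signature", "n_targets", "count"])
        out.attrs["n_nonprojecting"] = n_zero
        return out
    patterns, counts = np.unique(nonzero, axis=0, return_counts=True)
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], tuple(patterns[i])))
    if top_n is not None:
        order = order[:top_n]
    out = pd.DataFrame(
        {
            "signature": [motif_to_signature(patterns[i], target_ids) for i in order],
            "n_targets": [int(patterns[i].sum()) for i in order],
            "count": [int(counts[i]) for i in order],
        }
    )
    out.attrs["n_nonprojecting"] = n_zero
    out.attrs["patterns"] = patterns[order]
    return out


def motif_expected(pattern: np.ndarray, marginals: np.ndarray, n_cells: int) -> float:
    """Expected count of an exact motif under target independence.

    ``n_cells * prod_{t in S} p_t * prod_{t not in S} (1 - p_t)`` for the
    signature ``pattern`` (0/1 over targets). Summed over all nonzero
    patterns this conserves probability: N * (1 - prod_t (1 - p_t)).
    """
    pattern = np.asarray(pattern)
    marginals = np.asarray(marginals, dtype=float)
    return float(n_cells * np.prod(np.where(pattern == 1, marginals, 1.0 - marginals)))


def motif_enrichment(
    binary: np.ndarray,
    target_ids: list[str],
    alpha: float = 0.05,
    min_observed: int = 5,
) -> pd.DataFrame:
    """Observed vs independence-expected motif counts with exact tests.

    Marginals ``p_t`` are the column means of the binary matrix over
    projecting cells. For each motif ``S`` observed at least
    ``min_observed`` times, the expected count under target independence is
    ``N * prod_{t in S} p_t * prod_{t not in S} (1 - p_t)`` and the
    p-value is a two-sided exact binomial test (minlike: summing outcome
    probabilities <= that of the observation) of the observed count against
    success probability expected/N over N trials. q-values are
    Benjamini-Hochberg across the tested motifs; labels are
    overrepresented / underrepresented / not significant by q <= alpha and
    the sign of observed - expected.

    Degenerate marginals (p_t of exactly 0 or 1) make the binomial test
    vacuous; affected motifs are flagged with p = 1, not significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    binary = np.asarray(binary)
    proj = binary[binary.sum(axis=1) > 0]
    N = len(proj)
    if N < 1:
        raise ValueError("no projecting cells")
    p_t = proj.mean(axis=0)

    motifs = enumerate_motifs(proj, target_ids)
    motifs = motifs[motifs["count"] >= min_observed].reset_index(drop=True)
    patterns = np.array(
        [_signature_to_row(s, target_ids) for s in motifs["signature"]], dtype=np.int8
    ).reshape(len(motifs), len(target_ids))

    rows = []
    for i in range(len(motifs)):
        sig_row = patterns[i]
        obs = int(motifs.loc[i, "count"])
        # a marginal of exactly 0 or 1 makes every motif probability either
        # structurally forced or zero; the binomial null is vacuous there
        degenerate = bool(np.any((p_t == 0) | (p_t == 1)))
        expected = motif_expected(sig_row, p_t, N)
        prob = expected / N
        if degenerate or prob in (0.0, 1.0):
            p_value, degenerate = 1.0, True
        else:
            p_value = binomtest(obs, N, prob, alternative="two-sided").pvalue
        rows.append(
            {
                "signature": motifs.loc[i, "signature"],
                "n_targets": int(motifs.loc[i, "n_targets"]),
                "observed": obs,
                "expected": expected,
                "p_value": p_value,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        table["q_value"] = []
        table["label"] = []
        table.attrs["marginals"] = pd.Series(p_t, index=target_ids, name="p_t")
        table.attrs["n_projecting"] = N
        return table
    table["q_value"] = false_discovery_control(table["p_value"].to_numpy(), method="bh")
    direction = np.sign(table["observed"] - table["expected"])
    table["label"] = np.where(
        (table["q_value"] <= alpha) & ~table["degenerate"],
        np.where(direction > 0, "overrepresented", "underrepresented"),
        "not significant",
    )
    table.attrs["marginals"] = pd.Series(p_t, index=target_ids, name="p_t")
    table.attrs["n_projecting"] = N
    return table


def _signature_to_row(signature: str, target_ids: list[str]) -> np.ndarray:
    parts = set(signature.split("+")) if signature else set()
    return np.array([1 if t in parts else 0 for t in target_ids], dtype=np.int8)
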