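"""Gene co-expression networks, modules, eigengenes and trait correlations.

A thresholded Pearson-correlation network is built on a curated gene panel;
modules come from average-linkage clustering of the 1 - |r| dissimilarity;
hub genes are the most intramodularly connected genes. Each module is
summarized per cell by its module eigengene (ME): the first principal
component of the module's standardized gene submatrix, unit variance, sign
aligned with the module's mean expression. MEs are then correlated with
per-target projection intensity, and a projection-group differential
expression contrast is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import false_discovery_control, fisher_exact, mannwhitneyu, pearsonr
from sklearn.metrics import silhouette_score

__all__ = [
    "GeneModuleSet",
    "correlation_network",
    "detect_modules",
    "module_eigengenes",
    "module_projection_correlation",
    "differential_expression",
]


@dataclass
class GeneModuleSet:
    gene_ids: list[str]
    module_of: dict[str, str]  # gene -> "M1".."Mk" ("M0" = unassigned/grey)
    adjacency: pd.DataFrame
    hub_genes: dict[str, list[str]] = field(default_factory=dict)
    eigengenes: pd.DataFrame | None = None  # cells x modules

    @property
    def modules(self) -> list[str]:
        return sorted({m for m in self.module_of.values() if m != "M0"},
                      key=lambda s: int(s[1:]))

    def genes_in(self, module: str) -> list[str]:
        return [g for g in self.gene_ids if self.module_of[g] == module]


def correlation_network(
    expr: np.ndarray, gene_ids: list[str], edge_threshold: float = 0.3
) -> pd.DataFrame:
    """Thresholded gene-gene Pearson correlation adjacency.

    Edge weight is r where |r| >= edge_threshold, else 0; diagonal 0.
    Constant genes get a zero row/column (correlation undefined).
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] != len(gene_ids):
        raise ValueError("expression columns do not match gene_ids")
    if len(gene_ids) < 2:
        raise ValueError("panel needs at least 2 genes")
    sd = expr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(expr, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    adj = np.where(np.abs(r) >= edge_threshold, r, 0.0)
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=gene_ids, columns=gene_ids)


def _correlation_from_adjacency(expr: np.ndarray) -> np.ndarray:
    sd = expr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(expr, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def detect_modules(
    expr: np.ndarray,
    gene_ids: list[str],
    k: int | None = None,
    hub_n: int = 10,
    edge_threshold: float = 0.3,
) -> GeneModuleSet:
    """Cluster the panel into co-expression modules and pick hub genes.

    Average-linkage hierarchical clustering on dissimilarity 1 - |r|; the
    tree is cut at ``k`` modules, or, when k is None, at the k in 2..10
    with the largest silhouette on the dissimilarity. Hubs are the top
    ``hub_n`` genes per module by within-module sum of |adjacency|.
    """
    expr = np.asarray(expr, dtype=float)
    n_genes = len(gene_ids)
    if k is not None and not 1 <= k <= n_genes:
        raise ValueError(f"k={k} out of range for panel of {n_genes} genes")
    r = _correlation_from_adjacency(expr)
    dissim = 1.0 - np.abs(r)
    dissim = 0.5 * (dissim + dissim.T)
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")

    if k is None:
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(10, n_genes - 1) + 1):
            lab = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(dissim, lab, metric="precomputed")
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = fcluster(Z, t=k, criterion="maxclust")

    # relabel modules by size (M1 largest) for stable naming
    order = pd.Series(labels).value_counts().index.tolist()
    rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
    module_of = {g: rename[lab] for g, lab in zip(gene_ids, labels)}

    adjacency = correlation_network(expr, gene_ids, edge_threshold=edge_threshold)
    hub_genes: dict[str, list[str]] = {}
    for mod in sorted(set(module_of.values()), key=lambda s: int(s[1:])):
        genes = [g for g in gene_ids if module_of[g] == mod]
        sub = adjacency.loc[genes, genes].abs()
        connectivity = sub.sum(axis=1)
        hub_genes[mod] = list(connectivity.sort_values(ascending=False).index[:hub_n])
    return GeneModuleSet(gene_ids=list(gene_ids), module_of=module_of,
                         adjacency=adjacency, hub_genes=hub_genes)


def module_eigengenes(
    expr: np.ndarray, gene_ids: list[str], modules: GeneModuleSet,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Cells x modules eigengene matrix.

    The ME is the first principal-component score of the module's
    z-scored gene submatrix, rescaled to unit sample variance and
    sign-aligned so that its correlation with the module mean expression
    is nonnegative. A single-gene module's ME is that gene's z-score.
    """
    expr = np.asarray(expr, dtype=float)
    gi = {g: j for j, g in enumerate(gene_ids)}
    out = {}
    for mod in modules.modules:
        genes = [g for g in modules.genes_in(mod) if g in gi]
        if not genes:
            continue
        sub = expr[:, [gi[g] for g in genes]]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        zs = (sub - mu) / sd
        if zs.shape[1] == 1:
            me = zs[:, 0]
        else:
            # first right singular vector of the standardized submatrix
            u, s, vt = np.linalg.svd(zs - zs.mean(axis=0), full_matrices=False)
            me = u[:, 0] * s[0]
        sdme = me.std(ddof=1)
        if sdme > 0:
            me = me / sdme
        mean_expr = zs.mean(axis=1)
        if np.std(mean_expr) > 0 and np.corrcoef(me, mean_expr)[0, 1] < 0:
            me = -me
        out[mod] = me
    index = pd.Index(cell_ids, name="cell_id") if cell_ids is not None else pd.RangeIndex(len(expr))
    return pd.DataFrame(out, index=index)


def module_projection_correlation(
    eigengenes: pd.DataFrame,
    intensity: np.ndarray,
    target_ids: list[str],
    method: str = "pearson_t",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Module x target association of MEs with projection intensity.

    pearson_t: Pearson r with its two-sided t-test p; fisher_discrete:
    dichotomize the ME at its median and the intensity at 0, two-sided
    Fisher's exact on the 2x2 table (odds ratio reported as the effect).
    BH q-values across the whole table per method; method="both" reports
    the two side by side.
    """
    if method not in ("pearson_t", "fisher_discrete", "both"):
        raise ValueError(f"unknown method {method!r}")
    intensity = np.asarray(intensity, dtype=float)
    rows = []
    for mod in eigengenes.columns:
        me = eigengenes[mod].to_numpy()
        for j, t in enumerate(target_ids):
            y = intensity[:, j]
            rec = {"module": mod, "target": t}
            if method in ("pearson_t", "both"):
                if np.std(me) == 0 or np.std(y) == 0:
                    rec["r"], rec["p_pearson"], rec["undefined"] = np.nan, np.nan, True
                else:
                    r, p = pearsonr(me, y)
                    rec["r"], rec["p_pearson"], rec["undefined"] = float(r), float(p), False
            if method in ("fisher_discrete", "both"):
                hi = me > np.median(me)
                pos = y > 0
                table = [
                    [int(np.sum(hi & pos)), int(np.sum(hi & ~pos))],
                    [int(np.sum(~hi & pos)), int(np.sum(~hi & ~pos))],
                ]
                try:
                    oddsratio, p = fisher_exact(table, alternative="two-sided")
                    rec["odds_ratio"], rec["p_fisher"] = float(oddsratio), float(p)
                except ValueError:
                    rec["odds_ratio"], rec["p_fisher"] = np.nan, np.nan
            rows.append(rec)
    out = pd.DataFrame(rows)
    for col, qcol in (("p_pearson", "q_pearson"), ("p_fisher", "q_fisher")):
        if col in out.columns:
            p = out[col].to_numpy(float)
            q = np.full_like(p, np.nan)
            ok = np.isfinite(p)
            if ok.any():
                q[ok] = false_discovery_control(p[ok], method="bh")
            out[qcol] = q
    out.attrs["alpha"] = alpha
    return out


def differential_expression(
    expr: np.ndarray,
    gene_ids: list[str],
    group_a: np.ndarray,
    group_b: np.ndarray,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene contrast between two disjoint cell groups.

    log2 fold change of group means on the log-normalized layer's linear
    scale (with a small epsilon guard), two-sided Wilcoxon rank-sum per
    gene, BH correction across genes.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool and group_b.dtype == bool:
        if np.any(group_a & group_b):
            raise ValueError("groups overlap")
    elif len(np.intersect1d(group_a, group_b)) > 0:
        raise ValueError("groups overlap")
    a = expr[group_a]
    b = expr[group_b]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 cells")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    pvals = np.empty(len(gene_ids))
    for j in range(len(gene_ids)):
        if np.all(a[:, j] == a[0, j]) and np.all(b[:, j] == a[0, j]):
            pvals[j] = 1.0
        else:
            pvals[j] = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "q_value": false_discovery_control(pvals, method="bh"),
        }
    ).set_index("gene_id")
    return out
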