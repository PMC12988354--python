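"""Projection prediction from transcriptome PCs plus spatial coordinates.

One gradient-boosted tree binary classifier per projection target, trained
on the top principal components of the gene-standardized log-normalized
expression matrix with the standardized (ap, dv, ml) coordinates appended.
Evaluation follows the standard controls: held-out ROC/AUC, a shuffle
control (test labels permuted), and a transcriptome-only ablation (model
retrained without the spatial columns). The fitted PC model (loadings,
per-gene centering/scaling) is retained so external spatial-transcriptomic
datasets can be projected into the same feature space and scored
(transfer prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

__all__ = [
    "PCModel",
    "FeatureMatrix",
    "PredictionResult",
    "build_features",
    "train_predictors",
    "evaluate_roc",
    "transfer_predict",
    "compare_projection_maps",
    "group_proportion_test",
]

# Shallow trees, modest round count: deterministic, quick, and enough for
# the planted-signal scale these models are exercised at.
XGB_DEFAULTS = dict(
    n_estimators=200,
    max_depth=3,
    learning_rate=0.1,
    subsample=0.9,
    colsample_bytree=0.9,
    tree_method="hist",
    n_jobs=1,
    eval_metric="logloss",
)


@dataclass
class PCModel:
    """Stored PCA + standardization parameters for reproducible transfer."""

    gene_ids: list[str]
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    components: np.ndarray  # (n_pcs, n_genes)
    pc_mean: np.ndarray
    pc_sd: np.ndarray
    coord_mean: np.ndarray | None = None
    coord_sd: np.ndarray | None = None

    def transform_expression(self, expr: np.ndarray, gene_ids: list[str]) -> np.ndarray:
        """Standardize with TRAINING means/sds and project into PC space.

        Genes absent from ``gene_ids`` are imputed at 0 (the training mean
        after standardization).
        """
        gi = {g: j for j, g in enumerate(gene_ids)}
        z = np.zeros((len(expr), len(self.gene_ids)))
        for k, g in enumerate(self.gene_ids):
            if g in gi:
                z[:, k] = (expr[:, gi[g]] - self.gene_mean[k]) / self.gene_sd[k]
        pcs = z @ self.components.T
        return (pcs - self.pc_mean) / self.pc_sd

    @property
    def n_shared_possible(self) -> int:
        return len(self.gene_ids)


@dataclass
class FeatureMatrix:
    cell_ids: list[str]
    features: np.ndarray
    feature_names: list[str]
    pc_model: PCModel
    use_spatial: bool

    @property
    def spatial_columns(self) -> list[int]:
        return [i for i, n in enumerate(self.feature_names) if n in ("ap_mm", "dv_mm", "ml_mm")]


@dataclass
class PredictionResult:
    per_target: dict[str, dict] = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def auc_table(self) -> pd.DataFrame:
        rows = []
        for t, rec in self.per_target.items():
            rows.append(
                {
                    "target": t,
                    "auc": rec.get("auc", np.nan),
                    "auc_shuffle": rec.get("auc_shuffle", np.nan),
                    "auc_transcriptome_only": rec.get("auc_transcriptome_only", np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("target")


def build_features(
    expr: np.ndarray,
    gene_ids: list[str],
    coords: pd.DataFrame | None,
    cell_ids: list[str],
    n_pcs: int = 50,
    use_spatial: bool = True,
) -> FeatureMatrix:
    """Standardized expression PCs, optionally with standardized coordinates.

    Constant genes are dropped before PCA. Standardization parameters
    (per-gene, per-PC and per-coordinate) are computed on this matrix and
    stored in the returned ``pc_model`` for later transfer.
    """
    expr = np.asarray(expr, dtype=float)
    n_pcs = int(n_pcs)
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    sd = expr.std(axis=0)
    # constant genes: sd at floating-point noise level relative to the mean
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(expr.mean(axis=0)))
    kept_genes = [g for g, k in zip(gene_ids, keep) if k]
    x = expr[:, keep]
    mu = x.mean(axis=0)
    sg = x.std(axis=0)
    z = (x - mu) / sg
    n_pcs = min(n_pcs, min(z.shape))
    # deterministic full SVD (data scale here keeps this cheap)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    components = vt[:n_pcs]
    # fix component sign: largest-|loading| entry positive
    for i in range(len(components)):
        jmax = int(np.argmax(np.abs(components[i])))
        if components[i, jmax] < 0:
            components[i] = -components[i]
    pcs = z @ components.T
    pc_mean = pcs.mean(axis=0)
    pc_sd = pcs.std(axis=0)
    pc_sd[pc_sd == 0] = 1.0
    feats = (pcs - pc_mean) / pc_sd
    names = [f"PC{i + 1}" for i in range(n_pcs)]

    coord_mean = coord_sd = None
    if use_spatial:
        if coords is None:
            raise ValueError("use_spatial=True requires coordinates")
        xyz = coords[["ap_mm", "dv_mm", "ml_mm"]].to_numpy(float)
        coord_mean = xyz.mean(axis=0)
        coord_sd = xyz.std(axis=0)
        coord_sd[coord_sd == 0] = 1.0
        feats = np.hstack([feats, (xyz - coord_mean) / coord_sd])
        names = names + ["ap_mm", "dv_mm", "ml_mm"]

    model = PCModel(
        gene_ids=kept_genes,
        gene_mean=mu,
        gene_sd=sg,
        components=components,
        pc_mean=pc_mean,
        pc_sd=pc_sd,
        coord_mean=coord_mean,
        coord_sd=coord_sd,
    )
    return FeatureMatrix(
        cell_ids=list(cell_ids),
        features=feats,
        feature_names=names,
        pc_model=model,
        use_spatial=use_spatial,
    )


def _fit_xgb(X: np.ndarray, y: np.ndarray, seed: int) -> XGBClassifier:
    clf = XGBClassifier(random_state=seed, **XGB_DEFAULTS)
    clf.fit(X, y)
    return clf


def train_predictors(
    features: FeatureMatrix,
    labels: np.ndarray,
    target_ids: list[str],
    train_fraction: float = 0.7,
    seed: int = 0,
    min_class_count: int = 10,
) -> PredictionResult:
    """Train one binary gradient-boosting classifier per target.

    The data are split once per target, stratified on that target's label
    at ``train_fraction``; targets with fewer than ``min_class_count``
    positives or negatives in training are skipped and reported.
    Deterministic given the seed.
    """
    labels = np.asarray(labels)
    result = PredictionResult(split={"train_fraction": train_fraction, "seed": seed})
    any_trained = False
    for j, t in enumerate(target_ids):
        y = labels[:, j].astype(int)
        if len(np.unique(y)) < 2:
            result.skipped[t] = "single-class labels"
            continue
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, random_state=seed, stratify=y
        )
        ytr = y[train_idx]
        n_pos, n_neg = int(ytr.sum()), int(len(ytr) - ytr.sum())
        if n_pos < min_class_count or n_neg < min_class_count:
            result.skipped[t] = f"training class counts {n_pos}/{n_neg} below {min_class_count}"
            continue
        clf = _fit_xgb(features.features[train_idx], ytr, seed)
        result.per_target[t] = {
            "model": clf,
            "train_idx": train_idx,
            "test_idx": test_idx,
        }
        any_trained = True
    if not any_trained:
        raise ValueError("no target satisfied the training class-count precondition")
    return result


def evaluate_roc(
    result: PredictionResult,
    features: FeatureMatrix,
    labels: np.ndarray,
    target_ids: list[str],
    seed: int = 0,
    controls: bool = True,
) -> PredictionResult:
    """Test-set ROC/AUC per target plus shuffle and spatial-ablation controls.

    The shuffle control permutes the test labels and rescores the same
    model; the transcriptome-only control retrains without the spatial
    columns on the same split. Targets whose test set has one class only
    are flagged with undefined AUC.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    t_index = {t: j for j, t in enumerate(target_ids)}
    nonspatial = [i for i in range(len(features.feature_names)) if i not in features.spatial_columns]
    for t, rec in result.per_target.items():
        j = t_index[t]
        test_idx = rec["test_idx"]
        y_test = labels[test_idx, j].astype(int)
        if len(np.unique(y_test)) < 2:
            rec["auc"] = np.nan
            rec["flag"] = "single-class test set"
            continue
        scores = rec["model"].predict_proba(features.features[test_idx])[:, 1]
        fpr, tpr, _ = roc_curve(y_test, scores)
        rec["roc"] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        rec["auc"] = float(roc_auc_score(y_test, scores))
        rec["scores"] = scores
        if controls:
            y_shuf = rng.permutation(y_test)
            if len(np.unique(y_shuf)) < 2:
                rec["auc_shuffle"] = np.nan
            else:
                rec["auc_shuffle"] = float(roc_auc_score(y_shuf, scores))
            if features.use_spatial:
                clf2 = _fit_xgb(
                    features.features[rec["train_idx"]][:, nonspatial],
                    labels[rec["train_idx"], j].astype(int),
                    seed,
                )
                s2 = clf2.predict_proba(features.features[test_idx][:, nonspatial])[:, 1]
                rec["auc_transcriptome_only"] = float(roc_auc_score(y_test, s2))
    return result


def transfer_predict(
    external_expr: np.ndarray,
    external_gene_ids: list[str],
    external_coords: pd.DataFrame | None,
    result: PredictionResult,
    features: FeatureMatrix,
    min_shared: int = 50,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score an external dataset with the stored PC model and classifiers.

    Shared genes are standardized with the TRAINING means/sds; training
    genes missing from the external panel are imputed at the training mean
    (0 after standardization); coordinates are standardized with the
    training parameters. Returns per-cell predicted probability and the
    binary call at ``threshold`` for every trained target.
    """
    pcm = features.pc_model
    shared = set(external_gene_ids) & set(pcm.gene_ids)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes; need >= {min_shared}")
    feats = pcm.transform_expression(np.asarray(external_expr, dtype=float), list(external_gene_ids))
    if features.use_spatial:
        if external_coords is None:
            raise ValueError("model uses spatial features; external coordinates required")
        xyz = external_coords[["ap_mm", "dv_mm", "ml_mm"]].to_numpy(float)
        feats = np.hstack([feats, (xyz - pcm.coord_mean) / pcm.coord_sd])
    out = {}
    for t, rec in result.per_target.items():
        proba = rec["model"].predict_proba(feats)[:, 1]
        out[f"{t}:proba"] = proba
        out[f"{t}:call"] = (proba >= threshold).astype(int)
    return pd.DataFrame(out)


def compare_projection_maps(
    predicted: pd.DataFrame,
    predicted_regions,
    reference: pd.DataFrame,
    reference_regions,
) -> dict:
    """Region x target projection percentage matrices and their correlation.

    Each entry is the percentage of a region's neurons projecting
    (predicted call, resp. observed label) to a target; Pearson r is
    computed over all region x target entries shared by both datasets.
    Regions present in one dataset only are excluded.
    """

    def _table(calls: pd.DataFrame, regions) -> pd.DataFrame:
        regions = np.asarray(regions)
        rows = {}
        for region in sorted(set(regions)):
            mask = regions == region
            rows[region] = 100.0 * calls.loc[mask].mean(axis=0)
        return pd.DataFrame(rows).T

    pred_tab = _table(predicted, predicted_regions)
    ref_tab = _table(reference, reference_regions)
    shared_regions = [r for r in pred_tab.index if r in ref_tab.index]
    shared_targets = [t for t in pred_tab.columns if t in ref_tab.columns]
    if not shared_regions or not shared_targets:
        raise ValueError("no shared regions/targets between datasets")
    a = pred_tab.loc[shared_regions, shared_targets].to_numpy().ravel()
    b = ref_tab.loc[shared_regions, shared_targets].to_numpy().ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return {
        "predicted": pred_tab.loc[shared_regions, shared_targets],
        "reference": ref_tab.loc[shared_regions, shared_targets],
        "r": r,
        "excluded_regions": sorted(
            (set(pred_tab.index) | set(ref_tab.index)) - set(shared_regions)
        ),
    }


def group_proportion_test(
    predicted_calls: pd.DataFrame,
    group_flags: np.ndarray,
    group_labels: np.ndarray,
    replicate_ids: np.ndarray,
) -> pd.DataFrame:
    """Per-target flagged-cell proportions across replicates, two-sided t-test.

    For each replicate and target: the fraction of flagged cells among the
    cells predicted to project to that target. Per target, a two-sided
    two-sample t-test compares the replicate-level proportions between the
    two groups. Replicates with no predicted cells for a target are
    excluded from that target's test.
    """
    group_flags = np.asarray(group_flags, dtype=bool)
    group_labels = np.asarray(group_labels)
    replicate_ids = np.asarray(replicate_ids)
    groups = sorted(set(group_labels))
    if len(groups) != 2:
        raise ValueError("group_proportion_test expects exactly 2 groups")
    targets = [c[:-5] for c in predicted_calls.columns if c.endswith(":call")]
    rows = []
    for t in targets:
        calls = predicted_calls[f"{t}:call"].to_numpy().astype(bool)
        props = {g: [] for g in groups}
        for g in groups:
            for rep in sorted(set(replicate_ids[group_labels == g])):
                mask = (group_labels == g) & (replicate_ids == rep) & calls
                denom = int(mask.sum())
                if denom == 0:
                    continue
                props[g].append(float(group_flags[mask].mean()))
        if min(len(props[g]) for g in groups) < 2:
            rows.append({"target": t, "p_value": np.nan, "note": "insufficient replicates"})
            continue
        a, b = props[groups[0]], props[groups[1]]
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            p = 1.0
        else:
            p = float(ttest_ind(a, b).pvalue)
        rows.append(
            {
                "target": t,
                f"mean_{groups[0]}": float(np.mean(a)),
                f"mean_{groups[1]}": float(np.mean(b)),
                f"sem_{groups[0]}": float(np.std(a, ddof=1) / np.sqrt(len(a))),
                f"sem_{groups[1]}": float(np.std(b, ddof=1) / np.sqrt(len(b))),
                "p_value": p,
                "note": "",
            }
        )
    return pd.DataFrame(rows).set_index("target")
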