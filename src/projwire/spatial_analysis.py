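"""Spatial organization of projection neurons.

Axis-binned target proportions (with per-target z-scores across bins, the
heatmap convention for dorsoventral / anteroposterior gradients), group
centroids, region-enrichment tables, and the motif-level correlation of
projection distance with spatial and transcriptomic distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "AxisProfile",
    "axis_binned_proportions",
    "group_centroids",
    "motif_distance_correlation",
    "region_enrichment",
]

AXIS_COLUMN = {"ap": "ap_mm", "dv": "dv_mm", "ml": "ml_mm"}


@dataclass
class AxisProfile:
    axis: str
    bin_edges: np.ndarray  # half-open [lo, hi), last bin closed
    proportions: pd.DataFrame  # targets x bins, rows sum to 1
    zscores: pd.DataFrame  # per-target z across bins
    dropped_targets: list[str]


def axis_binned_proportions(
    binary: np.ndarray,
    target_ids: list[str],
    coords: np.ndarray,
    axis: str,
    n_bins: int = 10,
) -> AxisProfile:
    """Per-target distribution of projecting cells along a spatial axis.

    Equal-width bins over the observed coordinate range; for each target
    the proportions of its projecting cells per bin (rows sum to 1), then
    z-scored across bins within the target (sample sd). Targets with no
    projecting cells are dropped.
    """
    if axis not in AXIS_COLUMN:
        raise ValueError(f"axis must be one of {sorted(AXIS_COLUMN)}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    binary = np.asarray(binary)
    edges = np.linspace(coords.min(), coords.max(), n_bins + 1)
    # np.digitize with right-open bins; clamp the max coordinate into the last bin
    bin_idx = np.clip(np.digitize(coords, edges[1:-1]), 0, n_bins - 1)

    rows, zrows, dropped = {}, {}, []
    for j, t in enumerate(target_ids):
        mask = binary[:, j] > 0
        n = mask.sum()
        if n == 0:
            dropped.append(t)
            continue
        counts = np.bincount(bin_idx[mask], minlength=n_bins)
        props = counts / n
        sd = props.std(ddof=1)
        rows[t] = props
        zrows[t] = (props - props.mean()) / sd if sd > 0 else np.zeros(n_bins)

    cols = [f"bin{i}" for i in range(n_bins)]
    return AxisProfile(
        axis=axis,
        bin_edges=edges,
        proportions=pd.DataFrame.from_dict(rows, orient="index", columns=cols),
        zscores=pd.DataFrame.from_dict(zrows, orient="index", columns=cols),
        dropped_targets=dropped,
    )


def group_centroids(labels, coords: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean (ap_mm, dv_mm, ml_mm) per group; empty groups excluded."""
    labels = np.asarray(labels)
    if len(labels) != len(coords):
        raise ValueError("labels and coords differ in length")
    df = coords[["ap_mm", "dv_mm", "ml_mm"]].copy()
    df["group"] = labels
    out = df.groupby("group", sort=True).mean()
    out.index.name = "group"
    return out


def motif_distance_correlation(
    signatures: np.ndarray,
    centroids: np.ndarray,
    mean_expression: np.ndarray,
) -> dict:
    """Motif-pair scatter of projection distance vs spatial / transcriptome distance.

    For each unordered pair of motifs: projection distance is the Euclidean
    distance between binary signatures; spatial distance the Euclidean
    distance between motif centroids (mm); transcriptome distance the
    Euclidean distance between motif mean log-normalized expression
    vectors. Pearson r is reported for each x-axis; degenerate (constant)
    distances yield r = NaN with a flag.
    """
    signatures = np.asarray(signatures, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    mean_expression = np.asarray(mean_expression, dtype=float)
    m = len(signatures)
    if m < 3:
        raise ValueError("need at least 3 motifs")
    if len(centroids) != m or len(mean_expression) != m:
        raise ValueError("centroids/mean_expression not aligned to signatures")

    rows = []
    for a in range(m):
        for b in range(a + 1, m):
            rows.append(
                {
                    "motif_a": a,
                    "motif_b": b,
                    "projection_distance": float(np.linalg.norm(signatures[a] - signatures[b])),
                    "spatial_distance": float(np.linalg.norm(centroids[a] - centroids[b])),
                    "transcriptome_distance": float(
                        np.linalg.norm(mean_expression[a] - mean_expression[b])
                    ),
                }
            )
    pairs = pd.DataFrame(rows)

    def _r(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(pearsonr(x, y)[0])

    r_spatial = _r(pairs["spatial_distance"], pairs["projection_distance"])
    r_transcriptome = _r(pairs["transcriptome_distance"], pairs["projection_distance"])
    return {
        "pairs": pairs,
        "r_spatial": r_spatial,
        "r_transcriptome": r_transcriptome,
        "spatial_degenerate": not np.isfinite(r_spatial),
        "transcriptome_degenerate": not np.isfinite(r_transcriptome),
    }


def region_enrichment(labels, regions, highlight_threshold: float = 0.25) -> pd.DataFrame:
    """Group x region row-normalized proportions with highlight flags.

    A cell of the table is flagged when the proportion exceeds
    ``highlight_threshold`` (the asterisk convention on motif-by-region
    composition heatmaps).
    """
    labels = np.asarray(labels)
    regions = np.asarray(regions)
    if len(labels) != len(regions):
        raise ValueError("labels and regions differ in length")
    counts = pd.crosstab(pd.Series(labels, name="group"), pd.Series(regions, name="region"))
    props = counts.div(counts.sum(axis=1), axis=0)
    flagged = props > highlight_threshold
    out = props.copy()
    out.attrs["flagged"] = flagged
    return out
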