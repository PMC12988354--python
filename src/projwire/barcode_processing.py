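"""Background filtering of barcode UMIs and projection-profile construction.

Raw barcode counts mix true projection signal (high UMI) with ambient
background (low UMI). For each target, the positive counts across cells are
sorted descending and a knee is located on the log10(count + 1) curve: the
rank with maximum perpendicular distance to the chord joining the first and
last points. Counts below the knee count are zeroed; what survives is the
per-cell projection intensity, binarized to the projection profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BarcodeCountMatrix

__all__ = [
    "ProjectionProfileSet",
    "NoKnee",
    "elbow_threshold",
    "filter_background",
    "normalize_intensity",
    "multiplicity_summary",
]


class DegenerateInputError(ValueError):
    """Too few points to locate a knee."""


class NoKnee(Exception):
    """Flat profile: every count equal, no knee exists; caller retains all."""


@dataclass
class ProjectionProfileSet:
    """Filtered per-cell projection intensity and binary profile.

    ``intensity`` holds the retained raw UMI counts (zeroed below each
    target's cutoff); ``binary`` is 1 wherever intensity > 0. Cells whose
    whole row was filtered away are flagged non-projecting.
    """

    cell_ids: list[str]
    target_ids: list[str]
    intensity: np.ndarray  # (cells, targets) nonnegative
    binary: np.ndarray  # (cells, targets) 0/1
    thresholds: dict[str, float | None]  # per-target cutoff (None = unfiltered)
    filter_report: pd.DataFrame  # target, cutoff, n_retained, note

    @property
    def projecting_mask(self) -> np.ndarray:
        return self.binary.sum(axis=1) > 0

    def projecting(self) -> "ProjectionProfileSet":
        """Restrict to projecting cells."""
        m = self.projecting_mask
        return ProjectionProfileSet(
            cell_ids=[c for c, keep in zip(self.cell_ids, m) if keep],
            target_ids=self.target_ids,
            intensity=self.intensity[m],
            binary=self.binary[m],
            thresholds=self.thresholds,
            filter_report=self.filter_report,
        )


def elbow_threshold(sorted_counts) -> int:
    """Knee of a descending positive count vector, as a count value.

    Points are (rank i, log10(count_i + 1)); the knee is the point with
    maximum perpendicular distance to the chord joining the first and last
    points, ties broken toward the smaller rank (the stricter filter).
    Cells with count >= the returned cutoff are retained.

    Raises DegenerateInputError for fewer than 3 points and NoKnee when all
    counts are equal.
    """
    counts = np.asarray(sorted_counts)
    if counts.ndim != 1 or len(counts) < 3:
        raise DegenerateInputError("elbow_threshold needs at least 3 counts")
    if np.any(counts <= 0):
        raise ValueError("elbow_threshold expects positive counts")
    if np.any(np.diff(counts) > 0):
        raise ValueError("elbow_threshold expects counts sorted descending")
    if counts[0] == counts[-1]:
        raise NoKnee("all counts equal; no knee")

    x = np.arange(len(counts), dtype=float)
    y = np.log10(counts.astype(float) + 1.0)
    # perpendicular distance of each point to the first->last chord
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    knee = int(np.argmax(dist))  # argmax returns the first (smallest rank) tie
    return int(counts[knee])


def _ambient_cutoff(positive_sorted: np.ndarray) -> int | None:
    """Locate the ambient-background cut for one target's positive counts.

    The chord knee of the log10 count curve marks the top of the ambient
    plateau when a background shoulder exists. A knee is accepted as an
    ambient cut only when it lies in the low-count regime — the bottom
    third of the log10(count + 1) range. A knee higher up means the curve
    is a smooth signal decay with no ambient shoulder (e.g. the
    zero-background limit), in which case no cut is made: the knee of a
    pure signal curve sits mid-range and cutting there would discard true
    projections. Returns the knee count (retain counts strictly above it)
    or None when no ambient shoulder is present.
    """
    knee = elbow_threshold(positive_sorted)
    top = np.log10(float(positive_sorted[0]) + 1.0)
    if np.log10(knee + 1.0) > top / 3.0:
        return None
    return knee


def filter_background(bc: BarcodeCountMatrix) -> ProjectionProfileSet:
    """Apply the per-target elbow filter to a raw barcode count matrix.

    Barcodes sharing a target are summed first (redundant barcodes across
    animals measure the same projection), then each target's positive
    counts across cells are elbow-analysed; counts at or below the
    ambient knee are zeroed (the knee count itself is the top of the
    ambient plateau and is removed). Targets with fewer than 3 positive
    cells, a flat positive-count profile, or no detectable ambient
    shoulder are flagged and retained unfiltered.
    """
    target_ids = list(dict.fromkeys(bc.barcode_to_target[b] for b in bc.barcode_ids))
    agg = np.zeros((len(bc.cell_ids), len(target_ids)), dtype=np.int64)
    t_index = {t: j for j, t in enumerate(target_ids)}
    for i, b in enumerate(bc.barcode_ids):
        agg[:, t_index[bc.barcode_to_target[b]]] += bc.counts[:, i].astype(np.int64)

    intensity = np.zeros_like(agg)
    thresholds: dict[str, float | None] = {}
    rows = []
    for j, t in enumerate(target_ids):
        col = agg[:, j]
        positive = col[col > 0]
        note = ""
        if len(positive) < 3:
            cutoff = None
            note = "unfilterable: fewer than 3 positive cells"
            intensity[:, j] = col
        else:
            try:
                cutoff = _ambient_cutoff(np.sort(positive)[::-1])
                if cutoff is None:
                    note = "no ambient shoulder detected"
                    intensity[:, j] = col
                else:
                    intensity[:, j] = np.where(col > cutoff, col, 0)
            except NoKnee:
                cutoff = None
                note = "no knee: all positive counts equal"
                intensity[:, j] = col
        thresholds[t] = cutoff
        rows.append(
            {
                "target": t,
                "cutoff": np.nan if cutoff is None else cutoff,
                "n_positive": int((col > 0).sum()),
                "n_retained": int((intensity[:, j] > 0).sum()),
                "note": note,
            }
        )

    report = pd.DataFrame(rows).set_index("target")
    return ProjectionProfileSet(
        cell_ids=list(bc.cell_ids),
        target_ids=target_ids,
        intensity=intensity.astype(float),
        binary=(intensity > 0).astype(np.int8),
        thresholds=thresholds,
        filter_report=report,
    )


def normalize_intensity(p: ProjectionProfileSet, mode: str) -> np.ndarray:
    """Normalize the intensity matrix.

    relative: each row divided by its row sum (all-zero rows stay zero);
    log1p: elementwise log(1 + x); zscore_by_target: per-column
    (x - mean)/sd computed over projecting cells only (sample sd, n-1).
    """
    x = np.asarray(p.intensity, dtype=float)
    if mode == "relative":
        sums = x.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, x / np.where(sums == 0, 1.0, sums), 0.0)
        return out
    if mode == "log1p":
        return np.log1p(x)
    if mode == "zscore_by_target":
        out = np.zeros_like(x)
        for j in range(x.shape[1]):
            mask = p.binary[:, j] > 0
            vals = x[mask, j]
            if len(vals) < 2:
                continue
            sd = vals.std(ddof=1)
            if sd == 0:
                continue
            out[mask, j] = (vals - vals.mean()) / sd
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


def multiplicity_summary(p: ProjectionProfileSet) -> dict:
    """Targets-per-cell distribution over projecting cells.

    Returns the histogram of binary row sums, the fraction of projecting
    cells hitting >= 2 targets, and the maximum multiplicity. An empty
    profile yields n_projecting == 0 with an empty histogram.
    """
    rowsums = p.binary.sum(axis=1)
    rowsums = rowsums[rowsums > 0]
    if len(rowsums) == 0:
        return {"n_projecting": 0, "histogram": {}, "fraction_multi": np.nan, "max_multiplicity": 0}
    values, counts = np.unique(rowsums, return_counts=True)
    return {
        "n_projecting": int(len(rowsums)),
        "histogram": {int(v): int(c) for v, c in zip(values, counts)},
        "fraction_multi": float((rowsums >= 2).mean()),
        "max_multiplicity": int(rowsums.max()),
    }
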