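"""Co-projection probability (phi) and its coupling to circuit connectivity.

The tendency of two targets to be innervated by the same neurons is
summarized by the Pearson correlation of their binary projection columns
(the phi coefficient of the 2x2 contingency table). Within-class vs
across-class contrasts use a one-sided Wilcoxon rank-sum; the wiring-logic
coupling correlates phi with an externally supplied target x target
connectivity matrix (e.g. axonal-density estimates between the downstream
nuclei), symmetrized by the arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr

__all__ = [
    "CoprojectionMatrix",
    "ConnectivityMatrix",
    "coprojection_matrix",
    "block_contrast",
    "coupling_correlation",
]


@dataclass
class CoprojectionMatrix:
    """Symmetric target x target phi matrix; NaN marks undefined entries."""

    target_ids: list[str]
    phi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.phi, index=self.target_ids, columns=self.target_ids)
        df.index.name = "target_id"
        return df


@dataclass
class ConnectivityMatrix:
    """Directed target x target connection intensity (row = source)."""

    target_ids: list[str]
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("connectivity intensities must be nonnegative")

    @classmethod
    def from_csv(cls, path: str) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column target ids differ")
        return cls(target_ids=[str(t) for t in df.index], intensity=df.to_numpy(float))

    def symmetrized(self) -> np.ndarray:
        return 0.5 * (self.intensity + self.intensity.T)


def coprojection_matrix(binary: np.ndarray, target_ids: list[str]) -> CoprojectionMatrix:
    """Pairwise phi over projecting cells' binary columns.

    Columns with a constant value (marginal 0 or 1 among projecting cells)
    have undefined correlation; their rows/columns are NaN. The diagonal is
    NaN by convention (self-co-projection is not meaningful).
    """
    binary = np.asarray(binary, dtype=float)
    proj = binary[binary.sum(axis=1) > 0]
    if len(proj) < 2:
        raise ValueError("need at least 2 projecting cells")
    sd = proj.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.corrcoef(proj, rowvar=False)
    phi = np.asarray(phi, dtype=float)
    phi[sd == 0, :] = np.nan
    phi[:, sd == 0] = np.nan
    np.fill_diagonal(phi, np.nan)
    phi = np.clip(phi, -1.0, 1.0)
    return CoprojectionMatrix(target_ids=list(target_ids), phi=phi)


def _pair_sets(matrix: np.ndarray, target_ids: list[str], target_class: dict[str, str | None]):
    sym = 0.5 * (matrix + matrix.T)
    within, across = [], []
    for i in range(len(target_ids)):
        for j in range(i + 1, len(target_ids)):
            v = sym[i, j]
            if not np.isfinite(v):
                continue
            ci, cj = target_class.get(target_ids[i]), target_class.get(target_ids[j])
            if ci is None or cj is None:
                continue
            (within if ci == cj else across).append(v)
    return np.array(within), np.array(across)


def block_contrast(
    matrix: np.ndarray,
    target_ids: list[str],
    target_class: dict[str, str | None],
    alternative: str = "greater",
) -> dict:
    """Within-class vs across-class contrast of a symmetric pair statistic.

    Off-diagonal upper-triangle entries (after symmetrizing as the mean of
    M and M^T) are split by whether the two targets share a projection
    class; significance is a Wilcoxon rank-sum with the requested
    alternative ("greater" tests within > across).
    """
    matrix = np.asarray(matrix, dtype=float)
    classes = {c for c in (target_class.get(t) for t in target_ids) if c is not None}
    if len(classes) < 2:
        raise ValueError("block_contrast needs at least 2 classes")
    within, across = _pair_sets(matrix, target_ids, target_class)
    if len(within) == 0 or len(across) == 0:
        raise ValueError("within/across pair set is empty; contrast undefined")
    if np.ptp(np.concatenate([within, across])) == 0:
        stat, p = float(len(within) * len(across) / 2.0), 1.0  # no separation at all
    else:
        stat, p = mannwhitneyu(within, across, alternative=alternative)
    return {
        "within": within,
        "across": across,
        "within_median": float(np.median(within)),
        "across_median": float(np.median(across)),
        "statistic": float(stat),
        "p_value": float(p),
        "alternative": alternative,
    }


def coupling_correlation(cp: CoprojectionMatrix, conn: ConnectivityMatrix) -> dict:
    """Pearson correlation of phi vs symmetrized connectivity over target pairs.

    Restricted to unordered pairs of targets present in both matrices with
    a defined phi. Returns the pair-level table alongside r and p.
    """
    shared = [t for t in cp.target_ids if t in conn.target_ids]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared targets")
    ci = {t: i for i, t in enumerate(cp.target_ids)}
    ki = {t: i for i, t in enumerate(conn.target_ids)}
    sym = conn.symmetrized()
    rows = []
    for a in range(len(shared)):
        for b in range(a + 1, len(shared)):
            s, t = shared[a], shared[b]
            v = cp.phi[ci[s], ci[t]]
            if not np.isfinite(v):
                continue
            rows.append({"target_a": s, "target_b": t, "phi": float(v),
                         "connectivity": float(sym[ki[s], ki[t]])})
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 valid target pairs")
    r, p = pearsonr(pairs["phi"], pairs["connectivity"])
    return {"r": float(r), "p_value": float(p), "pairs": pairs}
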