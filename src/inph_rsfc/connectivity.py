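"""ROI-to-ROI functional connectivity: Pearson r, Fisher z, vectorization.

Each subject's denoised (time x ROI) table becomes a symmetric correlation
matrix and then a feature vector of Fisher-z values laid out in the
canonical edge order from :func:`inph_rsfc.atlas.enumerate_edges`.  The
vector carries a hash of the RoiTable so that vectors built under different
ROI orders can never be silently mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiTable, edge_classes, enumerate_edges
from .errors import DegenerateSeriesError, InvalidInputError

logger = logging.getLogger(__name__)

#: |r| is clamped to 1 - CLAMP_EPS before atanh, keeping z finite (~8.05)
CLAMP_EPS = 1e-7


@dataclass
class FeatureVector:
    """Fisher-z connectivity values in canonical edge order."""

    values: np.ndarray
    roi_table_hash: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("feature vector contains non-finite values")


def fc_matrix(roi_series) -> np.ndarray:
    """Sample Pearson correlation between every pair of ROI series."""
    if isinstance(roi_series, pd.DataFrame):
        names = list(roi_series.columns)
        y = roi_series.to_numpy(dtype=float)
    else:
        y = np.asarray(roi_series, dtype=float)
        names = [f"roi_{k}" for k in range(y.shape[1])]
    if y.shape[0] < 3:
        raise InvalidInputError("need at least 3 time points")
    sd = y.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateSeriesError([names[k] for k in dead])
    r = np.corrcoef(y.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return r


def fisher_z(r):
    """atanh(r) with |r| clamped into [-(1-1e-7), 1-1e-7]; clamping is logged."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise InvalidInputError(f"|r| > 1 beyond rounding slack: {arr[np.abs(arr) > 1 + 1e-9]}")
    clipped = np.clip(arr, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS)
    n_clamped = int(np.sum(clipped != np.clip(arr, -1.0, 1.0)))
    if n_clamped:
        logger.info("fisher_z clamped %d coefficient(s) near |r|=1", n_clamped)
    out = np.arctanh(clipped)
    return out if out.ndim else float(out)


def vectorize(fc: np.ndarray, rois: RoiTable) -> FeatureVector:
    """Fisher-z upper triangle of an FC matrix in canonical edge order."""
    fc = np.asarray(fc, dtype=float)
    n = len(rois)
    if fc.shape != (n, n):
        raise InvalidInputError(f"FC matrix shape {fc.shape} != ({n}, {n})")
    if not np.allclose(fc, fc.T, atol=1e-12):
        raise InvalidInputError("FC matrix is not symmetric")
    iu = np.triu_indices(n, k=1)
    return FeatureVector(values=fisher_z(fc[iu]), roi_table_hash=rois.table_hash())


def devectorize(vec: FeatureVector, rois: RoiTable) -> np.ndarray:
    """Rebuild the symmetric z-matrix (zero diagonal) from a feature vector."""
    n = len(rois)
    if vec.roi_table_hash != rois.table_hash():
        raise InvalidInputError("feature vector built under a different RoiTable")
    if vec.values.size != n * (n - 1) // 2:
        raise InvalidInputError("feature vector length mismatch")
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec.values
    return out + out.T


def feature_table(vec: FeatureVector, rois: RoiTable) -> pd.DataFrame:
    """Self-describing edge table: indices, names, hemisphere class, z."""
    edges = enumerate_edges(len(rois))
    cls = edge_classes(rois)
    names = rois.names
    return pd.DataFrame(
        {
            "edge_i": [i for i, _ in edges],
            "edge_j": [j for _, j in edges],
            "name_i": [names[i] for i, _ in edges],
            "name_j": [names[j] for _, j in edges],
            "class": cls,
            "z": vec.values,
        }
    )


def cohort_features(series_list, rois: RoiTable) -> np.ndarray:
    """Stack per-subject feature vectors into an (n_subjects x n_edges) matrix."""
    mats = [vectorize(fc_matrix(ts), rois).values for ts in series_list]
    return np.vstack(mats)
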