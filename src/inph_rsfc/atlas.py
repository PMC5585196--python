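"""ROI metadata, canonical edge enumeration, and label-volume operations.

The feature space of the whole pipeline is defined here: a ``RoiTable``
fixes the ROI order, :func:`enumerate_edges` fixes the edge (ROI-pair)
order, and :func:`edge_class` partitions edges into inter-hemispheric
(the two ROIs lie in different hemispheres) and intra-hemispheric pairs.

The packaged default table carries the 90 cerebral AAL region names in the
standard order (left/right homologous pairs, odd ids left).  The MNI
barycenter coordinates shipped with it are approximate, mirror-symmetric
synthetic stand-ins for the true region centroids; they are used only for
the hemisphere-consistency check (sign of x), never in any computation.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DegenerateRoiError,
    IncompatibleGeometryError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

DEFAULT_ROI_TABLE = "aal90_approx_centroids.tsv"


@dataclass(frozen=True)
class Roi:
    roi_id: int
    name: str
    hemisphere: str  # "L" or "R"
    barycenter: tuple[float, float, float]


@dataclass
class RoiTable:
    """Ordered ROI metadata; the order is the canonical feature order."""

    entries: list[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate roi_id in RoiTable")
        for r in self.entries:
            if r.hemisphere not in ("L", "R"):
                raise InvalidInputError(
                    f"ROI {r.name}: hemisphere must be L or R, got {r.hemisphere!r}"
                )
        self._check_barycenter_consistency()

    def _check_barycenter_consistency(self) -> None:
        # Name-based hemisphere assignment is authoritative; the barycenter
        # x-sign is a consistency check only (regions can straddle midline).
        for r in self.entries:
            x = r.barycenter[0]
            if (r.hemisphere == "L" and x > 0) or (r.hemisphere == "R" and x < 0):
                warnings.warn(
                    f"ROI {r.name}: hemisphere {r.hemisphere} but barycenter "
                    f"x={x:+.1f}; using the hemisphere column",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.entries]

    @property
    def ids(self) -> list[int]:
        return [r.roi_id for r in self.entries]

    @property
    def hemispheres(self) -> list[str]:
        return [r.hemisphere for r in self.entries]

    def index_of_id(self, roi_id: int) -> int:
        try:
            return self.ids.index(roi_id)
        except ValueError:
            raise InvalidInputError(f"roi_id {roi_id} not in table") from None

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j), i<j, of left/right homologues.

        Homologues are matched by base name after stripping a trailing
        ``_L``/``_R`` suffix.
        """
        by_base: dict[str, dict[str, int]] = {}
        for idx, r in enumerate(self.entries):
            base = r.name
            if base.endswith(("_L", "_R")):
                base = base[:-2]
            by_base.setdefault(base, {})[r.hemisphere] = idx
        pairs = []
        for base, sides in by_base.items():
            if "L" in sides and "R" in sides:
                i, j = sorted((sides["L"], sides["R"]))
                pairs.append((i, j))
        return sorted(pairs)

    def table_hash(self) -> str:
        """Stable hash of (id, name, hemisphere) order, for provenance."""
        h = hashlib.sha256()
        for r in self.entries:
            h.update(f"{r.roi_id}\t{r.name}\t{r.hemisphere}\n".encode())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.ids,
                "name": self.names,
                "hemisphere": self.hemispheres,
                "x": [r.barycenter[0] for r in self.entries],
                "y": [r.barycenter[1] for r in self.entries],
                "z": [r.barycenter[2] for r in self.entries],
            }
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiTable":
        required = {"roi_id", "name", "hemisphere", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"RoiTable missing columns: {sorted(missing)}")
        entries = [
            Roi(
                int(row.roi_id),
                str(row.name),
                str(row.hemisphere),
                (float(row.x), float(row.y), float(row.z)),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(entries)

    @classmethod
    def load_tsv(cls, path: str | Path) -> "RoiTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def default(cls) -> "RoiTable":
        """The packaged 90-region AAL table (45 L / 45 R homologous pairs)."""
        with resources.files("inph_rsfc.data").joinpath(DEFAULT_ROI_TABLE).open() as f:
            return cls.from_frame(pd.read_csv(f, sep="\t"))


def enumerate_edges(n_rois: int) -> list[tuple[int, int]]:
    """Canonical row-major upper-triangle edge order: (0,1), (0,2), ...

    This order defines feature-vector indexing for every downstream stage.
    """
    if int(n_rois) != n_rois or n_rois < 2:
        raise InvalidInputError(f"n_rois must be an integer >= 2, got {n_rois}")
    n = int(n_rois)
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def n_edges(n_rois: int) -> int:
    return n_rois * (n_rois - 1) // 2


def edge_class(edge: tuple[int, int], rois: RoiTable) -> str:
    """Classify an ROI pair as ``"inter"`` or ``"intra"``-hemispheric."""
    i, j = edge
    n = len(rois)
    if not (0 <= i < n and 0 <= j < n):
        raise InvalidInputError(f"edge {edge} out of range for {n} ROIs")
    if i == j:
        raise InvalidInputError("edge must join two distinct ROIs")
    hemi = rois.hemispheres
    return "inter" if hemi[i] != hemi[j] else "intra"


def edge_classes(rois: RoiTable) -> np.ndarray:
    """Vector of edge classes over :func:`enumerate_edges` order."""
    hemi = np.asarray(rois.hemispheres)
    return np.asarray(
        ["inter" if hemi[i] != hemi[j] else "intra" for i, j in enumerate_edges(len(rois))]
    )


@dataclass
class LabelVolume:
    """Integer label grid (0 = background, k>0 = roi_id) with NIfTI affine."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise InvalidInputError("label grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")

    def voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.grid[self.grid > 0], return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.grid.astype(np.int16), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(int), img.affine)


@dataclass
class BinaryMask:
    """A {0,1} grid sharing geometry with the LabelVolume it modifies."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise InvalidInputError("mask grid must be 3-D")
        if not np.isin(self.grid, (0, 1)).all():
            raise InvalidInputError("mask values must be 0 or 1")

    @classmethod
    def from_nifti(cls, path: str | Path) -> "BinaryMask":
        img = nib.load(str(path))
        return cls((np.asarray(img.dataobj) > 0).astype(int), img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.grid.astype(np.int16), self.affine), str(path))


def _check_geometry(a_grid, a_aff, b_grid, b_aff) -> None:
    if a_grid.shape != b_grid.shape:
        raise IncompatibleGeometryError(
            f"grid shapes differ: {a_grid.shape} vs {b_grid.shape}"
        )
    if not np.allclose(a_aff, b_aff, atol=1e-6):
        raise IncompatibleGeometryError("affines differ")


def modify_rois(labels: LabelVolume, ventricle: BinaryMask) -> LabelVolume:
    """Zero out label voxels under the ventricle template mask.

    Removing the atlas/ventricle intersection keeps enlarged-ventricle CSF
    out of the ROI signal averages; the same modified set is applied to every
    subject.  A warning is recorded for any ROI losing more than half of its
    voxels; an ROI emptied entirely is an error.
    """
    _check_geometry(labels.grid, labels.affine, ventricle.grid, ventricle.affine)
    before = labels.voxel_counts()
    out = labels.grid.copy()
    out[ventricle.grid == 1] = 0
    result = LabelVolume(out, labels.affine.copy())
    after = result.voxel_counts()
    emptied = [rid for rid in before if after.get(rid, 0) == 0]
    if emptied:
        raise DegenerateRoiError(emptied, f"ventricle mask empties ROI(s) {emptied}")
    for rid, n_before in before.items():
        n_after = after[rid]
        if n_after < 0.5 * n_before:
            warnings.warn(
                f"ROI {rid} lost {n_before - n_after}/{n_before} voxels "
                "(>50%) to the ventricle mask",
                stacklevel=2,
            )
    return result


def roi_average(
    volume_series: np.ndarray, labels: LabelVolume, rois: RoiTable
) -> pd.DataFrame:
    """Average a 4-D (x, y, z, t) series over each ROI's voxels.

    Returns a (time x ROI) table in RoiTable column order.
    """
    vol = np.asarray(volume_series, dtype=float)
    if vol.ndim != 4:
        raise InvalidInputError("volume_series must be 4-D (x, y, z, t)")
    if vol.shape[:3] != labels.grid.shape:
        raise IncompatibleGeometryError(
            f"series spatial shape {vol.shape[:3]} != label shape {labels.grid.shape}"
        )
    n_t = vol.shape[3]
    flat = vol.reshape(-1, n_t)
    lab_flat = labels.grid.reshape(-1)
    empty = [rid for rid in rois.ids if not np.any(lab_flat == rid)]
    if empty:
        raise DegenerateRoiError(empty)
    cols = {}
    for roi in rois.entries:
        sel = lab_flat == roi.roi_id
        cols[roi.name] = flat[sel].mean(axis=0)
    return pd.DataFrame(cols, columns=rois.names)
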