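"""Seeded synthetic resting-state cohorts with severity-graded connectivity.

No public data exist for this analysis, so every downstream stage is
exercised on synthetic cohorts whose *statistical* structure mirrors the
study design: 90 AAL ROIs in left/right homologous pairs, ~6-minute runs
(116 volumes at TR = 3 s), a baseline within-hemisphere community
correlation, homotopic (left-right homologue) correlations that are
attenuated multiplicatively with symptom severity in the patient group, and
additive shared confound signals (6 motion channels + white-matter + CSF)
that inflate raw pairwise correlations and are removable by nuisance
regression.

The generator is deliberately simple: a target correlation matrix per
subject, AR(1) temporal smoothing, Gaussian innovations, linear confound
contamination.  It makes no claim to hemodynamic realism; see
docs/methods.md for what passing tests on these cohorts do and do not show.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import BinaryMask, LabelVolume, RoiTable
from .errors import InvalidConfigError, InvalidInputError

CONFOUND_COLUMNS = [f"motion_{k}" for k in range(1, 7)] + ["wm", "csf"]

#: number of within-hemisphere "communities" (contiguous blocks of ROIs)
N_COMMUNITIES = 5


@dataclass(frozen=True)
class SubjectSpec:
    """One participant: diagnosis plus the three severity scores (0-4)."""

    subject_id: str
    group: str  # "HC" or "iNPH"
    gs_gait: int = 0
    gs_cognition: int = 0
    gs_urinary: int = 0
    mmse: int | None = None
    fab: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("HC", "iNPH"):
            raise InvalidInputError(f"group must be HC or iNPH, got {self.group!r}")
        scores = (self.gs_gait, self.gs_cognition, self.gs_urinary)
        if any(not (0 <= s <= 4) for s in scores):
            raise InvalidInputError(f"severity scores must be 0-4, got {scores}")
        if self.group == "HC" and any(s != 0 for s in scores):
            # healthy controls are assumed normal on every domain
            raise InvalidInputError("HC subjects must have all severity scores 0")

    @property
    def gs_max(self) -> int:
        return max(self.gs_gait, self.gs_cognition, self.gs_urinary)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_rois: int = 90
    n_volumes: int = 116  # 120 acquired minus 4 discarded
    tr_seconds: float = 3.0
    rho_intra: float = 0.3  # within-hemisphere community correlation
    rho_homo: float = 0.6  # homotopic correlation in healthy subjects
    kappa: float = 0.85  # severity attenuation coefficient in [0, 1]
    confound_loading: float = 0.5  # shared-confound mixing weight
    ar1_coef: float = 0.3  # temporal autocorrelation of BOLD-like signal
    noise_sd: float = 0.4  # white measurement noise, signal units
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.rho_intra < 1.0 and 0.0 <= self.rho_homo < 1.0):
            raise InvalidConfigError("rho_intra and rho_homo must be in [0, 1)")
        if not (0.0 <= self.kappa <= 1.0):
            raise InvalidConfigError("kappa must be in [0, 1]")
        if self.n_volumes < 20:
            raise InvalidConfigError("n_volumes must be >= 20")
        if self.n_rois < 2:
            raise InvalidConfigError("n_rois must be >= 2")
        if not (0.0 <= abs(self.ar1_coef) < 1.0):
            raise InvalidConfigError("|ar1_coef| must be < 1")
        if self.noise_sd < 0 or self.confound_loading < 0:
            raise InvalidConfigError("noise_sd and confound_loading must be >= 0")


@dataclass
class CohortDataset:
    """A simulated cohort: shared RoiTable plus per-subject tables."""

    rois: RoiTable
    subjects: list[tuple[SubjectSpec, pd.DataFrame, pd.DataFrame]]
    provenance: dict = field(default_factory=dict)

    @property
    def specs(self) -> list[SubjectSpec]:
        return [s for s, _, _ in self.subjects]

    def series(self) -> list[pd.DataFrame]:
        return [ts for _, ts, _ in self.subjects]

    def with_series(self, new_series: Sequence[pd.DataFrame]) -> "CohortDataset":
        if len(new_series) != len(self.subjects):
            raise InvalidInputError("series count mismatch")
        return CohortDataset(
            self.rois,
            [(s, ts, cf) for (s, _, cf), ts in zip(self.subjects, new_series)],
            dict(self.provenance),
        )


def _subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    # counter-based split keyed by subject_id: changing cohort composition
    # never reshuffles another subject's draws
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % 2**31, key]))


def _community_index(rois: RoiTable) -> np.ndarray:
    """Contiguous community blocks within each hemisphere."""
    hemi = np.asarray(rois.hemispheres)
    comm = np.zeros(len(rois), dtype=int)
    for side in ("L", "R"):
        idx = np.flatnonzero(hemi == side)
        size = max(1, int(np.ceil(len(idx) / N_COMMUNITIES)))
        for rank, i in enumerate(idx):
            comm[i] = rank // size
    return comm


def nearest_positive_definite(mat: np.ndarray, eig_floor: float = 1e-6):
    """Eigenvalue-clipped PD repair, re-normalized to unit diagonal.

    Returns (repaired, was_repaired, min_eigenvalue_before).
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    min_eig = float(vals.min())
    if min_eig >= eig_floor:
        return sym, False, min_eig
    clipped = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    out = clipped / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, True, min_eig


def build_target_correlation(
    spec: SubjectSpec, config: SimConfig, rois: RoiTable
) -> tuple[np.ndarray, dict]:
    """Target ROI-correlation matrix for one subject.

    Homotopic entries are ``rho_homo * (1 - kappa * GSmax / 4)`` where GSmax
    is the subject's worst severity score; same-hemisphere same-community
    entries are ``rho_intra``; everything else is 0 before the
    positive-definiteness repair.  Returns the repaired matrix and a
    provenance dict recording whether repair changed anything.
    """
    config.validate()
    if len(rois) != config.n_rois:
        raise InvalidConfigError(
            f"RoiTable has {len(rois)} ROIs but config.n_rois={config.n_rois}"
        )
    n = config.n_rois
    target = np.zeros((n, n))
    comm = _community_index(rois)
    hemi = np.asarray(rois.hemispheres)
    same_hemi = hemi[:, None] == hemi[None, :]
    same_comm = comm[:, None] == comm[None, :]
    target[same_hemi & same_comm] = config.rho_intra
    rho_h = config.rho_homo * (1.0 - config.kappa * spec.gs_max / 4.0)
    for i, j in rois.homotopic_pairs():
        target[i, j] = target[j, i] = rho_h
    np.fill_diagonal(target, 1.0)
    repaired, was_repaired, min_eig = nearest_positive_definite(target)
    prov = {
        "pd_repaired": bool(was_repaired),
        "min_eigenvalue_before_repair": min_eig,
        "rho_homotopic": rho_h,
    }
    return repaired, prov


def _ar1_series(rng: np.random.Generator, n_t: int, n_ch: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) columns."""
    w = rng.standard_normal((n_t, n_ch))
    out = np.empty_like(w)
    out[0] = w[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n_t):
        out[t] = phi * out[t - 1] + scale * w[t]
    return out


def simulate_subject(
    spec: SubjectSpec,
    config: SimConfig,
    rois: RoiTable,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one subject's (roi_series, confound_table).

    The latent signal has the subject's target cross-ROI correlation and
    AR(1) temporal structure.  A shared latent drives both the WM/CSF
    confound channels and an additive contamination of every ROI, so raw
    correlations are inflated toward positive values until the confounds
    are regressed out.  Deterministic given (config.seed, subject_id).
    """
    config.validate()
    if rng is None:
        rng = _subject_rng(config.seed, spec.subject_id)
    target, _ = build_target_correlation(spec, config, rois)
    chol = np.linalg.cholesky(target)
    n_t = config.n_volumes
    latent = _ar1_series(rng, n_t, config.n_rois, config.ar1_coef)
    signal = latent @ chol.T

    motion = 0.5 * _ar1_series(rng, n_t, 6, 0.5)
    shared = _ar1_series(rng, n_t, 1, 0.5)[:, 0]
    wm = 0.95 * shared + np.sqrt(1 - 0.95**2) * rng.standard_normal(n_t)
    csf = 0.95 * shared + np.sqrt(1 - 0.95**2) * rng.standard_normal(n_t)

    # per-ROI susceptibility to the shared confound spans none-to-double the
    # average loading, so raw pseudo-correlation is heterogeneous across
    # pairs (it widens the correlation distribution, not just its mean)
    lam = config.confound_loading * rng.uniform(0.0, 2.0, size=config.n_rois)
    contaminated = (
        signal
        + np.outer(shared, lam)
        + config.noise_sd * rng.standard_normal((n_t, config.n_rois))
    )

    roi_series = pd.DataFrame(contaminated, columns=rois.names)
    confounds = pd.DataFrame(
        np.column_stack([motion, wm, csf]), columns=CONFOUND_COLUMNS
    )
    return roi_series, confounds


def default_cohort_specs() -> list[SubjectSpec]:
    """11 iNPH patients with the packaged clinical severity profiles + 11 HC."""
    with resources.files("inph_rsfc.data").joinpath("inph_cohort.tsv").open() as f:
        df = pd.read_csv(f, sep="\t")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            SubjectSpec(
                subject_id=str(row.subject_id),
                group=str(row.group),
                gs_gait=int(row.gs_gait),
                gs_cognition=int(row.gs_cognition),
                gs_urinary=int(row.gs_urinary),
                mmse=None if pd.isna(row.mmse) else int(row.mmse),
                fab=None if pd.isna(row.fab) else int(row.fab),
            )
        )
    return specs


def clinical_table() -> pd.DataFrame:
    """The packaged per-patient clinical table (scores for iNPH subjects)."""
    with resources.files("inph_rsfc.data").joinpath("inph_cohort.tsv").open() as f:
        return pd.read_csv(f, sep="\t")


def simulate_cohort(
    specs: Sequence[SubjectSpec] | None = None,
    config: SimConfig | None = None,
    rois: RoiTable | None = None,
) -> CohortDataset:
    """Simulate a cohort; defaults to the 11 iNPH + 11 HC design."""
    config = config or SimConfig()
    config.validate()
    specs = list(specs) if specs is not None else default_cohort_specs()
    if len(specs) < 2:
        raise InvalidInputError("need at least 2 subjects")
    ids = [s.subject_id for s in specs]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate subject_id in cohort specs")
    rois = rois if rois is not None else RoiTable.default()
    subjects = []
    for spec in specs:
        ts, cf = simulate_subject(spec, config, rois)
        subjects.append((spec, ts, cf))
    provenance = {
        "config": asdict(config),
        "roi_table_hash": rois.table_hash(),
        "n_subjects": len(specs),
    }
    return CohortDataset(rois=rois, subjects=subjects, provenance=provenance)


def write_cohort(cohort: CohortDataset, outdir: str | Path) -> Path:
    """Write a cohort directory: cohort.yaml, subjects.tsv, per-subject TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cohort.yaml", "w") as f:
        yaml.safe_dump(cohort.provenance, f, sort_keys=True)
    cohort.rois.save_tsv(out / "rois.tsv")
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort.specs],
            "group": [s.group for s in cohort.specs],
            "gs_gait": [s.gs_gait for s in cohort.specs],
            "gs_cognition": [s.gs_cognition for s in cohort.specs],
            "gs_urinary": [s.gs_urinary for s in cohort.specs],
            "mmse": [s.mmse for s in cohort.specs],
            "fab": [s.fab for s in cohort.specs],
        }
    )
    meta.to_csv(out / "subjects.tsv", sep="\t", index=False)
    for spec, ts, cf in cohort.subjects:
        ts.to_csv(out / f"sub-{spec.subject_id}_roi.tsv", sep="\t", index=False)
        cf.to_csv(out / f"sub-{spec.subject_id}_confounds.tsv", sep="\t", index=False)
    return out


def read_cohort(path: str | Path) -> CohortDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    with open(path / "cohort.yaml") as f:
        provenance = yaml.safe_load(f)
    rois = RoiTable.load_tsv(path / "rois.tsv")
    meta = pd.read_csv(path / "subjects.tsv", sep="\t")
    subjects = []
    for row in meta.itertuples(index=False):
        spec = SubjectSpec(
            subject_id=str(row.subject_id),
            group=str(row.group),
            gs_gait=int(row.gs_gait),
            gs_cognition=int(row.gs_cognition),
            gs_urinary=int(row.gs_urinary),
            mmse=None if pd.isna(row.mmse) else int(row.mmse),
            fab=None if pd.isna(row.fab) else int(row.fab),
        )
        ts = pd.read_csv(path / f"sub-{spec.subject_id}_roi.tsv", sep="\t")
        cf = pd.read_csv(path / f"sub-{spec.subject_id}_confounds.tsv", sep="\t")
        subjects.append((spec, ts, cf))
    return CohortDataset(rois=rois, subjects=subjects, provenance=provenance)


def voxel_fixture(
    rois: RoiTable,
    config: SimConfig | None = None,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    voxels_per_roi: int = 2,
    n_mask_rois: int = 3,
) -> tuple[LabelVolume, BinaryMask, np.ndarray, pd.DataFrame, dict]:
    """Build a toy voxel-level fixture exercising the atlas path end-to-end.

    Each ROI gets ``voxels_per_roi`` voxels whose series average exactly to a
    designated per-ROI series (voxel k gets the ROI series plus an offset
    summing to zero across the ROI's voxels).  A "ventricle" mask covers one
    voxel of each of the first ``n_mask_rois`` ROIs.

    Returns (labels, mask, voxel_series_4d, designated_roi_series,
    construction_table) where construction_table records per-ROI voxel counts
    and mask overlaps.
    """
    config = config or SimConfig()
    if any(s > 24 for s in grid_shape):
        raise InvalidConfigError("fixture grids are capped at 24^3 voxels")
    n_vox = int(np.prod(grid_shape))
    needed = len(rois) * voxels_per_roi
    if needed > n_vox:
        raise InvalidConfigError(
            f"grid {grid_shape} too small for {len(rois)} ROIs x {voxels_per_roi} voxels"
        )
    rng = _subject_rng(config.seed, "voxel_fixture")
    n_t = config.n_volumes
    designated = pd.DataFrame(
        rng.standard_normal((n_t, len(rois))), columns=rois.names
    )
    grid = np.zeros(grid_shape, dtype=int)
    series = np.zeros(grid_shape + (n_t,))
    flat_order = np.arange(n_vox)
    construction = {}
    for k, roi in enumerate(rois.entries):
        vox = flat_order[k * voxels_per_roi : (k + 1) * voxels_per_roi]
        offsets = rng.standard_normal(voxels_per_roi)
        offsets -= offsets.mean()
        for v, off in zip(vox, offsets):
            ijk = np.unravel_index(v, grid_shape)
            grid[ijk] = roi.roi_id
            series[ijk] = designated[roi.name].to_numpy() + off
        construction[roi.roi_id] = {"n_voxels": voxels_per_roi, "mask_overlap": 0}
    mask = np.zeros(grid_shape, dtype=int)
    for k in range(min(n_mask_rois, len(rois))):
        v = flat_order[k * voxels_per_roi]  # first voxel of ROI k
        mask[np.unravel_index(v, grid_shape)] = 1
        construction[rois.entries[k].roi_id]["mask_overlap"] = 1
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return (
        LabelVolume(grid, affine),
        BinaryMask(mask, affine),
        series,
        designated,
        construction,
    )
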