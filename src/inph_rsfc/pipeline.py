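"""Stage orchestration: simulate -> denoise -> fc -> classify -> weights.

Every stage writes plain-text outputs (TSV/JSON/YAML) into a run directory,
stamped with a hash of the run configuration so outputs from different
configurations can never be silently mixed.  Re-running with an identical
configuration reproduces identical bytes; completed stages are skipped, so
partial runs resume from the last finished stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas, classify, connectivity, denoise, simulate, weights as weights_mod
from .errors import InvalidInputError, ProvenanceError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
STAGES = ("simulate", "denoise", "fc", "classify", "weights")


@dataclass
class RunConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    band: denoise.FilterBand = field(default_factory=denoise.FilterBand)
    classifier: classify.ClassifierConfig = field(
        default_factory=classify.ClassifierConfig
    )
    filter_method: str = "brickwall"
    tasks: tuple = classify.TASKS
    top_k: int = 20
    roi_table_path: str | None = None  # None -> packaged AAL-90 table

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = simulate.SimConfig(**d["sim"])
        if "band" in d:
            d["band"] = denoise.FilterBand(**d["band"])
        if "classifier" in d:
            d["classifier"] = classify.ClassifierConfig(**d["classifier"])
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def rois(self) -> atlas.RoiTable:
        if self.roi_table_path:
            return atlas.RoiTable.load_tsv(self.roi_table_path)
        return atlas.RoiTable.default()


def build_labeled_features(
    cohort: simulate.CohortDataset,
    band: denoise.FilterBand | None = None,
    filter_method: str = "brickwall",
    tr_seconds: float | None = None,
) -> classify.LabeledFeatures:
    """Denoise every subject and stack Fisher-z feature vectors."""
    tr = tr_seconds
    if tr is None:
        tr = float(cohort.provenance.get("config", {}).get("tr_seconds", 3.0))
    clean = [
        denoise.denoise_subject(ts, cf, tr, band, method=filter_method)[0]
        for _, ts, cf in cohort.subjects
    ]
    feats = connectivity.cohort_features(clean, cohort.rois)
    specs = cohort.specs
    severity = pd.DataFrame(
        {
            "gs_gait": [s.gs_gait for s in specs],
            "gs_cognition": [s.gs_cognition for s in specs],
            "gs_urinary": [s.gs_urinary for s in specs],
        }
    )
    return classify.LabeledFeatures(
        features=feats,
        subject_ids=[s.subject_id for s in specs],
        groups=np.asarray([s.group for s in specs]),
        severity=severity,
        roi_table_hash=cohort.rois.table_hash(),
    )


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=str)


def _stamp(path: Path, cfg_hash: str) -> None:
    _write_json(path, {"config_hash": cfg_hash, "schema_version": SCHEMA_VERSION})


def _check_stamp(path: Path, cfg_hash: str) -> bool:
    """True if the stage is complete under this config; error on mismatch."""
    if not path.exists():
        return False
    with open(path) as f:
        stamp = json.load(f)
    if stamp.get("config_hash") != cfg_hash:
        raise ProvenanceError(
            f"{path.parent} was produced under config {stamp.get('config_hash')}, "
            f"current config is {cfg_hash}"
        )
    return True


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all stages into ``outdir`` and write a consolidated report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    with open(out / "run_config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)
    rois = config.rois()

    # --- simulate ---------------------------------------------------------
    cohort_dir = out / "cohort"
    if not _check_stamp(cohort_dir / ".done.json", cfg_hash):
        cohort = simulate.simulate_cohort(config=config.sim, rois=rois)
        simulate.write_cohort(cohort, cohort_dir)
        _stamp(cohort_dir / ".done.json", cfg_hash)
    cohort = simulate.read_cohort(cohort_dir)

    # --- denoise ----------------------------------------------------------
    den_dir = out / "denoised"
    if not _check_stamp(den_dir / ".done.json", cfg_hash):
        den_dir.mkdir(exist_ok=True)
        for spec, ts, cf in cohort.subjects:
            clean, prov = denoise.denoise_subject(
                ts, cf, config.sim.tr_seconds, config.band, config.filter_method
            )
            clean.to_csv(den_dir / f"sub-{spec.subject_id}_roi.tsv", sep="\t", index=False)
            _write_json(den_dir / f"sub-{spec.subject_id}_provenance.json", prov)
        _stamp(den_dir / ".done.json", cfg_hash)
    clean_series = [
        pd.read_csv(den_dir / f"sub-{s.subject_id}_roi.tsv", sep="\t")
        for s in cohort.specs
    ]
    qc = denoise.qc_correlation_shift(cohort.series(), clean_series)

    # --- fc ---------------------------------------------------------------
    fc_dir = out / "fc"
    if not _check_stamp(fc_dir / ".done.json", cfg_hash):
        fc_dir.mkdir(exist_ok=True)
        for spec, ts in zip(cohort.specs, clean_series):
            vec = connectivity.vectorize(connectivity.fc_matrix(ts), rois)
            table = connectivity.feature_table(vec, rois)
            with open(fc_dir / f"sub-{spec.subject_id}_edges.tsv", "w") as f:
                f.write(f"# roi_table_hash={vec.roi_table_hash}\n")
                table.to_csv(f, sep="\t", index=False)
        _stamp(fc_dir / ".done.json", cfg_hash)
    dataset = classify.LabeledFeatures(
        features=np.vstack(
            [
                pd.read_csv(
                    fc_dir / f"sub-{s.subject_id}_edges.tsv", sep="\t", comment="#"
                )["z"].to_numpy()
                for s in cohort.specs
            ]
        ),
        subject_ids=[s.subject_id for s in cohort.specs],
        groups=np.asarray([s.group for s in cohort.specs]),
        severity=pd.DataFrame(
            {
                "gs_gait": [s.gs_gait for s in cohort.specs],
                "gs_cognition": [s.gs_cognition for s in cohort.specs],
                "gs_urinary": [s.gs_urinary for s in cohort.specs],
            }
        ),
        roi_table_hash=rois.table_hash(),
    )

    # --- classify ---------------------------------------------------------
    cls_dir = out / "classify"
    if not _check_stamp(cls_dir / ".done.json", cfg_hash):
        cls_dir.mkdir(exist_ok=True)
        for task in config.tasks:
            res = classify.loocv(dataset, task, config.classifier)
            res.to_json(cls_dir / f"{task}.json")
            pd.DataFrame([asdict(f) for f in res.folds]).to_csv(
                cls_dir / f"{task}_folds.tsv", sep="\t", index=False
            )
        _stamp(cls_dir / ".done.json", cfg_hash)

    # --- weights ----------------------------------------------------------
    w_dir = out / "weights"
    if not _check_stamp(w_dir / ".done.json", cfg_hash):
        w_dir.mkdir(exist_ok=True)
        for task in config.tasks:
            report = weights_mod.build_weight_report(
                dataset, task, rois, config.classifier
            )
            report.to_json(w_dir / f"{task}.json")
            k = min(config.top_k, len(report.ranking))
            report.ranked_table(rois).head(k).to_csv(
                w_dir / f"{task}_top{k}.tsv", sep="\t", index=False
            )
        _stamp(w_dir / ".done.json", cfg_hash)

    # --- consolidated report ---------------------------------------------
    cv_results = {
        task: json.loads((cls_dir / f"{task}.json").read_text())
        for task in config.tasks
    }
    weight_reports = {
        task: json.loads((w_dir / f"{task}.json").read_text())
        for task in config.tasks
    }
    checksums = {
        str(p.relative_to(out)): _checksum(p)
        for p in sorted(out.rglob("*.tsv"))
    }
    report = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": cfg_hash,
        "n_subjects": len(cohort.specs),
        "n_edges": atlas.n_edges(len(rois)),
        "qc": qc.as_dict(),
        "classification": {
            task: {
                k: v
                for k, v in r.items()
                if k not in ("folds", "selected_pooled")
            }
            for task, r in cv_results.items()
        },
        "weights": {
            task: {
                "inter_sum": r["inter_sum"],
                "intra_sum": r["intra_sum"],
                "inter_fraction_selected": r["inter_fraction_selected"],
                "wilcoxon_p": r["wilcoxon_p"],
                "n_selected": len(r["selected_edges"]),
            }
            for task, r in weight_reports.items()
        },
        "stage_checksums": checksums,
    }
    _write_json(out / "report.json", report)
    return out
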