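"""End-to-end orchestration of the synthetic study.

Runs the full flow — simulate, normative atlas fit, registration QC,
lesion geometry, z-scoring, repeatability-informed longitudinal
labelling, feature extraction, univariate statistics, and multivariate
classification — into a run directory with a manifest recording the
configuration hash, seeds, per-stage counts and a checksum for every
artifact. All constants live in a single :class:`PipelineConfig`; a
rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rimla import classify as clf
from rimla import features as feat
from rimla import geometry as geo
from rimla import longitudinal as rim
from rimla import normative as norm
from rimla import synth
from rimla.core import MODALITIES, child_rng, write_csv, write_json, write_nifti

logger = logging.getLogger(__name__)

_MOD_TAG = {m: m.replace("/", "") for m in MODALITIES}


@dataclasses.dataclass
class PipelineConfig:
    """Single source of every pipeline constant.

    Analysis constants default to the method's canonical values (ring
    cutoffs 2 / 3.5 mm, volume window 3-150 uL, 100 synthetic volumes
    and 100 bootstrap fits, 95 % sign rule, 5th-percentile MI QC, 50
    importance permutations); the scene-size fields control the bundled
    synthetic study.
    """

    # scene
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_healthy: int = 30
    n_patients: int = 16
    lesions_per_patient: int = 8
    n_scan_rescan: int = 200
    sp_fraction: float = 0.15  # secondary-progressive disease-course fraction
    # analysis constants
    ring_cutoffs: tuple[float, float] = (2.0, 3.5)
    volume_range_ul: tuple[float, float] = (3.0, 150.0)
    n_synth: int = 100
    n_boot: int = 100
    sig_fraction: float = 0.95
    mi_percentile: float = 5.0
    mi_bins: int = 64
    age_center_mode: str = "cohort-mean"  # or "fixed"
    age_center_fixed: float = 37.3
    # classifier
    n_train: int = 96
    n_trees: int = 200
    per_tree: int = 400
    n_perm: int = 50
    # misc
    cov_true: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot <= 0 or self.n_synth <= 0:
            raise ValueError("n_boot and n_synth must be positive")
        if not 0.5 <= self.sig_fraction <= 1.0:
            raise ValueError("sig_fraction must lie in [0.5, 1]")
        if not 0.0 <= self.mi_percentile <= 100.0:
            raise ValueError("mi_percentile must lie in [0, 100]")
        if not 0.0 < self.ring_cutoffs[0] <= self.ring_cutoffs[1]:
            raise ValueError("ring cutoffs must be positive and ordered")
        if self.volume_range_ul[0] > self.volume_range_ul[1]:
            raise ValueError("volume_range_ul must be ordered")
        if self.age_center_mode not in ("cohort-mean", "fixed"):
            raise ValueError("age_center_mode must be 'cohort-mean' or 'fixed'")
        if self.n_perm <= 0 or self.n_trees <= 0 or self.per_tree <= 0:
            raise ValueError("classifier sizes must be positive")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            grid_shape=tuple(self.grid_shape),
            voxel_dims=tuple(self.voxel_dims),
            n_healthy=self.n_healthy,
            cov_true=self.cov_true,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute all stages into ``out_dir``; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = cfg.synth_config()
    counts: dict = {}

    # ---- stage 1: simulate -------------------------------------------
    logger.info("stage simulate: healthy cohort and patient cases")
    cohort = synth.gen_healthy_cohort(scfg)
    demo = pd.DataFrame(
        {
            "subject": [f"H{i:03d}" for i in range(len(cohort))],
            "age": [s.age for s in cohort],
            "sex": [s.sex for s in cohort],
        }
    )
    write_csv(demo, out / "healthy_demographics.csv")
    rng = child_rng(cfg.seed, "pipeline")
    cases = []
    for p in range(cfg.n_patients):
        case = synth.gen_patient_case(scfg, cfg.lesions_per_patient, case_id=p)
        cases.append((f"P{p:03d}", case))
    courses = {
        pid: ("SP" if rng.random() < cfg.sp_fraction else "RR") for pid, _ in cases
    }
    counts["healthy_subjects"] = len(cohort)
    counts["patients"] = len(cases)
    for pid, case in cases:
        write_nifti(out / f"{pid}_lesions.nii", case.lesion_labels, cfg.voxel_dims)
        write_nifti(out / f"{pid}_tissue.nii", case.tissue_mask, cfg.voxel_dims)
        for mod in MODALITIES:
            write_nifti(
                out / f"{pid}_{_MOD_TAG[mod]}.nii",
                case.maps[mod].data.astype(np.float32),
                cfg.voxel_dims,
            )
    truth = {
        pid: {str(k): v for k, v in case.phenotypes.items()} for pid, case in cases
    }
    write_json({"phenotypes": truth, "disease_course": courses}, out / "ground_truth.json")

    # ---- stage 2: normative atlas ------------------------------------
    logger.info("stage atlas: voxelwise fit per modality")
    age_center = (
        cfg.age_center_fixed if cfg.age_center_mode == "fixed" else None
    )
    ages = np.array([s.age for s in cohort])
    sexes = np.array([s.sex for s in cohort])
    atlases = {}
    for mod in MODALITIES:
        atlas = norm.fit_atlas([s.maps[mod] for s in cohort], ages, sexes, age_center)
        atlases[mod] = atlas
        tag = _MOD_TAG[mod]
        for name, vol in [
            ("beta0", atlas.beta0), ("beta_sex", atlas.beta_sex),
            ("beta_age", atlas.beta_age), ("beta_age2", atlas.beta_age2),
            ("sigma", atlas.sigma), ("valid", atlas.valid_mask.astype(np.uint8)),
        ]:
            write_nifti(out / f"atlas_{tag}_{name}.nii",
                        np.asarray(vol, dtype=np.float32), cfg.voxel_dims)
        write_json(
            {"modality": mod, "age_center": atlas.age_center,
             "n_subjects": atlas.n_subjects},
            out / f"atlas_{tag}_meta.json",
        )

    # ---- stage 3: registration QC ------------------------------------
    logger.info("stage qc: mutual-information registration check")
    mi_vals = np.array(
        [
            norm.mutual_information(case.maps["T1"], atlases["T1"].beta0, bins=cfg.mi_bins)
            for _, case in cases
        ]
    )
    thr, flags = norm.qc_pass(mi_vals, cfg.mi_percentile)
    write_csv(
        pd.DataFrame({"patient_id": [pid for pid, _ in cases], "mi": mi_vals,
                      "qc_pass": flags}),
        out / "qc.csv",
    )
    counts["qc_failed"] = int((~flags).sum())

    # ---- stage 4: geometry + z-scores + longitudinal + features ------
    logger.info("stage lesions: geometry, z-scoring, longitudinal labels")
    all_series: list[rim.LesionSeries] = []
    feat_cases = []
    n_volume_filtered = n_wm_filtered = 0
    for (pid, case), keep in zip(cases, flags):
        if not keep:
            continue
        lm = geo.label_lesions(
            (case.lesion_labels > 0).astype(np.int8), cfg.voxel_dims
        )
        vols = geo.lesion_volumes(lm)
        kept_vol = set(geo.filter_by_volume(vols, *cfg.volume_range_ul))
        kept_wm = set(geo.restrict_to_wm(lm, case.tissue_mask))
        n_volume_filtered += len(vols) - len(kept_vol)
        n_wm_filtered += len(kept_vol) - len(kept_vol & kept_wm)
        kept = sorted(kept_vol & kept_wm)
        if not kept:
            continue
        rings = geo.make_rings(lm, cutoffs=tuple(cfg.ring_cutoffs))
        zmaps = {}
        for mod in MODALITIES:
            zm = norm.zscore(case.maps[mod], atlases[mod], case.age, case.sex)
            zmaps[mod] = zm
            write_nifti(out / f"{pid}_z{_MOD_TAG[mod]}.nii",
                        zm.z.astype(np.float32), cfg.voxel_dims)
        # planted phenotype drives the simulated volume trajectory
        classes = [case.phenotypes[lid] for lid in kept]
        series = synth.gen_lesion_series(
            scfg, len(kept), classes=classes, prefix=f"{pid}:"
        )
        for s, lid in zip(series, kept):
            s.lesion_id = f"{pid}:{lid}"
            s.patient_id = pid
        all_series.extend(series)
        feat_cases.append(
            {
                "patient_id": pid,
                "labels": lm,
                "rings": rings,
                "kept_ids": kept,
                "volumes": vols,
                "zmaps": zmaps,
                "phenotype": courses[pid],
            }
        )
    counts["lesions_volume_filtered"] = n_volume_filtered
    counts["lesions_wm_filtered"] = n_wm_filtered

    # ---- stage 5: scan-rescan repeatability + RIMLA -------------------
    logger.info("stage rimla: repeatability and bootstrap slope labels")
    sr = synth.gen_scan_rescan(scfg, cfg.n_scan_rescan)
    write_csv(sr, out / "scan_rescan.csv")
    scan_cols = [c for c in sr.columns if c.startswith("scan")]
    _, mean_cov = rim.compute_cov(sr[scan_cols].to_numpy())
    counts["mean_cov"] = round(mean_cov, 6)

    write_csv(rim.series_to_csv(all_series), out / "lesion_series.csv")
    fits, label_counts = rim.run_rimla(
        all_series,
        mean_cov,
        n_synth=cfg.n_synth,
        n_boot=cfg.n_boot,
        sig_fraction=cfg.sig_fraction,
        seed=cfg.seed,
    )
    write_csv(fits, out / "rimla_fits.csv")
    counts["rimla_labels"] = label_counts

    # ---- stage 6: features -------------------------------------------
    logger.info("stage features: 18 z-score metrics per lesion")
    label_map = dict(zip(fits["lesion_id"], fits["label"]))
    table = feat.build_feature_table(feat_cases, rimla_labels=label_map)
    write_csv(table, out / "features.csv")
    counts["feature_rows"] = len(table)

    # ---- stage 7: univariate stats -----------------------------------
    logger.info("stage stats: aligned-rank ANOVA per metric")
    from rimla.stats import analyze_feature_table

    metrics = list(feat.FEATURE_COLUMNS) + ["volume_ul"]
    usable = table[table["complete"]]
    stats_table = analyze_feature_table(usable, metrics)
    write_csv(stats_table, out / "stats.csv")

    # ---- stage 8: multivariate classification -------------------------
    logger.info("stage classify: balanced forest, importance, VIF")
    cls_table = usable.copy()
    cls_table["course_binary"] = (cls_table["phenotype"] == "SP").astype(float)
    feature_cols = list(feat.FEATURE_COLUMNS) + ["volume_ul", "course_binary"]
    report = clf.evaluate(
        cls_table,
        feature_cols,
        n_train=min(cfg.n_train, len(cls_table) - max(4, len(cls_table) // 4)),
        n_trees=cfg.n_trees,
        per_tree=cfg.per_tree,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    write_json(
        {
            "balanced_accuracy": report.balanced_accuracy,
            "multiclass_auc": report.multiclass_auc,
            "auc_method": report.auc_method,
            "accuracy": report.accuracy,
            "krippendorff_alpha": report.krippendorff_alpha,
            "krippendorff_p": report.krippendorff_p,
            "classes": list(report.classes),
        },
        out / "classifier_report.json",
    )
    write_csv(report.importance, out / "importance.csv")
    write_csv(report.vif, out / "vif.csv")
    report.confusion.to_csv(out / "confusion.csv")

    # ---- manifest ------------------------------------------------------
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": counts,
        "files": {p.name: _sha256(p) for p in files},
    }
    write_json(manifest, out / "manifest.json")
    return manifest
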