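"""Synthetic cohort generator.

Produces every input the analysis pipeline consumes — healthy-cohort
quantitative maps obeying the additive age/sex normative model, patient
maps with planted lesions whose z-score profiles differ by longitudinal
phenotype, lesion-volume time series with known true slopes and
multiplicative (COV-scaled) measurement noise, and scan–rescan volume
quadruplets — so that every downstream estimator can be validated
against known ground truth.

The defaults encode the study conditions the analysis assumes: class
prevalences of 62.4 / 14.6 / 12.1 / 10.9 % (stable / shrinking /
enlarging / new), lesion-core z-score targets taken from the observed
T1 class medians (4.33 / 3.97 / 3.84 / 2.77 for the mean, 1.92 / 1.33 /
1.51 / 0.98 for the within-lesion spread), a segmentation repeatability
COV of 0.17, and lesion volumes confined to the 3–150 uL analysis
window.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from rimla.core import MODALITIES, QuantMap, child_rng
from rimla.longitudinal import LesionSeries

#: labels of the synthetic tissue mask
TISSUE_BACKGROUND, TISSUE_CORTEX, TISSUE_WM = 0, 1, 2

_VOLUME_FLOOR_UL = 0.1  # resampling floor for non-positive volume draws


@dataclasses.dataclass
class ModalityModel:
    """Voxelwise normative generative model for one quantitative modality.

    E{X} = beta0 + beta_sex*sex + beta_age*age_c + beta_age2*age_c^2,
    with sex binary (1 = male), age_c age centred at ``age_center`` of
    the config, plus i.i.d. Gaussian noise of SD ``noise_sd``. Units are
    native (ms for T1/T2, unitless for the ratio).
    """

    beta0: float
    beta_sex: float
    beta_age: float
    beta_age2: float
    noise_sd: float

    def expectation(self, age_c: float, sex: int) -> float:
        return (
            self.beta0
            + self.beta_sex * sex
            + self.beta_age * age_c
            + self.beta_age2 * age_c**2
        )


@dataclasses.dataclass
class LesionClassSpec:
    """Planted microstructural profile of one longitudinal phenotype."""

    prevalence: float
    core_mean_z: float   # target mean z inside the lesion
    ring1_mean_z: float  # target mean z in the first perilesional ring
    z_spread: float      # within-lesion SD of planted z
    ring_z_spread: float = 1.2


@dataclasses.dataclass
class SeriesSpec:
    """Volume-trajectory model of one phenotype: v(t) = v0 + slope*t."""

    slope_ul_per_day: float
    n_timepoints: int = 4
    interval_days: float = 182.5


def _default_modality_models() -> dict[str, ModalityModel]:
    # plausible 3T white-matter relaxometry values and age/sex trends
    return {
        "T1": ModalityModel(850.0, 20.0, 1.5, 0.02, 30.0),
        "T2": ModalityModel(75.0, 2.0, 0.15, 0.005, 4.0),
        "T2/T1": ModalityModel(0.088, -0.002, -2e-4, 2e-6, 0.006),
    }


def _default_lesion_spec() -> dict[str, LesionClassSpec]:
    return {
        "stable": LesionClassSpec(0.624, 4.33, 1.14, 1.92),
        "shrinking": LesionClassSpec(0.146, 3.97, 1.41, 1.33),
        "enlarging": LesionClassSpec(0.121, 3.84, 1.30, 1.51),
        "new": LesionClassSpec(0.109, 2.77, 0.97, 0.98),
    }


def _default_series_spec() -> dict[str, SeriesSpec]:
    return {
        "stable": SeriesSpec(0.0),
        "enlarging": SeriesSpec(0.5),
        "shrinking": SeriesSpec(-0.5),
        "new": SeriesSpec(0.0),
    }


@dataclasses.dataclass
class SynthConfig:
    """All knobs of the synthetic study, with validated invariants."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_healthy: int = 68
    age_range: tuple[float, float] = (20.0, 54.6)
    sex_ratio: float = 0.66  # fraction female
    age_center: float = 37.3
    modality_models: dict[str, ModalityModel] = dataclasses.field(
        default_factory=_default_modality_models
    )
    lesion_spec: dict[str, LesionClassSpec] = dataclasses.field(
        default_factory=_default_lesion_spec
    )
    series_spec: dict[str, SeriesSpec] = dataclasses.field(
        default_factory=_default_series_spec
    )
    lesion_volume_range_ul: tuple[float, float] = (5.0, 120.0)
    series_baseline_range_ul: tuple[float, float] = (10.0, 60.0)
    ring_outer_mm: float = 3.5
    cov_true: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(float(v) <= 0 for v in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")
        prev = sum(s.prevalence for s in self.lesion_spec.values())
        if abs(prev - 1.0) > 1e-9:
            raise ValueError(f"class prevalences must sum to 1, got {prev}")
        for name, m in self.modality_models.items():
            if m.noise_sd < 0:
                raise ValueError(f"noise_sd of {name} must be >= 0")
        for name, s in self.lesion_spec.items():
            if s.z_spread < 0 or s.ring_z_spread < 0 or s.prevalence < 0:
                raise ValueError(f"lesion_spec[{name}] has a negative parameter")
        if self.cov_true < 0:
            raise ValueError(f"cov_true must be >= 0, got {self.cov_true}")

    # ------------------------------------------------------------------
    def expectation_map(self, modality: str, age: float, sex: int) -> float:
        """Noise-free normative expectation for a subject (true atlas)."""
        return self.modality_models[modality].expectation(age - self.age_center, sex)

    def true_zscore(self, values: np.ndarray, modality: str, age: float, sex: int):
        """z-score of observed values under the true generative atlas."""
        m = self.modality_models[modality]
        return (values - self.expectation_map(modality, age, sex)) / m.noise_sd

    def class_names(self) -> list[str]:
        return list(self.lesion_spec)


@dataclasses.dataclass
class HealthySubject:
    maps: dict[str, QuantMap]
    age: float
    sex: int  # 1 = male, 0 = female


@dataclasses.dataclass
class PatientCase:
    """One synthetic patient scan with planted lesions and ground truth."""

    maps: dict[str, QuantMap]
    lesion_labels: np.ndarray        # int volume, 0 = background
    tissue_mask: np.ndarray          # 0 bg / 1 cortical band / 2 WM+subcortical
    phenotypes: dict[int, str]       # lesion label -> true class
    voxel_dims: tuple[float, float, float]
    age: float
    sex: int


# ----------------------------------------------------------------------
# healthy cohort
# ----------------------------------------------------------------------

def _draw_demographics(cfg: SynthConfig, rng: np.random.Generator):
    age = rng.uniform(*cfg.age_range)
    sex = int(rng.random() >= cfg.sex_ratio)  # 1 = male with prob 1 - sex_ratio
    return age, sex


def gen_healthy_cohort(cfg: SynthConfig) -> list[HealthySubject]:
    """Simulate the healthy normative cohort.

    Each voxel value is the additive age/sex model expectation plus
    Gaussian noise; two calls with the same config seed are
    bit-identical.
    """
    if cfg.n_healthy < 5:
        raise ValueError(
            f"n_healthy={cfg.n_healthy} < 5: the 4-coefficient voxelwise fit "
            "needs at least 5 subjects"
        )
    cohort = []
    for i in range(cfg.n_healthy):
        rng = child_rng(cfg.seed, "healthy", i)
        age, sex = _draw_demographics(cfg, rng)
        maps = {}
        for mod in MODALITIES:
            m = cfg.modality_models[mod]
            data = m.expectation(age - cfg.age_center, sex) + m.noise_sd * (
                rng.standard_normal(cfg.grid_shape)
            )
            maps[mod] = QuantMap(data, cfg.voxel_dims, mod)
        cohort.append(HealthySubject(maps, age, sex))
    return cohort


# ----------------------------------------------------------------------
# patient cases with planted lesions
# ----------------------------------------------------------------------

def make_tissue_mask(grid_shape, bg_margin: int = 3, cortex_width: int = 2) -> np.ndarray:
    """Three-label tissue map: background shell, cortical band, WM interior.

    The cortical band exists solely to exercise the white-matter
    restriction filter; no anatomical realism is intended.
    """
    mask = np.zeros(grid_shape, dtype=np.int16)
    inner = tuple(slice(bg_margin, s - bg_margin) for s in grid_shape)
    mask[inner] = TISSUE_CORTEX
    wm_lo = bg_margin + cortex_width
    wm = tuple(slice(wm_lo, s - wm_lo) for s in grid_shape)
    mask[wm] = TISSUE_WM
    return mask


def _sphere_mask(grid_shape, voxel_dims, center_vox, radius_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    d2 = sum(
        ((g - c) * v) ** 2 for g, c, v in zip(grids, center_vox, voxel_dims)
    )
    return d2 <= radius_mm**2


def _radius_for_volume(volume_ul: float) -> float:
    return (3.0 * volume_ul / (4.0 * math.pi)) ** (1.0 / 3.0)


def gen_patient_case(
    cfg: SynthConfig,
    n_lesions: int,
    case_id: int = 0,
    classes: list[str] | None = None,
) -> PatientCase:
    """Simulate one patient scan with ``n_lesions`` planted lesions.

    Lesions are digital spheres fully inside the white-matter interior,
    pairwise separated by at least twice the outer ring cutoff plus the
    maximal radius so that perilesional rings never interact. Inside
    each lesion the modality values are replaced so that the true
    z-score is N(core target, spread) of its class; the first ring is
    shifted to its ring target; the background obeys the healthy model
    for the patient's age and sex.
    """
    rng = child_rng(cfg.seed, "patient", case_id)
    age, sex = _draw_demographics(cfg, rng)
    tissue = make_tissue_mask(cfg.grid_shape)

    if classes is None:
        names = cfg.class_names()
        probs = np.array([cfg.lesion_spec[c].prevalence for c in names])
        classes = list(rng.choice(names, size=n_lesions, p=probs / probs.sum()))
    elif len(classes) != n_lesions:
        raise ValueError("classes must have one entry per lesion")

    vmin, vmax = cfg.lesion_volume_range_ul
    radii = [_radius_for_volume(rng.uniform(vmin, vmax)) for _ in range(n_lesions)]
    r_max = max(radii) if radii else 0.0
    min_sep_mm = 2.0 * (cfg.ring_outer_mm + r_max)

    # candidate centres: WM voxels far enough from the WM boundary that the
    # lesion plus one-voxel erosion margin stays interior
    centers: list[np.ndarray] = []
    vd = np.asarray(cfg.voxel_dims)
    wm = tissue == TISSUE_WM
    idx = np.argwhere(wm)
    order = rng.permutation(len(idx))
    lo = np.array([0, 0, 0])
    hi = np.array(cfg.grid_shape) - 1
    for k, ri in enumerate(radii):
        margin_vox = np.ceil(ri / vd).astype(int) + 2
        placed = False
        for j in order:
            c = idx[j]
            if np.any(c - margin_vox < lo) or np.any(c + margin_vox > hi):
                continue
            sub = tuple(
                slice(int(c[a] - margin_vox[a]), int(c[a] + margin_vox[a] + 1))
                for a in range(3)
            )
            if not np.all(wm[sub]):
                continue
            if any(np.linalg.norm((c - p) * vd) < min_sep_mm for p in centers):
                continue
            centers.append(c)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"requested {n_lesions} lesions but only {k} fit in the grid "
                f"at minimum separation {min_sep_mm:.1f} mm"
            )

    labels = np.zeros(cfg.grid_shape, dtype=np.int32)
    for lid, (c, ri) in enumerate(zip(centers, radii), start=1):
        labels[_sphere_mask(cfg.grid_shape, cfg.voxel_dims, c, ri)] = lid

    maps = {}
    from scipy.ndimage import distance_transform_edt

    ring1_sets = []
    for lid in range(1, n_lesions + 1):
        d = distance_transform_edt(labels != lid, sampling=cfg.voxel_dims)
        ring1_sets.append((d > 0) & (d < 2.0) & (labels == 0))

    for mod in MODALITIES:
        m = cfg.modality_models[mod]
        exp = m.expectation(age - cfg.age_center, sex)
        data = exp + m.noise_sd * rng.standard_normal(cfg.grid_shape)
        for lid in range(1, n_lesions + 1):
            spec = cfg.lesion_spec[classes[lid - 1]]
            core = labels == lid
            z = spec.core_mean_z + spec.z_spread * rng.standard_normal(int(core.sum()))
            data[core] = exp + m.noise_sd * z
            ring1 = ring1_sets[lid - 1]
            zr = spec.ring1_mean_z + spec.ring_z_spread * rng.standard_normal(
                int(ring1.sum())
            )
            data[ring1] = exp + m.noise_sd * zr
        maps[mod] = QuantMap(data, cfg.voxel_dims, mod)

    phenotypes = {lid: classes[lid - 1] for lid in range(1, n_lesions + 1)}
    return PatientCase(maps, labels, tissue, phenotypes, cfg.voxel_dims, age, sex)


# ----------------------------------------------------------------------
# longitudinal volume series and scan-rescan tables
# ----------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, floor=_VOLUME_FLOOR_UL, size=None):
    """N(mean, sd) resampled (not clipped) to stay above ``floor``."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= floor
    # vectorised resampling loop; unbiased above the floor
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = out <= floor
    return out


def gen_lesion_series(
    cfg: SynthConfig,
    n_lesions: int,
    classes: list[str] | None = None,
    prefix: str = "L",
) -> list[LesionSeries]:
    """Simulate per-lesion volume-vs-time observations with known class.

    Observed volumes are Gaussian around the true linear trajectory with
    SD = cov_true * v_true(t) (the multiplicative repeatability model),
    resampled above a small positive floor. Series of class "new" are
    flagged undetected at all but the last timepoint.
    """
    if classes is None:
        names = cfg.class_names()
        probs = np.array([cfg.lesion_spec[c].prevalence for c in names])
        rng0 = child_rng(cfg.seed, "series-classes", prefix)
        classes = list(rng0.choice(names, size=n_lesions, p=probs / probs.sum()))
    elif len(classes) != n_lesions:
        raise ValueError("classes must have one entry per series")

    out = []
    for i, cls in enumerate(classes):
        spec = cfg.series_spec[cls]
        if cls != "new" and spec.n_timepoints < 3:
            raise ValueError(
                f"series of class {cls!r} need >= 3 timepoints, got {spec.n_timepoints}"
            )
        rng = child_rng(cfg.seed, "series", prefix, i)
        times = np.arange(spec.n_timepoints, dtype=float) * spec.interval_days
        v0 = rng.uniform(*cfg.series_baseline_range_ul)
        # keep the true trajectory positive over the whole follow-up
        v0 = max(v0, 5.0 - spec.slope_ul_per_day * times[-1])
        v_true = v0 + spec.slope_ul_per_day * times
        if cfg.cov_true == 0:
            observed = v_true.copy()
        else:
            observed = _truncated_normal(rng, v_true, cfg.cov_true * v_true)
        detected = np.ones(spec.n_timepoints, dtype=bool)
        if cls == "new":
            detected[:-1] = False
        volumes = np.where(detected, observed, np.nan)
        out.append(
            LesionSeries(
                lesion_id=f"{prefix}{i}",
                times=times,
                volumes=volumes,
                detected=detected,
                true_class=cls,
            )
        )
    return out


# ----------------------------------------------------------------------
# direct feature-table generation (for the statistical stages)
# ----------------------------------------------------------------------

#: class-conditional profiles of the 18 z-score metrics and the volume:
#: per metric, (median, IQR) for stable / enlarging / shrinking / new.
#: These encode the observed microstructural contrasts between
#: longitudinal phenotypes (highest lesion-core z in stable lesions,
#: lowest in new ones).
FEATURE_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "T1_lesion_mean":  {"stable": (4.33, 2.31), "enlarging": (3.84, 1.98), "shrinking": (3.97, 2.23), "new": (2.77, 2.53)},
    "T1_lesion_sd":    {"stable": (1.92, 1.42), "enlarging": (1.51, 0.93), "shrinking": (1.33, 1.04), "new": (0.98, 0.92)},
    "T1_ring1_mean":   {"stable": (1.14, 1.02), "enlarging": (1.30, 1.03), "shrinking": (1.41, 1.12), "new": (0.97, 1.13)},
    "T1_ring1_sd":     {"stable": (1.24, 0.43), "enlarging": (1.16, 0.39), "shrinking": (1.28, 0.47), "new": (1.07, 0.47)},
    "T1_ring2_mean":   {"stable": (0.39, 0.78), "enlarging": (0.56, 0.82), "shrinking": (0.56, 0.80), "new": (0.37, 0.78)},
    "T1_ring2_sd":     {"stable": (0.82, 0.28), "enlarging": (0.84, 0.29), "shrinking": (0.86, 0.28), "new": (0.81, 0.30)},
    "T2_lesion_mean":  {"stable": (3.10, 2.03), "enlarging": (3.01, 1.74), "shrinking": (2.48, 1.72), "new": (2.12, 1.85)},
    "T2_lesion_sd":    {"stable": (1.10, 0.89), "enlarging": (0.93, 0.70), "shrinking": (0.72, 0.55), "new": (0.60, 0.54)},
    "T2_ring1_mean":   {"stable": (1.61, 1.12), "enlarging": (1.67, 1.03), "shrinking": (1.59, 1.25), "new": (1.32, 1.42)},
    "T2_ring1_sd":     {"stable": (1.13, 0.52), "enlarging": (1.13, 0.52), "shrinking": (0.97, 0.43), "new": (0.92, 0.44)},
    "T2_ring2_mean":   {"stable": (0.90, 0.94), "enlarging": (0.94, 0.92), "shrinking": (1.00, 0.98), "new": (0.76, 1.08)},
    "T2_ring2_sd":     {"stable": (0.95, 0.33), "enlarging": (1.01, 0.39), "shrinking": (0.95, 0.33), "new": (0.91, 0.38)},
    "T2T1_lesion_mean": {"stable": (-0.41, 1.21), "enlarging": (-0.27, 1.20), "shrinking": (-0.62, 1.23), "new": (-0.30, 1.27)},
    "T2T1_lesion_sd":  {"stable": (0.91, 0.47), "enlarging": (0.82, 0.44), "shrinking": (0.72, 0.42), "new": (0.62, 0.50)},
    "T2T1_ring1_mean": {"stable": (0.45, 0.83), "enlarging": (0.43, 0.85), "shrinking": (0.21, 0.79), "new": (0.35, 0.92)},
    "T2T1_ring1_sd":   {"stable": (0.95, 0.31), "enlarging": (0.91, 0.30), "shrinking": (0.92, 0.29), "new": (0.83, 0.29)},
    "T2T1_ring2_mean": {"stable": (0.40, 0.72), "enlarging": (0.35, 0.75), "shrinking": (0.31, 0.75), "new": (0.35, 0.72)},
    "T2T1_ring2_sd":   {"stable": (0.88, 0.26), "enlarging": (0.87, 0.27), "shrinking": (0.86, 0.28), "new": (0.84, 0.28)},
    "volume_ul":       {"stable": (27.0, 10.0), "enlarging": (16.0, 21.75), "shrinking": (11.0, 17.0), "new": (9.0, 12.0)},
}

_IQR_TO_SD = 1.3489795  # IQR of a normal distribution in SD units


def gen_feature_table(
    cfg: SynthConfig,
    n_lesions: int,
    n_patients: int = 50,
    patient_sd: float = 0.2,
    sp_fraction: float = 0.11,
    classes: list[str] | None = None,
    profiles: dict | None = None,
) -> pd.DataFrame:
    """Simulate the lesion feature table directly at the metric level.

    Each lesion draws its 18 z-score metrics and volume from the
    class-conditional normal profiles (median, IQR/1.349 as SD) in
    :data:`FEATURE_PROFILES`, plus an additive per-patient offset of SD
    ``patient_sd`` shared by all lesions of a patient. Patients are
    assigned a disease course (SP with probability ``sp_fraction``).
    Volumes are resampled above 3 uL. This generator feeds the
    statistical stages at cohort scale without any image simulation.
    """
    rng = child_rng(cfg.seed, "featuretable")
    profiles = profiles or FEATURE_PROFILES
    names = cfg.class_names()
    probs = np.array([cfg.lesion_spec[c].prevalence for c in names])
    if classes is None:
        classes = list(rng.choice(names, size=n_lesions, p=probs / probs.sum()))
    elif len(classes) != n_lesions:
        raise ValueError("classes must have one entry per lesion")
    patients = [f"P{int(i):03d}" for i in rng.integers(0, n_patients, size=n_lesions)]
    course = {
        f"P{i:03d}": ("SP" if rng.random() < sp_fraction else "RR")
        for i in range(n_patients)
    }
    offsets = {
        (f"P{i:03d}", m): patient_sd * rng.standard_normal()
        for i in range(n_patients)
        for m in profiles
    }
    rows = []
    for i, (cls, pid) in enumerate(zip(classes, patients)):
        row = {
            "lesion_id": f"L{i:05d}",
            "patient_id": pid,
            "phenotype": course[pid],
            "rimla_label": cls,
        }
        for metric, prof in profiles.items():
            med, iqr = prof[cls]
            sd = iqr / _IQR_TO_SD
            val = med + offsets[(pid, metric)] + sd * rng.standard_normal()
            if metric == "volume_ul":
                while val < 3.0:
                    val = med + sd * rng.standard_normal()
            row[metric] = val
        rows.append(row)
    return pd.DataFrame(rows)


def gen_scan_rescan(cfg: SynthConfig, n_lesions: int, n_scans: int = 4) -> pd.DataFrame:
    """Simulate a scan-rescan repeatability table.

    Each lesion has a fixed true volume; every scan observes
    N(v_true, cov_true * v_true). Returns one row per lesion with the
    per-scan volumes and the true volume.
    """
    if n_scans < 2:
        raise ValueError("scan-rescan COV needs at least 2 scans")
    rng = child_rng(cfg.seed, "scanrescan")
    vmin, vmax = 3.0, 150.0
    rows = []
    for i in range(n_lesions):
        v = rng.uniform(vmin, vmax)
        if cfg.cov_true == 0:
            obs = np.full(n_scans, v)
        else:
            obs = _truncated_normal(rng, np.full(n_scans, v), cfg.cov_true * v)
        rows.append([f"SR{i}", v, *obs])
    cols = ["lesion_id", "true_volume_ul"] + [f"scan{s+1}" for s in range(n_scans)]
    return pd.DataFrame(rows, columns=cols)
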