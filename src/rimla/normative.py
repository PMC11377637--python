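"""Voxelwise normative modelling and deviation (z-score) mapping.

For each quantitative modality X (T1, T2, T2/T1) a voxelwise ordinary
least-squares model

    E{X} = b0 + b_sex * sex + b_age * age_c + b_age2 * age_c^2

is fitted on a healthy cohort, with sex binary (1 = male) and age
centred at the cohort mean. A patient map is converted to a z-score map
by comparing the measured values with the normative expectation for the
patient's age and sex, scaled by the voxelwise residual standard
deviation. Registration quality control uses the mutual information of
the joint histogram, discarding subjects below the cohort's fifth
percentile.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from rimla.core import QuantMap

_SIGMA_EPS = 1e-6  # residual SD below this (native units) -> invalid voxel


@dataclasses.dataclass
class NormativeAtlas:
    """Per-voxel regression coefficients and residual spread for one modality."""

    modality: str
    beta0: np.ndarray
    beta_sex: np.ndarray
    beta_age: np.ndarray
    beta_age2: np.ndarray
    sigma: np.ndarray
    age_center: float
    valid_mask: np.ndarray
    voxel_dims: tuple[float, float, float]
    n_subjects: int = 0

    def expectation(self, age: float, sex: int) -> np.ndarray:
        age_c = age - self.age_center
        return (
            self.beta0
            + self.beta_sex * sex
            + self.beta_age * age_c
            + self.beta_age2 * age_c**2
        )


@dataclasses.dataclass
class ZScoreMap:
    """Voxelwise deviation map; NaN wherever the atlas is invalid."""

    z: np.ndarray
    modality: str
    voxel_dims: tuple[float, float, float]
    age: float = np.nan
    sex: int = -1

    def as_quantmap(self) -> QuantMap:
        return QuantMap(self.z, self.voxel_dims, f"{self.modality}-z")


def fit_atlas(
    cohort_maps: list[QuantMap],
    ages: np.ndarray,
    sexes: np.ndarray,
    age_center: float | None = None,
) -> NormativeAtlas:
    """Fit the voxelwise age/sex normative model on a healthy cohort.

    All maps must share one grid. The design is [1, sex, age_c, age_c^2];
    the voxelwise residual SD uses an n-4 denominator. ``age_center``
    defaults to the cohort mean age. A rank-deficient design (e.g. a
    single-sex, single-age cohort) flags all voxels invalid with a
    warning rather than failing.
    """
    n = len(cohort_maps)
    if n < 5:
        raise ValueError(f"normative fit needs >= 5 subjects, got {n}")
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes, dtype=float)
    if ages.size != n or sexes.size != n:
        raise ValueError("ages and sexes must match the number of maps")
    grid = cohort_maps[0].data.shape
    vd = cohort_maps[0].voxel_dims
    for m in cohort_maps[1:]:
        if m.data.shape != grid or not np.allclose(m.voxel_dims, vd):
            raise ValueError("all cohort maps must share one grid")

    if age_center is None:
        age_center = float(ages.mean())
    age_c = ages - age_center
    X = np.column_stack([np.ones(n), sexes, age_c, age_c**2])
    Y = np.stack([m.data.ravel() for m in cohort_maps])  # (n, V)

    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        warnings.warn(
            "rank-deficient normative design (rank "
            f"{rank} < 4); all voxels flagged invalid",
            stacklevel=2,
        )
        shape = grid
        nanvol = np.full(shape, np.nan)
        return NormativeAtlas(
            cohort_maps[0].modality,
            nanvol.copy(), nanvol.copy(), nanvol.copy(), nanvol.copy(),
            np.zeros(shape), float(age_center), np.zeros(shape, dtype=bool),
            vd, n,
        )

    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)  # (4, V)
    resid = Y - X @ coef
    sigma = np.sqrt((resid**2).sum(axis=0) / (n - 4))
    valid = sigma >= _SIGMA_EPS

    def vol(a):
        return a.reshape(grid)

    return NormativeAtlas(
        cohort_maps[0].modality,
        vol(coef[0]), vol(coef[1]), vol(coef[2]), vol(coef[3]),
        vol(sigma), float(age_center), vol(valid), vd, n,
    )


def zscore(qmap: QuantMap, atlas: NormativeAtlas, age: float, sex: int) -> ZScoreMap:
    """Deviation map: z = (x - E{X | age, sex}) / sigma on valid voxels."""
    if qmap.data.shape != atlas.beta0.shape:
        raise ValueError("map and atlas are on different grids")
    expect = atlas.expectation(age, sex)
    z = np.full(qmap.data.shape, np.nan)
    v = atlas.valid_mask
    z[v] = (qmap.data[v] - expect[v]) / atlas.sigma[v]
    return ZScoreMap(z, atlas.modality, qmap.voxel_dims, age, int(sex))


def t2t1_ratio(t2: QuantMap, t1: QuantMap) -> QuantMap:
    """Voxelwise T2/T1 ratio map; voxels with T1 <= 0 become NaN."""
    if not t2.same_grid(t1):
        raise ValueError("T2 and T1 maps must be co-registered on one grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(t1.data > 0, t2.data / t1.data, np.nan)
    return QuantMap(ratio, t2.voxel_dims, "T2/T1")


def mutual_information(
    a: QuantMap | np.ndarray,
    b: QuantMap | np.ndarray,
    bins: int = 64,
    binning: str = "width",
) -> float:
    """Mutual information (nats) from the joint histogram of two volumes.

    Restricted to jointly finite voxels. ``binning`` is "width"
    (equal-width bins over each finite range, the default) or "quantile"
    (equal-count bins, which makes MI invariant to monotone rescaling).
    Zero-count bins contribute nothing.
    """
    x = (a.data if isinstance(a, QuantMap) else np.asarray(a)).ravel()
    y = (b.data if isinstance(b, QuantMap) else np.asarray(b)).ravel()
    if x.size != y.size:
        raise ValueError("volumes must have equal size")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no jointly finite voxels")
    if binning == "width":
        edges_x = edges_y = bins
    elif binning == "quantile":
        q = np.linspace(0, 1, bins + 1)
        edges_x = np.unique(np.quantile(x, q))
        edges_y = np.unique(np.quantile(y, q))
    else:
        raise ValueError(f"unknown binning {binning!r}")
    joint, _, _ = np.histogram2d(x, y, bins=(edges_x, edges_y))
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def qc_pass(mi_values: np.ndarray, percentile: float = 5.0) -> tuple[float, np.ndarray]:
    """Registration QC: fail subjects below the cohort MI percentile.

    Returns the (linearly interpolated) percentile threshold and a
    boolean pass flag per subject; a subject fails iff MI < threshold.
    """
    mi_values = np.asarray(mi_values, dtype=float)
    if mi_values.size == 0:
        raise ValueError("qc_pass needs at least one MI value")
    threshold = float(np.percentile(mi_values, percentile))
    return threshold, mi_values >= threshold
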