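"""Per-lesion microstructural feature extraction.

For every lesion surviving the volume, white-matter and detection
filters, the mean and the sample standard deviation of the z-score are
computed in three regions (lesion core, first and second perilesional
ring) for each of the three modalities (T1, T2, T2/T1), yielding 18
z-score metrics per lesion, joined with the lesion volume, the
longitudinal phenotype from the bootstrap slope analysis, and the
patient's disease course.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from rimla.core import MODALITIES
from rimla.geometry import LesionLabelMap, RingMasks
from rimla.normative import ZScoreMap

logger = logging.getLogger(__name__)

REGIONS = ("lesion", "ring1", "ring2")

#: canonical column order of the 18 z-score metrics
FEATURE_COLUMNS = tuple(
    f"{mod.replace('/', '')}_{region}_{stat}"
    for mod in MODALITIES
    for region in REGIONS
    for stat in ("mean", "sd")
)


def _region_stats(z: np.ndarray, region: np.ndarray) -> tuple[float, float]:
    vals = z[region]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return (float(vals.mean()) if vals.size else np.nan, np.nan)
    return float(vals.mean()), float(vals.std(ddof=1))


def extract_features(
    zmaps: dict[str, ZScoreMap],
    lesion_mask: np.ndarray,
    rings: RingMasks,
    lesion_id: int,
    volume_ul: float,
    patient_id: str = "",
    phenotype: str = "",
    rimla_label: str = "",
) -> dict:
    """One lesion's feature row: 18 z-score metrics + volume + metadata.

    Mean and sample (n-1) SD of z over the lesion core and both rings
    for each modality; non-finite z voxels are excluded, and a region
    with fewer than 2 valid voxels yields missing statistics (the row is
    retained, flagged via ``complete``).
    """
    row: dict = {
        "lesion_id": lesion_id,
        "patient_id": patient_id,
        "phenotype": phenotype,
        "rimla_label": rimla_label,
        "volume_ul": float(volume_ul),
    }
    regions = {
        "lesion": np.asarray(lesion_mask, dtype=bool),
        "ring1": rings.ring1[lesion_id],
        "ring2": rings.ring2[lesion_id],
    }
    complete = True
    for mod in MODALITIES:
        zm = zmaps[mod]
        if zm.z.shape != regions["lesion"].shape:
            raise ValueError("z-map and masks are on different grids")
        for rname, rmask in regions.items():
            mean, sd = _region_stats(zm.z, rmask)
            tag = mod.replace("/", "")
            row[f"{tag}_{rname}_mean"] = mean
            row[f"{tag}_{rname}_sd"] = sd
            if not (np.isfinite(mean) and np.isfinite(sd)):
                complete = False
    row["complete"] = complete
    return row


def build_feature_table(
    cases: list[dict],
    rimla_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the lesion feature table from per-case extraction inputs.

    Each case dict carries ``zmaps``, a :class:`LesionLabelMap`
    ``labels``, ``rings``, the ``kept_ids`` surviving volume and WM
    filters, per-lesion ``volumes``, and metadata (``patient_id``,
    ``phenotype``, optional ``rimla_label`` per lesion). When
    ``rimla_labels`` maps "patient_id:lesion_id" to a phenotype label,
    lesions without an entry are excluded with a logged reason.
    """
    rows = []
    for case in cases:
        lm: LesionLabelMap = case["labels"]
        for lid in case["kept_ids"]:
            key = f"{case.get('patient_id', '')}:{lid}"
            if rimla_labels is not None:
                if key not in rimla_labels or rimla_labels[key] == "discarded":
                    logger.info("lesion %s excluded: no usable longitudinal label", key)
                    continue
                label = rimla_labels[key]
            else:
                label = case.get("rimla_label", {}).get(lid, "")
            rows.append(
                extract_features(
                    case["zmaps"],
                    lm.labels == lid,
                    case["rings"],
                    lid,
                    case["volumes"][lid],
                    patient_id=case.get("patient_id", ""),
                    phenotype=case.get("phenotype", ""),
                    rimla_label=label,
                )
            )
    cols = ["lesion_id", "patient_id", "phenotype", "rimla_label", "volume_ul"]
    cols += list(FEATURE_COLUMNS) + ["complete"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
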