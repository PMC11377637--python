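import numpy as np
import pytest

from rimla.synth import ModalityModel, SynthConfig


@pytest.fixture
def small_cfg():
    """Small, fast synthetic configuration shared across tests."""
    return SynthConfig(grid_shape=(20, 20, 20), n_healthy=10, seed=123)


@pytest.fixture
def noise_free_cfg():
    """Deterministic generative model: zero noise in every modality."""
    models = {
        "T1": ModalityModel(800.0, 50.0, -2.0, 0.0, 0.0),
        "T2": ModalityModel(80.0, 5.0, 0.1, 0.0, 0.0),
        "T2/T1": ModalityModel(0.1, 0.01, 0.0, 0.0, 0.0),
    }
    return SynthConfig(
        grid_shape=(12, 12, 12), n_healthy=8, modality_models=models, seed=5
    )


def brute_force_distance(labels, voxel_dims, outer_cutoff=3.5):
    """Independent pairwise-distance oracle for small grids.

    Returns (min distance, nearest label with low-id tie-break, number of
    labels with min distance < outer_cutoff), matching the geometry
    module's contract.
    """
    labels = np.asarray(labels)
    vd = np.asarray(voxel_dims, dtype=float)
    grid = np.argwhere(np.ones(labels.shape, dtype=bool)) * vd
    ids = np.unique(labels[labels > 0])
    per_label = np.empty((ids.size, grid.shape[0]))
    for k, lid in enumerate(ids):
        pts = np.argwhere(labels == lid) * vd
        d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        per_label[k] = np.sqrt(d2.min(axis=1))
    best = per_label.min(axis=0)
    nearest = ids[per_label.argmin(axis=0)]  # argmin takes the first (lowest id)
    count = (per_label < outer_cutoff).sum(axis=0)
    # voxels where any lesion sits numerically on the cutoff: the side of
    # the strict inequality is float-rounding dependent there
    boundary = (np.abs(per_label - outer_cutoff) < 1e-9).any(axis=0)
    shape = labels.shape
    return (
        best.reshape(shape),
        nearest.reshape(shape).astype(np.int32),
        count.reshape(shape),
        boundary.reshape(shape),
    )
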