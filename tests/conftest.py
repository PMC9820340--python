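import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from xenbkit import struct_io, synthetic_data


@pytest.fixture(scope="session")
def pocket_complex():
    return synthetic_data.make_pocket_complex()


@pytest.fixture(scope="session")
def stable_trajectory():
    """Single-mode bound complex: 500 frames, HAD ~ N(3.5, 0.2), seed 7."""
    recipe = synthetic_data.ComplexRecipe(
        n_frames=500, had_mean=3.5, had_sd=0.2, seed=7
    )
    return synthetic_data.make_complex_trajectory(recipe)


@pytest.fixture(scope="session")
def two_mode_trajectory():
    """Two pose modes 4.5 Angstrom apart, 50 frames each on average."""
    modes = [
        synthetic_data.PoseMode((0.0, 0.0, 0.0), 0.5, 0.4),
        synthetic_data.PoseMode((4.5, 0.0, 0.0), 0.5, 0.4),
    ]
    recipe = synthetic_data.ComplexRecipe(n_frames=100, pose_modes=modes, seed=3)
    return synthetic_data.make_complex_trajectory(recipe)


@pytest.fixture
def ligand_selection(pocket_complex):
    return struct_io.select_atoms(pocket_complex, "resname TNT and not element H")


def brute_force_dbscan(dist: np.ndarray, eps: float, min_points: int) -> np.ndarray:
    """Reference DBSCAN: the original visit-and-expand queue formulation.

    Visits points in index order; a cluster grows from each unvisited core
    point by exhausting a FIFO seed queue.  Border points keep the label of
    the cluster that first reaches them.
    """
    n = dist.shape[0]
    UNVISITED, NOISE = -2, -1
    labels = np.full(n, UNVISITED, dtype=int)
    cluster = -1
    for p in range(n):
        if labels[p] != UNVISITED:
            continue
        neighbors = list(np.nonzero(dist[p] <= eps)[0])
        if len(neighbors) < min_points:
            labels[p] = NOISE
            continue
        cluster += 1
        labels[p] = cluster
        queue = [q for q in neighbors if q != p]
        while queue:
            q = queue.pop(0)
            if labels[q] == NOISE:
                labels[q] = cluster
            if labels[q] != UNVISITED:
                continue
            labels[q] = cluster
            q_neighbors = list(np.nonzero(dist[q] <= eps)[0])
            if len(q_neighbors) >= min_points:
                queue.extend(q_neighbors)
    labels[labels == UNVISITED] = NOISE
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so labelings compare up to renaming."""
    mapping: dict[int, int] = {}
    out = np.full(labels.shape, -1, dtype=int)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out
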