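import numpy as np
import pytest

from capsid import (
    build_graph,
    classify_capsomers,
    generate_icosahedral,
    render_density,
)

# (h, k) grid used throughout: all canonical classes with h <= 4.
HK_GRID = [
    (1, 0), (1, 1),
    (2, 0), (2, 1), (2, 2),
    (3, 0), (3, 1), (3, 2), (3, 3),
    (4, 0), (4, 1), (4, 2), (4, 3), (4, 4),
]


def t_of(h: int, k: int) -> int:
    return h * h + h * k + k * k


@pytest.fixture(scope="session")
def t1_set():
    return generate_icosahedral(1, 0, 24.0)


@pytest.fixture(scope="session")
def t3_set():
    return generate_icosahedral(1, 1, 24.0)


@pytest.fixture(scope="session")
def t9_set():
    return generate_icosahedral(3, 0, 24.0)


@pytest.fixture(scope="session")
def t9_graph(t9_set):
    return classify_capsomers(build_graph(t9_set))


@pytest.fixture(scope="session")
def t9_map(t9_set):
    return render_density(t9_set, voxel_nm=1.0, blob_sigma_nm=1.5)


@pytest.fixture(scope="session")
def morphology_maps(t9_set):
    """Noise-free prototype maps for both interior morphologies."""
    return {
        kind: render_density(t9_set, voxel_nm=2.0, blob_sigma_nm=1.5,
                             interior=kind)
        for kind in ("thick_shell", "condensed_core")
    }


def nn_spacing(positions: np.ndarray) -> float:
    """Modal nearest-neighbor spacing (median of per-point NN distances)."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(positions))
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))
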