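import numpy as np
import pytest

import tmsbem as tb
from tmsbem.geometry import Interface, build_head_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def placed_fig8():
    """Figure-8 coil 1 cm above the default outer sphere, aimed at +z pole."""
    coil = tb.build_figure8_coil(0.035, turns=1, segments_per_turn=64)
    return tb.place_coil(coil, target=(0.0, 0.0, 0.092), axis_dir=(0, 0, -1),
                         handle_dir=(1, 0, 0), standoff=0.01)


@pytest.fixture(scope="session")
def small_head():
    """Four-layer sphere at level 1: 320 facets total, fast to assemble."""
    return tb.four_layer_sphere_model(1)


@pytest.fixture(scope="session")
def single_sphere_head():
    """Homogeneous brain-conductivity sphere in air (K = 1), 1280 facets."""
    mesh = tb.icosphere(0.092, 3)
    return build_head_model([Interface(mesh, 0.275, 0.0, "sphere")])


@pytest.fixture(scope="session")
def zero_contrast_head():
    """Sphere with sigma_in = sigma_out: K = 0 everywhere."""
    mesh = tb.icosphere(0.08, 1)
    return build_head_model([Interface(mesh, 0.3, 0.3, "null")])


def make_fake_head(face_vertices, sigma_in=0.3, sigma_out=0.0):
    """HeadModel from bare triangles (no manifold requirements) for
    operator-level tests."""
    from tmsbem.geometry import HeadModel

    fv = np.asarray(face_vertices, dtype=np.float64)
    cross = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0])
    a2 = np.linalg.norm(cross, axis=1)
    centroids = fv.mean(axis=1)
    K = (sigma_in - sigma_out) / (sigma_in + sigma_out)
    n = len(fv)
    return HeadModel(
        interfaces=[], normals=cross / a2[:, None], areas=0.5 * a2,
        centroids=centroids, face_vertices=fv,
        contrast=np.full(n, K), sigma_in=np.full(n, sigma_in),
        sigma_out=np.full(n, sigma_out),
        circumradii=np.linalg.norm(fv - centroids[:, None, :], axis=2).max(axis=1),
        interface_slices=[slice(0, n)],
    )
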