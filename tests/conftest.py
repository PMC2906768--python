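import logging

import numpy as np
import pytest

import toothcarve as tc

logging.getLogger("toothcarve").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid15():
    return tc.make_plane_grid(15, 15)


@pytest.fixture(scope="session")
def sphere3():
    return tc.make_sphere(3)


@pytest.fixture(scope="session")
def clean_torus():
    return tc.make_torus(tc.TorusSpec(R=2.0, r=1.0, n_u=100, n_v=50))


@pytest.fixture(scope="session")
def cylinder_band_mesh():
    """Open grid cylinder (40 around x 20 along) for band/ring fixtures."""
    nt, nz = 40, 20
    th = 2 * np.pi * np.arange(nt) / nt
    verts = np.array(
        [
            [np.cos(th[i]), np.sin(th[i]), j * 0.3]
            for i in range(nt)
            for j in range(nz)
        ]
    )

    def vid(i, j):
        return (i % nt) * nz + j

    faces = []
    for i in range(nt):
        for j in range(nz - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    mesh = tc.Mesh(verts, np.asarray(faces))
    return mesh, vid, nt, nz


@pytest.fixture(scope="session")
def fused_phantom():
    """Two-cusp phantom with one fused pair plus ground truth."""
    spec = tc.PhantomSpec(n_cusps=2, fused=(0,), resolution=0.45)
    return tc.make_dental_phantom(spec)
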