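import numpy as np
import pytest

from aneuscale.mesh_core import TriangleMesh
from aneuscale.neck_geometry import build_neck_frame, extract_neck_curve, split_sac
from aneuscale.phantom import PhantomSpec, make_phantom


def build_model(result):
    """phantom result -> labeled neck-frame model (shared pipeline helper)."""
    frame = build_neck_frame(result.mesh, result.plane)
    frame = extract_neck_curve(frame)
    return split_sac(frame, frame.transform.apply(result.apex_seed))


@pytest.fixture(scope="session")
def hemi_phantom():
    """Hemisphere sac (radius 1) on a straight tube; analytic ASR 0.5."""
    return make_phantom(PhantomSpec(sac_radius=1.0, sac_height=1.0, tessellation=32))


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Half-ellipsoid sac (base radius 1, height 2); analytic ASR 1.0."""
    return make_phantom(PhantomSpec(sac_radius=1.0, sac_height=2.0, tessellation=32))


@pytest.fixture(scope="session")
def hemi_model(hemi_phantom):
    return build_model(hemi_phantom)


@pytest.fixture(scope="session")
def ellipsoid_model(ellipsoid_phantom):
    return build_model(ellipsoid_phantom)


@pytest.fixture
def icosahedron():
    """Closed regular icosahedron (golden-ratio coordinates)."""
    p = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, p, 0], [1, p, 0], [-1, -p, 0], [1, -p, 0],
            [0, -1, p], [0, 1, p], [0, -1, -p], [0, 1, -p],
            [p, 0, -1], [p, 0, 1], [-p, 0, -1], [-p, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return TriangleMesh(verts, faces)


def capped_cylinder(radius=1.0, length=4.0, segments=64, axis="z"):
    """Closed cylinder along z (or x) for cross-section tests."""
    theta = 2.0 * np.pi * np.arange(segments) / segments
    ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    lo = np.column_stack([ring, np.full(segments, -length / 2.0)])
    hi = np.column_stack([ring, np.full(segments, length / 2.0)])
    verts = np.vstack(
        [lo, hi, [[0.0, 0.0, -length / 2.0]], [[0.0, 0.0, length / 2.0]]]
    )
    c_lo, c_hi = 2 * segments, 2 * segments + 1
    faces = []
    for j in range(segments):
        j2 = (j + 1) % segments
        faces.append((j, j2, segments + j2))
        faces.append((j, segments + j2, segments + j))
        faces.append((c_lo, j2, j))
        faces.append((c_hi, segments + j, segments + j2))
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
    if axis == "x":
        mesh.vertices = mesh.vertices[:, [2, 0, 1]]
    return mesh
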