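import numpy as np
import pytest

from osteokit.geometry3d import PointCloudGrid, loft
from osteokit.plate_design import build_reference_line, extract_contact_patch
from osteokit.synthetic_data import GeneratorConfig, generate_population


def ols_oracle(clouds, design):
    """Literal normal-equations solver: A = X'X, B = inv(A) X' y.

    Kept deliberately naive (explicit inverse) and independent of the
    package's fitting path; used only on well-conditioned instances.
    """
    S, P, _ = clouds.shape
    X = np.asarray(design, dtype=float)
    A = X.T @ X
    K = np.linalg.inv(A)
    Y = clouds.reshape(S, -1)
    B = K @ X.T @ Y                       # (1+k) x (P*3)
    return B.reshape(X.shape[1], P, 3).transpose(1, 2, 0)


@pytest.fixture(scope="session")
def tube_exact():
    """Noise-free tube population: fits must recover truth exactly."""
    cfg = GeneratorConfig(bone_family="tube", S=8, noise_sigma=0.0, seed=11)
    pop, B = generate_population(cfg)
    return pop, B


@pytest.fixture(scope="session")
def tube_noisy():
    cfg = GeneratorConfig(bone_family="tube", S=8, seed=7)
    pop, B = generate_population(cfg)
    return pop, B


@pytest.fixture(scope="session")
def horseshoe_exact():
    cfg = GeneratorConfig(bone_family="horseshoe", S=6, L=9, M=12,
                          noise_sigma=0.0, seed=5)
    pop, B = generate_population(cfg)
    return pop, B


def cylinder_grid(radius=20.0, height=100.0, L=5, M=12):
    z = np.linspace(0.0, height, L)
    th = 2 * np.pi * np.arange(M) / M
    pts = np.array([[[radius * np.cos(t), radius * np.sin(t), zz]
                     for t in th] for zz in z])
    return PointCloudGrid(pts)


@pytest.fixture(scope="session")
def cylinder_mesh():
    return loft(cylinder_grid(), samples_per_slice=64, cap_ends=True)


def flat_patch(nu=12, nv=9, length=110.0, width=16.0):
    """Planar bone-point grid with an axial reference line through it."""
    xs = np.linspace(0.0, length, nu)
    ys = np.linspace(-width / 2, width / 2, nv)
    pts = np.array([[[x, y, 0.0] for y in ys] for x in xs]).reshape(-1, 3)
    line = build_reference_line(
        np.array([[0.0, 0.0, 0.0], [length / 2, 0.0, 0.0], [length, 0.0, 0.0]]))
    patch = extract_contact_patch(
        pts, line, width / 2 + 0.5,
        outward_hint=np.array([length / 2, 0.0, -100.0]))
    return pts, line, patch
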