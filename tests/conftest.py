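import numpy as np
import pytest

from quadflex.io import CoordinateModel, ScatteringProfile


def sphere_intensity(q, radius, i0=1.0):
    """Analytic homogeneous-sphere form factor I(q) = I0 * Phi^2(qR)."""
    x = np.asarray(q) * radius
    phi = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    return i0 * phi ** 2


def sphere_pr(r, radius):
    """Analytic pair-distance distribution of a homogeneous sphere
    (unnormalized): p(r) ~ r^2 (1 - 3x/2 + x^3/2), x = r/(2R)."""
    x = np.asarray(r) / (2.0 * radius)
    p = r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
    return np.where(x <= 1.0, p, 0.0)


@pytest.fixture
def q_grid():
    return np.linspace(0.006, 0.4, 200)


@pytest.fixture
def sphere_profile(q_grid):
    """Noise-free sphere profile, R = 25 A, with a nominal 1% sigma."""
    i = sphere_intensity(q_grid, 25.0, i0=100.0)
    return ScatteringProfile(q_grid, i, 0.01 * i + 1e-4, label="sphere25")


@pytest.fixture
def guinier_profile():
    """Exact Guinier law, Rg = 20 A, I0 = 100."""
    q = np.linspace(0.004, 0.12, 60)
    i = 100.0 * np.exp(-(q ** 2) * 20.0 ** 2 / 3.0)
    return ScatteringProfile(q, i, np.full_like(i, 1.0), label="guinier20")


def bead_line(n, spacing, radius=5.0, weight=1.0):
    """n collinear beads along z at the given center spacing."""
    xyz = np.zeros((n, 3))
    xyz[:, 2] = spacing * np.arange(n)
    return CoordinateModel(xyz, np.full(n, weight), np.full(n, radius),
                           label=f"line{n}")
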