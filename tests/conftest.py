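"""Shared fixtures: analytic meshes and small-resolution torsos.

Everything is generated programmatically; no binary fixtures.  Registration
fixtures use the 41 x 48 grid to keep the suite fast; measurement-accuracy
fixtures use finer grids where the tolerance demands it.
"""

import numpy as np
import pytest
import trimesh

import torsometry as tm


@pytest.fixture(scope="session")
def atlas_small():
    return tm.build_template_atlas(n_levels=41, n_around=48)


@pytest.fixture(scope="session")
def cylinder():
    """Closed cylinder r=100 mm, h=400 mm, 256 segments, centered at origin."""
    mesh = trimesh.creation.cylinder(radius=100.0, height=400.0, sections=256)
    return tm.make_mesh(mesh.vertices, mesh.faces)


@pytest.fixture(scope="session")
def flat_torso():
    """Symmetric flat-backed torso (no deformity) with its ground truth."""
    spec = tm.TorsoSpec(bow_mm=0.0, theta_deg=0.0, hump_mm=0.0)
    mesh, lms, truth = tm.generate_torso(spec)
    return spec, mesh, lms, truth


@pytest.fixture(scope="session")
def deformed_torso():
    """Default deformed torso (bow 15 mm, twist 10 deg, hump 8 mm)."""
    spec = tm.TorsoSpec()
    mesh, lms, truth = tm.generate_torso(spec)
    return spec, mesh, lms, truth


def star_polygon(rng, n_vertices=None, radius=100.0):
    """Random simple star-shaped polygon about the origin (for oracles)."""
    n = n_vertices or rng.integers(8, 40)
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    # keep angular gaps bounded away from zero so edges stay well-formed
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False) + rng.uniform(
        -0.3 * np.pi / n, 0.3 * np.pi / n, size=n)
    r = radius * rng.uniform(0.5, 1.5, size=n)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def polygon_moments_oracle(poly):
    """Exact area/centroid/second moments by fan triangulation from an
    interior point, using closed-form triangle integrals (independent of the
    boundary-integral implementation)."""
    inner = poly.mean(axis=0)
    area = 0.0
    first = np.zeros(2)
    sxx = syy = sxy = 0.0
    n = len(poly)
    for i in range(n):
        p1, p2 = poly[i], poly[(i + 1) % n]
        v1, v2 = p1 - inner, p2 - inner
        a = 0.5 * (v1[0] * v2[1] - v1[1] * v2[0])
        x = np.array([inner[0], p1[0], p2[0]])
        y = np.array([inner[1], p1[1], p2[1]])
        area += a
        first += a * np.array([x.mean(), y.mean()])
        sxx += a / 6.0 * (np.sum(x * x) + x[0] * x[1] + x[1] * x[2] + x[0] * x[2])
        syy += a / 6.0 * (np.sum(y * y) + y[0] * y[1] + y[1] * y[2] + y[0] * y[2])
        sxy += a / 12.0 * (x[0] * (2 * y[0] + y[1] + y[2]) +
                           x[1] * (y[0] + 2 * y[1] + y[2]) +
                           x[2] * (y[0] + y[1] + 2 * y[2]))
    centroid = first / area
    sxx -= area * centroid[0] ** 2
    syy -= area * centroid[1] ** 2
    sxy -= area * centroid[0] * centroid[1]
    return abs(area), centroid, (sxx, syy, sxy, np.sign(area))


def icc21_oracle(x):
    """Definitional two-way ANOVA ICC(2,1): raw sums over cells (loops)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
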