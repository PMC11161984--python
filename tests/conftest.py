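"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from kambin import GeneratorConfig, build_paper_fixture, measure_case

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_cohort():
    """The calibrated 40-case cohort (session-cached; ~1 s to build)."""
    return build_paper_fixture(GeneratorConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def fixture_measurements(fixture_cohort):
    return [measure_case(c) for c in fixture_cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# oracles (independent of the package implementation)
# ---------------------------------------------------------------------------


def incircle_grid_oracle(A, B, C, rounds=8, grid=41):
    """Incircle center and radius by zoomed grid search.

    Maximizes the minimum signed distance to the three edge lines (signed
    positive inside), working in the triangle's own plane.  The zoom
    shrinks gently (x0.35 per round) because for elongated triangles the
    sampled argmax localizes poorly along the flat ridge of the
    min-distance function; 8 rounds put the center well below 0.01 mm for
    triangles tens of mm across.
    """
    A, B, C = (np.asarray(p, float) for p in (A, B, C))
    ex = B - A
    ex = ex / np.linalg.norm(ex)
    n = np.cross(B - A, C - A)
    n = n / np.linalg.norm(n)
    ey = np.cross(n, ex)
    verts = np.array([[0.0, 0.0]] + [
        [np.dot(P - A, ex), np.dot(P - A, ey)] for P in (B, C)
    ])

    # inward edge normals
    edges = []
    for i in range(3):
        p, q = verts[i], verts[(i + 1) % 3]
        t = q - p
        nrm = np.array([-t[1], t[0]])
        nrm = nrm / np.linalg.norm(nrm)
        other = verts[(i + 2) % 3]
        if np.dot(other - p, nrm) < 0:
            nrm = -nrm
        edges.append((p, nrm))

    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    center = (lo + hi) / 2.0
    span = (hi - lo).max()
    best = None
    for _ in range(rounds):
        xs = np.linspace(center[0] - span / 2, center[0] + span / 2, grid)
        ys = np.linspace(center[1] - span / 2, center[1] + span / 2, grid)
        X, Y = np.meshgrid(xs, ys)
        dmin = np.full_like(X, np.inf)
        for p, nrm in edges:
            dmin = np.minimum(dmin, (X - p[0]) * nrm[0] + (Y - p[1]) * nrm[1])
        k = np.unravel_index(np.argmax(dmin), dmin.shape)
        best = (float(X[k]), float(Y[k]), float(dmin[k]))
        center = np.array([best[0], best[1]])
        span *= 0.35
    cx, cy, r = best
    return A + cx * ex + cy * ey, r


def clearance_sampling_oracle(origin, direction, p, q, radius, n=200001):
    """Min distance from a dense sampling of segment pq to the axis, − radius."""
    origin = np.asarray(origin, float)
    t = np.asarray(direction, float)
    t = t / np.linalg.norm(t)
    s = np.linspace(0.0, 1.0, n)[:, None]
    pts = np.asarray(p, float)[None, :] * (1 - s) + np.asarray(q, float)[None, :] * s
    w = pts - origin
    proj = w @ t
    perp = w - proj[:, None] * t
    return float(np.sqrt((perp**2).sum(axis=1)).min()) - radius


def random_rotation(rng):
    """Haar-ish random rotation matrix via QR."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_right_triangle(rng, lo=5.0, hi=40.0, posed=True):
    """Right triangle (right angle at C) with optional random rigid pose."""
    base = rng.uniform(lo, hi)
    height = rng.uniform(lo, hi)
    C = np.zeros(3)
    B = np.array([base, 0.0, 0.0])
    A = np.array([0.0, 0.0, height])
    if posed:
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        A, B, C = (R @ P + t for P in (A, B, C))
    return A, B, C, base, height
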