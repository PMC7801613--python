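"""Finite-difference operators against brute-force loop oracles and the
analytic heat kernel."""

import numpy as np
import pytest

from angiosim.errors import StabilityError
from angiosim.fields import (
    Grid,
    ScalarField,
    VectorField,
    advection,
    clamp_nonnegative,
    laplacian,
    step_field,
)

from conftest import make_field


def loop_laplacian(values, boundary, spacing):
    """Naive triple-loop 7-point stencil with Dirichlet ghosts."""
    n = values.shape[0]
    g = np.full((n + 2, n + 2, n + 2), boundary)
    g[1:-1, 1:-1, 1:-1] = values
    out = np.zeros_like(values)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                ci, cj, ck = i + 1, j + 1, k + 1
                out[i, j, k] = (
                    g[ci + 1, cj, ck] + g[ci - 1, cj, ck]
                    + g[ci, cj + 1, ck] + g[ci, cj - 1, ck]
                    + g[ci, cj, ck + 1] + g[ci, cj, ck - 1]
                    - 6.0 * g[ci, cj, ck]
                ) / spacing ** 2
    return out


def loop_advection(values, u, spacing):
    """Naive upwind evaluation of -div(u f), edge-replicated ghost fluxes."""
    n = values.shape[0]
    out = np.zeros_like(values)
    for axis in range(3):
        flux = u[axis] * values
        for idx in np.ndindex(values.shape):
            lo = list(idx)
            hi = list(idx)
            lo[axis] = max(idx[axis] - 1, 0)
            hi[axis] = min(idx[axis] + 1, n - 1)
            if u[axis][idx] > 0:
                d = (flux[idx] - flux[tuple(lo)]) / spacing
            else:
                d = (flux[tuple(hi)] - flux[idx]) / spacing
            out[idx] -= d
    return out


class TestLaplacian:
    def test_uniform_field_is_harmonic(self, grid7):
        f = make_field(grid7, np.full(grid7.shape, 2.5), boundary=2.5)
        assert np.allclose(laplacian(f, grid7), 0.0)

    def test_unit_spike_stencil(self):
        grid = Grid(5, 5.0, 1.0)
        v = np.zeros(grid.shape)
        v[2, 2, 2] = 1.0
        lap = laplacian(make_field(grid, v), grid)
        assert lap[2, 2, 2] == -6.0
        for off in [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]:
            assert lap[off] == 1.0
        assert lap.sum() == pytest.approx(0.0)

    def test_matches_loop_oracle_on_random_field(self, grid7, rng):
        v = rng.random(grid7.shape)
        f = make_field(grid7, v, boundary=0.3)
        assert np.allclose(laplacian(f, grid7),
                           loop_laplacian(v, 0.3, grid7.spacing), atol=1e-12)


class TestAdvection:
    def test_zero_velocity(self, grid7, rng):
        f = make_field(grid7, rng.random(grid7.shape))
        u = VectorField.zeros(grid7)
        assert np.allclose(advection(f, u, grid7), 0.0)

    def test_uniform_field_uniform_velocity(self, grid7):
        f = make_field(grid7, np.full(grid7.shape, 3.0))
        u = VectorField(np.ones((3,) + grid7.shape))
        out = advection(f, u, grid7)
        interior = out[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 0.0)

    def test_ramp_upwind_value(self, grid7):
        x = np.arange(7, dtype=float)
        v = np.broadcast_to(x[:, None, None], grid7.shape).copy()
        f = make_field(grid7, v)
        comps = np.zeros((3,) + grid7.shape)
        comps[0] = 1.0
        out = advection(f, VectorField(comps), grid7)
        assert np.allclose(out[1:-1, :, :], -1.0)

    def test_matches_loop_oracle_on_random_input(self, grid7, rng):
        v = rng.random(grid7.shape)
        u = rng.standard_normal((3,) + grid7.shape)
        f = make_field(grid7, v)
        out = advection(f, VectorField(u), grid7)
        assert np.allclose(out, loop_advection(v, u, grid7.spacing), atol=1e-12)


class TestStepField:
    def test_uniform_steady_state(self, grid7):
        f = make_field(grid7, np.full(grid7.shape, 1.0), boundary=1.0)
        step_field(f, D=0.1, source=0.0, sink=0.0, u=None, grid=grid7)
        assert np.allclose(f.values, 1.0)

    def test_sink_clamps_at_zero(self, grid7):
        f = make_field(grid7, np.full(grid7.shape, 0.01))
        sink = np.zeros(grid7.shape)
        sink[3, 3, 3] = 100.0
        step_field(f, D=0.0, source=0.0, sink=sink, u=None, grid=grid7)
        assert f.values[3, 3, 3] == 0.0
        assert f.values.min() >= 0.0

    def test_stability_guard(self, grid7):
        f = make_field(grid7)
        with pytest.raises(StabilityError):
            step_field(f, D=1.0, source=0.0, sink=0.0, u=None, grid=grid7)
        step_field(f, D=1.0, source=0.0, sink=0.0, u=None, grid=grid7,
                   allow_unstable=True)

    def test_deterministic(self, grid7, rng):
        v = rng.random(grid7.shape)
        src = rng.random(grid7.shape)
        u = VectorField(0.05 * rng.standard_normal((3,) + grid7.shape))
        f1 = make_field(grid7, v.copy(), boundary=0.2)
        f2 = make_field(grid7, v.copy(), boundary=0.2)
        for _ in range(5):
            step_field(f1, 0.05, src, 0.01, u, grid7)
            step_field(f2, 0.05, src, 0.01, u, grid7)
        assert np.array_equal(f1.values, f2.values)

    def test_dirichlet_faces_after_steps(self, grid7, rng):
        f = make_field(grid7, rng.random(grid7.shape), boundary=0.7)
        for _ in range(4):
            step_field(f, 0.1, rng.random(grid7.shape), 0.0, None, grid7)
        for face in (f.values[0], f.values[-1], f.values[:, 0], f.values[:, -1],
                     f.values[:, :, 0], f.values[:, :, -1]):
            assert np.allclose(face, 0.7)

    def test_matches_heat_kernel(self):
        """Free diffusion of an interior Gaussian matches the analytic
        solution to within 2% (L-inf) before boundary influence."""
        n = 21
        grid = Grid(n, float(n), dt=0.05)
        x = np.arange(n, dtype=float) - n // 2
        r2 = (x[:, None, None] ** 2 + x[None, :, None] ** 2
              + x[None, None, :] ** 2)
        s0 = 2.0
        D = 0.5
        f = make_field(grid, np.exp(-r2 / (2 * s0 ** 2)))
        steps = 40
        for _ in range(steps):
            step_field(f, D, 0.0, 0.0, None, grid)
        t = steps * grid.dt
        s2 = s0 ** 2 + 2 * D * t
        exact = (s0 ** 2 / s2) ** 1.5 * np.exp(-r2 / (2 * s2))
        err = np.abs(f.values - exact).max() / exact.max()
        assert err < 0.02


def test_clamp_nonnegative():
    arr = np.array([-0.2, 0.0, 0.3])
    assert np.array_equal(clamp_nonnegative(arr.copy()), [0.0, 0.0, 0.3])
    pos = np.array([0.1, 0.4])
    assert np.array_equal(clamp_nonnegative(pos.copy()), pos)
    assert np.array_equal(clamp_nonnegative(np.array([-1.0, -2.0])), [0.0, 0.0])


def test_grid_invariants():
    g = Grid(200, 1.0, 1 / 33)
    assert g.spacing == pytest.approx(0.005)
    with pytest.raises(ValueError):
        Grid(2, 1.0, 1 / 33)
    with pytest.raises(ValueError):
        Grid(10, 1.0, -0.1)
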