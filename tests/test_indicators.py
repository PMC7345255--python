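import numpy as np
import pytest

from mesoid.elasticity import ElasticTensor
from mesoid.grids import StrainField, StructuredGrid
from mesoid.indicators import (DispersionStat, corrlen_estimate,
                               dispersion_stat, j_delta, j_ell, j_h, j_macro)
from mesoid.random_field import sample_gaussian_germ


def field(grid, values):
    return StrainField(grid, np.asarray(values, dtype=float))


GRID3 = StructuredGrid((3, 3), (1.0, 1.0))
GRID4 = StructuredGrid((4, 4), (1.0, 1.0))


def test_j_macro_trivial_and_constant_offset(rng):
    a = field(GRID3, rng.standard_normal((9, 3)))
    assert j_macro(a, a) == 0.0
    offset = np.array([0.3, -0.4, 1.2])
    e = np.linalg.norm(offset)
    b = field(GRID3, a.values + offset)
    assert j_macro(a, b) == pytest.approx(e**2, rel=1e-12)


def test_j_macro_hand_summed_oracle(rng):
    a_vals = rng.standard_normal((9, 3))
    b_vals = rng.standard_normal((9, 3))
    oracle = sum(np.sum((a_vals[i] - b_vals[i]) ** 2) for i in range(9)) / 9
    assert j_macro(field(GRID3, a_vals),
                   field(GRID3, b_vals)) == pytest.approx(oracle, rel=1e-12)


def test_j_macro_grid_mismatch():
    a = field(GRID3, np.ones((9, 3)))
    b = field(GRID4, np.ones((16, 3)))
    with pytest.raises(ValueError):
        j_macro(a, b)


def test_j_macro_invariant_under_shared_rigid_motion():
    """Adding the same rigid-body motion to both displacement fields leaves
    the strain-level indicator unchanged."""
    from mesoid.fem import strain_from_displacement
    from mesoid.grids import DisplacementField

    grid = StructuredGrid((6, 6), (0.1, 0.1))
    rng = np.random.default_rng(1)
    u_a = rng.standard_normal((grid.n_nodes, 2)) * 1e-4
    u_b = rng.standard_normal((grid.n_nodes, 2)) * 1e-4
    coords = grid.node_coords()
    rigid = np.stack([0.3 - 2.0 * coords[:, 1], -0.1 + 2.0 * coords[:, 0]],
                     axis=1)
    base = j_macro(strain_from_displacement(grid, DisplacementField(grid, u_a)),
                   strain_from_displacement(grid, DisplacementField(grid, u_b)))
    shifted = j_macro(
        strain_from_displacement(grid, DisplacementField(grid, u_a + rigid)),
        strain_from_displacement(grid, DisplacementField(grid, u_b + rigid)))
    assert shifted == pytest.approx(base, rel=1e-9)


def test_dispersion_stat_constant_field():
    s = dispersion_stat(field(GRID4, np.tile([1.0, 2.0, 0.5], (16, 1))))
    assert s.v == 0.0 and s.d == 0.0


def test_dispersion_stat_two_half_field():
    """Field at mean*(1+c) on one half and mean*(1-c) on the other has
    pseudo-dispersion exactly c."""
    mean = np.array([2.0, -1.0, 0.5])
    c = 0.3
    vals = np.vstack([np.tile(mean * (1 + c), (8, 1)),
                      np.tile(mean * (1 - c), (8, 1))])
    s = dispersion_stat(field(GRID4, vals))
    assert s.d == pytest.approx(c, rel=1e-12)


def test_dispersion_stat_explicit_sum_oracle(rng):
    vals = rng.standard_normal((16, 3)) + np.array([3.0, 0, 0])
    mean = vals.mean(axis=0)
    v = np.mean([np.sum((vals[i] - mean) ** 2) for i in range(16)])
    s = dispersion_stat(field(GRID4, vals))
    assert s.v == pytest.approx(v, rel=1e-12)
    assert s.d == pytest.approx(np.sqrt(v) / np.linalg.norm(mean), rel=1e-12)


def test_dispersion_stat_scale_invariance(rng):
    vals = rng.standard_normal((16, 3)) + np.array([3.0, 0, 0])
    d1 = dispersion_stat(field(GRID4, vals)).d
    d2 = dispersion_stat(field(GRID4, 17.3 * vals)).d
    assert d1 == pytest.approx(d2, rel=1e-12)


def test_dispersion_stat_zero_mean_raises(rng):
    vals = rng.standard_normal((16, 3))
    vals -= vals.mean(axis=0)
    with pytest.raises(ValueError):
        dispersion_stat(field(GRID4, vals))


def test_j_delta_arithmetic():
    exp = DispersionStat(v=0.25, d=0.5)
    stats = [DispersionStat(v=0, d=d) for d in (0.3, 0.4, 0.5)]
    j, _ = j_delta(stats, exp)
    assert j == pytest.approx(0.04, rel=1e-12)
    j, _ = j_delta([DispersionStat(v=0, d=0.5)], exp)
    assert j == 0.0
    j, _ = j_delta([DispersionStat(v=0, d=1.0)], exp)
    assert j == pytest.approx(1.0)
    with pytest.raises(ValueError):
        j_delta(stats, DispersionStat(v=0, d=0.0))


def test_corrlen_white_noise(rng):
    """A cell-wise i.i.d. field decorrelates within ~one cell."""
    grid = StructuredGrid((64, 8), (1.0, 1.0))
    vals = rng.standard_normal((grid.n_cells, 3))
    est = corrlen_estimate(field(grid, vals), axis=0)
    assert est.value <= 2.0
    assert not est.saturated


def test_corrlen_known_kernel(rng):
    """Mean estimate over 60 germ realizations with a known correlation
    length (8 cells) is within 15%."""
    ell = 8.0
    grid = StructuredGrid((256, 1), (1.0, 1.0))
    g = sample_gaussian_germ(grid, (ell, ell), "squared_exponential", rng,
                             n_fields=64)
    sgrid = StructuredGrid((256, 8), (1.0, 1.0))
    ests = []
    for k in range(0, 64, 8):
        lines = g[k:k + 8, :, 0]  # 8 independent lines as a pseudo 2D field
        vals = np.zeros((256 * 8, 3))
        vals[:, 0] = lines.ravel()  # flat index = i + 256*line (F layout)
        ests.append(corrlen_estimate(StrainField(sgrid, vals), axis=0).value)
    assert np.mean(ests) == pytest.approx(ell, rel=0.15)


def test_corrlen_monotone_in_kernel_length(rng):
    grid = StructuredGrid((256, 1), (1.0, 1.0))
    means = []
    for ell in (2.0, 8.0, 32.0):
        g = sample_gaussian_germ(grid, (ell, ell), "squared_exponential",
                                 rng, n_fields=40)
        sgrid = StructuredGrid((256, 8), (1.0, 1.0))
        ests = []
        for k in range(0, 40, 8):
            vals = np.zeros((256 * 8, 3))
            vals[:, 0] = g[k:k + 8, :, 0].ravel()
            ests.append(corrlen_estimate(StrainField(sgrid, vals),
                                         axis=0).value)
        means.append(np.mean(ests))
    assert means[0] < means[1] < means[2]


def test_corrlen_constant_along_axis_saturates():
    grid = StructuredGrid((16, 16), (1.0, 1.0))
    vals = np.zeros((256, 3))
    col = np.arange(16, dtype=float)
    vals[:, 0] = np.repeat(col, 16)  # varies along axis 1, constant along 0
    est = corrlen_estimate(field(grid, vals), axis=0)
    assert est.saturated
    assert est.value == pytest.approx(16.0)


def test_corrlen_too_few_samples():
    grid = StructuredGrid((4, 8), (1.0, 1.0))
    with pytest.raises(ValueError):
        corrlen_estimate(field(grid, np.ones((32, 3))), axis=0)


def test_j_ell_arithmetic():
    exp = np.array([1.0, 1.0])
    assert j_ell(np.array([[1.0, 1.0]]), exp)[0] == 0.0
    j, _ = j_ell(np.array([[1.1, 1.0]]), exp)
    assert j == pytest.approx(0.01, rel=1e-10)
    j, _ = j_ell(np.array([[1.1, 0.8]]), exp)
    assert j == pytest.approx(0.05, rel=1e-10)
    with pytest.raises(ValueError):
        j_ell(np.array([[1.0, 1.0]]), np.array([1.0, 0.0]))
    with pytest.raises(ValueError):
        j_ell(np.array([[1.0]]), np.array([1.0, 1.0]))


def test_j_h_arithmetic(rng):
    base = rng.standard_normal((3, 3))
    m = ElasticTensor(base @ base.T + 3 * np.eye(3), kind="stiffness",
                      form="plane2d")
    assert j_h(m, m) == 0.0
    double = ElasticTensor(2 * m.kelvin, kind="stiffness", form="plane2d")
    assert j_h(double, m) == pytest.approx(1.0, rel=1e-12)
    pert = m.kelvin.copy()
    pert[0, 1] += 0.05
    pert[1, 0] += 0.05
    p = ElasticTensor(pert, kind="stiffness", form="plane2d")
    expect = (np.sqrt(2 * 0.05**2) / np.linalg.norm(m.kelvin)) ** 2
    assert j_h(p, m) == pytest.approx(expect, rel=1e-12)
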