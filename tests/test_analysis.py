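"""Ensemble analytics: superposition, domain angles, fields, fluctuations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kgsample import analysis
from kgsample.analysis import (DisplacementField, breathing_angle,
                               circular_rmsf, displacement_angle_distribution,
                               dof_rmsf, landscape_histogram, mean_displacement,
                               opening_angle, superpose, zenith_azimuth)


@pytest.fixture
def cloud():
    rng = np.random.default_rng(0)
    return rng.normal(size=(40, 3)) * 5.0


# -- superposition ----------------------------------------------------------

def test_superpose_identity(cloud):
    R, t, rmsd = superpose(cloud, cloud)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t, 0.0, atol=1e-12)
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_superpose_recovers_translation(cloud):
    shift = np.array([3.0, -2.0, 7.5])
    R, t, rmsd = superpose(cloud + shift, cloud)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(t, -shift, atol=1e-10)
    assert rmsd < 1e-10


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_superpose_recovers_constructed_rotation(cloud, seed):
    rot = Rotation.random(rng=np.random.default_rng(seed))
    moved = cloud @ rot.as_matrix().T + np.array([1.0, 2.0, 3.0])
    R, t, rmsd = superpose(moved, cloud)
    err = Rotation.from_matrix(R @ rot.as_matrix()).magnitude()
    assert err < 1e-9
    assert rmsd < 1e-9
    np.testing.assert_allclose(analysis.apply_transform(moved, R, t), cloud,
                               atol=1e-9)


def test_superpose_rejects_degenerate_input(cloud):
    with pytest.raises(ValueError, match="mismatch"):
        superpose(cloud[:5], cloud[:6])
    line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="degenerate|collinear"):
        superpose(line, line)


# -- domain angles ----------------------------------------------------------

def _two_blobs():
    rng = np.random.default_rng(5)
    stable = rng.normal(size=(20, 3)) + [0.0, 0.0, 0.0]
    mobile = rng.normal(size=(20, 3)) + [12.0, 0.0, 0.0]
    coords = np.vstack([stable, mobile])
    return coords, np.arange(20), np.arange(20, 40)


def test_opening_angle_zero_for_reference():
    coords, s, m = _two_blobs()
    assert opening_angle(coords, coords, s, m) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("angle", [1.0, 25.0, 60.0, 90.0])
def test_opening_angle_recovers_programmed_rotation(angle):
    coords, s, m = _two_blobs()
    com_s = coords[s].mean(axis=0)
    v = coords[m].mean(axis=0) - com_s
    axis = np.cross(v, [0.0, 0.0, 1.0])  # perpendicular to the COM line
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    rotated = coords.copy()
    rotated[m] = (coords[m] - com_s) @ R.T + com_s
    got = opening_angle(rotated, coords, s, m)
    assert got == pytest.approx(angle, abs=1e-6)


def test_opening_angle_invariant_under_global_transform():
    coords, s, m = _two_blobs()
    com_s = coords[s].mean(axis=0)
    v = coords[m].mean(axis=0) - com_s
    axis = np.cross(v, [0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    R25 = Rotation.from_rotvec(np.radians(25.0) * axis).as_matrix()
    sample = coords.copy()
    sample[m] = (coords[m] - com_s) @ R25.T + com_s
    g = Rotation.random(rng=np.random.default_rng(8)).as_matrix()
    shift = np.array([5.0, 6.0, 7.0])
    assert opening_angle(sample @ g.T + shift, coords, s, m) == \
        pytest.approx(25.0, abs=1e-6)
    assert opening_angle(sample, coords @ g.T + shift, s, m) == \
        pytest.approx(25.0, abs=1e-6)


def test_zenith_azimuth_reference_is_polar():
    coords, d1, d2 = _two_blobs()
    theta, phi = zenith_azimuth(coords, coords, d1, d2)
    assert theta == pytest.approx(0.0, abs=1e-6)
    assert phi == 0.0


@pytest.mark.parametrize("target", [(10.0, 30.0), (45.0, 200.0), (90.0, 359.0)])
def test_zenith_azimuth_recovers_constructed_direction(target):
    theta_t, phi_t = target
    coords, d1, d2 = _two_blobs()
    # rotate the reference so the interdomain axis is +z, then move domain 2
    # to the target spherical direction
    v = coords[d2].mean(axis=0) - coords[d1].mean(axis=0)
    rot, _ = Rotation.align_vectors([[0, 0, 1]], [v / np.linalg.norm(v)])
    ref_z = coords @ rot.as_matrix().T
    com1 = ref_z[d1].mean(axis=0)
    r = np.linalg.norm(ref_z[d2].mean(axis=0) - com1)
    th, ph = np.radians(theta_t), np.radians(phi_t)
    direction = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                          np.cos(th)])
    sample = ref_z.copy()
    sample[d2] = ref_z[d2] - ref_z[d2].mean(axis=0) + com1 + r * direction
    theta, phi = zenith_azimuth(sample, coords, d1, d2)
    assert theta == pytest.approx(theta_t, abs=1e-6)
    assert phi % 360.0 == pytest.approx(phi_t % 360.0, abs=1e-6)


def test_breathing_angle_constructions():
    a = np.array([[1.0, 0.0, 0.0]])
    b = np.array([[0.0, 0.0, 0.0]])
    c_straight = np.array([[-1.0, 0.0, 0.0]])
    c_right = np.array([[0.0, 1.0, 0.0]])
    sel = np.array([0])
    assert breathing_angle(np.vstack([a, b, c_straight]), sel, sel + 1, sel + 2) \
        == pytest.approx(180.0)
    assert breathing_angle(np.vstack([a, b, c_right]), sel, sel + 1, sel + 2) \
        == pytest.approx(90.0)


def test_breathing_angle_linear_in_small_arc_perturbation():
    sel = np.array([0])
    base = 90.0
    for delta in (0.5, 2.0):
        th = np.radians(base + delta)
        pts = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0],
                        [np.cos(th), np.sin(th), 0.0]])
        got = breathing_angle(pts, sel, sel + 1, sel + 2)
        assert got == pytest.approx(base + delta, abs=1e-9)


# -- landscapes -------------------------------------------------------------

def test_histogram_single_point_and_conservation():
    counts, ex, ey, neglog = landscape_histogram([3.2], [1.07])
    assert counts.sum() == 1 and (counts == 1).sum() == 1
    assert neglog[counts == 1] == pytest.approx(0.0)
    rng = np.random.default_rng(2)
    x, y = rng.uniform(0, 10, 5000), rng.uniform(0, 2, 5000)
    counts, *_ = landscape_histogram(x, y)
    assert counts.sum() == 5000


def test_histogram_uniform_within_poisson():
    rng = np.random.default_rng(3)
    n, nx, ny = 40000, 10, 10
    x = rng.uniform(0, nx * 0.5, n)
    y = rng.uniform(0, ny * 0.1, n)
    counts, *_ = landscape_histogram(x, y)
    expected = n / (nx * ny)
    assert np.abs(counts - expected).max() < 4 * np.sqrt(expected)


def test_histogram_rejects_bad_bins():
    with pytest.raises(ValueError):
        landscape_histogram([1.0], [1.0], bin_x=0.0)


# -- displacement fields ----------------------------------------------------

def _field_setup():
    rng = np.random.default_rng(6)
    ref = rng.normal(size=(30, 3)) * 4.0
    align = np.arange(10)
    report = np.arange(10, 30)
    residues = np.arange(11, 31)
    return ref, align, report, residues


def test_mean_displacement_zero_for_reference_ensemble():
    ref, align, report, residues = _field_setup()
    field = mean_displacement([ref, ref], ref, align, report, residues)
    np.testing.assert_allclose(field.vectors, 0.0, atol=1e-12)


def test_mean_displacement_averages_and_cancels():
    ref, align, report, residues = _field_setup()
    v = np.array([0.3, -0.1, 0.2])
    plus, minus, triple = ref.copy(), ref.copy(), ref.copy()
    plus[report] += v
    minus[report] -= v
    triple[report] += 3 * v
    cancel = mean_displacement([plus, minus], ref, align, report, residues)
    np.testing.assert_allclose(cancel.vectors, 0.0, atol=1e-9)
    mean = mean_displacement([plus, triple], ref, align, report, residues)
    np.testing.assert_allclose(mean.vectors, np.tile(2 * v, (20, 1)), atol=1e-9)
    normed = mean_displacement([plus, triple], ref, align, report, residues,
                               normalize=True)
    assert normed.magnitudes.max() == pytest.approx(1.0)


def test_displacement_angle_distribution_constructions():
    residues = np.arange(5)
    vecs = np.tile([1.0, 0.0, 0.0], (5, 1))
    f = DisplacementField(residues, vecs)
    _, angles, _ = displacement_angle_distribution(f, f)
    np.testing.assert_allclose(angles, 0.0, atol=1e-12)
    _, angles, _ = displacement_angle_distribution(
        f, DisplacementField(residues, -vecs))
    np.testing.assert_allclose(angles, 180.0, atol=1e-9)
    th = np.radians(57.6)
    rotated = np.tile([np.cos(th), np.sin(th), 0.0], (5, 1))
    _, angles, _ = displacement_angle_distribution(
        f, DisplacementField(residues, rotated))
    np.testing.assert_allclose(angles, 57.6, atol=1e-9)
    # near-zero vectors excluded and reported
    tiny = vecs.copy()
    tiny[2] = 1e-12
    res, angles, excluded = displacement_angle_distribution(
        f, DisplacementField(residues, tiny))
    assert excluded == [2] and len(res) == 4


# -- dihedral fluctuations --------------------------------------------------

def test_circular_rmsf_wrap_safe():
    angles = np.radians([359.0, 1.0])
    assert circular_rmsf(angles)[0] == pytest.approx(1.0, abs=1e-9)


def test_circular_rmsf_matches_linear_std_for_small_fluctuations():
    rng = np.random.default_rng(4)
    a = rng.normal(0.7, np.radians(2.0), size=20000)
    circ = circular_rmsf(a)[0]
    lin = np.degrees(np.std(a))
    assert abs(circ - lin) / lin < 1e-3


def test_dof_rmsf_constant_dof_and_subset_means():
    q = np.zeros((50, 3))
    q[:, 1] = np.radians(np.linspace(-5, 5, 50))
    q[:, 2] = np.radians(178.0)  # constant, near the wrap point
    fluct = dof_rmsf(q, ["free", "cycle", "cycle"], rigid_ids=[2])
    assert fluct.rmsf[0] == 0.0
    assert fluct.rmsf[2] == pytest.approx(0.0, abs=1e-9)
    assert fluct.mean_free == 0.0
    assert fluct.mean_mobile_cycle == pytest.approx(fluct.rmsf[1])
    assert fluct.mean_cycle == pytest.approx(
        (fluct.rmsf[1] + fluct.rmsf[2]) / 2)


def test_dof_rmsf_single_sample_warns():
    with pytest.warns(UserWarning, match="single-sample"):
        fluct = dof_rmsf(np.zeros((1, 4)), ["free"] * 4)
    assert np.all(fluct.rmsf == 0.0)
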