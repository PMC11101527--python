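import numpy as np
import pytest

from dermafiber.orientation3d import (OrientationField, directional_summary,
                                      estimate_orientation, fold_angle,
                                      layer_histograms,
                                      polar_from_projections)
from dermafiber.stack_io import ImageStack


def literal_center_of_mass(theta_deg, beta_deg, gamma_deg, phi_deg):
    """Term-by-term evaluation of the axial center-of-mass sums.

    Independent oracle: uses b_j = sqrt(1/tan²β + 1/tan²γ) and the sign-index
    rule literally, voxel by voxel, instead of the sin/cos shortcut.
    """
    n = len(theta_deg)
    C = S = Z = 0.0
    for t, b, g, p in zip(theta_deg, beta_deg, gamma_deg, phi_deg):
        tb, tg = np.tan(np.radians(b)), np.tan(np.radians(g))
        bj = np.sqrt(1.0 / tb**2 + 1.0 / tg**2)
        si = 1.0 if p == 90 else -(p - 90.0) / abs(p - 90.0)
        C += (bj / np.sqrt(1 + bj**2)) * np.cos(2 * np.radians(t))
        S += (bj / np.sqrt(1 + bj**2)) * np.sin(2 * np.radians(t))
        Z += si / np.sqrt(1 + bj**2)
    return C / n, S / n, Z / n


def circular_mean_axial(theta_deg):
    return np.degrees(0.5 * np.angle(np.mean(np.exp(2j * np.radians(theta_deg))))) % 180


@pytest.mark.parametrize("beta, gamma, expected", [
    (90.0, 90.0, 0.0),           # both projections along z
    (45.0, 90.0, 45.0),          # single-plane tilt: tan²φ = 1
    (45.0, 45.0, 54.7356103),    # arctan(sqrt 2)
    (0.0, 30.0, 90.0),           # any in-plane projection forces φ = 90
])
def test_polar_from_projections(beta, gamma, expected):
    assert polar_from_projections(beta, gamma) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize("theta, expected", [(135.0, 45.0), (90.0, 90.0),
                                             (27.0, 27.0), (0.0, 0.0)])
def test_fold_angle(theta, expected):
    assert fold_angle(theta) == expected


def test_fold_angle_rejects_out_of_range():
    with pytest.raises(ValueError):
        fold_angle(180.0)


def test_summary_identical_orientations():
    s = directional_summary(np.full(1000, 30.0), np.full(1000, 90.0))
    assert s.c_bar == pytest.approx(0.5, abs=1e-12)
    assert s.s_bar == pytest.approx(np.sin(np.radians(60)), abs=1e-12)
    assert s.z_bar == pytest.approx(0.0, abs=1e-12)
    assert s.oi3d == pytest.approx(1.0, abs=1e-12)
    assert s.main_theta == pytest.approx(30.0, abs=1e-9)
    assert s.main_phi == pytest.approx(90.0, abs=1e-9)


def test_summary_along_z_axis():
    s = directional_summary(np.zeros(5), np.zeros(5))
    assert (s.c_bar, s.s_bar) == (0.0, 0.0)
    assert s.z_bar == pytest.approx(1.0)
    assert s.oi3d == pytest.approx(1.0)


def test_summary_perpendicular_axial_pair_cancels():
    s = directional_summary(np.array([0.0, 90.0]), np.array([90.0, 90.0]))
    assert s.oi3d == pytest.approx(0.0, abs=1e-12)


def test_summary_matches_literal_oracle(rng):
    # random fields of <= 100 voxels; phi away from {0,90} so tan is finite
    for _ in range(5):
        n = rng.integers(5, 100)
        theta = rng.uniform(0, 180, n)
        phi = rng.uniform(5, 85, n)
        # build consistent beta/gamma from the direction vector
        t, p = np.radians(theta), np.radians(phi)
        dx, dy, dz = np.sin(p) * np.cos(t), np.sin(p) * np.sin(t), np.cos(p)
        beta = np.degrees(np.arctan2(dz, dx)) % 180
        gamma = np.degrees(np.arctan2(dz, dy)) % 180
        C, S, Z = literal_center_of_mass(theta, beta, gamma, phi)
        s = directional_summary(theta, phi)
        assert s.c_bar == pytest.approx(C, abs=1e-10)
        assert s.s_bar == pytest.approx(S, abs=1e-10)
        assert abs(s.z_bar) == pytest.approx(abs(Z), abs=1e-10)


def test_summary_invariant_to_ordering_and_duplication(rng):
    theta = rng.uniform(0, 180, 50)
    phi = rng.uniform(30, 90, 50)
    s1 = directional_summary(theta, phi)
    perm = rng.permutation(50)
    s2 = directional_summary(theta[perm], phi[perm])
    s3 = directional_summary(np.tile(theta, 3), np.tile(phi, 3))
    for s in (s2, s3):
        assert s.oi3d == pytest.approx(s1.oi3d, abs=1e-12)
        assert s.main_theta == pytest.approx(s1.main_theta, abs=1e-9)


def test_summary_rotation_equivariance(rng):
    theta = rng.uniform(0, 180, 200)
    phi = np.full(200, 90.0)
    s1 = directional_summary(theta, phi)
    delta = 37.0
    s2 = directional_summary((theta + delta) % 180, phi)
    assert s2.oi3d == pytest.approx(s1.oi3d, abs=1e-12)
    assert s2.main_theta % 180 == pytest.approx((s1.main_theta + delta) % 180,
                                                abs=1e-6)


def test_uniform_random_orientations_have_low_oi3d(rng):
    # uniform axial directions on the sphere
    n = 20000
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 180
    phi = np.degrees(np.arccos(np.clip(v[:, 2], -1, 1)))  # polar angle from z
    s = directional_summary(theta, phi)
    assert s.oi3d < 0.05


def test_estimate_orientation_validates_inputs():
    with pytest.raises(ValueError):
        estimate_orientation(ImageStack(np.ones((5, 5, 5))), window_size=11)
    with pytest.raises(ValueError):
        estimate_orientation(ImageStack(np.ones((16, 16, 16))), window_size=4)
    with pytest.warns(UserWarning, match="all-zero"):
        field = estimate_orientation(ImageStack(np.zeros((16, 16, 16))))
    assert field.n_valid == 0


def test_parallel_tubes_recover_theta_and_phi(parallel_tube_phantom):
    stack, truth = parallel_tube_phantom
    field = estimate_orientation(stack)
    assert field.n_valid > 1000
    theta = field.theta[field.valid]
    mean_theta = circular_mean_axial(theta)
    assert min(mean_theta, 180 - mean_theta) < 3.0
    assert abs(field.phi[field.valid].mean() - 90.0) < 5.0


def test_single_tube_at_45_degrees():
    from dermafiber.synthetic_data import FiberPhantomSpec, gen_fiber_stack
    from dermafiber.vonmises import VonMisesMixture

    spec = FiberPhantomSpec(
        shape=(16, 64, 64),
        theta_mixture=VonMisesMixture(b=0, w=1.0, alpha1=45.0, a1=500.0,
                                      alpha2=135.0, a2=500.0),
        phi_concentration=500.0, target_fill=0.02, noise_sd=0.0, seed=5)
    stack, truth = gen_fiber_stack(spec)
    field = estimate_orientation(stack)
    on_fiber = field.valid & (truth["labels"] > 0)
    theta = field.theta[on_fiber]
    assert abs(circular_mean_axial(theta) - 45.0) < 3.0
    dev = np.minimum(np.abs(theta - 45.0), 180 - np.abs(theta - 45.0))
    assert np.median(dev) < 3.0


def test_noise_stack_is_disordered(rng):
    vox = rng.uniform(0, 1, size=(26, 48, 48))
    field = estimate_orientation(ImageStack(vox))
    above = (vox > 0.45 * vox.mean()).mean()
    interior = (26 - 10) * (48 - 10) * (48 - 10)
    assert field.n_valid > 1e4
    assert field.n_valid / interior == pytest.approx(above, abs=0.1)
    s = directional_summary(field)
    assert s.oi3d < 0.05


def test_layer_histograms_delta_and_normalization():
    theta = np.full((4, 8, 8), 45.2)
    valid = np.ones_like(theta, dtype=bool)
    valid[2] = False  # one empty layer
    field = OrientationField(theta, np.full_like(theta, 90.0), valid)
    hist = layer_histograms(field)
    assert hist.empty_layers.tolist() == [False, False, True, False]
    for z in (0, 1, 3):
        row = hist.per_layer[z]
        assert row.sum() == pytest.approx(1.0)
        assert row[45] == pytest.approx(1.0)  # bin (45, 46]
    assert hist.aggregate.sum() == pytest.approx(1.0)


def test_two_family_histogram_bimodal(two_family_phantom):
    stack, _ = two_family_phantom
    field = estimate_orientation(stack)
    hist = layer_histograms(field)
    agg = hist.aggregate
    centers = hist.bin_centers
    m1 = agg[(centers > 25) & (centers < 65)].sum()
    m2 = agg[(centers > 115) & (centers < 155)].sum()
    rest = 1.0 - m1 - m2
    assert m1 > rest / 2 and m2 > rest / 2
    peak1 = centers[(centers > 25) & (centers < 65)][
        np.argmax(agg[(centers > 25) & (centers < 65)])]
    assert abs(peak1 - 45) < 12


def test_rotating_stack_shifts_histogram(two_family_phantom):
    stack, _ = two_family_phantom
    field = estimate_orientation(stack)
    agg = layer_histograms(field).aggregate
    rot = ImageStack(np.rot90(stack.voxels, k=1, axes=(1, 2)).copy())
    field_r = estimate_orientation(rot)
    agg_r = layer_histograms(field_r).aggregate
    # in-plane 90-degree rotation shifts every theta by 90 (mod 180)
    shifted = np.roll(agg, 90)
    overlap = np.minimum(agg_r, shifted).sum()
    assert overlap > 0.75
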