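import math

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt
from skimage.feature import hessian_matrix

import vesselac as va
from vesselac.vesselness import (
    HessianField,
    VesselnessField,
    eigen2x2,
    hessian_at_scale,
    multiscale_vesselness,
    vesselness_response,
    vvf_direction,
    vvf_force,
    vvf_speed,
)

FULL_SCALES = [1.0, 1.5, 2.0, 3.0, 4.0, 5.0]


class TestHessian:
    def test_flat_image(self):
        h = hessian_at_scale(np.full((20, 20), 0.3), 1.5)
        assert np.allclose(h.hrr, 0) and np.allclose(h.hrc, 0) and np.allclose(h.hcc, 0)

    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_quadratic_normalized_response(self, sigma):
        """I = c^2 has exact second derivative 2; times sigma^2 normalization."""
        cols = np.arange(40, dtype=float)
        image = np.tile(cols**2, (40, 1))
        h = hessian_at_scale(image, sigma)
        interior = h.hcc[15:25, 15:25]
        assert np.allclose(interior, 2.0 * sigma**2, rtol=1e-6)
        assert np.allclose(h.hrr[15:25, 15:25], 0.0, atol=1e-8)

    def test_cross_check_against_skimage(self, rng):
        """Independent derivative-of-Gaussian implementation agrees."""
        image = rng.uniform(0, 1, (40, 40))
        sigma = 2.0
        h = hessian_at_scale(image, sigma)
        hrr, hrc, hcc = hessian_matrix(
            image, sigma=sigma, order="rc", use_gaussian_derivatives=True, mode="nearest"
        )
        # small differences expected: our kernels correct the discrete
        # moments (zero DC, exact monomial response); skimage uses the raw
        # sampled derivatives
        s2 = sigma * sigma
        inner = (slice(6, -6),) * 2
        assert np.allclose(h.hrr[inner], hrr[inner] * s2, atol=5e-4)
        assert np.allclose(h.hrc[inner], hrc[inner] * s2, atol=5e-4)
        assert np.allclose(h.hcc[inner], hcc[inner] * s2, atol=5e-4)

    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((5, 5)), 0.0)


class TestEigen2x2:
    def test_diagonal(self):
        h = HessianField(
            hrr=np.full((1, 1), -1.0), hrc=np.zeros((1, 1)), hcc=np.full((1, 1), -10.0)
        )
        lam1, lam2, v1 = eigen2x2(h)
        assert lam1[0, 0] == pytest.approx(-1.0)
        assert lam2[0, 0] == pytest.approx(-10.0)
        assert abs(v1[0, 0, 0]) == pytest.approx(1.0)  # row axis
        assert v1[0, 0, 1] == pytest.approx(0.0)

    def test_zero_matrix_convention(self):
        h = HessianField(hrr=np.zeros((2, 2)), hrc=np.zeros((2, 2)), hcc=np.zeros((2, 2)))
        lam1, lam2, v1 = eigen2x2(h)
        assert np.all(lam1 == 0) and np.all(lam2 == 0)
        assert np.allclose(v1[..., 0], 1.0) and np.allclose(v1[..., 1], 0.0)

    def test_reconstruction(self, rng):
        """V Lambda V^T reproduces 1000 random symmetric matrices."""
        a = rng.normal(size=(25, 40))
        b = rng.normal(size=(25, 40))
        c = rng.normal(size=(25, 40))
        h = HessianField(hrr=a, hrc=b, hcc=c)
        lam1, lam2, v1 = eigen2x2(h)
        assert np.all(np.abs(lam1) <= np.abs(lam2) + 1e-12)
        v2 = np.stack([-v1[..., 1], v1[..., 0]], axis=-1)  # perpendicular
        rec_rr = lam1 * v1[..., 0] ** 2 + lam2 * v2[..., 0] ** 2
        rec_rc = lam1 * v1[..., 0] * v1[..., 1] + lam2 * v2[..., 0] * v2[..., 1]
        rec_cc = lam1 * v1[..., 1] ** 2 + lam2 * v2[..., 1] ** 2
        assert np.max(np.abs(rec_rr - a)) < 1e-10
        assert np.max(np.abs(rec_rc - b)) < 1e-10
        assert np.max(np.abs(rec_cc - c)) < 1e-10


class TestVesselnessResponse:
    def test_positive_lam2_is_zero(self):
        assert vesselness_response(0.5, 3.0, 0.5, 1.0) == 0.0

    def test_zero_eigenvalues_zero(self):
        assert vesselness_response(0.0, 0.0, 0.5, 1.0) == 0.0

    @pytest.mark.parametrize("L", [0.1, 1.0, 10.0])
    def test_pure_ridge_closed_form(self, L):
        expected = 1.0 - math.exp(-(L * L) / 2.0)
        assert vesselness_response(0.0, -L, 0.5, 1.0) == pytest.approx(expected)

    def test_in_unit_interval(self, rng):
        lam2 = -np.abs(rng.normal(size=500))
        lam1 = lam2 * rng.uniform(-1, 1, 500)
        r = vesselness_response(lam1, lam2, 0.5, 0.7)
        assert np.all((r >= 0) & (r <= 1))

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            vesselness_response(5.0, -1.0, 0.5, 1.0)


class TestMultiscale:
    def test_single_scale_identity(self, tube_phantom_clean):
        image = tube_phantom_clean.image
        multi = multiscale_vesselness(image, scales=[2.0])
        h = hessian_at_scale(image, 2.0)
        lam1, lam2, _ = eigen2x2(h)
        s_max = float(np.hypot(lam1, lam2).max())
        single = vesselness_response(lam1, lam2, 0.5, 0.5 * s_max)
        assert np.allclose(multi.R, single)

    def test_max_dominates_each_scale(self, tube_phantom_clean):
        image = tube_phantom_clean.image
        multi = multiscale_vesselness(image, scales=FULL_SCALES)
        # per-scale responses evaluated with the same shared contrast gate
        for s in FULL_SCALES:
            sub = multiscale_vesselness(image, scales=[s], beta=multi_beta(multi, image))
            assert np.all(multi.R >= sub.R - 1e-12)

    def test_wider_bar_selects_larger_scale(self):
        spec = va.PhantomSpec(
            height=80,
            width=120,
            branches=(
                va.Branch(points=((20.0, 10.0), (20.0, 110.0)), half_width=1.5, intensity=1.0),
                va.Branch(points=((55.0, 10.0), (55.0, 110.0)), half_width=4.5, intensity=1.0),
            ),
            noise_fraction=0.0,
            seed=0,
        )
        ph = va.render_phantom(spec)
        vess = multiscale_vesselness(ph.image, scales=FULL_SCALES)
        narrow = np.median(vess.best_scale[20, 20:100])
        wide = np.median(vess.best_scale[55, 20:100])
        assert wide > narrow

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            multiscale_vesselness(np.zeros((10, 10)), scales=[])

    def test_r_in_unit_interval(self, tube_phantom):
        vess = multiscale_vesselness(tube_phantom.image)
        assert vess.R.min() >= 0 and vess.R.max() <= 1
        lengths = np.linalg.norm(vess.v1[vess.R > 0], axis=-1)
        assert np.allclose(lengths, 1.0, atol=1e-12)


def multi_beta(multi: VesselnessField, image) -> float:
    """Recover the shared beta the multiscale sweep used (half of max S)."""
    s_max = 0.0
    for s in FULL_SCALES:
        lam1, lam2, _ = eigen2x2(hessian_at_scale(image, s))
        s_max = max(s_max, float(np.hypot(lam1, lam2).max()))
    return 0.5 * s_max


class TestTubeBehavior:
    def test_centerline_bright_background_dark(self, tube_phantom):
        vess = multiscale_vesselness(tube_phantom.image, scales=FULL_SCALES)
        cl = tuple(tube_phantom.centerline.T)
        assert np.median(vess.R[cl]) > 0.5
        far = distance_transform_edt(~tube_phantom.mask) >= 10
        assert np.median(vess.R[far]) < 0.05

    def test_direction_follows_tube_axis(self, tube_phantom_clean):
        vess = multiscale_vesselness(tube_phantom_clean.image, scales=FULL_SCALES)
        cl = tuple(tube_phantom_clean.centerline.T)
        v1 = vess.v1[cl]
        angles = np.degrees(np.arccos(np.clip(np.abs(v1[:, 1]), 0, 1)))
        assert np.mean(angles < 10.0) >= 0.9


class TestVVF:
    def _field(self, R, v1):
        return VesselnessField(
            R=np.asarray(R, float),
            best_scale=np.ones_like(np.asarray(R, float)),
            v1=np.asarray(v1, float),
            params={},
        )

    def test_below_threshold_zeroed(self):
        vess = self._field([[0.04]], [[[0.0, 1.0]]])
        V = vvf_direction(vess, (np.array([[0.3]]), np.array([[0.0]])), tau=0.05)
        assert np.all(V == 0)

    def test_aligned_kept_antialigned_flipped(self):
        vess = self._field([[0.2, 0.2]], [[[1.0, 0.0], [1.0, 0.0]]])
        grad_phi = (np.array([[0.3, -0.3]]), np.array([[0.0, 0.0]]))
        V = vvf_direction(vess, grad_phi, tau=0.05)
        assert np.allclose(V[0, 0], [1.0, 0.0])
        assert np.allclose(V[0, 1], [-1.0, 0.0])

    @pytest.mark.parametrize(
        "R, eps_v, expected",
        [
            (0.05, 0.05, 0.5),  # arctan(0)
            (0.0, 0.05, 0.25),  # arctan(-1) = -pi/4
            (1.0, 0.05, 0.5 * (1 + 2 / math.pi * math.atan(19.0))),  # ~0.98325
        ],
    )
    def test_speed_values(self, R, eps_v, expected):
        assert vvf_speed(R, eps_v) == pytest.approx(expected, abs=1e-12)

    def test_speed_monotone(self):
        r = np.linspace(0, 1, 101)
        f = vvf_speed(r, 0.05)
        assert np.all(np.diff(f) > 0)

    def test_speed_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            vvf_speed(0.5, 0.0)

    def test_force_zero_cases_and_product(self):
        grad_phi = (np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        V = np.array([[[0.0, 0.0], [1.0, 0.0]]])  # zero vector; perpendicular
        f = vvf_force(V, np.array([[1.0, 1.0]]), grad_phi, lam_vvf=-0.1)
        assert f[0, 0] == 0.0 and f[0, 1] == 0.0
        V2 = np.array([[[1.0, 0.0]]])
        f2 = vvf_force(V2, np.array([[1.0]]), (np.array([[2.0]]), np.array([[0.0]])), -0.1)
        assert f2[0, 0] == pytest.approx(-0.2)
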