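"""Ramp removal, derivatives, vertical/horizontal alignment, QC, weights."""
import numpy as np
import pytest

from cryopxct import align as al
from cryopxct import phantom as ph


@pytest.fixture(scope="module")
def desk_sinogram():
    """Clean 90-angle derivative sinogram of a structured phantom."""
    spec = ph.PhantomSpec()
    phan = ph.build_phantom(spec, seed=21)
    lam = 1.99975e-10
    angles = np.arange(0, 180, 2.0)
    stack = np.stack(
        [
            al.phase_derivative(
                ph.ground_truth_projection(phan, float(a), lam).transmission
            )
            for a in angles
        ]
    )
    return stack, angles, phan


def _gauge_removed_rmse(err: np.ndarray, angles: np.ndarray) -> float:
    """RMSE of shift errors modulo the translational gauge A·cosθ+B·sinθ+c."""
    th = np.deg2rad(angles)
    basis = np.stack([np.cos(th), np.sin(th), np.ones(len(th))], axis=1)
    coef, *_ = np.linalg.lstsq(basis, err, rcond=None)
    r = err - basis @ coef
    return float(np.sqrt(np.mean(r**2)))


class TestRemoveRamp:
    def _mask(self, h, w, edge=6):
        m = np.zeros((h, w), bool)
        m[:, :edge] = m[:, -edge:] = True
        return m

    def test_pure_plane_maps_to_zero(self):
        yy, xx = np.mgrid[0:32, 0:48].astype(float)
        plane = 0.3 + 0.02 * xx - 0.01 * yy
        out = al.remove_ramp(plane, self._mask(32, 48))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_inject_recover(self, desk_sinogram):
        stack, _, _ = desk_sinogram
        phase = al.integrate_derivative(stack[5])
        h, w = phase.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        mask = self._mask(h, w)
        clean = al.remove_ramp(phase, mask)
        ramped = clean + 0.5 + 0.01 * xx + 0.004 * yy
        rec = al.remove_ramp(ramped, mask)
        assert np.sqrt(np.mean((rec - clean)[mask] ** 2)) < 1e-6

    def test_idempotent(self, desk_sinogram):
        stack, _, _ = desk_sinogram
        phase = al.integrate_derivative(stack[0])
        mask = self._mask(*phase.shape)
        once = al.remove_ramp(phase, mask)
        twice = al.remove_ramp(once, mask)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            al.remove_ramp(np.zeros((8, 8)), np.zeros((8, 8), bool))


class TestPhaseDerivative:
    def test_constant_phase_zero(self):
        t = np.full((4, 16), np.exp(1j * 0.3))
        assert np.abs(al.phase_derivative(t)).max() < 1e-12

    def test_linear_phase_exact(self):
        x = np.arange(32.0)
        t = np.exp(1j * 0.1 * x)[None].repeat(3, 0)
        d = al.phase_derivative(t)
        np.testing.assert_allclose(d[:, :-1], 0.1, atol=1e-12)

    def test_2pi_jump_invisible(self):
        phase = np.zeros((2, 10))
        phase[:, 5:] = 2 * np.pi  # true step of exactly 2π
        d = al.phase_derivative(np.exp(1j * phase))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_integration_inverts_derivative(self):
        rng = np.random.default_rng(0)
        phase = np.cumsum(rng.uniform(-1, 1, (3, 20)), axis=1)
        phase -= phase[:, :1]
        d = al.phase_derivative(np.exp(1j * phase))
        np.testing.assert_allclose(al.integrate_derivative(d), phase, atol=1e-9)


class TestVerticalAlign:
    def test_unshifted_gives_zero(self, desk_sinogram):
        stack, _, _ = desk_sinogram
        dy, _ = al.vertical_align(stack)
        assert np.abs(dy).max() < 0.02

    def test_inject_recover(self, desk_sinogram):
        stack, _, _ = desk_sinogram
        rng = np.random.default_rng(3)
        dy_true = rng.uniform(-3, 3, len(stack))
        dy_true -= dy_true.mean()  # gauge: mean shift is unobservable
        shifted = al.shift_vertical(stack, dy_true)
        dy_est, _ = al.vertical_align(shifted)
        assert np.sqrt(np.mean((dy_est - dy_true) ** 2)) < 0.1

    def test_zero_mean_gauge(self, desk_sinogram):
        stack, _, _ = desk_sinogram
        dy, _ = al.vertical_align(stack)
        assert abs(dy.mean()) < 1e-9

    def test_too_few_angles_rejected(self, desk_sinogram):
        stack, _, _ = desk_sinogram
        with pytest.raises(ValueError):
            al.vertical_align(stack[:2])


class TestComPrealign:
    def test_centered_phantom_near_zero(self, desk_sinogram):
        stack, angles, _ = desk_sinogram
        shifts, info = al.com_prealign(stack, angles)
        assert info["amplitude_px"] < 0.5
        assert np.abs(shifts).max() < 0.1

    def test_offset_object_amplitude(self, desk_sinogram):
        """Object 5 px off the rotation axis -> fitted sinusoid amplitude ≈ 5."""
        stack, angles, _ = desk_sinogram
        th = np.deg2rad(angles)
        moved = al.shift_rows(stack, 5.0 * np.cos(th))
        _, info = al.com_prealign(moved, angles)
        assert info["amplitude_px"] == pytest.approx(5.0, abs=0.3)

    def test_residual_decreases_after_shifts(self, desk_sinogram):
        stack, angles, _ = desk_sinogram
        rng = np.random.default_rng(9)
        bad = al.shift_rows(stack, rng.uniform(-4, 4, len(stack)))
        shifts, info0 = al.com_prealign(bad, angles)
        _, info1 = al.com_prealign(al.shift_rows(bad, shifts), angles)
        assert info1["residual_px"] < info0["residual_px"]


class TestConsistencyAlign:
    def test_aligned_input_first_update_below_tolerance(self, desk_sinogram):
        stack, angles, _ = desk_sinogram
        _, info = al.consistency_align(stack, angles, n_outer=1)
        assert info["residual_history"][0] < 0.05

    def test_inject_recover_90_angles(self, desk_sinogram):
        stack, angles, _ = desk_sinogram
        rng = np.random.default_rng(12)
        dx_true = rng.uniform(-4, 4, len(stack))
        bad = al.shift_rows(stack, dx_true)
        dx0, _ = al.com_prealign(bad, angles)
        dx_est, _ = al.consistency_align(bad, angles, n_outer=10, init_shifts=dx0)
        assert _gauge_removed_rmse(dx_est + dx_true, angles) < 0.1


class TestFlagBadProjections:
    def test_clean_stack_no_flags(self, desk_sinogram):
        stack, _, phan = desk_sinogram
        lam = 1.99975e-10
        amps = np.stack(
            [
                ph.ground_truth_projection(phan, a, lam).amplitude_attenuation
                for a in np.arange(0, 180, 10.0)
            ]
        )
        assert al.flag_bad_projections(amps) == []

    def test_injected_amplitude_loss_flagged_exactly(self, desk_sinogram):
        stack, _, phan = desk_sinogram
        lam = 1.99975e-10
        angles = np.arange(0, 180, 6.0)
        amps = np.stack(
            [
                ph.ground_truth_projection(phan, a, lam).amplitude_attenuation
                for a in angles
            ]
        )
        corrupt = [4, 11, 23]
        w0 = amps.shape[2] // 2
        for i in corrupt:
            amps[i, :, w0 : w0 + 10] *= 0.5  # localized transmissivity loss
        assert al.flag_bad_projections(amps) == corrupt

    def test_infinite_k_flags_nothing(self, desk_sinogram):
        stack, _, phan = desk_sinogram
        lam = 1.99975e-10
        amps = np.stack(
            [
                ph.ground_truth_projection(phan, a, lam).amplitude_attenuation
                for a in np.arange(0, 180, 10.0)
            ]
        )
        amps[3] *= 0.2
        assert al.flag_bad_projections(amps, k=1e12) == []


class TestAngularWeights:
    def test_equally_spaced_unit_weights(self):
        w = al.angular_weights(np.arange(0, 180, 2.0))
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_removed_angle_gap_compensation(self):
        """Neighbors of a removed angle carry 1.5× the weight of the rest."""
        angles = np.arange(0, 180, 2.0)
        kept = np.delete(angles, 40)
        w = al.angular_weights(kept)
        assert w.sum() == pytest.approx(len(kept), rel=1e-12)
        ratio = w[39] / w[0]
        assert ratio == pytest.approx(1.5, rel=1e-9)
        assert w[40] / w[0] == pytest.approx(1.5, rel=1e-9)

    def test_normalization_any_input(self):
        rng = np.random.default_rng(4)
        angles = np.sort(rng.uniform(0, 179.9, 37))
        w = al.angular_weights(angles)
        assert w.sum() == pytest.approx(37, rel=1e-9)
        assert np.all(w > 0)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            al.angular_weights(np.array([0.0, 10.0, 10.0, 20.0]))
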