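"""Difference-map and maximum-likelihood phase retrieval."""
import numpy as np
import pytest

from cryopxct import ptycho as pt
from cryopxct.forward_model import simulate_diffraction


@pytest.fixture(scope="module")
def weak_probe(unit_scene):
    """Probe rescaled to 1e4 photons/frame: strongly photon-limited data."""
    import copy

    p = copy.copy(unit_scene["probe"])
    p.field = p.field * np.sqrt(1e4 / p.total_photons)
    p.total_photons = 1e4
    return p


@pytest.fixture(scope="module")
def noisy_data(unit_scene, weak_probe):
    return simulate_diffraction(
        unit_scene["truth"],
        weak_probe,
        unit_scene["scan"],
        noise=True,
        seed=5,
        optics=unit_scene["optics"],
    )


class TestFourierError:
    def test_exact_data_zero(self, unit_scene):
        e = pt.fourier_error(
            unit_scene["truth"], unit_scene["probe"].field, unit_scene["data"]
        )
        assert e < 1e-12

    def test_zero_object_unit_error(self, unit_scene):
        obj = np.zeros(unit_scene["padded_shape"], complex)
        e = pt.fourier_error(obj, unit_scene["probe"].field, unit_scene["data"])
        assert e == pytest.approx(1.0, rel=1e-12)

    def test_amplitude_only_metric(self, unit_scene):
        """Scrambling the object phase by a constant leaves the error at 0."""
        obj = unit_scene["truth"] * np.exp(1j * 0.7)
        e = pt.fourier_error(obj, unit_scene["probe"].field, unit_scene["data"])
        assert e < 1e-12


class TestDifferenceMap:
    def test_truth_is_fixed_point(self, unit_scene):
        res = pt.dm_reconstruct(
            unit_scene["data"],
            unit_scene["probe"],
            object_init=unit_scene["truth"],
            n_iter=1,
            probe_freeze_iters=10,
        )
        assert res.fourier_error_history[-1] < 1e-10

    def test_deterministic_error_history(self, unit_scene):
        kw = dict(object_shape=unit_scene["padded_shape"], n_iter=8)
        a = pt.dm_reconstruct(unit_scene["data"], unit_scene["probe"], **kw)
        b = pt.dm_reconstruct(unit_scene["data"], unit_scene["probe"], **kw)
        assert a.fourier_error_history == b.fourier_error_history

    def test_error_decreases_and_phase_recovered(self, unit_scene):
        """Noiseless DM converges to the true object phase (probe known)."""
        res = pt.dm_reconstruct(
            unit_scene["data"],
            unit_scene["probe"],
            object_shape=unit_scene["padded_shape"],
            n_iter=80,
            update_probe=False,
        )
        assert res.fourier_error_history[-1] < 0.01
        cov = pt.probe_coverage(
            unit_scene["probe"].field,
            unit_scene["data"].offsets_px,
            unit_scene["padded_shape"],
        )
        mask = cov > 0.3 * cov.max()
        rmse = pt.phase_rmse(res.object, unit_scene["truth"], mask=mask, weights=cov)
        assert rmse < 0.02

    def test_all_zero_frames_rejected(self, unit_scene):
        import copy

        bad = copy.copy(unit_scene["data"])
        bad.frames = np.zeros_like(bad.frames)
        with pytest.raises(ValueError):
            pt.dm_reconstruct(bad, unit_scene["probe"], n_iter=1)

    def test_nonfinite_frames_rejected(self, unit_scene):
        import copy

        bad = copy.copy(unit_scene["data"])
        bad.frames = bad.frames.copy()
        bad.frames[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            pt.dm_reconstruct(bad, unit_scene["probe"], n_iter=1)


class TestMLRefine:
    def test_stationary_at_noiseless_truth(self, unit_scene):
        init = pt.PtychoResult(
            object=unit_scene["truth"].astype(complex),
            probe=unit_scene["probe"].field.copy(),
            fourier_error_history=[],
            iterations_run=(0, 0),
        )
        res = pt.ml_refine(init, unit_scene["data"], n_iter=3)
        # at the global optimum the solver must not move the solution
        assert np.abs(res.object - unit_scene["truth"]).max() < 1e-4
        drop = res.nll_history[0] - res.nll_history[-1]
        assert abs(drop) < 1e-6 * abs(res.nll_history[0])

    def test_monotone_decrease_on_noisy_data(self, unit_scene, weak_probe, noisy_data):
        dm = pt.dm_reconstruct(
            noisy_data,
            weak_probe,
            object_shape=unit_scene["padded_shape"],
            n_iter=60,
        )
        res = pt.ml_refine(dm, noisy_data, n_iter=50)
        nll = np.array(res.nll_history)
        assert np.all(np.diff(nll) < 0)
        # Poisson-weighted refinement must not degrade the object estimate
        cov = pt.probe_coverage(
            weak_probe.field, noisy_data.offsets_px, unit_scene["padded_shape"]
        )
        mask = cov > 0.3 * cov.max()
        rmse_dm = pt.phase_rmse(dm.object, unit_scene["truth"], mask=mask, weights=cov)
        rmse_ml = pt.phase_rmse(res.object, unit_scene["truth"], mask=mask, weights=cov)
        assert rmse_ml <= rmse_dm * 1.05

    def test_epsilon_robustness(self, unit_scene, weak_probe, noisy_data):
        dm = pt.dm_reconstruct(
            noisy_data,
            weak_probe,
            object_shape=unit_scene["padded_shape"],
            n_iter=20,
        )
        a = pt.ml_refine(dm, noisy_data, n_iter=10, eps_rel=1e-8)
        b = pt.ml_refine(dm, noisy_data, n_iter=10, eps_rel=2e-8)
        assert abs(a.nll_history[-1] - b.nll_history[-1]) < 1e-3 * abs(
            a.nll_history[-1]
        )


class TestProbeRetrieval:
    def test_probe_power_recovered(self, desk_scene):
        """Retrieved probe power within 5% of the simulated photon count.

        Needs the well-overlapped desk scan (40 positions); the air
        margin anchors the object/probe scale split (unit transmission
        in vacuum), the only gauge in which probe power is well defined.
        """
        res = pt.dm_reconstruct(
            desk_scene["data"],
            desk_scene["probe"],
            object_shape=desk_scene["padded_shape"],
            n_iter=150,
            update_probe=True,
            gauge_mask=desk_scene["air_mask"],
        )
        power = np.sum(np.abs(res.probe) ** 2)
        assert power == pytest.approx(desk_scene["probe"].total_photons, rel=0.05)


class TestAmbiguityRemoval:
    def test_inject_and_recover_ramp(self, unit_scene):
        truth = unit_scene["truth"]
        h, w = truth.shape
        yy, xx = np.mgrid[0:h, 0:w]
        ramped = truth * np.exp(1j * (0.4 + 0.05 * xx - 0.03 * yy))
        fixed = pt.remove_phase_ambiguity(ramped, truth)
        resid = np.angle(fixed * np.conj(truth))
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_rmse_zero_for_identical_fields(self, unit_scene):
        assert pt.phase_rmse(unit_scene["truth"], unit_scene["truth"]) < 1e-12
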