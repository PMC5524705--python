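"""Shared fixtures: small simulated datasets reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from cryopxct import forward_model as fm
from cryopxct import phantom as ph
from cryopxct import pipeline as pl


@pytest.fixture(scope="session")
def unit_cfg() -> pl.RunConfig:
    return pl.profile_config("unit", seed=7)


@pytest.fixture(scope="session")
def unit_phantom(unit_cfg) -> ph.TissuePhantom:
    return ph.build_phantom(unit_cfg.make_phantom_spec(), seed=11)


@pytest.fixture(scope="session")
def unit_scene(unit_cfg, unit_phantom):
    """One angle's noiseless simulation with all intermediates exposed."""
    optics = unit_cfg.make_optics()
    ny, nx, _ = unit_phantom.shape
    scan, pad, padded_shape, air_mask = pl._geometry(unit_cfg, (ny, nx))
    probe = fm.make_probe(
        optics, grid_px=unit_cfg.frame_px, total_photons=1e6, defocus_rad=3.0
    )
    proj = ph.ground_truth_projection(unit_phantom, 0.0, optics.wavelength_m)
    t_pad = np.pad(proj.transmission, pad, mode="constant", constant_values=1.0)
    data = fm.simulate_diffraction(t_pad, probe, scan, noise=False, optics=optics)
    return {
        "cfg": unit_cfg,
        "optics": optics,
        "phantom": unit_phantom,
        "scan": scan,
        "pad": pad,
        "padded_shape": padded_shape,
        "air_mask": air_mask,
        "probe": probe,
        "truth": t_pad,
        "data": data,
    }


@pytest.fixture(scope="session")
def desk_scene():
    """One desk-profile angle: 40 positions, 64-px frames, noiseless."""
    cfg = pl.profile_config("desk", seed=3)
    phan = ph.build_phantom(cfg.make_phantom_spec(), seed=13)
    optics = cfg.make_optics()
    ny, nx, _ = phan.shape
    scan, pad, padded_shape, air_mask = pl._geometry(cfg, (ny, nx))
    probe = fm.make_probe(
        optics, grid_px=cfg.frame_px, total_photons=1e8, defocus_rad=3.0
    )
    proj = ph.ground_truth_projection(phan, 33.0, optics.wavelength_m)
    t_pad = np.pad(proj.transmission, pad, mode="constant", constant_values=1.0)
    data = fm.simulate_diffraction(t_pad, probe, scan, noise=False, optics=optics)
    return {
        "cfg": cfg,
        "optics": optics,
        "phantom": phan,
        "scan": scan,
        "pad": pad,
        "padded_shape": padded_shape,
        "air_mask": air_mask,
        "probe": probe,
        "truth": t_pad,
        "data": data,
    }


@pytest.fixture(scope="session")
def truth_sinogram(unit_phantom, unit_cfg):
    """Noiseless ground-truth derivative sinogram of the unit phantom."""
    from cryopxct import align as al

    optics = unit_cfg.make_optics()
    n_ang = 24
    angles = np.arange(n_ang) * 180.0 / n_ang
    stack = []
    for a in angles:
        proj = ph.ground_truth_projection(unit_phantom, float(a), optics.wavelength_m)
        stack.append(al.phase_derivative(proj.transmission))
    return np.stack(stack), angles, optics.wavelength_m
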