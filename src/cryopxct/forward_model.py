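"""Ptychographic measurement simulator.

Models the acquisition chain of a far-field ptychography beamline: a
confined coherent probe (~7 µm disc) is stepped over the sample on a
Fermat-spiral trajectory; at each position the exit wave under the
multiplicative approximation, ψ_j(r) = P(r − r_j) O(r), propagates to the
far field where the detector records photon counts |F ψ_j|² with Poisson
statistics.  The DFT is orthonormal throughout, so photon number is
conserved between sample and detector planes (Parseval).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import OpticsConfig

__all__ = [
    "ScanPattern",
    "Probe",
    "DiffractionData",
    "fermat_spiral",
    "make_probe",
    "simulate_diffraction",
]

GOLDEN_ANGLE_DEG = 137.508


@dataclass
class ScanPattern:
    """Scan positions in metres, ordered by generation index."""

    positions_m: np.ndarray  # (n, 2) array of (x, y)
    nominal_step_m: float
    field_of_view_m: tuple[float, float]  # (width, height)

    @property
    def n_positions(self) -> int:
        return len(self.positions_m)


@dataclass
class Probe:
    """Complex illumination field sampled on the reconstruction grid."""

    field: np.ndarray  # (N, N) complex
    total_photons: float
    pixel_size_m: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape


@dataclass
class DiffractionData:
    """One tomography angle's stack of diffraction frames.

    ``offsets_px`` are the integer (row, col) corner offsets of each
    probe window in the object grid (scan positions quantized to the
    reconstruction pixel grid).
    """

    frames: np.ndarray  # (n_pos, N, N) counts
    scan: ScanPattern
    offsets_px: np.ndarray  # (n_pos, 2) int
    angle_deg: float
    optics: OpticsConfig
    noise: bool
    seed: int | None = None


def fermat_spiral(
    field_of_view_m: tuple[float, float], step_m: float
) -> ScanPattern:
    """Fermat-spiral scan positions clipped to a rectangular field of view.

    Point k sits at radius c√k and azimuth k·137.508° with c = step/√π so
    the mean area per point equals step².  The spiral gives near-uniform
    point density without the periodic artifacts of raster scanning.
    """
    w, h = field_of_view_m
    if step_m <= 0:
        raise ValueError("step must be positive")
    if w <= 0 or h <= 0:
        raise ValueError("field of view must be positive")
    if step_m > min(w, h) and min(w, h) > 0:
        # a single row/column of points can still be meaningful for very
        # anisotropic FOVs, but a step exceeding both extents cannot overlap
        if step_m > max(w, h):
            raise ValueError("step larger than the field of view: no overlap possible")
    c = step_m / np.sqrt(np.pi)
    r_max = 0.5 * np.hypot(w, h)  # circumscribing circle of the rectangle
    n = int(np.ceil((r_max / c) ** 2)) + 1
    k = np.arange(n, dtype=float)
    r = c * np.sqrt(k)
    th = np.deg2rad(GOLDEN_ANGLE_DEG) * k
    x = r * np.cos(th)
    y = r * np.sin(th)
    keep = (np.abs(x) <= w / 2) & (np.abs(y) <= h / 2)
    pos = np.stack([x[keep], y[keep]], axis=1)
    if len(pos) == 0:
        raise ValueError("no scan positions inside the field of view")
    return ScanPattern(
        positions_m=pos, nominal_step_m=step_m, field_of_view_m=(w, h)
    )


def make_probe(
    optics: OpticsConfig,
    grid_px: int | None = None,
    total_photons: float = 1.0,
    defocus_rad: float = 3.0,
) -> Probe:
    """Tapered-disc probe with quadratic (defocus) phase.

    The real beam is shaped by a Fresnel zone plate with central stop and
    order-sorting aperture; for pipeline purposes only the probe extent
    (hence overlap) matters, and the reconstruction retrieves the actual
    probe, so a generic model is used: a circular top-hat of the nominal
    diameter with a cosine-tapered edge (taper width 10% of the diameter)
    and a quadratic phase of ``defocus_rad`` radians at the edge.
    Normalized so that Σ|field|² = total_photons exactly.
    """
    n = grid_px if grid_px is not None else optics.detector_region_px
    p = optics.pixel_size_m
    radius_px = 0.5 * optics.probe_diameter_m / p
    if radius_px < 2:
        raise ValueError("probe diameter must span at least 4 reconstruction pixels")
    if 2 * radius_px > n:
        raise ValueError(
            f"probe diameter ({2 * radius_px:.1f} px) exceeds the {n}-px grid"
        )
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c)
    taper = 0.1 * 2 * radius_px
    amp = np.clip((radius_px - rr) / max(taper, 1e-9), 0.0, 1.0)
    amp = 0.5 - 0.5 * np.cos(np.pi * amp)
    phase = defocus_rad * (rr / radius_px) ** 2
    f = amp * np.exp(1j * phase)
    power = np.sum(np.abs(f) ** 2)
    if power == 0:
        raise ValueError("degenerate probe (zero power)")
    f *= np.sqrt(total_photons / power)
    return Probe(field=f.astype(np.complex128), total_photons=total_photons, pixel_size_m=p)


def positions_to_offsets(
    scan: ScanPattern, pixel_size_m: float, object_shape: tuple[int, int], probe_px: int
) -> np.ndarray:
    """Integer top-left window offsets (row, col) for each scan position.

    Scan (x, y) coordinates are metres relative to the object-grid centre;
    x maps to columns and y to rows.  Positions are quantized to the
    reconstruction pixel grid.
    """
    h, w = object_shape
    cy, cx = (h - probe_px) / 2.0, (w - probe_px) / 2.0
    cols = np.rint(scan.positions_m[:, 0] / pixel_size_m + cx).astype(int)
    rows = np.rint(scan.positions_m[:, 1] / pixel_size_m + cy).astype(int)
    off = np.stack([rows, cols], axis=1)
    if (off < 0).any() or (off[:, 0] > h - probe_px).any() or (off[:, 1] > w - probe_px).any():
        raise ValueError(
            "a scan position's probe window leaves the object grid; enlarge the "
            "object grid or shrink the scan field of view"
        )
    return off


def simulate_diffraction(
    projection_transmission: np.ndarray,
    probe: Probe,
    scan: ScanPattern,
    angle_deg: float = 0.0,
    noise: bool = False,
    seed: int | None = None,
    optics: OpticsConfig | None = None,
) -> DiffractionData:
    """Far-field diffraction frames for one angle's scan.

    For each position the exit wave is ψ_j = P·O over the probe window and
    the noiseless intensity is |DFT(ψ_j)|² with orthonormal scaling.  With
    ``noise`` enabled, counts are Poisson-sampled with a generator seeded
    deterministically per (seed, angle, position).
    """
    obj = np.asarray(projection_transmission)
    if not np.isfinite(obj).all():
        raise ValueError("non-finite values in the object transmission")
    n = probe.shape[0]
    offsets = positions_to_offsets(scan, probe.pixel_size_m, obj.shape, n)
    frames = np.empty((len(offsets), n, n), dtype=np.float64)
    for j, (r0, c0) in enumerate(offsets):
        psi = probe.field * obj[r0 : r0 + n, c0 : c0 + n]
        frames[j] = np.abs(np.fft.fft2(psi, norm="ortho")) ** 2
    if noise:
        if seed is None:
            raise ValueError("a seed is required for Poisson noise")
        out = np.empty_like(frames)
        for j in range(len(frames)):
            rng = np.random.default_rng(
                [int(seed), int(round(angle_deg * 1000)) % (2**31), j]
            )
            out[j] = rng.poisson(frames[j])
        frames = out
    if optics is None:
        optics = OpticsConfig()
    return DiffractionData(
        frames=frames,
        scan=scan,
        offsets_px=offsets,
        angle_deg=float(angle_deg),
        optics=optics,
        noise=noise,
        seed=seed,
    )
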