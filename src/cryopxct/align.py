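"""Projection processing and alignment into a consistent derivative sinogram.

Tomography from ptychographic projections requires: removal of the
per-projection phase offset/ramp ambiguity (fitted over the air region
that surrounds the sample at every angle), conversion to wrap-safe
horizontal phase derivatives, vertical alignment (each horizontal slice's
total projected mass is angle-invariant), horizontal alignment by
center-of-mass pre-alignment followed by tomographic-consistency
refinement (reconstruct → reproject → register), automatic flagging of
projections with localized transmissivity loss (grazing-incidence
artifacts), and gap-compensating angular weights for the uneven angle
distribution left after removing projections.

All sub-pixel shifts are applied as Fourier-domain phase ramps on
edge-padded arrays (10% padding suppresses wrap-around).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "AlignedSinogram",
    "remove_ramp",
    "phase_derivative",
    "integrate_derivative",
    "shift_rows",
    "shift_vertical",
    "vertical_align",
    "com_prealign",
    "consistency_align",
    "flag_bad_projections",
    "angular_weights",
]


@dataclass
class AlignedSinogram:
    """Aligned stack of horizontal phase derivatives ∂φ/∂x (rad/pixel)."""

    derivative_projections: np.ndarray  # (n_angle, H, W)
    angles_deg: np.ndarray  # strictly increasing in [0, 180)
    shifts_px: np.ndarray  # (n_angle, 2) applied (dy, dx)
    weights: np.ndarray  # per-angle, sums to n_angle
    removed_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, float)
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")


# ----------------------------------------------------------------------
# elementwise projection processing


def remove_ramp(
    phase: np.ndarray, air_mask: np.ndarray, per_row: bool = True
) -> np.ndarray:
    """Anchor the phase to zero over the surrounding air.

    Ptychography leaves phase offset and ramp undetermined per
    projection; the air region surrounding the sample provides the zero
    reference.  A least-squares plane (offset + 2 linear terms) over the
    air mask is subtracted first; with ``per_row`` (default), each row is
    then re-anchored by the line through its own left- and right-strip
    air means.  The per-row step matters when the phase comes from
    integrating a measured derivative: tiny derivative errors accumulate
    over the row into offsets/slopes far larger than the pointwise
    error, and only the row's own air level can remove them.  After
    removal the air-region mean phase is 0.
    """
    air_mask = np.asarray(air_mask, bool)
    if not air_mask.any():
        raise ValueError("air mask is empty")
    cols = air_mask.any(axis=0)
    w = len(cols)
    if not (cols[: w // 2].any() and cols[w // 2 :].any()):
        import warnings

        warnings.warn("air mask does not cover both lateral sides of the projection")
    h, wd = phase.shape
    yy, xx = np.mgrid[0:h, 0:wd].astype(float)
    a = np.stack([np.ones(air_mask.sum()), yy[air_mask], xx[air_mask]], axis=1)
    coef, *_ = np.linalg.lstsq(a, phase[air_mask], rcond=None)
    out = phase - (coef[0] + coef[1] * yy + coef[2] * xx)
    if per_row:
        left = air_mask & (xx < wd / 2)
        right = air_mask & (xx >= wd / 2)
        x_row = np.arange(wd, dtype=float)
        for i in range(h):
            li, ri = left[i], right[i]
            if li.any() and ri.any():
                xl, xr = x_row[li].mean(), x_row[ri].mean()
                vl, vr = out[i, li].mean(), out[i, ri].mean()
                slope = (vr - vl) / (xr - xl)
                out[i] -= vl + slope * (x_row - xl)
            elif li.any() or ri.any():
                out[i] -= out[i, li | ri].mean()
    return out


def phase_derivative(transmission: np.ndarray) -> np.ndarray:
    """Wrap-safe horizontal phase derivative of a complex projection.

    d(y, x) = arg( T(y, x+1) · conj(T(y, x)) ) avoids 2-D phase
    unwrapping; a true inter-pixel jump of exactly 2π is invisible to it
    (documented limitation of derivative-domain processing).  The last
    column is zero-padded so the output keeps the input shape.
    """
    t = np.asarray(transmission)
    d = np.angle(t[:, 1:] * np.conj(t[:, :-1]))
    return np.pad(d, ((0, 0), (0, 1)))


def integrate_derivative(derivative: np.ndarray) -> np.ndarray:
    """Integrate ∂φ/∂x back to phase, up to a per-row constant.

    The forward difference d(x) = φ(x+1) − φ(x) telescopes to
    φ(x) − φ(0) = Σ_{x'<x} d(x'), so the cumulative sum is prepended with
    a zero (not taken in place) to keep the result on the same pixel grid
    as the projection — otherwise every profile lands one pixel to the
    left and alignment chases a spurious global shift.
    """
    c = np.cumsum(derivative, axis=-1)
    return np.concatenate([np.zeros_like(c[..., :1]), c[..., :-1]], axis=-1)


# ----------------------------------------------------------------------
# sub-pixel shifting (Fourier phase ramps on edge-padded arrays)


def _fourier_shift_1d(row: np.ndarray, s: float) -> np.ndarray:
    n = len(row)
    pad = max(4, int(0.1 * n))
    padded = np.pad(row, pad, mode="edge")
    f = np.fft.fft(padded)
    freq = np.fft.fftfreq(len(padded))
    out = np.fft.ifft(f * np.exp(-2j * np.pi * freq * s)).real
    return out[pad : pad + n]


def shift_rows(stack: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Shift each projection of a (n, H, W) stack along x by dx[i] pixels."""
    out = np.empty_like(stack, dtype=float)
    for i, s in enumerate(dx):
        n = stack.shape[-1]
        pad = max(4, int(0.1 * n))
        padded = np.pad(stack[i], ((0, 0), (pad, pad)), mode="edge")
        f = np.fft.fft(padded, axis=-1)
        freq = np.fft.fftfreq(padded.shape[-1])
        out[i] = np.fft.ifft(f * np.exp(-2j * np.pi * freq * s), axis=-1).real[
            :, pad : pad + n
        ]
    return out


def shift_vertical(stack: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Shift each projection of a (n, H, W) stack along y by dy[i] pixels."""
    return np.transpose(
        shift_rows(np.transpose(stack, (0, 2, 1)), dy), (0, 2, 1)
    )


def _register_1d(moving: np.ndarray, reference: np.ndarray, upsample: int = 100) -> float:
    """Sub-pixel shift that maps ``moving`` onto ``reference``."""
    shift, _, _ = phase_cross_correlation(
        reference[:, None], moving[:, None], upsample_factor=upsample
    )
    return float(shift[0])


def _register_block_x(
    moving: np.ndarray, reference: np.ndarray, upsample: int = 100
) -> float:
    """Joint sub-pixel x-shift of a (rows, W) block onto a reference block.

    Row-wise cross-correlations are summed before peak finding, which
    averages down per-row noise while keeping a single rigid shift; the
    peak is refined on a 1/upsample grid by explicit DFT evaluation.
    """
    fm = np.fft.fft(moving, axis=1)
    fr = np.fft.fft(reference, axis=1)
    cross = (fr * np.conj(fm)).sum(axis=0)
    corr = np.fft.ifft(cross).real
    w = len(corr)
    s0 = int(np.argmax(corr))
    if s0 > w // 2:
        s0 -= w
    freq = np.fft.fftfreq(w)
    fine = s0 + np.arange(-upsample, upsample + 1) / upsample
    # C(s) = Σ_w cross(w)·e^{2πi w s}
    vals = (cross[None, :] * np.exp(2j * np.pi * freq[None, :] * fine[:, None])).sum(
        axis=1
    ).real
    return float(fine[np.argmax(vals)])


# ----------------------------------------------------------------------
# vertical alignment


def vertical_align(
    derivative_stack: np.ndarray,
    max_iter: int = 30,
    tol: float = 0.02,
) -> tuple[np.ndarray, bool]:
    """Per-angle vertical shifts from mass-profile consistency.

    The derivative is integrated along x and summed over x into a
    vertical mass profile m_θ(y); by mass conservation this profile is
    the same at every angle for an aligned stack.  Shifts are found by
    iteratively registering each profile to the current mean profile
    (sub-pixel, Fourier), with the mean shift constrained to 0.
    Returns (shifts dy, converged flag).
    """
    n = derivative_stack.shape[0]
    if n < 3:
        raise ValueError("need at least 3 angles for vertical alignment")
    profiles = integrate_derivative(derivative_stack).sum(axis=2)  # (n, H)
    shifts = np.zeros(n)
    converged = False
    for _ in range(max_iter):
        shifted = np.stack(
            [_fourier_shift_1d(profiles[i], -shifts[i]) for i in range(n)]
        )
        ref = shifted.mean(axis=0)
        updates = np.array(
            [_register_1d(shifted[i], ref) for i in range(n)]
        )
        shifts -= updates
        shifts -= shifts.mean()
        if np.abs(updates).max() < tol:
            converged = True
            break
    return shifts, converged


# ----------------------------------------------------------------------
# horizontal alignment


def com_prealign(
    derivative_stack: np.ndarray, angles_deg: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Center-of-mass pre-alignment of the horizontal shifts.

    The projected center of mass of a rigid object follows
    x_c(θ) = A cos θ + B sin θ + c.  Residuals from the least-squares
    sinusoid are per-angle misalignments; the returned shifts remove
    them.  Used only to initialize the consistency refinement.
    """
    n, h, w = derivative_stack.shape
    if n < 3:
        raise ValueError("need at least 3 angles")
    phase = integrate_derivative(derivative_stack)
    mass = -phase.sum(axis=1)  # (n, W); positive inside matter
    mass = np.clip(mass, 0.0, None)
    x = np.arange(w) - (w - 1) / 2.0
    tot = mass.sum(axis=1)
    good = tot > 0
    xc = np.zeros(n)
    xc[good] = (mass[good] * x).sum(axis=1) / tot[good]
    th = np.deg2rad(np.asarray(angles_deg, float))
    a = np.stack([np.cos(th), np.sin(th), np.ones(n)], axis=1)
    coef, *_ = np.linalg.lstsq(a[good], xc[good], rcond=None)
    fit = a @ coef
    shifts = np.where(good, -(xc - fit), 0.0)
    info = {
        "amplitude_px": float(np.hypot(coef[0], coef[1])),
        "axis_offset_px": float(coef[2]),
        "residual_px": float(np.sqrt(np.mean((xc - fit)[good] ** 2))),
    }
    return shifts, info


def consistency_align(
    derivative_stack: np.ndarray,
    angles_deg: np.ndarray,
    n_outer: int = 10,
    init_shifts: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    slab_rows: int = 5,
    tol_px: float = 0.02,
    upsample: int = 100,
) -> tuple[np.ndarray, dict]:
    """Horizontal shifts from tomographic consistency.

    Iterates: reconstruct a central slab by derivative filtered
    back-projection → reproject at all angles → register each measured
    projection to its reprojection by sub-pixel cross-correlation
    (Fourier upsampling) → update shifts; stops when the largest update
    falls below ``tol_px`` or after ``n_outer`` iterations.  Returns the
    best shifts found plus diagnostics (converged/diverged flags and the
    residual history).
    """
    from . import tomo  # local import: align <-> tomo cooperation

    n, h, w = derivative_stack.shape
    angles = np.asarray(angles_deg, float)
    shifts = np.zeros(n) if init_shifts is None else np.asarray(init_shifts, float).copy()
    if weights is None:
        weights = np.ones(n)
    rows = np.arange(max(h // 2 - slab_rows // 2, 0), min(h // 2 + slab_rows // 2 + 1, h))
    residuals: list[float] = []
    best_shifts = shifts.copy()
    best_res = np.inf
    grow = 0
    converged = False
    damping = 1.0
    for _ in range(n_outer):
        shifted = shift_rows(derivative_stack[:, rows, :], shifts)
        # reproject each slab slice and compare in the derivative domain,
        # whose sharper features localize the correlation peak better than
        # the smooth integrated phase
        reproj_d = np.empty_like(shifted)
        for ridx in range(len(rows)):
            slice_phase = tomo.fbp_slice_from_derivative(
                shifted[:, ridx, :], angles, weights
            )
            reproj = tomo.forward_project_slice(slice_phase, angles)
            reproj_d[:, ridx, :] = np.pad(np.diff(reproj, axis=1), ((0, 0), (0, 1)))
        updates = np.array(
            [
                _register_block_x(shifted[i], reproj_d[i], upsample=upsample)
                for i in range(n)
            ]
        )
        # project out the translational gauge: a shift pattern
        # A·cosθ + B·sinθ + c merely translates the reconstruction and is
        # invisible to consistency, so it must not accumulate as drift
        th = np.deg2rad(angles)
        basis = np.stack([np.cos(th), np.sin(th), np.ones(n)], axis=1)
        coef, *_ = np.linalg.lstsq(basis, updates, rcond=None)
        updates = updates - basis @ coef
        shifts += damping * updates
        res = float(np.abs(updates).max())
        residuals.append(res)
        if res < best_res:
            best_res = res
            best_shifts = shifts.copy()
            grow = 0
        else:
            grow += 1
            if grow >= 3:
                return best_shifts, {
                    "converged": False,
                    "diverged": True,
                    "residual_history": residuals,
                }
        if res < tol_px:
            converged = True
            break
    return shifts, {
        "converged": converged,
        "diverged": False,
        "residual_history": residuals,
    }


# ----------------------------------------------------------------------
# projection quality control


def flag_bad_projections(
    amplitudes: np.ndarray,
    support_mask: np.ndarray | None = None,
    k: float = 5.0,
    box: int = 5,
    min_drop: float = 0.05,
) -> list[int]:
    """Flag projections with a localized loss of transmissivity amplitude.

    Grazing-incidence reflection from the sample edge can cause an
    apparent local absorption far beyond anything physical.  For each
    angle the minimum boxcar-averaged amplitude inside the support is
    compared across angles; angles more than ``k`` MAD below the median
    statistic are flagged for removal.  ``min_drop`` additionally
    requires the drop to be practically significant (a fraction of the
    median): a genuine grazing-incidence loss halves the local
    amplitude, whereas per-angle reconstruction noise moves the
    statistic by a couple of percent and must not trigger removal when
    the across-angle MAD happens to be tiny.
    """
    amps = np.asarray(amplitudes, float)
    stats = np.empty(len(amps))
    for i, a in enumerate(amps):
        local = ndimage.uniform_filter(a, size=box)
        stats[i] = local[support_mask].min() if support_mask is not None else local.min()
    med = np.median(stats)
    mad = np.median(np.abs(stats - med))
    thresh = med - max(k * mad, min_drop * abs(med))
    return [int(i) for i in np.nonzero(stats < thresh)[0]]


def angular_weights(angles_deg: np.ndarray) -> np.ndarray:
    """Gap-compensating projection weights, periodic over 180°.

    w_i ∝ (θ_{i+1} − θ_{i−1})/2 with the angle set closed periodically
    over the half-turn, normalized so Σ w_i = n.  Equally spaced angles
    get unit weights; removing an angle raises its neighbors' weights by
    half the vacated gap.
    """
    a = np.asarray(angles_deg, float)
    if len(a) < 2:
        raise ValueError("need at least 2 angles")
    if np.any(np.diff(a) <= 0):
        raise ValueError("angles must be strictly increasing (no duplicates)")
    if a[0] < 0 or a[-1] >= 180:
        raise ValueError("angles must lie in [0, 180)")
    ext = np.concatenate([[a[-1] - 180.0], a, [a[0] + 180.0]])
    gaps = (ext[2:] - ext[:-2]) / 2.0
    return gaps * len(a) / gaps.sum()
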