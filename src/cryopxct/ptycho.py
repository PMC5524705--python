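"""Ptychographic phase retrieval: difference map + maximum-likelihood refinement.

One tomography angle's diffraction frames are inverted for the complex
object transmission O(r) and the shared complex probe P(r).  The solver
follows the two-stage scheme standard for this kind of data:

1. Difference map (DM) on the stack of per-position exit waves ψ_j,
       ψ_j ← ψ_j + P_F(2 P_O(ψ_j) − ψ_j) − P_O(ψ_j),
   where P_O enforces the multiplicative overlap model ψ_j = P(·−r_j)·O
   (least-squares object/probe factorization) and P_F enforces the
   measured Fourier amplitudes.
2. Maximum-likelihood (ML) refinement: nonlinear conjugate gradient on
   the Poisson negative log-likelihood
       L = Σ_{j,q} [ |Ψ_j(q)|² − I_j(q) ln(|Ψ_j(q)|² + ε) ],
   with analytic Wirtinger gradients w.r.t. O and P and a parabolic line
   search; accepted steps never increase L.

Ptychography leaves a global phase offset and a linear phase ramp
undetermined; :func:`remove_phase_ambiguity` and :func:`phase_rmse`
factor these out before any comparison to ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import DiffractionData, Probe

__all__ = [
    "PtychoResult",
    "dm_reconstruct",
    "ml_refine",
    "fourier_error",
    "probe_coverage",
    "remove_phase_ambiguity",
    "phase_rmse",
]

_FFT = {"norm": "ortho"}


@dataclass
class PtychoResult:
    """Reconstructed complex object and probe for one angle."""

    object: np.ndarray  # (H, W) complex transmission estimate
    probe: np.ndarray  # (N, N) complex
    fourier_error_history: list[float]
    iterations_run: tuple[int, int]  # (dm, ml)
    converged: bool = True
    nll_history: list[float] = field(default_factory=list)


def _windows(arr: np.ndarray, offsets: np.ndarray, n: int) -> np.ndarray:
    """Stack of n×n views of ``arr`` at the given (row, col) offsets."""
    return np.stack([arr[r : r + n, c : c + n] for r, c in offsets])


def _scatter_add(acc: np.ndarray, offsets: np.ndarray, patches: np.ndarray) -> None:
    n = patches.shape[-1]
    for (r, c), p in zip(offsets, patches):
        acc[r : r + n, c : c + n] += p


def probe_coverage(
    probe: np.ndarray, offsets: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Σ_j |P(r − r_j)|², the illumination coverage of the object grid."""
    cov = np.zeros(shape, dtype=float)
    n = probe.shape[0]
    p2 = np.abs(probe) ** 2
    for r, c in offsets:
        cov[r : r + n, c : c + n] += p2
    return cov


def _factorize(
    psi: np.ndarray,
    offsets: np.ndarray,
    obj: np.ndarray,
    probe: np.ndarray,
    update_probe: bool,
    n_inner: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares object/probe factorization of the exit-wave stack.

    Alternates O(r) = Σ_j P* ψ_j / (Σ_j |P|² + ε) with the symmetric probe
    update.  This is the overlap-constraint half of the difference map.
    """
    n = probe.shape[0]
    for _ in range(n_inner):
        num = np.zeros_like(obj)
        _scatter_add(num, offsets, psi * probe.conj()[None])
        den = probe_coverage(probe, offsets, obj.shape)
        eps = 1e-12 * max(den.max(), 1e-300)
        obj = num / (den + eps)
        if update_probe:
            ow = _windows(obj, offsets, n)
            pnum = (psi * ow.conj()).sum(axis=0)
            pden = (np.abs(ow) ** 2).sum(axis=0)
            peps = 1e-12 * max(pden.max(), 1e-300)
            probe = pnum / (pden + peps)
    return obj, probe


def fourier_error(
    obj: np.ndarray, probe: np.ndarray, data: DiffractionData
) -> float:
    """sqrt( Σ_{j,q} (|Ψ_j| − √I_j)² / Σ_{j,q} I_j ): amplitude-domain misfit."""
    n = probe.shape[0]
    ow = _windows(obj, data.offsets_px, n)
    amp = np.abs(np.fft.fft2(probe[None] * ow, **_FFT))
    sqrt_i = np.sqrt(data.frames)
    denom = data.frames.sum()
    if denom <= 0:
        raise ValueError("degenerate all-zero frames")
    return float(np.sqrt(((amp - sqrt_i) ** 2).sum() / denom))


def _fix_gauge(
    obj: np.ndarray,
    probe: np.ndarray,
    gauge_mask: np.ndarray | None,
    offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the object/probe scale ambiguity against an air region.

    The product P·O is all the data determine; the split of a scale
    factor between the two is fixed by requiring unit mean transmission
    amplitude over ``gauge_mask`` (pixels known to be air/vacuum).  Only
    well-illuminated gauge pixels (coverage above 30% of its maximum)
    participate — the object estimate is meaningless elsewhere.
    """
    if gauge_mask is None:
        return obj, probe
    mask = np.asarray(gauge_mask, bool)
    if offsets is not None:
        cov = probe_coverage(probe, offsets, obj.shape)
        mask = mask & (cov > 0.3 * cov.max())
    if not mask.any():
        return obj, probe
    s = float(np.mean(np.abs(obj[mask])))
    if s <= 0:
        return obj, probe
    return obj / s, probe * s


def dm_reconstruct(
    data: DiffractionData,
    probe_init: Probe | np.ndarray,
    object_shape: tuple[int, int] | None = None,
    object_init: np.ndarray | None = None,
    n_iter: int = 300,
    beta_dm: float = 1.0,
    probe_freeze_iters: int = 10,
    update_probe: bool = True,
    gauge_mask: np.ndarray | None = None,
    average_last: int = 0,
) -> PtychoResult:
    """Difference-map reconstruction of object and probe from one angle.

    The probe update is frozen for the first ``probe_freeze_iters``
    iterations to stabilize the factorization while the object estimate
    forms.  Records the Fourier error every iteration.

    ``average_last``: the difference map typically settles into a small
    limit cycle rather than a fixed point on real (or probe-retrieving)
    problems; averaging the overlap-consistent estimates over the last k
    iterations (with global-phase alignment) suppresses the cycle and is
    the standard way to read out its solution.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not np.isfinite(data.frames).all():
        raise ValueError("non-finite values in frames")
    if data.frames.sum() <= 0:
        raise ValueError("degenerate all-zero frames")
    probe = (
        probe_init.field if isinstance(probe_init, Probe) else np.asarray(probe_init)
    ).astype(np.complex128).copy()
    n = probe.shape[0]
    offsets = np.asarray(data.offsets_px)
    if object_shape is None:
        if object_init is not None:
            object_shape = object_init.shape
        else:
            object_shape = (
                int(offsets[:, 0].max()) + n,
                int(offsets[:, 1].max()) + n,
            )
    if object_init is None:
        obj = np.ones(object_shape, dtype=np.complex128)
    else:
        obj = np.asarray(object_init, dtype=np.complex128).copy()
    if (offsets < 0).any() or (offsets[:, 0] > object_shape[0] - n).any() or (
        offsets[:, 1] > object_shape[1] - n
    ).any():
        raise ValueError("probe window outside object grid")

    sqrt_i = np.sqrt(data.frames)
    total_i = data.frames.sum()
    psi = probe[None] * _windows(obj, offsets, n)
    errors: list[float] = []
    acc_o = acc_p = None
    n_acc = 0
    for it in range(n_iter):
        upd = update_probe and it >= probe_freeze_iters
        obj, probe = _factorize(psi, offsets, obj, probe, update_probe=upd)
        if average_last > 0 and it >= n_iter - average_last:
            if acc_o is None:
                acc_o, acc_p, n_acc = obj.copy(), probe.copy(), 1
            else:
                off = np.angle(np.sum(obj * np.conj(acc_o)))
                acc_o += obj * np.exp(-1j * off)
                acc_p += probe * np.exp(1j * off)
                n_acc += 1
        phi = probe[None] * _windows(obj, offsets, n)  # P_O(psi)
        # Fourier error of the overlap-consistent estimate
        amp_phi = np.abs(np.fft.fft2(phi, **_FFT))
        errors.append(float(np.sqrt(((amp_phi - sqrt_i) ** 2).sum() / total_i)))
        # Fourier projection of the reflected iterate
        refl = np.fft.fft2(2.0 * phi - psi, **_FFT)
        mag = np.abs(refl)
        proj = np.where(mag > 0, refl * (sqrt_i / np.where(mag > 0, mag, 1.0)), sqrt_i)
        pf = np.fft.ifft2(proj, **_FFT)
        psi = psi + beta_dm * (pf - phi)
    if n_acc > 0:
        obj, probe = acc_o / n_acc, acc_p / n_acc
    else:
        obj, probe = _factorize(psi, offsets, obj, probe, update_probe=update_probe)
    obj, probe = _fix_gauge(obj, probe, gauge_mask, offsets)
    return PtychoResult(
        object=obj,
        probe=probe,
        fourier_error_history=errors,
        iterations_run=(n_iter, 0),
    )


def _nll_and_grad(
    obj: np.ndarray,
    probe: np.ndarray,
    offsets: np.ndarray,
    frames: np.ndarray,
    eps: float,
    want_grad: bool = True,
):
    n = probe.shape[0]
    ow = _windows(obj, offsets, n)
    psi = probe[None] * ow
    big = np.fft.fft2(psi, **_FFT)
    inten = np.abs(big) ** 2
    nll = float((inten - frames * np.log(inten + eps)).sum())
    if not want_grad:
        return nll, None, None
    dl_dpsi_hat = big * (1.0 - frames / (inten + eps))
    chi = np.fft.ifft2(dl_dpsi_hat, **_FFT)
    g_obj = np.zeros_like(obj)
    _scatter_add(g_obj, offsets, chi * probe.conj()[None])
    g_probe = (chi * ow.conj()).sum(axis=0)
    return nll, g_obj, g_probe


def ml_refine(
    result: PtychoResult,
    data: DiffractionData,
    n_iter: int = 50,
    update_probe: bool = True,
    eps_rel: float = 1e-8,
    gauge_mask: np.ndarray | None = None,
) -> PtychoResult:
    """Poisson maximum-likelihood refinement by nonlinear conjugate gradient.

    Polishes a difference-map solution; with photon-counting noise this
    stage weights the data by its actual statistics rather than the
    amplitude metric the DM enforces.  Accepted steps strictly decrease
    the negative log-likelihood; on a failed line search after bounded
    backtracking the current state is returned with ``converged=False``.
    """
    obj = result.object.astype(np.complex128).copy()
    probe = result.probe.astype(np.complex128).copy()
    offsets = np.asarray(data.offsets_px)
    frames = np.asarray(data.frames, dtype=float)
    eps = eps_rel * max(float(frames.max()), 1e-300)

    nll, g_o, g_p = _nll_and_grad(obj, probe, offsets, frames, eps)
    if not update_probe:
        g_p = np.zeros_like(g_p)
    nll_hist = [nll]
    d_o, d_p = -g_o, -g_p
    g_norm2 = float((np.abs(g_o) ** 2).sum() + (np.abs(g_p) ** 2).sum())
    alpha = None
    converged = True
    it_done = 0
    for it in range(n_iter):
        if g_norm2 == 0:
            break
        # directional derivative along (d_o, d_p): dL/dα = 2 Re<g, d>
        slope = 2.0 * float(
            np.real((g_o.conj() * d_o).sum() + (g_p.conj() * d_p).sum())
        )
        if slope >= 0:  # not a descent direction: restart with steepest descent
            d_o, d_p = -g_o, -g_p
            slope = -2.0 * g_norm2
        if alpha is None:
            scale = np.sqrt(
                ((np.abs(obj) ** 2).sum() + (np.abs(probe) ** 2).sum())
                / max((np.abs(d_o) ** 2).sum() + (np.abs(d_p) ** 2).sum(), 1e-300)
            )
            alpha = 0.05 * float(scale)
        # parabolic model through L(0), L(alpha)
        nll_t, _, _ = _nll_and_grad(
            obj + alpha * d_o, probe + alpha * d_p, offsets, frames, eps, want_grad=False
        )
        curv = (nll_t - nll - slope * alpha) / (alpha * alpha)
        if curv > 0:
            step = -slope / (2.0 * curv)
            step = min(step, 10.0 * alpha)
        else:
            step = 2.0 * alpha if nll_t < nll else 0.5 * alpha
        accepted = False
        for _ in range(12):
            cand_o = obj + step * d_o
            cand_p = probe + step * d_p
            nll_c, _, _ = _nll_and_grad(cand_o, cand_p, offsets, frames, eps, want_grad=False)
            if nll_c < nll:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = False
            break
        obj, probe, nll = cand_o, cand_p, nll_c
        alpha = step
        nll_hist.append(nll)
        it_done = it + 1
        g_o_new, g_p_new = None, None
        _, g_o_new, g_p_new = _nll_and_grad(obj, probe, offsets, frames, eps)
        if not update_probe:
            g_p_new = np.zeros_like(g_p_new)
        g_norm2_new = float(
            (np.abs(g_o_new) ** 2).sum() + (np.abs(g_p_new) ** 2).sum()
        )
        # Polak-Ribière with automatic restart
        beta_pr = float(
            np.real(
                (g_o_new.conj() * (g_o_new - g_o)).sum()
                + (g_p_new.conj() * (g_p_new - g_p)).sum()
            )
        ) / max(g_norm2, 1e-300)
        beta_pr = max(beta_pr, 0.0)
        d_o = -g_o_new + beta_pr * d_o
        d_p = -g_p_new + beta_pr * d_p
        g_o, g_p, g_norm2 = g_o_new, g_p_new, g_norm2_new
    obj, probe = _fix_gauge(obj, probe, gauge_mask, offsets)
    err_hist = list(result.fourier_error_history)
    try:
        err_hist.append(fourier_error(obj, probe, data))
    except ValueError:
        pass
    return PtychoResult(
        object=obj,
        probe=probe,
        fourier_error_history=err_hist,
        iterations_run=(result.iterations_run[0], it_done),
        converged=converged,
        nll_history=nll_hist,
    )


# ----------------------------------------------------------------------
# ambiguity handling


def remove_phase_ambiguity(
    recon: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Remove the global phase offset and linear phase ramp of ``recon``.

    Both are inherent ptychographic ambiguities.  The ramp is estimated
    from the weighted product Q = recon · conj(reference): a pure
    offset+ramp makes Q a single complex exponential, located coarsely as
    the peak of a 4×-padded FFT and refined by wrap-safe weighted means of
    neighboring-pixel phase differences.
    """
    q = recon * np.conj(reference)
    h, w = q.shape
    wt = np.ones_like(q, dtype=float) if weights is None else np.asarray(weights, float)
    qw = q * wt
    pad = 4
    spec = np.fft.fft2(qw, s=(pad * h, pad * w))
    iy, ix = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    fy = np.fft.fftfreq(pad * h)[iy] * 2 * np.pi
    fx = np.fft.fftfreq(pad * w)[ix] * 2 * np.pi
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(3):
        resid = q * np.exp(-1j * (fy * yy + fx * xx))
        dx = resid[:, 1:] * np.conj(resid[:, :-1])
        dy = resid[1:, :] * np.conj(resid[:-1, :])
        wx = wt[:, 1:] * wt[:, :-1]
        wy = wt[1:, :] * wt[:-1, :]
        fx += float(np.angle((dx * wx).sum() / max(wx.sum(), 1e-300)))
        fy += float(np.angle((dy * wy).sum() / max(wy.sum(), 1e-300)))
    ramp = np.exp(-1j * (fy * yy + fx * xx))
    offset = np.angle((qw * ramp).sum())
    return recon * ramp * np.exp(-1j * offset)


def phase_rmse(
    recon: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Wrap-safe RMSE of the phase difference after ambiguity removal."""
    aligned = remove_phase_ambiguity(recon, reference, weights)
    diff = np.angle(aligned * np.conj(reference))
    if mask is not None:
        diff = diff[mask]
    return float(np.sqrt(np.mean(diff**2)))
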