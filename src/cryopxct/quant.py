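"""Quantitative analysis: FSC resolution, dose, segmentation, feature stats.

The resolution of a tomogram is estimated by Fourier shell correlation
between two reconstructions from independent halves of the angle set,
read off at the half-bit information threshold.  Surface dose follows
the weak-absorption estimate D = Φ·E·(μ/ρ)·n_proj with water optical
constants.  Density-band segmentation mimics contrast-based
semi-automated segmentation of reconstructed tomograms: voxels are
binned into disjoint density intervals, connected components below a
minimum size are dropped, and per-component equivalent-sphere diameters
are aggregated per class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import constants

__all__ = [
    "FSCResult",
    "DoseParams",
    "fsc",
    "estimate_dose",
    "segment_density_bands",
    "feature_size_stats",
    "depth_of_field_check",
]


@dataclass
class FSCResult:
    """Fourier shell correlation curve and its threshold crossing."""

    shell_frequency: np.ndarray  # cycles/voxel
    correlation: np.ndarray
    half_bit_threshold: np.ndarray
    n_voxels_per_shell: np.ndarray
    resolution_nm: float | None  # None => curve never crosses (beyond Nyquist)
    voxel_size_nm: float

    @property
    def crossed(self) -> bool:
        return self.resolution_nm is not None


@dataclass
class DoseParams:
    """Inputs of the surface-dose estimate."""

    fluence_per_projection: float  # photons/µm²
    photon_energy_kev: float
    attenuation_length_m: float = 451e-6  # water at 6.2 keV
    medium_density_kg_m3: float = 1000.0
    n_projections: int = 1

    def __post_init__(self) -> None:
        if (
            self.fluence_per_projection <= 0
            or self.photon_energy_kev <= 0
            or self.attenuation_length_m <= 0
            or self.medium_density_kg_m3 <= 0
            or self.n_projections < 0
        ):
            raise ValueError("dose parameters must be strictly positive")


def _hann_3d(shape: tuple[int, ...]) -> np.ndarray:
    w = np.ones(shape)
    for ax, n in enumerate(shape):
        h = np.hanning(n)
        w *= h.reshape([-1 if i == ax else 1 for i in range(len(shape))])
    return w


def fsc(
    vol1: np.ndarray,
    vol2: np.ndarray,
    voxel_size_nm: float = 1.0,
    apodize: bool = True,
) -> FSCResult:
    """Fourier shell correlation with the half-bit resolution threshold.

    FSC(k) = |Σ_shell F₁F₂*| / sqrt(Σ|F₁|²·Σ|F₂|²) over integer-radius
    shells of the 3-D Fourier transforms; both volumes are apodized by a
    shared Hann window first (suppresses box-boundary correlation).  The
    half-bit threshold T(k) = (0.2071 + 1.9102/√n) / (1.2071 + 0.9102/√n)
    with n the shell voxel count; resolution is the inverse frequency of
    the first downward crossing, linearly interpolated.  If the curve
    never crosses, ``resolution_nm`` is None ("beyond Nyquist").
    """
    v1 = np.asarray(vol1, float)
    v2 = np.asarray(vol2, float)
    if v1.shape != v2.shape:
        raise ValueError("volumes must share a grid")
    if apodize:
        w = _hann_3d(v1.shape)
        v1 = v1 * w
        v2 = v2 * w
    f1 = np.fft.fftn(v1)
    f2 = np.fft.fftn(v2)
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n) for n in v1.shape], indexing="ij", sparse=True
    )
    r = np.sqrt(sum(f**2 for f in freqs))
    nmax = min(v1.shape) // 2
    shell = np.minimum(np.rint(r * min(v1.shape)).astype(int), 10 * nmax)
    num = np.bincount(shell.ravel(), weights=(f1 * np.conj(f2)).real.ravel())
    num_i = np.bincount(shell.ravel(), weights=(f1 * np.conj(f2)).imag.ravel())
    d1 = np.bincount(shell.ravel(), weights=(np.abs(f1) ** 2).ravel())
    d2 = np.bincount(shell.ravel(), weights=(np.abs(f2) ** 2).ravel())
    cnt = np.bincount(shell.ravel())
    ks = np.arange(1, nmax + 1)  # skip DC shell for the curve
    corr = np.abs(num[ks] + 1j * num_i[ks]) / np.sqrt(
        np.maximum(d1[ks] * d2[ks], 1e-300)
    )
    n_eff = cnt[ks].astype(float)
    sq = np.sqrt(np.maximum(n_eff, 1.0))
    thr = (0.2071 + 1.9102 / sq) / (1.2071 + 0.9102 / sq)
    freq = ks / float(min(v1.shape))  # cycles/voxel
    resolution = None
    below = corr < thr
    for i in range(len(ks)):
        if below[i]:
            if i == 0:
                f_cross = freq[0]
            else:
                c0, c1 = corr[i - 1] - thr[i - 1], corr[i] - thr[i]
                t = c0 / (c0 - c1)
                f_cross = freq[i - 1] + t * (freq[i] - freq[i - 1])
            resolution = float(voxel_size_nm / f_cross)
            break
    if resolution is not None:
        resolution = max(resolution, 2.0 * voxel_size_nm)  # Nyquist floor
    return FSCResult(
        shell_frequency=freq,
        correlation=corr,
        half_bit_threshold=thr,
        n_voxels_per_shell=cnt[ks],
        resolution_nm=resolution,
        voxel_size_nm=voxel_size_nm,
    )


def estimate_dose(params: DoseParams) -> float:
    """Surface dose in Gray for a weakly absorbing medium.

    D = Φ · E · (1/Λ)/ρ · n_proj, with Φ the fluence per projection
    (photons/µm² → photons/m²), E the photon energy in joules, Λ the
    attenuation length and ρ the density of the medium.  With water at
    6.2 keV (Λ = 451 µm, ρ = 1000 kg/m³) and 1e7 ph/µm² this is ≈22 kGy
    per projection.
    """
    fluence_m2 = params.fluence_per_projection * 1e12
    energy_j = params.photon_energy_kev * 1e3 * constants.EV_J
    mu_over_rho = (1.0 / params.attenuation_length_m) / params.medium_density_kg_m3
    return fluence_m2 * energy_j * mu_over_rho * params.n_projections


def segment_density_bands(
    volume: np.ndarray,
    bands: dict[str, tuple[float, float]],
    min_voxels: int = 1,
) -> tuple[np.ndarray, list[dict]]:
    """Threshold segmentation into disjoint density bands.

    Voxels are assigned to the band whose [lo, hi) interval contains
    them, connected components (26-connectivity) smaller than
    ``min_voxels`` are discarded, and a per-component table of class,
    size and centroid is returned alongside the relabelled volume
    (component ids 1..K, 0 = background).
    """
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (na, (lo_a, hi_a)), (nb, (lo_b, hi_b)) in zip(items, items[1:]):
        if hi_a > lo_b:
            raise ValueError(f"density bands {na!r} and {nb!r} overlap")
    vol = np.asarray(volume)
    labels = np.zeros(vol.shape, dtype=np.int32)
    table: list[dict] = []
    structure = np.ones((3,) * vol.ndim, dtype=bool)
    next_id = 1
    for name, (lo, hi) in items:
        mask = (vol >= lo) & (vol < hi)
        comp, n_comp = ndimage.label(mask, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        keep = np.nonzero(sizes >= min_voxels)[0] + 1
        if len(keep) == 0:
            continue
        centroids = ndimage.center_of_mass(mask, comp, keep)
        for cid, ctr in zip(keep, centroids):
            labels[comp == cid] = next_id
            table.append(
                {
                    "id": next_id,
                    "class": name,
                    "n_voxels": int(sizes[cid - 1]),
                    "centroid": tuple(float(c) for c in ctr),
                }
            )
            next_id += 1
    return labels, table


def feature_size_stats(
    table: list[dict], voxel_size_nm: float
) -> dict[str, dict[str, float]]:
    """Equivalent-sphere diameter statistics per class.

    Each component of volume V voxels has diameter (6V/π)^(1/3) voxels;
    returns mean, sd (ddof=1, 0 for singletons) and count per class, in
    nm.
    """
    out: dict[str, dict[str, float]] = {}
    by_class: dict[str, list[float]] = {}
    for row in table:
        d_vox = (6.0 * row["n_voxels"] / np.pi) ** (1.0 / 3.0)
        by_class.setdefault(row["class"], []).append(d_vox * voxel_size_nm)
    for name, diams in by_class.items():
        arr = np.asarray(diams)
        out[name] = {
            "mean_nm": float(arr.mean()),
            "sd_nm": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n": len(arr),
        }
    return out


def depth_of_field_check(
    resolution_m: float, wavelength_m: float, sample_thickness_m: float
) -> tuple[bool, float]:
    """Advisory multiplicative-approximation depth-of-field check.

    DOF = 5.2·resolution²/λ; flags (advisory only, never blocking)
    configurations whose sample thickness exceeds it, i.e. where a single
    2-D projection can no longer represent the 3-D object faithfully.
    Returns (flagged, dof_m).
    """
    if resolution_m <= 0 or wavelength_m <= 0 or sample_thickness_m <= 0:
        raise ValueError("inputs must be positive")
    dof = 5.2 * resolution_m**2 / wavelength_m
    return sample_thickness_m > dof, dof
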