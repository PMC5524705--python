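"""Voxelized 3-D tissue phantoms with quantitative electron densities.

The phantom emulates the feature classes seen in cryo-ptychographic
tomograms of sucrose/PVP-infused brain tissue: a block of cryoprotectant
medium containing myelinated axons (low-density multilamellar sheaths
around axoplasm cores), cell bodies with nuclei (nucleus below cytoplasm
in density), and ~3 µm pigmented autophagic vacuoles (lipid-dominated,
lowest density, each with a dense pigment sub-inclusion).

Density conventions
-------------------
Electron density n_e is carried in e/Å³ (water ≈ 0.3344 e/Å³).  The
refractive-index decrement follows δ = r_e λ² n_e / (2π), and mass density
follows ρ_m = n_e · M/e / N_A with the soft-matter molar-mass-per-electron
ratio M/e = 1.86 g/mol.

Coordinate conventions (repo-wide)
----------------------------------
Grids are indexed (y, x, z): y is the vertical rotation axis, the beam
travels along +z at tomography angle 0, and the system is right-handed.
Phase retardation is φ = −(2π/λ) ∫ δ dz (denser material → more negative
phase); the refractive index is n = 1 − δ + iβ.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import constants

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "DEFAULT_DENSITIES",
    "PhantomSpec",
    "TissuePhantom",
    "ComplexProjection",
    "build_phantom",
    "delta_beta_from_electron_density",
    "mass_density_from_electron_density",
    "ground_truth_projection",
    "project_delta",
]

#: Feature-class label codes.  Order encodes overlap precedence: when two
#: features claim a voxel the higher code wins (pigment > vacuole lipid >
#: nucleus > myelin > axoplasm > cytoplasm > medium > air).
LABELS = {
    "air": 0,
    "medium": 1,
    "cytoplasm": 2,
    "axoplasm": 3,
    "myelin": 4,
    "nucleus": 5,
    "vacuole_lipid": 6,
    "vacuole_pigment": 7,
}

LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: Default electron densities, e/Å³.  Chosen to honour the qualitative
#: orderings observed in cryo-PXCT of sucrose-infused tissue: the 1.8 M
#: sucrose + PVP medium is densest among the bulk phases, myelin and lipid
#: vacuoles sit below it, nucleus below cytoplasm, and the pigment
#: (iron-bearing) inclusion is densest of all.
DEFAULT_DENSITIES = {
    "air": 0.0,
    "medium": 0.40,
    "cytoplasm": 0.37,
    "nucleus": 0.35,
    "myelin": 0.34,
    "axoplasm": 0.36,
    "vacuole_lipid": 0.31,
    "vacuole_pigment": 0.45,
}


@dataclass
class PhantomSpec:
    """Description of a phantom to generate.

    Sizes are in voxels unless suffixed otherwise.  ``shape`` is (ny, nx,
    nz).  The support cross-section (the trimmed block footprint in the
    x–z plane) is a centred rectangle or cylinder that must fit, with its
    circumscribing circle, strictly inside the grid so the sample is
    surrounded by air at every rotation angle.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size_nm: float = 305.0
    #: Cross-section of the trimmed block.  The cylinder is the default:
    #: a flat face parallel to the beam produces an inter-pixel phase jump
    #: exceeding π at grazing angles, which derivative-domain processing
    #: cannot represent (the known cause of streak artifacts for
    #: rectangular-pyramid samples); a cylinder keeps every jump below π.
    support_shape: str = "cylinder"  # "rect" or "cylinder"
    #: Half-extent of the support in x and z as a fraction of the largest
    #: half-extent that still fits under rotation.
    support_fraction: float = 0.80
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    n_axons: int = 6
    axon_radius_vox: tuple[float, float] = (4.0, 7.0)
    myelin_thickness_vox: tuple[float, float] = (1.5, 3.0)
    n_cells: int = 2
    cell_radius_vox: float = 14.0
    nucleus_semiaxes_vox: tuple[float, float, float] = (7.0, 9.0, 7.0)
    n_vacuoles: int = 4
    vacuole_diameter_um: float = 3.0
    pigment_radius_fraction: float = 0.45
    beta_over_delta: float = 0.005

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom grid must be at least 8 voxels per side")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        if not 0 < self.support_fraction <= 1:
            raise ValueError("support_fraction must be in (0, 1]")
        if self.support_shape not in ("rect", "cylinder"):
            raise ValueError(f"unknown support shape {self.support_shape!r}")
        for k, v in self.densities.items():
            if v < 0:
                raise ValueError(f"density for {k!r} must be nonnegative")

    @property
    def vacuole_radius_vox(self) -> float:
        return 0.5 * self.vacuole_diameter_um * 1e3 / self.voxel_size_nm


@dataclass
class TissuePhantom:
    """Voxelized tissue block: electron density + feature labels."""

    electron_density: np.ndarray  # (ny, nx, nz) float32, e/Å³
    labels: np.ndarray  # (ny, nx, nz) uint8
    voxel_size_nm: float
    support_mask: np.ndarray  # (nx, nz) bool cross-sectional footprint
    densities: dict[str, float]
    seed: int
    beta_over_delta: float = 0.005

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.electron_density.shape

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def median_density(self, name: str) -> float:
        m = self.label_mask(name)
        if not m.any():
            raise ValueError(f"phantom has no voxels of class {name!r}")
        return float(np.median(self.electron_density[m]))


@dataclass
class ComplexProjection:
    """Complex transmission of the sample at one tomography angle.

    ``phase`` is the continuous (non-wrapped) line integral
    φ(y, x) = −(2π/λ) ∫ δ dz; ``amplitude_attenuation`` is
    exp(−(2π/λ) ∫ β dz) ≤ 1; ``transmission`` = A · exp(iφ).
    """

    transmission: np.ndarray  # (ny, nx) complex
    phase: np.ndarray  # (ny, nx) float, rad
    amplitude_attenuation: np.ndarray  # (ny, nx) float in (0, 1]
    angle_deg: float
    pixel_size_nm: float


# ----------------------------------------------------------------------
# density conversions


def delta_beta_from_electron_density(
    electron_density: np.ndarray | float,
    wavelength_m: float,
    beta_over_delta: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """δ = r_e λ² n_e / (2π), β = (β/δ) · δ, for n_e in e/Å³.

    Phase contrast dominates absorption at multi-keV energies, so β is
    modelled as a small fixed fraction of δ.
    """
    if wavelength_m <= 0:
        raise ValueError("wavelength must be positive")
    if not 0 <= beta_over_delta <= 0.1:
        raise ValueError("beta_over_delta must lie in [0, 0.1]")
    n_e = np.asarray(electron_density, dtype=float)
    if np.any(n_e < 0):
        raise ValueError("electron density must be nonnegative")
    n_e_si = n_e * 1e30  # e/Å³ -> e/m³
    delta = constants.R_E_M * wavelength_m**2 * n_e_si / (2.0 * np.pi)
    beta = beta_over_delta * delta
    return delta, beta


def mass_density_from_electron_density(
    electron_density: np.ndarray | float,
) -> np.ndarray | float:
    """Mass density in g/cm³ from electron density in e/Å³.

    ρ_m = n_e · (M/e) / N_A with M/e = 1.86 g/mol, the molar mass per
    electron of a water/lipid/protein/chromatin mixture.  Water
    (0.3344 e/Å³) maps to ≈1.033 g/cm³.
    """
    n_e = np.asarray(electron_density, dtype=float)
    if np.any(n_e < 0):
        raise ValueError("electron density must be nonnegative")
    rho = n_e * 1e24 * constants.MOLAR_MASS_PER_ELECTRON_G_MOL / constants.N_AVOGADRO
    if np.isscalar(electron_density) or np.ndim(electron_density) == 0:
        return float(rho)
    return rho


# ----------------------------------------------------------------------
# phantom construction


def _support_mask(spec: PhantomSpec) -> np.ndarray:
    _, nx, nz = spec.shape
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    x = np.arange(nx)[:, None] - cx
    z = np.arange(nz)[None, :] - cz
    # The support's circumscribing circle must stay >= 1 voxel inside the
    # grid at every rotation angle.
    r_fit = min(nx, nz) / 2.0 - 1.5
    if spec.support_shape == "cylinder":
        r = spec.support_fraction * r_fit
        return (x**2 + z**2) <= r**2
    half = spec.support_fraction * r_fit / np.sqrt(2.0)
    return (np.abs(x) <= half) & (np.abs(z) <= half)


def _paint(labels: np.ndarray, mask: np.ndarray, code: int) -> None:
    """Assign ``code`` where ``mask``, respecting precedence (higher wins)."""
    np.maximum(labels, np.where(mask, np.uint8(code), np.uint8(0)), out=labels)


def _sphere_mask(shape, center, radius) -> np.ndarray:
    ny, nx, nz = shape
    y = np.arange(ny)[:, None, None] - center[0]
    x = np.arange(nx)[None, :, None] - center[1]
    z = np.arange(nz)[None, None, :] - center[2]
    return (y**2 + x**2 + z**2) <= radius**2


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    ny, nx, nz = shape
    y = (np.arange(ny)[:, None, None] - center[0]) / semiaxes[0]
    x = (np.arange(nx)[None, :, None] - center[1]) / semiaxes[1]
    z = (np.arange(nz)[None, None, :] - center[2]) / semiaxes[2]
    return (y**2 + x**2 + z**2) <= 1.0


def build_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> TissuePhantom:
    """Generate a deterministic voxelized tissue phantom.

    Axons are vertical cylinders (axoplasm core + myelin annulus of
    randomized thickness), cells are cytoplasm spheres containing a
    nucleus ellipsoid, and vacuoles are spheres of ~``vacuole_diameter_um``
    with an internal dense pigment sub-sphere.  Features are placed by
    rejection sampling inside the support; overlaps are resolved by class
    precedence, never by error.  A feature that cannot fit inside the
    support at all raises a sizing error.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    ny, nx, nz = spec.shape
    support = _support_mask(spec)

    labels = np.zeros(spec.shape, dtype=np.uint8)
    _paint(labels, np.broadcast_to(support[None, :, :], spec.shape), LABELS["medium"])

    sup_x, sup_z = np.nonzero(support)
    if len(sup_x) == 0:
        raise ValueError("support mask is empty")
    x_lo, x_hi = sup_x.min(), sup_x.max()
    z_lo, z_hi = sup_z.min(), sup_z.max()

    def _place_xz(margin: float, n_try: int = 200) -> tuple[float, float]:
        """Random (x, z) whose ``margin``-ball lies inside the support."""
        m = int(np.ceil(margin))
        if x_hi - x_lo < 2 * m or z_hi - z_lo < 2 * m:
            raise ValueError(
                f"feature of radius {margin:.1f} voxels does not fit inside the "
                f"support footprint ({x_hi - x_lo + 1}×{z_hi - z_lo + 1} voxels)"
            )
        eroded = ndimage.binary_erosion(support, iterations=max(m, 1))
        cand_x, cand_z = np.nonzero(eroded)
        if len(cand_x) == 0:
            raise ValueError(
                f"feature of radius {margin:.1f} voxels does not fit inside the support"
            )
        i = rng.integers(len(cand_x))
        return float(cand_x[i]), float(cand_z[i])

    # --- cells: cytoplasm sphere + nucleus ellipsoid
    for _ in range(spec.n_cells):
        r = spec.cell_radius_vox
        cx, cz = _place_xz(r * 0.7)
        cy = rng.uniform(r * 0.8, ny - 1 - r * 0.8) if ny > 2 * r else (ny - 1) / 2
        cyto = _sphere_mask(spec.shape, (cy, cx, cz), r)
        cyto &= support[None, :, :]
        _paint(labels, cyto, LABELS["cytoplasm"])
        nuc = _ellipsoid_mask(spec.shape, (cy, cx, cz), spec.nucleus_semiaxes_vox)
        nuc &= cyto
        _paint(labels, nuc, LABELS["nucleus"])

    # --- myelinated axons: vertical cylinders, full height
    xg = np.arange(nx)[:, None]
    zg = np.arange(nz)[None, :]
    for _ in range(spec.n_axons):
        r_ax = rng.uniform(*spec.axon_radius_vox)
        t_my = rng.uniform(*spec.myelin_thickness_vox)
        cx, cz = _place_xz(r_ax + t_my)
        rr2 = (xg - cx) ** 2 + (zg - cz) ** 2
        core = rr2 <= r_ax**2
        sheath = (rr2 <= (r_ax + t_my) ** 2) & ~core
        core &= support
        sheath &= support
        _paint(labels, np.broadcast_to(core[None], spec.shape), LABELS["axoplasm"])
        _paint(labels, np.broadcast_to(sheath[None], spec.shape), LABELS["myelin"])

    # --- pigmented vacuoles: lipid sphere + dense pigment sub-sphere
    r_vac = spec.vacuole_radius_vox
    for _ in range(spec.n_vacuoles):
        if r_vac < 2:
            raise ValueError(
                f"vacuole radius {r_vac:.2f} voxels is below the 2-voxel minimum; "
                "increase vacuole_diameter_um or decrease voxel_size_nm"
            )
        cx, cz = _place_xz(r_vac)
        cy = rng.uniform(r_vac, ny - 1 - r_vac) if ny > 2 * r_vac else (ny - 1) / 2
        vac = _sphere_mask(spec.shape, (cy, cx, cz), r_vac)
        vac &= support[None, :, :]
        _paint(labels, vac, LABELS["vacuole_lipid"])
        r_pig = spec.pigment_radius_fraction * r_vac
        off = (r_vac - r_pig) * 0.5
        pc = (cy + rng.uniform(-off, off), cx + rng.uniform(-off, off), cz + rng.uniform(-off, off))
        pig = _sphere_mask(spec.shape, pc, r_pig)
        pig &= vac
        _paint(labels, pig, LABELS["vacuole_pigment"])

    density = np.zeros(spec.shape, dtype=np.float32)
    for name, code in LABELS.items():
        density[labels == code] = spec.densities.get(name, 0.0)
    density[labels == LABELS["air"]] = 0.0

    return TissuePhantom(
        electron_density=density,
        labels=labels,
        voxel_size_nm=spec.voxel_size_nm,
        support_mask=support,
        densities=dict(spec.densities),
        seed=seed,
        beta_over_delta=spec.beta_over_delta,
    )


# ----------------------------------------------------------------------
# ground-truth projection


def project_delta(
    delta: np.ndarray, angle_deg: float, voxel_size_m: float
) -> np.ndarray:
    """Line integral ∫ δ dz of a (y, x, z) volume at one tomography angle.

    The volume is rotated about the vertical (y) axis by ``angle_deg``
    with bilinear interpolation and zero padding, then summed along the
    beam axis z.  Returns a (ny, nx) map in metres (δ·length).
    """
    if angle_deg % 360.0 == 0.0:
        rot = delta
    else:
        rot = ndimage.rotate(
            delta, angle_deg, axes=(2, 1), reshape=False, order=1,
            mode="constant", cval=0.0, prefilter=False,
        )
    return rot.sum(axis=2) * voxel_size_m


def ground_truth_projection(
    phantom: TissuePhantom,
    angle_deg: float,
    wavelength_m: float,
    beta_over_delta: float | None = None,
) -> ComplexProjection:
    """Complex transmission T = exp(−(2π/λ)∫β dz) · exp(−i(2π/λ)∫δ dz).

    Uses the multiplicative (projection) approximation: the 3-D object is
    represented by the 2-D line integral of its refractive index along the
    beam.  Raises if the rotated support would clip at the grid edge.
    """
    if not 0.0 <= angle_deg < 360.0:
        raise ValueError("angle must lie in [0, 360) degrees")
    if beta_over_delta is None:
        beta_over_delta = phantom.beta_over_delta
    _, nx, nz = phantom.shape
    sup_x, sup_z = np.nonzero(phantom.support_mask)
    if len(sup_x):
        cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
        r_sup = np.sqrt((sup_x - cx) ** 2 + (sup_z - cz) ** 2).max()
        if r_sup > min(nx, nz) / 2.0 - 1.0:
            raise ValueError(
                "projection grid smaller than the rotated support; mass would clip"
            )
    delta, beta = delta_beta_from_electron_density(
        phantom.electron_density, wavelength_m, beta_over_delta
    )
    voxel_m = phantom.voxel_size_nm * 1e-9
    k = 2.0 * np.pi / wavelength_m
    proj_delta = project_delta(delta, angle_deg, voxel_m)
    phase = -k * proj_delta
    if beta_over_delta > 0:
        proj_beta = project_delta(beta, angle_deg, voxel_m)
        amplitude = np.exp(-k * proj_beta)
    else:
        amplitude = np.ones_like(phase)
    transmission = amplitude * np.exp(1j * phase)
    return ComplexProjection(
        transmission=transmission,
        phase=phase,
        amplitude_attenuation=amplitude,
        angle_deg=float(angle_deg),
        pixel_size_nm=phantom.voxel_size_nm,
    )
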