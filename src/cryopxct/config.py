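"""Configuration dataclasses: beamline optics and run profiles.

The optics geometry determines the reconstruction pixel size
p = λ D / (N Δ_det), i.e. the real-space sampling of the retrieved
object for a detector region of N×N pixels of pitch Δ_det at distance D.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from . import constants


@dataclass(frozen=True)
class OpticsConfig:
    """Beamline/detector geometry of a far-field ptychography measurement.

    Parameters
    ----------
    photon_energy_kev:
        Photon energy in keV.
    detector_distance_m:
        Sample-to-detector distance in metres.
    detector_pixel_pitch_m:
        Detector pixel pitch in metres.
    detector_region_px:
        Side length N of the square detector region used, in pixels.
    probe_diameter_m:
        Nominal beam diameter at the sample, metres.
    fluence_per_projection:
        Incident photons per µm² per projection.
    """

    photon_energy_kev: float = 6.20
    detector_distance_m: float = 7.33
    detector_pixel_pitch_m: float = 75e-6
    detector_region_px: int = 452
    probe_diameter_m: float = 7e-6
    fluence_per_projection: float = 1e7

    def __post_init__(self) -> None:
        for name in (
            "photon_energy_kev",
            "detector_distance_m",
            "detector_pixel_pitch_m",
            "detector_region_px",
            "probe_diameter_m",
            "fluence_per_projection",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def wavelength_m(self) -> float:
        """λ = hc/E."""
        return constants.wavelength_m(self.photon_energy_kev)

    @property
    def pixel_size_m(self) -> float:
        """Reconstruction (object) pixel size p = λ D / (N Δ_det)."""
        return self.wavelength_m * self.detector_distance_m / (
            self.detector_region_px * self.detector_pixel_pitch_m
        )

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size_m * 1e9

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "OpticsConfig":
        return cls(**d)


def reconstruction_pixel_size(optics: OpticsConfig) -> float:
    """Reconstruction pixel size in nanometres for the given geometry.

    With the published geometry (6.20 keV, 7.33 m, N=452, 75 µm pitch) this
    evaluates to ≈43.25 nm.
    """
    return optics.pixel_size_nm
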