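"""HDF5 (and TIFF) persistence for every pipeline stage.

Layouts:
  phantom:      /phantom/electron_density, /phantom/labels (+ attrs)
  diffraction:  /entry/data/frames, /entry/scan/positions_m,
                /entry/angles_deg, /entry/optics/*, /entry/seed
  projection:   /proj/object_phase, /proj/object_amplitude, /proj/probe,
                /proj/error_history
  sinogram:     /sino/derivative, /sino/angles_deg, /sino/shifts_px,
                /sino/weights, /sino/removed_indices
  tomogram:     /tomo/delta, /tomo/electron_density (+ attrs)
"""
from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from .align import AlignedSinogram
from .config import OpticsConfig
from .phantom import TissuePhantom
from .tomo import Tomogram

__all__ = [
    "write_phantom",
    "read_phantom",
    "write_diffraction",
    "read_diffraction_meta",
    "write_projection",
    "write_sinogram",
    "read_sinogram",
    "write_tomogram",
    "read_tomogram",
    "export_tiff_slices",
]


def write_phantom(path, phantom: TissuePhantom) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.create_dataset("electron_density", data=phantom.electron_density.astype(np.float32))
        g.create_dataset("labels", data=phantom.labels.astype(np.uint8))
        g.create_dataset("support_mask", data=phantom.support_mask)
        g.attrs["voxel_size_nm"] = phantom.voxel_size_nm
        g.attrs["seed"] = phantom.seed
        g.attrs["beta_over_delta"] = phantom.beta_over_delta
        g.attrs["density_table"] = json.dumps(phantom.densities)


def read_phantom(path) -> TissuePhantom:
    with h5py.File(path, "r") as f:
        g = f["phantom"]
        return TissuePhantom(
            electron_density=g["electron_density"][...],
            labels=g["labels"][...],
            voxel_size_nm=float(g.attrs["voxel_size_nm"]),
            support_mask=g["support_mask"][...].astype(bool),
            densities=json.loads(g.attrs["density_table"]),
            seed=int(g.attrs["seed"]),
            beta_over_delta=float(g.attrs["beta_over_delta"]),
        )


def write_diffraction(path, datasets: list, optics: OpticsConfig, seed) -> None:
    """Store per-angle DiffractionData stacks as one frame hypercube."""
    frames = np.stack([d.frames for d in datasets])
    with h5py.File(path, "w") as f:
        e = f.create_group("entry")
        noisy = any(d.noise for d in datasets)
        e.create_dataset(
            "data/frames",
            data=frames.astype(np.uint32 if noisy else np.float32),
            compression="gzip",
        )
        e.create_dataset("scan/positions_m", data=datasets[0].scan.positions_m)
        e.create_dataset("scan/offsets_px", data=np.stack([d.offsets_px for d in datasets]))
        e.create_dataset("angles_deg", data=np.array([d.angle_deg for d in datasets]))
        og = e.create_group("optics")
        for k, v in optics.to_dict().items():
            og.attrs[k] = v
        e.attrs["seed"] = -1 if seed is None else seed


def read_diffraction_meta(path) -> dict:
    with h5py.File(path, "r") as f:
        e = f["entry"]
        return {
            "n_angles": e["data/frames"].shape[0],
            "n_positions": e["data/frames"].shape[1],
            "frame_px": e["data/frames"].shape[2],
            "angles_deg": e["angles_deg"][...],
            "optics": OpticsConfig.from_dict(dict(e["optics"].attrs)),
            "seed": int(e.attrs["seed"]),
        }


def write_projection(path, result, angle_deg: float | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("proj")
        g.create_dataset("object_phase", data=np.angle(result.object).astype(np.float32))
        g.create_dataset("object_amplitude", data=np.abs(result.object).astype(np.float32))
        g.create_dataset("probe", data=result.probe.astype(np.complex64))
        g.create_dataset("error_history", data=np.asarray(result.fourier_error_history))
        g.attrs["iterations_dm"] = result.iterations_run[0]
        g.attrs["iterations_ml"] = result.iterations_run[1]
        if angle_deg is not None:
            g.attrs["angle_deg"] = angle_deg


def write_sinogram(path, sino: AlignedSinogram) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("sino")
        g.create_dataset("derivative", data=sino.derivative_projections.astype(np.float32))
        g.create_dataset("angles_deg", data=np.asarray(sino.angles_deg))
        g.create_dataset("shifts_px", data=np.asarray(sino.shifts_px))
        g.create_dataset("weights", data=np.asarray(sino.weights))
        g.create_dataset("removed_indices", data=np.asarray(sino.removed_indices, dtype=int))


def read_sinogram(path) -> AlignedSinogram:
    with h5py.File(path, "r") as f:
        g = f["sino"]
        return AlignedSinogram(
            derivative_projections=g["derivative"][...],
            angles_deg=g["angles_deg"][...],
            shifts_px=g["shifts_px"][...],
            weights=g["weights"][...],
            removed_indices=[int(i) for i in g["removed_indices"][...]],
        )


def write_tomogram(path, tomo: Tomogram) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("tomo")
        g.create_dataset("delta", data=tomo.delta.astype(np.float32))
        g.create_dataset(
            "electron_density", data=np.asarray(tomo.electron_density, dtype=np.float32)
        )
        g.attrs["voxel_size_nm"] = tomo.voxel_size_nm
        g.attrs["wavelength_m"] = tomo.wavelength_m
        if tomo.provenance:
            g.attrs["provenance"] = json.dumps(tomo.provenance, default=str)


def read_tomogram(path) -> Tomogram:
    with h5py.File(path, "r") as f:
        g = f["tomo"]
        prov = json.loads(g.attrs["provenance"]) if "provenance" in g.attrs else None
        return Tomogram(
            delta=g["delta"][...],
            voxel_size_nm=float(g.attrs["voxel_size_nm"]),
            wavelength_m=float(g.attrs["wavelength_m"]),
            provenance=prov,
        )


def export_tiff_slices(path, volume: np.ndarray) -> None:
    """Multi-page TIFF of axial (y) slices for visual inspection."""
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
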