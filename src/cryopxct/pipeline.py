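"""End-to-end orchestration: phantom → simulate → ptycho → align → tomo → quant.

A :class:`RunConfig` fully determines a run: the phantom, the acquisition
geometry, solver iteration counts and alignment settings, plus a master
seed from which every stage derives its own substream (stage name + angle
index hashed into the seed), so runs are bit-reproducible and inserting a
stage never silently changes another stage's random stream.

Profiles scale angle count, detector size and iteration counts together
so that a full desk-scale run finishes in minutes; the paper-geometry
profiles keep the published optics numbers (energy, distance, detector
region/pitch — hence the 43.25 nm pixel) exactly while the simulation
remains desk-sized.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import align as al
from . import forward_model as fm
from . import io as pio
from . import phantom as ph
from . import ptycho as pt
from . import quant as qu
from . import tomo as tm
from .config import OpticsConfig

__all__ = ["RunConfig", "profile_config", "run_pipeline", "make_fixture", "stage_seed"]

PROFILES = ("unit", "desk", "noisy-desk", "paper-A", "paper-B", "paper-C")


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Derived per-stage seed: sha256(master:stage:index) mod 2^31."""
    h = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    profile: str = "desk"
    seed: int = 0
    output_dir: str | None = None
    # phantom
    phantom_shape: tuple[int, int, int] = (64, 128, 128)
    phantom: dict = field(default_factory=dict)  # extra PhantomSpec overrides
    # optics / acquisition
    optics: dict = field(default_factory=dict)  # OpticsConfig overrides
    pixel_size_nm: float = 305.0
    frame_px: int = 64
    probe_px: int = 31
    #: width of the air margin around the sample that the scan must cover
    #: (used as the phase-zero reference); the ptycho object grid extends a
    #: further frame_px/2 beyond it so every probe window fits.
    air_px: int = 8
    scan_step_px: float = 17.0
    n_angles: int = 60
    noise: bool = False
    # solver
    n_dm: int = 150
    n_ml: int = 30
    #: probe retrieval needs a well-overlapped scan; tiny scans (unit
    #: profile) keep the simulated probe fixed instead
    update_probe: bool = True
    defocus_rad: float = 3.0
    # alignment
    align_n_outer: int = 6
    bad_projection_k: float = 5.0
    removed_overrides: list[int] = field(default_factory=list)
    run_alignment: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom_shape"] = list(self.phantom_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom_shape"] = tuple(d["phantom_shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # ------------------------------------------------------------------
    def make_optics(self) -> OpticsConfig:
        """Optics whose reconstruction pixel matches ``pixel_size_nm``.

        Explicit ``optics`` overrides win; otherwise the detector pitch is
        solved from the requested pixel size at the default energy and
        distance.
        """
        base = dict(
            photon_energy_kev=6.20,
            detector_distance_m=7.33,
            detector_region_px=self.frame_px,
            probe_diameter_m=self.probe_px * self.pixel_size_nm * 1e-9,
            fluence_per_projection=1e7,
        )
        base.update(self.optics)
        if "detector_pixel_pitch_m" not in base:
            lam = 1.23984193e-9 / base["photon_energy_kev"]
            base["detector_pixel_pitch_m"] = (
                lam
                * base["detector_distance_m"]
                / (base["detector_region_px"] * self.pixel_size_nm * 1e-9)
            )
        return OpticsConfig(**base)

    def make_phantom_spec(self) -> ph.PhantomSpec:
        kw = dict(shape=self.phantom_shape, voxel_size_nm=self.pixel_size_nm)
        kw.update(self.phantom)
        return ph.PhantomSpec(**kw)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * 180.0 / self.n_angles


def profile_config(profile: str, seed: int = 0, output_dir: str | None = None) -> RunConfig:
    """Canonical configurations per profile name."""
    if profile == "unit":
        return RunConfig(
            profile=profile,
            seed=seed,
            output_dir=output_dir,
            phantom_shape=(16, 32, 32),
            phantom=dict(
                n_axons=1,
                n_cells=0,
                n_vacuoles=1,
                axon_radius_vox=(3.0, 4.0),
                myelin_thickness_vox=(1.5, 2.0),
            ),
            pixel_size_nm=600.0,
            frame_px=32,
            probe_px=15,
            air_px=4,
            scan_step_px=8.9,
            n_angles=16,
            n_dm=40,
            n_ml=5,
            update_probe=False,
        )
    if profile in ("desk", "noisy-desk"):
        return RunConfig(
            profile=profile,
            seed=seed,
            output_dir=output_dir,
            noise=(profile == "noisy-desk"),
        )
    if profile in ("paper-A", "paper-B", "paper-C"):
        n_proj = {"paper-A": 446, "paper-B": 894, "paper-C": 785}[profile]
        iters = {"paper-A": (800, 150), "paper-B": (600, 100), "paper-C": (600, 100)}[
            profile
        ]
        optics = OpticsConfig()  # published geometry: 6.2 keV, 7.33 m, 452 px, 75 µm
        cfg = RunConfig(
            profile=profile,
            seed=seed,
            output_dir=output_dir,
            optics=optics.to_dict(),
            pixel_size_nm=optics.pixel_size_nm,
            frame_px=452,
            probe_px=int(round(optics.probe_diameter_m / optics.pixel_size_m)),
            scan_step_px=2.2e-6 / optics.pixel_size_m,
            n_angles=n_proj,
            n_dm=iters[0],
            n_ml=iters[1],
        )
        return cfg
    raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")


# ----------------------------------------------------------------------


def _geometry(config: RunConfig, core_shape: tuple[int, int]):
    """Scan pattern, object-grid padding and air mask for a projection.

    The scan covers the sample plus an ``air_px`` margin on every side
    (Fermat spiral clipped to that rectangle); the ptycho object grid
    extends a further frame_px/2 so each probe window stays inside it.
    The air mask marks the well-illuminated air strips flanking the
    sample, used as the phase-zero reference for ramp removal.
    """
    ny, nx = core_shape
    p = config.pixel_size_nm * 1e-9
    air = config.air_px
    pad = air + config.frame_px // 2
    padded_shape = (ny + 2 * pad, nx + 2 * pad)
    fov = ((nx + 2 * air) * p, (ny + 2 * air) * p)
    scan = fm.fermat_spiral(fov, config.scan_step_px * p)
    m = np.zeros(padded_shape, bool)
    rows = slice(pad - air, pad + ny + air)
    m[rows, pad - air : pad] = True
    m[rows, pad + nx : pad + nx + air] = True
    return scan, pad, padded_shape, m


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the full chain and return the run report.

    Persists every intermediate artifact (HDF5) when ``output_dir`` is
    set.  Any stage error aborts with the stage name attached.
    """
    t0 = time.time()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    report: dict = {"profile": config.profile, "seed": config.seed, "stages": {}}

    def _stage(name):
        log(f"[{config.profile}] stage {name} ({time.time() - t0:.1f}s)")

    stage = "phantom"
    try:
        _stage(stage)
        spec = config.make_phantom_spec()
        phan = ph.build_phantom(spec, seed=stage_seed(config.seed, "phantom"))
        optics = config.make_optics()
        lam = optics.wavelength_m
        if outdir:
            pio.write_phantom(outdir / "phantom.h5", phan)
        report["voxel_size_nm"] = optics.pixel_size_nm
        report["wavelength_m"] = lam

        stage = "simulate"
        _stage(stage)
        ny, nx, _ = phan.shape
        scan, pad, padded_shape, air = _geometry(config, (ny, nx))
        n_pos = scan.n_positions
        fov_area_um2 = (
            scan.field_of_view_m[0] * scan.field_of_view_m[1] * 1e12
        )
        total_photons = max(
            optics.fluence_per_projection * fov_area_um2 / max(n_pos, 1), 1.0
        )
        probe = fm.make_probe(
            optics,
            grid_px=config.frame_px,
            total_photons=total_photons,
            defocus_rad=config.defocus_rad,
        )
        angles = config.angles_deg
        datasets = []
        truth_phases = []
        for i, ang in enumerate(angles):
            proj = ph.ground_truth_projection(phan, float(ang), lam)
            t_pad = np.pad(proj.transmission, pad, mode="constant", constant_values=1.0)
            truth_phases.append(np.pad(proj.phase, pad))
            datasets.append(
                fm.simulate_diffraction(
                    t_pad,
                    probe,
                    scan,
                    angle_deg=float(ang),
                    noise=config.noise,
                    seed=stage_seed(config.seed, "noise", i) if config.noise else None,
                    optics=optics,
                )
            )
        report["stages"]["simulate"] = {
            "n_angles": len(angles),
            "n_positions": n_pos,
            "photons_per_frame": total_photons,
        }
        if outdir:
            pio.write_diffraction(outdir / "frames.h5", datasets, optics, config.seed)

        stage = "ptycho"
        _stage(stage)
        recon_objs = []
        final_errors = []
        for i, data in enumerate(datasets):
            res = pt.dm_reconstruct(
                data,
                probe,
                object_shape=padded_shape,
                n_iter=config.n_dm,
                update_probe=config.update_probe,
                gauge_mask=air,
            )
            if config.n_ml > 0:
                res = pt.ml_refine(
                    res,
                    data,
                    n_iter=config.n_ml,
                    update_probe=config.update_probe,
                    gauge_mask=air,
                )
            recon_objs.append(res.object)
            final_errors.append(res.fourier_error_history[-1])
            if outdir and i == 0:
                pio.write_projection(outdir / "proj_000.h5", res, float(angles[i]))
        report["stages"]["ptycho"] = {
            "n_dm": config.n_dm,
            "n_ml": config.n_ml,
            "median_final_fourier_error": float(np.median(final_errors)),
        }

        stage = "align"
        _stage(stage)
        # restrict to the analysis region (sample + air margin): the outer
        # frame/2 band of the object grid is only weakly illuminated and
        # its retrieved phase is meaningless
        a_px = config.air_px
        crop = (
            slice(pad - a_px, pad + ny + a_px),
            slice(pad - a_px, pad + nx + a_px),
        )
        air_c = air[crop]
        cropped_shape = (ny + 2 * a_px, nx + 2 * a_px)
        derivs = np.empty((len(angles),) + cropped_shape)
        amps = np.empty_like(derivs)
        for i, obj in enumerate(recon_objs):
            o = obj[crop]
            d = al.phase_derivative(o)
            phase = al.remove_ramp(al.integrate_derivative(d), air_c)
            derivs[i] = np.pad(np.diff(phase, axis=1), ((0, 0), (0, 1)))
            amps[i] = np.abs(o)
        sample_region = np.zeros(cropped_shape, bool)
        sample_region[a_px : a_px + ny, a_px : a_px + nx] = True
        removed = sorted(
            set(
                al.flag_bad_projections(
                    amps, support_mask=sample_region, k=config.bad_projection_k
                )
                + list(config.removed_overrides)
            )
        )
        keep = [i for i in range(len(angles)) if i not in removed]
        derivs = derivs[keep]
        kept_angles = angles[keep]
        shifts = np.zeros((len(keep), 2))
        if config.run_alignment:
            # alignment operates on rows whose integrated-phase mass is
            # stable across angles: rows near the frame edge (weak probe
            # coverage) accumulate large integration noise and would
            # dominate the registration
            prof = al.integrate_derivative(derivs).sum(axis=2)
            row_std = prof.std(axis=0)
            good = row_std < 0.1 * np.abs(prof.mean(axis=0)).max()
            if good.any():
                r0 = int(np.argmax(good))
                r1 = int(len(good) - np.argmax(good[::-1]))
            else:
                r0, r1 = derivs.shape[1] // 4, 3 * derivs.shape[1] // 4
            rows = slice(r0, r1)
            dy, _ = al.vertical_align(derivs[:, rows, :])
            derivs = al.shift_vertical(derivs, -dy)
            dx0, _ = al.com_prealign(derivs[:, rows, :], kept_angles)
            dx, info = al.consistency_align(
                derivs[:, rows, :],
                kept_angles,
                n_outer=config.align_n_outer,
                init_shifts=dx0,
            )
            derivs = al.shift_rows(derivs, dx)
            shifts = np.stack([-dy, dx], axis=1)
            report["stages"]["align"] = {
                "removed": removed,
                "consistency": {k: v for k, v in info.items() if k != "residual_history"},
            }
        weights = al.angular_weights(kept_angles)
        # crop the air margin back off: tomogram grid == phantom grid
        core = derivs[:, a_px : a_px + ny, a_px : a_px + nx]
        sino = al.AlignedSinogram(
            derivative_projections=core,
            angles_deg=kept_angles,
            shifts_px=shifts,
            weights=weights,
            removed_indices=removed,
        )
        if outdir:
            pio.write_sinogram(outdir / "sinogram.h5", sino)

        stage = "tomo"
        _stage(stage)
        tomogram = tm.derivative_fbp(
            sino,
            voxel_size_nm=config.pixel_size_nm,
            wavelength_m=lam,
            provenance={"config": config.to_dict(), "removed": removed},
        )
        if outdir:
            pio.write_tomogram(outdir / "tomogram.h5", tomogram)

        stage = "quant"
        _stage(stage)
        n_e = np.asarray(tomogram.electron_density)
        densities = {}
        for name in ("medium", "cytoplasm", "nucleus", "myelin", "axoplasm",
                     "vacuole_lipid", "vacuole_pigment"):
            mask = phan.label_mask(name)
            eroded = ndimage.binary_erosion(mask, iterations=2)
            if eroded.sum() >= 8:
                densities[name] = {
                    "assigned_e_A3": phan.densities[name],
                    "recovered_median_e_A3": float(np.median(n_e[eroded])),
                }
        report["feature_densities"] = densities
        dose = qu.estimate_dose(
            qu.DoseParams(
                fluence_per_projection=optics.fluence_per_projection,
                photon_energy_kev=optics.photon_energy_kev,
                n_projections=len(keep),
            )
        )
        report["dose_gy"] = dose
        half_a, half_b = tm.split_half_tomograms(
            sino, voxel_size_nm=config.pixel_size_nm, wavelength_m=lam
        )
        fsc_res = qu.fsc(half_a.delta, half_b.delta, voxel_size_nm=config.pixel_size_nm)
        report["fsc_resolution_nm"] = fsc_res.resolution_nm
        # density-band segmentation of the vacuoles (lowest-density band)
        d_vac = phan.densities["vacuole_lipid"]
        d_next = min(phan.densities["myelin"], phan.densities["medium"])
        bands = {"vacuole": (d_vac - 0.5 * (d_next - d_vac), 0.5 * (d_vac + d_next))}
        labels, table = qu.segment_density_bands(n_e, bands, min_voxels=27)
        report["segmentation"] = {
            "vacuole_components": len(table),
            "size_stats": qu.feature_size_stats(table, config.pixel_size_nm),
        }
        report["elapsed_s"] = time.time() - t0
        if outdir:
            (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        return report
    except Exception as exc:
        exc.args = (f"pipeline stage {stage!r} failed: {exc}",) + exc.args[1:]
        if outdir:
            (outdir / "failed_stage.txt").write_text(stage)
        raise


def make_fixture(profile: str, seed: int, output_dir) -> dict:
    """Generate and store a miniature dataset + ground truth for tests."""
    if profile not in ("unit", "desk", "noisy-desk"):
        raise ValueError(
            f"unknown fixture profile {profile!r}; choose from unit, desk, noisy-desk"
        )
    cfg = profile_config(profile, seed=seed)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cfg.make_phantom_spec()
    phan = ph.build_phantom(spec, seed=stage_seed(seed, "phantom"))
    optics = cfg.make_optics()
    pio.write_phantom(outdir / "phantom.h5", phan)
    ny, nx, _ = phan.shape
    scan, pad, padded_shape, _ = _geometry(cfg, (ny, nx))
    fov_area_um2 = scan.field_of_view_m[0] * scan.field_of_view_m[1] * 1e12
    total_photons = max(
        optics.fluence_per_projection * fov_area_um2 / max(scan.n_positions, 1), 1.0
    )
    probe = fm.make_probe(
        optics, grid_px=cfg.frame_px, total_photons=total_photons,
        defocus_rad=cfg.defocus_rad,
    )
    datasets = []
    for i, ang in enumerate(cfg.angles_deg):
        proj = ph.ground_truth_projection(phan, float(ang), optics.wavelength_m)
        t_pad = np.pad(proj.transmission, pad, mode="constant", constant_values=1.0)
        datasets.append(
            fm.simulate_diffraction(
                t_pad, probe, scan, angle_deg=float(ang), noise=cfg.noise,
                seed=stage_seed(seed, "noise", i) if cfg.noise else None,
                optics=optics,
            )
        )
    pio.write_diffraction(outdir / "frames.h5", datasets, optics, seed)
    cfg.to_yaml(outdir / "config.yaml")
    return {
        "n_angles": len(datasets),
        "n_positions": scan.n_positions,
        "frame_px": cfg.frame_px,
        "paths": [str(outdir / p) for p in ("phantom.h5", "frames.h5", "config.yaml")],
    }
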