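"""Raw-data and image containers, HDF5 round-trip, NIfTI export.

The package-native raw container is an HDF5 file with layout::

    /kspace       complex (arm, sample, coil)
    /trajectory   float   (arm, sample, 2)   cycles/mm
    /dcf          float   (arm, sample)      optional
    /caipi_phase  complex (slice, arm)
    /truth/...    optional ground-truth group (synthetic data only)
    attrs: tr_ms, te_ms, dwell_time_s, sms_factor, slice_positions_mm,
           fov_mm, matrix_size, seed, noise_sigma, kmax, n_arms_full

Image series export uses NIfTI with the frame axis as the 4th dimension and
pixel spacing / frame duration in the header zooms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

from .trajectory import SpiralTrajectory

__all__ = ["RawData", "ImageSeries", "read_raw", "write_raw", "write_nifti", "read_nifti"]


class FormatError(ValueError):
    """Container does not match the expected HDF5 schema."""


@dataclass
class RawData:
    """In-memory raw acquisition: multi-coil spiral k-space plus metadata."""

    kspace: np.ndarray  # (arm, sample, coil) complex
    trajectory: SpiralTrajectory
    caipi_phase: np.ndarray  # (slice, arm) unit-modulus complex
    tr_ms: float
    sms_factor: int
    slice_positions_mm: np.ndarray
    fov_mm: float
    matrix_size: int
    seed: int = 0
    te_ms: float = 0.0
    noise_sigma: float = 0.0
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        a, s, _ = self.kspace.shape
        if self.trajectory.kx.shape != (a, s):
            raise FormatError("trajectory shape does not match k-space")
        if self.caipi_phase.shape != (self.sms_factor, a):
            raise FormatError("caipi_phase shape must be (sms_factor, n_arms)")
        if not np.allclose(np.abs(self.caipi_phase), 1.0, atol=1e-9):
            raise FormatError("caipi_phase must be unit modulus")

    @property
    def n_arms(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[2]

    @property
    def pixel_spacing(self) -> float:
        return self.fov_mm / self.matrix_size


@dataclass
class ImageSeries:
    """Reconstructed complex frames per slice: (slice, frame, y, x)."""

    data: np.ndarray
    pixel_spacing: float  # mm
    frame_duration_ms: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


def write_raw(raw: RawData, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=raw.kspace)
        traj = np.stack([raw.trajectory.kx, raw.trajectory.ky], axis=-1)
        f.create_dataset("trajectory", data=traj)
        if raw.trajectory.dcf is not None:
            f.create_dataset("dcf", data=raw.trajectory.dcf)
        f.create_dataset("caipi_phase", data=raw.caipi_phase)
        f.attrs["tr_ms"] = raw.tr_ms
        f.attrs["te_ms"] = raw.te_ms
        f.attrs["dwell_time_s"] = raw.trajectory.dwell_time
        f.attrs["sms_factor"] = raw.sms_factor
        f.attrs["slice_positions_mm"] = np.asarray(raw.slice_positions_mm, dtype=float)
        f.attrs["fov_mm"] = raw.fov_mm
        f.attrs["matrix_size"] = raw.matrix_size
        f.attrs["seed"] = raw.seed
        f.attrs["noise_sigma"] = raw.noise_sigma
        f.attrs["kmax"] = raw.trajectory.kmax
        f.attrs["n_arms_full"] = raw.trajectory.n_arms_full
        f.attrs["arm_angles"] = raw.trajectory.arm_angles
        if raw.truth is not None:
            g = f.create_group("truth")
            g.attrs["sigma"] = raw.truth.get("sigma", 0.0)
            g.attrs["seed"] = raw.truth.get("seed", 0)
            g.attrs["blood_attenuation"] = raw.truth.get("blood_attenuation", 1.0)
            g.attrs["slice_set"] = np.asarray(raw.truth.get("slice_set", []), dtype=int)
            if "coil_maps" in raw.truth:
                g.create_dataset("coil_maps", data=raw.truth["coil_maps"])
            if "spec" in raw.truth:
                g.attrs["spec_json"] = json.dumps(raw.truth["spec"])


def read_raw(path) -> RawData:
    with h5py.File(path, "r") as f:
        for name in ("kspace", "trajectory", "caipi_phase"):
            if name not in f:
                raise FormatError(f"missing dataset /{name} in {path}")
        for attr in ("tr_ms", "sms_factor", "fov_mm", "matrix_size"):
            if attr not in f.attrs:
                raise FormatError(f"missing attribute {attr} in {path}")
        traj_arr = f["trajectory"][()]
        traj = SpiralTrajectory(
            kx=np.ascontiguousarray(traj_arr[..., 0]),
            ky=np.ascontiguousarray(traj_arr[..., 1]),
            arm_angles=f.attrs.get("arm_angles", np.zeros(traj_arr.shape[0])),
            dwell_time=float(f.attrs.get("dwell_time_s", 0.0)),
            kmax=float(f.attrs.get("kmax", np.hypot(traj_arr[..., 0], traj_arr[..., 1]).max())),
            fov=float(f.attrs["fov_mm"]),
            n_arms_full=int(f.attrs.get("n_arms_full", traj_arr.shape[0])),
            dcf=f["dcf"][()] if "dcf" in f else None,
        )
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = {
                "sigma": float(g.attrs.get("sigma", 0.0)),
                "seed": int(g.attrs.get("seed", 0)),
                "blood_attenuation": float(g.attrs.get("blood_attenuation", 1.0)),
                "slice_set": list(g.attrs.get("slice_set", [])),
            }
            if "coil_maps" in g:
                truth["coil_maps"] = g["coil_maps"][()]
            if "spec_json" in g.attrs:
                truth["spec"] = json.loads(g.attrs["spec_json"])
        return RawData(
            kspace=f["kspace"][()],
            trajectory=traj,
            caipi_phase=f["caipi_phase"][()],
            tr_ms=float(f.attrs["tr_ms"]),
            te_ms=float(f.attrs.get("te_ms", 0.0)),
            sms_factor=int(f.attrs["sms_factor"]),
            slice_positions_mm=np.asarray(f.attrs.get("slice_positions_mm", [0.0])),
            fov_mm=float(f.attrs["fov_mm"]),
            matrix_size=int(f.attrs["matrix_size"]),
            seed=int(f.attrs.get("seed", 0)),
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
            truth=truth,
        )


def write_nifti(series: ImageSeries, path, slice_index: int = 0) -> None:
    """Write one slice's magnitude series as a 4D NIfTI (y, x, 1, frame)."""
    mag = np.abs(series.data[slice_index])  # (frame, y, x)
    vol = np.transpose(mag, (1, 2, 0))[:, :, None, :]
    aff = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), aff)
    img.header.set_zooms((series.pixel_spacing, series.pixel_spacing, 1.0,
                          series.frame_duration_ms / 1000.0))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_nifti(path) -> ImageSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)  # (y, x, 1, frame)
    data = np.transpose(vol[:, :, 0, :], (2, 0, 1))[None]
    zooms = img.header.get_zooms()
    return ImageSeries(
        data=data.astype(np.complex128),
        pixel_spacing=float(zooms[0]),
        frame_duration_ms=float(zooms[3]) * 1000.0 if len(zooms) > 3 else 0.0,
    )
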