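"""Readers, writers and domain containers for the formats the pipeline touches.

All images are NIfTI-1/2 (via nibabel); the plethysmogram and motion
parameters are plain-text/TSV.  Voxel indices are 0-based, and every loader
enforces exact grid agreement with the BOLD reference — spatial resampling
and registration are deliberately outside this package: masks must already
live on the fMRI grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryMismatchError, PulseVesselError

__all__ = [
    "Bold4D",
    "Mask3D",
    "PhysioTrace",
    "MotionTable",
    "load_bold",
    "load_mask",
    "load_physio",
    "load_motion",
    "save_mask",
    "save_map",
]

MASK_LABELS = ("brain", "general_artery", "general_sss", "segmentation", "ground_truth")


@dataclass
class Bold4D:
    """A 4D BOLD series: ``data[x, y, z, t]`` in arbitrary scanner units.

    Parameters
    ----------
    data : ndarray
        4D array, spatial axes first, time last.
    voxel_dims : ndarray
        Voxel edge lengths in mm, shape (3,), all positive.
    tr : float
        Repetition time in seconds.
    slice_offsets : ndarray or None
        Optional per-slice acquisition offset within a volume, seconds,
        each in ``[0, tr)``.  When absent all slices of a volume are
        treated as acquired at the volume onset plus ``tr / 2``.
    affine : ndarray
        4x4 voxel-to-world map; carried through to outputs, never
        interpreted.
    """

    data: np.ndarray
    voxel_dims: np.ndarray
    tr: float
    slice_offsets: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise PulseVesselError(
                f"not a 4D series: got {self.data.ndim} dimensions"
            )
        if self.data.shape[3] < 2:
            raise PulseVesselError("BOLD series needs at least 2 timepoints")
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.voxel_dims.shape != (3,) or np.any(self.voxel_dims <= 0):
            raise PulseVesselError("voxel_dims must be 3 positive lengths (mm)")
        if not self.tr > 0:
            raise PulseVesselError(f"repetition time must be positive, got {self.tr}")
        if self.slice_offsets is not None:
            self.slice_offsets = np.asarray(self.slice_offsets, dtype=float)
            if self.slice_offsets.shape != (self.data.shape[2],):
                raise PulseVesselError(
                    "slice_offsets must have one entry per slice "
                    f"({self.data.shape[2]}), got {self.slice_offsets.shape}"
                )
            if np.any(self.slice_offsets < 0) or np.any(self.slice_offsets >= self.tr):
                raise PulseVesselError("slice_offsets must lie in [0, tr)")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def acquisition_times(self) -> np.ndarray:
        """Per-(slice, volume) acquisition times, shape (nz, t), seconds.

        Time zero is the onset of the first volume in this series.
        """
        onsets = np.arange(self.n_volumes) * self.tr
        if self.slice_offsets is None:
            offs = np.full(self.data.shape[2], self.tr / 2.0)
        else:
            offs = self.slice_offsets
        return offs[:, None] + onsets[None, :]


@dataclass
class Mask3D:
    """A binary mask on the BOLD voxel grid, tagged with its role."""

    data: np.ndarray
    label: str = "segmentation"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise PulseVesselError(f"mask must be 3D, got {self.data.ndim}D")
        if self.label not in MASK_LABELS:
            raise PulseVesselError(
                f"unknown mask label {self.label!r}; expected one of {MASK_LABELS}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, reference: "Bold4D | Mask3D") -> None:
        ref_shape = (
            reference.spatial_shape
            if isinstance(reference, Bold4D)
            else reference.data.shape
        )
        if self.data.shape != tuple(ref_shape):
            raise GeometryMismatchError(
                f"mask grid {self.data.shape} does not match reference "
                f"grid {tuple(ref_shape)}"
            )


@dataclass
class PhysioTrace:
    """A finger-plethysmography (PPG) recording.

    ``t0`` is the time of the first sample relative to the first *retained*
    fMRI volume (after trimming), in seconds.  The synchronization
    convention between scanner and physiological clocks varies between
    sites, so ``t0`` is user-provided metadata; it defaults to 0.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise PulseVesselError("sampling rate must be positive")
        if self.samples.size < 2 * self.fs:
            raise PulseVesselError(
                "trace too short: need at least 2 s of samples "
                f"({int(2 * self.fs)}), got {self.samples.size}"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class MotionTable:
    """Per-volume rigid-motion parameters.

    Columns follow the FSL MCFLIRT convention: three rotations (rad) then
    three translations (mm), relative to the reference volume.
    ``covers`` declares whether rows correspond to the original or the
    retained (trimmed) volume count.
    """

    params: np.ndarray
    covers: str = "original"

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[0] < 1 or self.params.shape[1] != 6:
            raise PulseVesselError(
                f"motion table must be (n_volumes, 6), got {self.params.shape}"
            )
        if self.covers not in ("original", "retained"):
            raise PulseVesselError("covers must be 'original' or 'retained'")

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, 3:6]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 0:3]


def load_bold(path: str | Path, tr: float | None = None) -> Bold4D:
    """Load a 4D NIfTI BOLD series.

    TR precedence: an explicit ``tr`` argument wins over the NIfTI header
    ``pixdim[4]``; if both are available and disagree by more than 1 ms a
    warning is emitted.  Slice timing is not stored in NIfTI-1 headers in a
    portable way, so ``slice_offsets`` must be attached by the caller.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise PulseVesselError(f"not a 4D series: {path} has {data.ndim} dimensions")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if not header_tr > 0:
            raise PulseVesselError(
                f"{path}: header TR is {header_tr}; pass tr= explicitly"
            )
        tr = header_tr
    elif header_tr > 0 and abs(header_tr - tr) > 1e-3:
        warnings.warn(
            f"{path}: header TR {header_tr:.4f} s differs from configured "
            f"TR {tr:.4f} s by more than 1 ms; using the configured value",
            stacklevel=2,
        )
    voxel_dims = np.asarray(zooms[:3], dtype=float)
    return Bold4D(data=data.astype(np.float64), voxel_dims=voxel_dims, tr=float(tr),
                  affine=img.affine)


def load_mask(path: str | Path, reference: Bold4D, label: str = "segmentation") -> Mask3D:
    """Load a 3D mask; values > 0.5 map to foreground.

    Raises :class:`GeometryMismatchError` if the grid differs from the
    reference BOLD — inputs are never resampled.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise PulseVesselError(f"mask {path} must be 3D, got {data.ndim}D")
    if data.shape != tuple(reference.spatial_shape):
        raise GeometryMismatchError(
            f"mask {path} grid {data.shape} does not match BOLD grid "
            f"{tuple(reference.spatial_shape)}"
        )
    return Mask3D(data=data > 0.5, label=label)


def load_physio(path: str | Path, fs: float | None = None, t0: float = 0.0) -> PhysioTrace:
    """Load a plethysmogram from a single- or two-column text/TSV file.

    Two-column files are read as (time s, value); the sampling rate is
    inferred from the median time step, with a warning if the step jitter
    exceeds 1%.  Single-column files require ``fs``.
    """
    arr = np.atleast_2d(np.loadtxt(str(path)))
    if arr.shape[0] == 1 and arr.shape[1] > 2:
        arr = arr.T
    if arr.shape[1] == 1:
        if fs is None:
            raise PulseVesselError("single-column physio requires an explicit fs")
        samples = arr[:, 0]
    elif arr.shape[1] == 2:
        t, samples = arr[:, 0], arr[:, 1]
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise PulseVesselError(f"{path}: time column is not strictly increasing")
        med = float(np.median(dt))
        if np.max(np.abs(dt - med)) > 0.01 * med:
            warnings.warn(
                f"{path}: time-step jitter exceeds 1% of the median step",
                stacklevel=2,
            )
        inferred = 1.0 / med
        if fs is None:
            fs = inferred
        t0 = float(t[0]) if t0 == 0.0 else t0
    else:
        raise PulseVesselError(
            f"physio file must have 1 or 2 columns, got {arr.shape[1]}"
        )
    return PhysioTrace(samples=samples, fs=float(fs), t0=float(t0))


def load_motion(path: str | Path, covers: str = "original") -> MotionTable:
    """Load a 6-column MCFLIRT-style motion parameter table."""
    params = np.loadtxt(str(path))
    return MotionTable(params=params, covers=covers)


def save_mask(mask: Mask3D, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a binary mask as uint8 NIfTI."""
    aff = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    nib.save(img, str(path))


def save_map(values: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a 3D real-valued map (e.g. a correlation map) as float32 NIfTI."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise PulseVesselError(f"map must be 3D, got {values.ndim}D")
    aff = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(values.astype(np.float32), aff)
    nib.save(img, str(path))
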