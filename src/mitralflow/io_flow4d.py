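"""Reading, writing and validation of 4D flow datasets and LV mask stacks.

A 4D flow acquisition encodes the three velocity components of blood flow
over the cardiac cycle.  Internally velocities live on a 5-axis grid
``[phase, z, y, x, component]`` in m/s, with components ``(vx, vy, vz)``
expressed in the scanner frame; voxel spacing is ``(dz, dy, dx)`` in mm.
Phase-contrast scanners store each component as a phase value normalised to
``[-1, 1)``; the velocity-encoding limit (VENC) maps that interval linearly
onto ``[-VENC, +VENC)``.  Velocities beyond the VENC wrap around (aliasing);
following clinical practice such voxels are flagged and reported, never
phase-unwrapped.

On disk a dataset is a 5-D NIfTI volume (file axes ``x, y, z, phase,
component``) plus a JSON sidecar carrying the VENC, RR interval and phase
duration.  Masks are NIfTI volumes with integer labels {0, 1}.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Flow4DDataset",
    "LVMaskStack",
    "AliasFlagMap",
    "load_flow4d",
    "save_flow4d",
    "load_mask_stack",
    "save_mask_stack",
    "scale_phase_to_velocity",
    "flag_aliasing",
]


class ValidationError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class Flow4DDataset:
    """Time-resolved three-component velocity field with geometry metadata.

    Attributes
    ----------
    velocity : ndarray, shape (n_phases, nz, ny, nx, 3), m/s
        Velocity components ``(vx, vy, vz)`` in the scanner frame.
    voxel_spacing : tuple of float, mm
        ``(dz, dy, dx)``.
    affine : ndarray, shape (4, 4)
        Voxel-index ``(x, y, z)`` to scanner-frame mm map.
    phase_duration : float, ms
        Temporal width of one reconstructed cardiac phase.
    rr_interval : float, ms
        Length of the (averaged) cardiac cycle.
    venc : float, m/s
        Velocity-encoding limit of the acquisition.
    magnitude : ndarray or None
        Optional magnitude image on the same grid (arbitrary units).
    """

    velocity: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray
    phase_duration: float
    rr_interval: float
    venc: float
    magnitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValidationError(
                "velocity must have axes [phase, z, y, x, component]; got "
                f"shape {self.velocity.shape}"
            )
        if self.n_phases < 2:
            raise ValidationError("need at least 2 cardiac phases")
        if self.venc <= 0:
            raise ValidationError("VENC must be positive")
        if not np.isfinite(self.velocity).all():
            raise ValidationError("velocity grid contains non-finite values")
        # temporal consistency: phases should tile one RR interval
        if abs(self.phase_duration * self.n_phases - self.rr_interval) > self.phase_duration:
            raise ValidationError(
                f"phase_duration ({self.phase_duration} ms) x n_phases "
                f"({self.n_phases}) inconsistent with rr_interval "
                f"({self.rr_interval} ms)"
            )

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return self.velocity.shape[1:4]

    def phase_times_ms(self) -> np.ndarray:
        """Mid-phase times, ms from the R-wave."""
        return (np.arange(self.n_phases) + 0.5) * self.phase_duration

    def scaled(self, c: float) -> "Flow4DDataset":
        """Return a copy with every velocity component multiplied by ``c``."""
        return replace(self, velocity=self.velocity * c, magnitude=self.magnitude)


@dataclass
class LVMaskStack:
    """Per-phase binary LV cavity masks on axes ``[phase, z, y, x]``.

    ``frame_tag`` records which grid the mask lives on (e.g. ``"cine"`` or
    ``"flow"``); translation of a cine-grid mask onto the flow grid is done
    by :func:`mitralflow.lv_volumes.apply_offset`.
    """

    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray
    frame_tag: str = "flow"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask.ndim != 4:
            raise ValidationError(
                f"mask must have axes [phase, z, y, x]; got shape {self.mask.shape}"
            )
        counts = self.mask.reshape(self.mask.shape[0], -1).sum(axis=1)
        if (counts == 0).any():
            empty = np.nonzero(counts == 0)[0].tolist()
            raise ValidationError(f"mask empty at phases {empty}")

    @property
    def n_phases(self) -> int:
        return self.mask.shape[0]


@dataclass
class AliasFlagMap:
    """Voxels of one phase whose speed approaches the VENC (wrap candidates)."""

    flags: np.ndarray
    venc_fraction: float = 0.98
    phase: int = 0

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


# ---------------------------------------------------------------------------
# phase-value scaling and aliasing


def scale_phase_to_velocity(stored: np.ndarray, venc: float) -> np.ndarray:
    """Convert stored phase values in ``[-1, 1)`` to velocities in m/s.

    The map is linear: ``v = stored * venc``, so ``-1`` maps to ``-VENC``
    and values just below ``+1`` map to just below ``+VENC``.
    """
    stored = np.asarray(stored, dtype=np.float64)
    lo, hi = float(stored.min(initial=0.0)), float(stored.max(initial=0.0))
    if lo < -1.0 or hi >= 1.0:
        raise ValueError(
            f"stored phase values must lie in [-1, 1); found range [{lo}, {hi}]"
        )
    return stored * float(venc)


def flag_aliasing(ds: Flow4DDataset, venc_fraction: float = 0.98) -> list[AliasFlagMap]:
    """Flag voxels whose largest component magnitude reaches the VENC.

    A voxel is flagged when ``max_c |v_c| >= venc_fraction * venc``.  Flagged
    voxels are candidates for velocity wrap-around; they are reported (and
    counted in the log) but never unwrapped.
    """
    if not 0.0 < venc_fraction <= 1.0:
        raise ValueError("venc_fraction must be in (0, 1]")
    threshold = venc_fraction * ds.venc
    maps = []
    for p in range(ds.n_phases):
        flags = np.abs(ds.velocity[p]).max(axis=-1) >= threshold
        maps.append(AliasFlagMap(flags=flags, venc_fraction=venc_fraction, phase=p))
    total = sum(m.n_flagged for m in maps)
    logger.info("aliasing scan: %d voxel(s) flagged at %.2f x VENC", total, venc_fraction)
    return maps


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
#
# File layout: NIfTI data axes are (x, y, z, phase, component); internally we
# use [phase, z, y, x, component].  The two are related by transposing the
# spatial/temporal axes only — component order is (vx, vy, vz) in both.

_REQUIRED_META = ("rr_ms", "phase_duration_ms")


def _to_file_axes(vel: np.ndarray) -> np.ndarray:
    return np.transpose(vel, (3, 2, 1, 0, 4))


def _from_file_axes(arr: np.ndarray) -> np.ndarray:
    return np.transpose(arr, (3, 2, 1, 0, 4))


def save_flow4d(ds: Flow4DDataset, velocity_path: str | Path, metadata_path: str | Path) -> None:
    """Write a dataset as a 5-D NIfTI plus JSON sidecar."""
    velocity_path, metadata_path = Path(velocity_path), Path(metadata_path)
    img = nib.Nifti1Image(_to_file_axes(ds.velocity), ds.affine)
    dz, dy, dx = ds.voxel_spacing
    img.header.set_zooms((dx, dy, dz, ds.phase_duration, 1.0))
    img.header.set_xyzt_units("mm", "msec")
    nib.save(img, velocity_path)
    meta = {
        "venc_m_per_s": ds.venc,
        "rr_ms": ds.rr_interval,
        "phase_duration_ms": ds.phase_duration,
        "frame_tag": "flow",
    }
    metadata_path.write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_flow4d(velocity_path: str | Path, metadata_path: str | Path) -> Flow4DDataset:
    """Read a 4D flow dataset from a 5-D NIfTI file and its JSON sidecar.

    The sidecar must provide the VENC (``venc_m_per_s`` or ``venc_cm_per_s``;
    cm/s values are converted), the RR interval ``rr_ms`` and the phase
    duration ``phase_duration_ms``.  Velocities are returned in m/s on axes
    ``[phase, z, y, x, component]``.

    ``velocity_path`` may also be a sequence of three 4-D NIfTI files, one
    per component ``(vx, vy, vz)``.
    """
    if isinstance(velocity_path, (list, tuple)):
        return _load_flow4d_components(velocity_path, metadata_path)
    meta = json.loads(Path(metadata_path).read_text())
    if "venc_m_per_s" in meta:
        venc = float(meta["venc_m_per_s"])
    elif "venc_cm_per_s" in meta:
        venc = float(meta["venc_cm_per_s"]) / 100.0
    else:
        raise ValidationError("VENC required: metadata must carry venc_m_per_s or venc_cm_per_s")
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ValidationError(f"metadata missing required keys: {missing}")

    img = nib.load(str(velocity_path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 5 or arr.shape[-1] != 3:
        raise ValidationError(
            "expected a 5-D velocity image with axes (x, y, z, phase, component); "
            f"file has {arr.ndim} axes with shape {arr.shape}"
        )
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))  # (dz, dy, dx)
    return Flow4DDataset(
        velocity=_from_file_axes(arr),
        voxel_spacing=spacing,
        affine=np.asarray(img.affine),
        phase_duration=float(meta["phase_duration_ms"]),
        rr_interval=float(meta["rr_ms"]),
        venc=venc,
    )


def _load_flow4d_components(paths, metadata_path: str | Path) -> Flow4DDataset:
    if len(paths) != 3:
        raise ValidationError("component-wise input requires exactly 3 files (vx, vy, vz)")
    comps, ref = [], None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim != 4:
            raise ValidationError(
                f"component file {p} must be 4-D (x, y, z, phase); has {arr.ndim} axes"
            )
        comps.append(arr)
        ref = img
    stacked = np.stack(comps, axis=-1)
    meta = json.loads(Path(metadata_path).read_text())
    if "venc_m_per_s" in meta:
        venc = float(meta["venc_m_per_s"])
    elif "venc_cm_per_s" in meta:
        venc = float(meta["venc_cm_per_s"]) / 100.0
    else:
        raise ValidationError("VENC required: metadata must carry venc_m_per_s or venc_cm_per_s")
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ValidationError(f"metadata missing required keys: {missing}")
    zooms = ref.header.get_zooms()
    return Flow4DDataset(
        velocity=_from_file_axes(stacked),
        voxel_spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        affine=np.asarray(ref.affine),
        phase_duration=float(meta["phase_duration_ms"]),
        rr_interval=float(meta["rr_ms"]),
        venc=venc,
    )


def save_mask_stack(masks: LVMaskStack, path: str | Path) -> None:
    arr = np.transpose(masks.mask.astype(np.uint8), (3, 2, 1, 0))
    img = nib.Nifti1Image(arr, masks.affine)
    dz, dy, dx = masks.voxel_spacing
    img.header.set_zooms((dx, dy, dz, 1.0))
    nib.save(img, Path(path))


def load_mask_stack(path: str | Path, frame_tag: str = "flow") -> LVMaskStack:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4:
        raise ValidationError(
            f"expected a 4-D mask image (x, y, z, phase); file has {arr.ndim} axes"
        )
    if not np.isin(np.unique(arr), [0, 1]).all():
        raise ValidationError("mask labels must be {0, 1}")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return LVMaskStack(
        mask=np.transpose(arr, (3, 2, 1, 0)).astype(bool),
        voxel_spacing=spacing,
        affine=np.asarray(img.affine),
        frame_tag=frame_tag,
    )
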