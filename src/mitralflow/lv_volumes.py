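"""LV volume curve, diastole window and cine-to-flow misalignment offsets.

The per-phase cavity volume (foreground voxels × voxel volume) identifies
end-systole (minimum volume) and end-diastole (maximum volume); diastole —
the filling period the transmitral E- and A-waves live in — runs cyclically
from the phase after end-systole up to and including end-diastole.

Because the cine stack used for segmentation and the 4D flow acquisition
are separate breath-holds, the contours can be spatially misaligned with
the velocity data; clinically this is corrected by manually nudging the
superimposed contours.  :func:`apply_offset` reproduces that correction as
an explicit user-supplied translation of the mask onto the flow grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_flow4d import Flow4DDataset, LVMaskStack

logger = logging.getLogger(__name__)

__all__ = ["VolumeCurve", "DiastoleWindow", "mask_volume_curve", "find_diastole", "apply_offset"]


@dataclass
class VolumeCurve:
    """Cavity volume per cardiac phase, with end-systole / end-diastole.

    ``es_phase`` is the argmin of the curve (first phase on ties);
    ``ed_phase`` is the argmax, with ties broken to the first phase that
    attains the maximum when scanning cyclically forward from end-systole
    — the phase at which filling is complete; later tied phases are
    diastasis.
    """

    volumes_ml: np.ndarray
    es_phase: int
    ed_phase: int

    @property
    def n_phases(self) -> int:
        return len(self.volumes_ml)


@dataclass
class DiastoleWindow:
    """Ordered (cyclic) phase indices from es_phase+1 through ed_phase."""

    phases: list[int]
    n_phases: int

    def __contains__(self, phase: int) -> bool:
        return phase in self.phases


def _ed_tiebreak(volumes: np.ndarray, es_phase: int) -> int:
    """First phase attaining the maximum, scanning cyclically forward from ES."""
    n = len(volumes)
    vmax = volumes.max()
    for step in range(1, n + 1):
        p = (es_phase + step) % n
        if volumes[p] == vmax:
            return p
    raise AssertionError("unreachable: max must exist")


def mask_volume_curve(masks: LVMaskStack) -> VolumeCurve:
    """Cavity volume per phase in mL (voxel count × voxel volume)."""
    dz, dy, dx = masks.voxel_spacing
    voxel_ml = dz * dy * dx / 1000.0  # mm³ → mL
    counts = masks.mask.reshape(masks.n_phases, -1).sum(axis=1)
    volumes = counts * voxel_ml
    if volumes.max() == volumes.min():
        raise ValueError("no systole detected: volume curve is flat")
    es = int(np.argmin(volumes))
    ed = _ed_tiebreak(volumes, es)
    return VolumeCurve(volumes_ml=volumes, es_phase=es, ed_phase=ed)


def find_diastole(vc: VolumeCurve) -> DiastoleWindow:
    """Phases of diastolic filling: (es_phase, ed_phase] in cyclic order.

    End-systole itself is excluded (its velocities are systolic residual);
    the window wraps around the cycle end when end-diastole has a smaller
    index than end-systole.
    """
    n = vc.n_phases
    if vc.es_phase == vc.ed_phase:
        raise ValueError("no systole detected: es_phase equals ed_phase")
    phases = []
    p = (vc.es_phase + 1) % n
    while True:
        phases.append(p)
        if p == vc.ed_phase:
            break
        p = (p + 1) % n
    return DiastoleWindow(phases=phases, n_phases=n)


def apply_offset(
    masks: LVMaskStack,
    offset_mm: tuple[float, float, float],
    target: Flow4DDataset,
) -> LVMaskStack:
    """Translate a mask stack by ``offset_mm`` and resample onto the flow grid.

    ``offset_mm = (dx, dy, dz)`` is the scanner-frame translation applied to
    the mask (the manual superimposition correction).  Each flow-grid voxel
    becomes foreground when the translated mask covers at least half of it
    — implemented as trilinear interpolation of the binary mask at the
    voxel centre followed by a 0.5 threshold, which is exactly the
    partial-volume fraction for pure translations.
    """
    offset = np.asarray(offset_mm, dtype=np.float64)
    if offset.shape != (3,):
        raise ValueError("offset_mm must be a 3-vector (dx, dy, dz)")

    # map each target voxel centre to source-mask voxel coordinates:
    # scanner point of target voxel v is A_t @ v; subtract the translation,
    # then pull back through the mask affine.
    a_src_inv = np.linalg.inv(masks.affine)
    m = a_src_inv @ target.affine
    nz, ny, nx = target.velocity.shape[1:4]
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    vox_xyz1 = np.stack([xx, yy, zz, np.ones_like(xx)], axis=0).reshape(4, -1).astype(np.float64)
    shift = a_src_inv[:3, :3] @ offset
    src_xyz = (m @ vox_xyz1)[:3] - shift[:, None]  # mask voxel coords (x, y, z)
    coords = src_xyz[::-1]  # (z, y, x) for map_coordinates on [z, y, x] arrays

    out = np.zeros((masks.n_phases, nz, ny, nx), dtype=bool)
    for p in range(masks.n_phases):
        frac = ndimage.map_coordinates(
            masks.mask[p].astype(np.float64), coords, order=1, mode="constant", cval=0.0
        )
        out[p] = (frac >= 0.5).reshape(nz, ny, nx)
    if not out.any():
        raise ValueError("offset moves the mask entirely outside the flow volume")
    return LVMaskStack(
        mask=out,
        voxel_spacing=target.voxel_spacing,
        affine=np.asarray(target.affine),
        frame_tag="flow",
    )
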