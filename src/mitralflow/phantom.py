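"""Ground-truthed synthetic 4D flow phantoms and paired-measurement cohorts.

The phantom emulates the one feature of a cardiac 4D flow study that the
downstream pipeline measures: a biphasic transmitral inflow jet inside a
contracting left ventricle.  Diastolic filling happens in two pulses — the
early (E) wave of passive atrial emptying and the late (A) wave driven by
atrial contraction; in atrial fibrillation the organised atrial kick is
lost and only the E-wave exists.  The centreline velocity over the cycle is
modelled as the sum of two raised-cosine pulses with compact, disjoint
supports, so the configured peak velocities are attained *exactly* at the
pulse centres; spatially the jet carries a parabolic (Poiseuille-like)
profile directed along the LV long axis.  The LV cavity itself is a
circular cylinder whose radius follows a smooth volume curve between
end-diastole (maximum volume) and end-systole (minimum volume).

Everything the pipeline later estimates — the peak velocities, the phases
they occur at, the end-systolic and end-diastolic phases — is therefore
known by construction and returned as a :class:`GroundTruth` record.

A second generator produces paired-measurement cohorts (echocardiography
vs 4D flow readings per subject with configurable modality bias, noise and
an atrial-fibrillation subgroup) for exercising the agreement statistics
with known truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .io_flow4d import Flow4DDataset, LVMaskStack
from .lv_volumes import mask_volume_curve

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "biphasic_waveform",
    "generate_phantom",
    "generate_cohort",
]


class PhantomConfig(BaseModel):
    """Configuration of the synthetic transmitral-jet phantom.

    Velocity defaults (0.94 / 0.81 m/s) are physiologic all-patient median
    peak E- and A-wave values; acquisition defaults (30 phases, 3 mm
    acquired voxels, VENC 1.5 m/s) match a routine whole-heart 4D flow
    protocol.  Pulse timing places the E-wave in early diastole and the
    A-wave in late diastole with disjoint supports.
    """

    peak_e: float = 0.94  # m/s
    peak_a: float = 0.81  # m/s; 0 allowed (suppresses the A pulse)
    t_e_frac: float = 0.65  # E pulse centre, fraction of RR
    t_a_frac: float = 0.92  # A pulse centre, fraction of RR
    w_e_frac: float = 0.12  # E pulse half-width, fraction of RR
    w_a_frac: float = 0.07  # A pulse half-width, fraction of RR
    jet_radius: float = 12.0  # mm
    lv_radius_ed: float = 25.0  # mm, cavity radius at end-diastole
    lv_length: float = 60.0  # mm, cavity long-axis extent
    ef_frac: float = 0.6  # ejection fraction of the mask volume curve
    rhythm: str = "sinus"  # "sinus" | "af"
    noise_sigma: float = 0.0  # m/s, i.i.d. Gaussian sd per velocity component
    venc: float = 1.5  # m/s
    n_phases: int = 30
    voxel_mm: float = 3.0
    rr_ms: float = 900.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if self.rhythm not in ("sinus", "af"):
            raise ValueError("rhythm must be 'sinus' or 'af'")
        if self.rhythm == "af" and self.peak_a != 0.0:
            # AF has no organised atrial contraction: the A pulse is forced off
            object.__setattr__(self, "peak_a", 0.0)
        if not 0.0 < self.jet_radius < self.lv_radius_ed:
            raise ValueError("need 0 < jet_radius < lv_radius_ed")
        if not 0.0 < self.ef_frac < 1.0:
            raise ValueError("ef_frac must be in (0, 1)")
        if self.peak_e <= 0.0 or self.peak_a < 0.0:
            raise ValueError("peak_e must be > 0 and peak_a >= 0")
        if self.rhythm == "sinus" and self.peak_a > 0.0:
            if self.t_e_frac + self.w_e_frac > self.t_a_frac - self.w_a_frac:
                raise ValueError(
                    "E and A pulse supports overlap: require "
                    "t_e_frac + w_e_frac <= t_a_frac - w_a_frac"
                )
        return self

    # phases sample the cycle at t_k = k / n_phases; pulse centres are
    # snapped onto this grid so the configured peaks are attained exactly
    # at a sampled phase (makes parameter-recovery sharp).
    def phase_fracs(self) -> np.ndarray:
        return np.arange(self.n_phases) / self.n_phases

    def snapped(self) -> "PhantomConfig":
        """Copy with pulse centres moved to the nearest sampled phase."""
        te = round(self.t_e_frac * self.n_phases) / self.n_phases
        ta = round(self.t_a_frac * self.n_phases) / self.n_phases
        return self.model_copy(update={"t_e_frac": te, "t_a_frac": ta})


class GroundTruth(BaseModel):
    """What the phantom actually contains, for parameter-recovery checks."""

    true_peak_e: float
    true_peak_a: float | None
    true_phase_e: int
    true_phase_a: int | None
    es_phase: int
    ed_phase: int


def _raised_cosine(t: np.ndarray, centre: float, half_width: float, amp: float) -> np.ndarray:
    """Single pulse: amp * (1 + cos(pi (t-centre)/w)) / 2 on |t-centre| < w."""
    if amp == 0.0:
        return np.zeros_like(t)
    x = (t - centre) / half_width
    out = np.where(np.abs(x) < 1.0, 0.5 * amp * (1.0 + np.cos(np.pi * x)), 0.0)
    return out


def biphasic_waveform(t_frac: np.ndarray | float, cfg: PhantomConfig) -> np.ndarray | float:
    """Centreline jet velocity (m/s) at cycle fraction ``t_frac`` in [0, 1).

    Sum of two raised-cosine pulses: the maximum over the E support equals
    ``peak_e`` exactly at ``t_e_frac``, the maximum over the A support
    equals ``peak_a`` at ``t_a_frac``, and the waveform is zero outside
    both supports.  In AF the A pulse is absent.
    """
    t = np.asarray(t_frac, dtype=np.float64)
    e = _raised_cosine(t, cfg.t_e_frac, cfg.w_e_frac, cfg.peak_e)
    a = _raised_cosine(t, cfg.t_a_frac, cfg.w_a_frac, cfg.peak_a)
    out = e + a
    return float(out) if np.isscalar(t_frac) else out


def _cavity_radius(t_frac: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """LV cavity radius over the cycle (mm).

    The cavity volume follows ``V(t) = V_es + (V_ed - V_es)(1 + cos 2πt)/2``
    — unique maximum at t = 0 (end-diastole) and unique minimum at t = 0.5
    (end-systole); since a cylinder's volume scales with radius², the
    radius is the square root of that curve, with
    ``V_es = (1 - ef_frac) V_ed``.
    """
    vol_frac = (1.0 - cfg.ef_frac) + cfg.ef_frac * 0.5 * (1.0 + np.cos(2.0 * np.pi * t_frac))
    return cfg.lv_radius_ed * np.sqrt(vol_frac)


def generate_phantom(cfg: PhantomConfig) -> tuple[Flow4DDataset, LVMaskStack, GroundTruth]:
    """Build the synthetic dataset, its mask stack and the ground truth.

    The LV cylinder axis runs along z through a voxel centre, so the jet
    axis coincides with a column of voxel centres and the configured peak
    velocity is attained exactly at a grid point (noise-free).  The jet
    fills the cavity length with the parabolic cross-profile
    ``waveform × (1 − (r/jet_radius)²)`` directed along +z; Gaussian noise
    of sd ``noise_sigma`` is added per component when requested.
    """
    cfg = cfg.snapped()
    rng = np.random.default_rng(cfg.seed)
    h = cfg.voxel_mm

    margin = 2  # voxels of empty border
    n_xy = 2 * (int(np.ceil(cfg.lv_radius_ed / h)) + margin) + 1
    n_z = int(np.ceil(cfg.lv_length / h)) + 2 * margin
    if n_xy < 3 or n_z < 3:
        raise ValueError("voxel grid too small to contain the LV")
    centre_xy = n_xy // 2  # voxel index of the cylinder axis
    z0 = margin
    z1 = z0 + int(round(cfg.lv_length / h))  # exclusive
    if z1 > n_z:
        raise ValueError("voxel grid too small to contain lv_length")

    # scanner frame == voxel lattice scaled by h (axis-aligned affine)
    affine = np.diag([h, h, h, 1.0])
    spacing = (h, h, h)

    ix = np.arange(n_xy, dtype=np.float64)
    r2 = (ix[None, :] - centre_xy) ** 2 + (ix[:, None] - centre_xy) ** 2  # (y, x), voxels²
    r_mm = np.sqrt(r2) * h

    t = cfg.phase_fracs()
    wave = biphasic_waveform(t, cfg)
    radii = _cavity_radius(t, cfg)

    profile = np.clip(1.0 - (r_mm / cfg.jet_radius) ** 2, 0.0, None)  # (y, x)
    in_z = np.zeros(n_z, dtype=bool)
    in_z[z0:z1] = True

    vel = np.zeros((cfg.n_phases, n_z, n_xy, n_xy, 3), dtype=np.float64)
    mask = np.zeros((cfg.n_phases, n_z, n_xy, n_xy), dtype=bool)
    for p in range(cfg.n_phases):
        cavity = r_mm <= radii[p]  # (y, x)
        mask[p] = in_z[:, None, None] & cavity[None, :, :]
        vz = wave[p] * profile  # (y, x)
        vel[p, :, :, :, 2] = np.where(in_z[:, None, None], vz[None, :, :], 0.0)
    if cfg.noise_sigma > 0.0:
        vel += rng.normal(0.0, cfg.noise_sigma, size=vel.shape)

    phase_duration = cfg.rr_ms / cfg.n_phases
    ds = Flow4DDataset(
        velocity=vel,
        voxel_spacing=spacing,
        affine=affine,
        phase_duration=phase_duration,
        rr_interval=cfg.rr_ms,
        venc=cfg.venc,
    )
    masks = LVMaskStack(mask=mask, voxel_spacing=spacing, affine=affine, frame_tag="flow")

    phase_e = int(round(cfg.t_e_frac * cfg.n_phases)) % cfg.n_phases
    phase_a = int(round(cfg.t_a_frac * cfg.n_phases)) % cfg.n_phases
    has_a = cfg.rhythm == "sinus" and cfg.peak_a > 0.0
    # ES/ED from the rasterised volume curve itself (the analytic radius
    # curve can tie after voxelisation), using the same tie-break as the
    # volume module, so ground truth and pipeline agree by construction.
    vc = mask_volume_curve(masks)
    gt = GroundTruth(
        true_peak_e=cfg.peak_e,
        true_peak_a=cfg.peak_a if has_a else None,
        true_phase_e=phase_e,
        true_phase_a=phase_a if has_a else None,
        es_phase=vc.es_phase,
        ed_phase=vc.ed_phase,
    )
    return ds, masks, gt


def generate_cohort(
    n_subjects: int,
    true_median: float = 0.94,
    log_sd: float = 0.35,
    modality_bias: float = 0.0,
    noise_sd: float = 0.0,
    af_fraction: float = 8 / 48,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a paired echo-vs-CMR measurement cohort with known truth.

    Per subject the true peak velocity is drawn lognormal with median
    ``true_median`` and log-scale sd ``log_sd``; the echo (TTE) reading is
    ``true + modality_bias + N(0, noise_sd)`` and the CMR reading is
    ``true + N(0, noise_sd)``.  Exactly ``round(af_fraction * n)`` subjects
    are labelled AF (not sampled — label counts are deterministic).
    Columns: ``subject_id, rhythm, tte_m_s, cmr_m_s``.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    true = np.exp(rng.normal(np.log(true_median), log_sd, size=n_subjects))
    tte = true + modality_bias + rng.normal(0.0, noise_sd, size=n_subjects)
    cmr = true + rng.normal(0.0, noise_sd, size=n_subjects)
    n_af = int(round(af_fraction * n_subjects))
    rhythm = np.array(["sinus"] * n_subjects, dtype=object)
    af_idx = rng.choice(n_subjects, size=n_af, replace=False)
    rhythm[af_idx] = "af"
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n_subjects)],
            "rhythm": rhythm,
            "tte_m_s": tte,
            "cmr_m_s": cmr,
        }
    )
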