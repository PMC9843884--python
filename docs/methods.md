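# Methods

## The measurement

`mitralflow` derives peak transmitral inflow velocities from a 4D flow CMR
acquisition (a time-resolved, three-directional phase-contrast velocity
field) and a per-phase binary segmentation of the LV cavity obtained from a
short-axis cine stack. The quantities of interest are the two diastolic
filling peaks familiar from Doppler echocardiography: the E-wave (passive
early filling) and the A-wave (active atrial contraction, absent in atrial
fibrillation). Both are used clinically to grade diastolic function and to
estimate LV filling pressure.

The pipeline mirrors how a reader works through such a dataset:

1. **Centreline.** Per-slice centroids of the cavity mask, mapped to the
   scanner frame, smoothed with a 3-point moving average; tangents by
   central differences. The centreline is computed once, at end-diastole,
   and reused for all phases (a fixed geometric frame; a
   `per_phase_centerline` option recomputes it per phase).
2. **Multi-planar reformat (MPR).** Planes are placed at equal arc-length
   steps along the centreline (default 60 slices, 2.5 mm apart, 1.5 mm
   in-plane pitch, zero thickness = one sample per pixel). Each plane's
   normal is the local tangent; the in-plane axes are propagated with
   rotation-minimising frames so they cannot flip on curved geometry.
   Planes requested beyond the centreline length are dropped with a logged
   warning.
3. **Velocity sampling.** Each scanner-frame component is interpolated
   trilinearly at the plane samples and then rotated into the plane frame;
   the mask is resampled nearest-neighbour so it stays binary.
   Out-of-volume samples are marked invalid and excluded. Trilinear
   interpolation is exact on constant and linear fields, and the rotation
   preserves the vector norm to machine precision — both are enforced by
   tests.
4. **Maximum-velocity trace.** Per phase, the speed (Euclidean norm) at
   every masked, valid sample is reduced to a robust maximum (see below),
   giving one velocity per cardiac phase.
5. **Diastole and peaks.** The cavity volume curve (voxel count × voxel
   volume) locates end-systole (minimum) and end-diastole (maximum);
   diastole runs cyclically from the phase after ES through ED. E and A
   are read off the trace restricted to that window.

## Speed, not through-plane velocity

The per-sample scalar is the full vector norm, which is robust to how each
plane happens to be tilted relative to the jet; a through-plane projection
(dot product with the plane normal) is available via
`masked_speed_map`/`TraceOptions` for sensitivity analyses. For a jet
directed along the long axis the two coincide at the jet core.

## The robust maximum (percentile q)

The trace value is the q-th percentile of the masked speeds, default
**q = 99.9**. A strict maximum (q = 100) over the ~10⁴ masked samples of a
typical phase estimates the supremum of the noise and is biased upward by
roughly σ·√(2 ln n); at a realistic per-component noise of 0.03 m/s this
bias alone is ~0.05 m/s. Trimming the top 0.1% of samples removes that
tail while remaining exact on noise-free data, because the discretised jet
core holds more than 0.1% of the samples within a fraction of a percent of
the true peak. q is exposed (`--q`), and q = 100 reproduces the strict
maximum. Percentiles much below ~99.9 begin to cut into the parabolic jet
profile itself and systematically under-read the peak (a 2% trim reaches
≈2.6 mm into a 12 mm jet, a ~6% under-read), which is why the default
trims so little.

## Peak-detection rules

Within the diastole window (cyclic order):

- Local maxima are samples strictly greater than both neighbours,
  one-sided at the window ends.
- Maxima below 20% of the window maximum are rejected as noise bumps —
  without this floor, the sample at the window start (systolic residual
  plus noise) is frequently a one-sided "maximum" and would be mistaken
  for E.
- **E** is the first remaining local maximum.
- **A** (sinus rhythm only) is the last remaining maximum after E whose
  inclusive phase span from E is at least `min_sep` (default 3 of 30
  phases, ~10% RR) and whose intervening trough dips to at most 90% of the
  smaller of the two peaks. If no candidate qualifies the trace is
  reported as `fused` (single diastolic peak, no A value) — the clinical
  E/A-fusion situation.
- In **AF** no A-wave is ever reported (`af_e_only`), regardless of what
  the trace looks like: without organised atrial contraction there is no
  A-wave to measure, and noise bumps must not masquerade as one.

The separation rule is an inclusive span (E at window position i, A at
position j qualifies when j − i + 1 ≥ min_sep). Since strict local maxima
are never adjacent, the rule only binds for settings above the default; it
exists to let stricter fusion policies be expressed.

## Aliasing

Velocities beyond the VENC wrap around. Voxels whose largest component
magnitude reaches `venc_fraction` × VENC (default 0.98) are flagged and
counted in the log and QC block; they are never phase-unwrapped, mirroring
the clinical repeat-or-exclude policy.

## Misalignment correction

Cine-derived masks and the flow acquisition are separate breath-holds and
can be offset. `apply_offset` translates the mask by a user-supplied
(dx, dy, dz) in mm and resamples it onto the flow grid; a target voxel is
foreground when the translated mask covers at least half of it. For pure
translations this partial-volume fraction is exactly the trilinear
interpolation of the binary mask, which is how it is computed. Offset
estimation (registration) is deliberately out of scope — the correction is
an explicit input, as it is a manual step in practice. Only translations
are supported, applied globally to all phases.

## The synthetic phantom

The phantom provides ground truth for every stage:

- **Waveform.** Centreline velocity over the cycle is the sum of two
  raised-cosine pulses with compact, disjoint supports. Defaults: E centre
  0.65·RR, half-width 0.12·RR; A centre 0.92·RR, half-width 0.07·RR —
  early- and late-diastolic filling with a clear separation. Raised
  cosines (rather than Gaussians) make the configured peaks attained
  *exactly*, so parameter-recovery tests are sharp. Pulse centres are
  snapped to the nearest sampled phase for the same reason.
- **Peak amplitudes.** Defaults 0.94 (E) and 0.81 (A) m/s — physiologic
  all-patient median values. In AF the A pulse is forced to zero.
- **Geometry.** The LV is a circular cylinder (default radius 25 mm at
  end-diastole, length 60 mm) whose volume follows a raised-cosine curve
  between end-diastole (t = 0) and end-systole (t = 0.5·RR) with a
  configurable ejection fraction (default 0.6). The jet (default radius
  12 mm) runs along the cylinder axis with a parabolic (Poiseuille-like)
  cross-profile, and the axis passes through a column of voxel centres so
  the true peak exists exactly at a grid point.
- **Acquisition.** 30 phases, 3 mm isotropic voxels (an acquired-resolution
  grid; 1.5 mm reconstructed-resolution phantoms are a parameter change),
  VENC 1.5 m/s, RR 900 ms. Noise is i.i.d. Gaussian per velocity component
  (velocity noise, not Rician magnitude noise, is what the pipeline sees).
- **Ground truth ES/ED** are taken from the rasterised volume curve itself
  (with the same tie-break as the measurement path) because voxelisation
  can tie adjacent phases near the analytic extremes.

What the phantom does **not** emulate: valve geometry and leaflet motion,
jet angulation and eccentricity, intra-voxel dephasing, eddy-current
background phase offsets, beat-to-beat variability (AF is modelled as
absent A-wave only — the acquisition averages to a single reconstructed
cycle anyway), and k-space/pulse-sequence physics. Passing tests therefore
demonstrate correctness of the geometry, tracing and statistics machinery
under controlled conditions, not clinical accuracy on patient data.

The cohort generator emulates paired echo-vs-CMR readings per subject:
true peaks lognormal (median 0.94 m/s, log-sd 0.35), echo = truth +
modality bias + noise, CMR = truth + noise, with an exact (not sampled)
AF label count, default 8 of 48 subjects.

## Agreement statistics

- **Bland–Altman:** differences as reference − new method (echo − CMR),
  bias, 95% limits of agreement bias ± 1.96·sd, and a t-based CI on the
  bias.
- **Spearman r** on midranks with a Fisher-z CI (sd 1/√(n−3)), chosen for
  determinism; a seeded percentile bootstrap is available.
- **Wilcoxon signed-rank:** zero differences dropped, exact null for n ≤
  25, normal approximation with continuity correction beyond. The exact
  two-sided p follows the conventional tie-free null distribution.
- **Repeatability CoV, logarithmic method:** s² = Σdᵢ²/(2n) with dᵢ the
  paired log-differences; CoV = √(exp(s²) − 1) × 100. Scale-invariant by
  construction; s² estimates the single-reading within-subject log
  variance.

## Numerical and design notes

- Axis order is pinned: velocity `[phase, z, y, x, component]`, components
  (vx, vy, vz) in the scanner frame; NIfTI files store `(x, y, z, phase,
  component)`. Stored phase values in [−1, 1) map linearly to
  [−VENC, +VENC); VENC metadata is accepted in m/s or cm/s.
- ED tie-break: first phase attaining the maximum volume scanning
  cyclically forward from ES (filling complete; later tied phases are
  diastasis). ES tie-break: first index at the minimum. The window
  excludes ES itself.
- Problem sizes in the test-suite and acceptance script — default phantom
  grids of ~23×23×24 voxels × 30 phases, 20-seed noise studies, 200–500
  simulated cohorts, 1000–2000 test replicates — were chosen so the full
  validation runs in about a minute on a laptop while keeping Monte-Carlo
  error well below the asserted tolerances.
- Centreline tangents from rasterised binary masks carry ±0.2–0.3 mm
  centroid jitter; smoothed tangents track a known tilted axis to ~1° on
  average (worst slice ~2°). This is a property of binary rasterisation at
  clinical voxel sizes, not of the differencing scheme.

## Known limitations

- Masks are inputs; the cine segmentation algorithm itself is out of
  scope, as are DICOM ingestion and vendor-specific phase dialects.
- No background phase-error (eddy current) correction is modelled.
- Rotational misalignment is not supported (translations only).
- The E/A separation is trace-shape based; no ECG timing information is
  used.
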