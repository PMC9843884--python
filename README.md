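# mitralflow

Automated quantification of **peak transmitral inflow velocities — the
diastolic E-wave and A-wave — from 4D flow cardiac MR**, driven by a
short-axis LV segmentation, together with a ground-truthed synthetic flow
phantom and the method-agreement statistics used to validate such a
measurement against Doppler echocardiography.

## Who this is for

4D flow CMR encodes all three blood-velocity components over the cardiac
cycle in a single free-running whole-heart acquisition. For patients with
suspected diastolic dysfunction (e.g. HFpEF work-up), the transmitral
E- and A-wave peak velocities normally measured by pulsed-wave Doppler can
instead be read from the 4D flow dataset — retrospectively, at any
location, without an acoustic window. This package implements that
measurement as a reproducible pipeline for imaging researchers: load (or
simulate) a velocity field and an LV cavity mask, and get back a
maximum-velocity trace over the cycle with detected peaks.

## The measurement

Given a velocity field **v**(x, t) (m/s, VENC-limited) and per-phase
binary cavity masks:

1. an LV **centreline** is fitted from per-slice mask centroids;
2. a **multi-planar reformatted (MPR) stack** of thin planes (default 60
   slices, 2–3 mm apart, normal to the centreline) resamples the field
   trilinearly, with the components rotated into each plane's frame;
3. the per-phase **maximum-velocity trace** is the robust maximum
   (default 99.9th percentile) of |**v**| over masked samples;
4. the LV **volume curve** V(t) locates end-systole (argmin) and
   end-diastole (argmax); diastole spans (ES, ED];
5. on the diastolic trace, **E** is the first genuine local maximum and
   **A** the last one separated from E by a ≥10% trough. In atrial
   fibrillation only E is reported, by definition.

Aliasing candidates (|v| ≥ 0.98·VENC) are flagged, never unwrapped, and a
user-supplied translation corrects cine-to-flow misalignment. See
`docs/methods.md` for the full model, parameter defaults and limitations.

## Worked example

Generate the default synthetic phantom — a biphasic transmitral jet with
configured peaks 0.94 / 0.81 m/s inside a contracting cylindrical LV,
30 phases at 3 mm isotropic — and trace it:

```bash
$ mitralflow phantom generate --out ph
phantom written to ph
$ mitralflow trace run --flow ph/flow.nii.gz --meta ph/flow_meta.json \
    --mask ph/mask.nii.gz --rhythm sinus --out result.json
peak E 0.940 m/s (phase 20), peak A 0.810 m/s
```

The configured peaks are recovered exactly: the jet axis passes through
voxel centres and the pulse centres land on sampled phases, so on
noise-free data nothing is lost to interpolation. `result.json` holds the
peaks with their phases and status (`ok` / `fused` / `af_e_only`), the
full per-phase trace, the volume curve, the diastole window and QC
counters (aliasing flags, truncated planes).

Simulate a 48-subject paired echo-vs-CMR cohort with a +0.05 m/s echo
bias and 0.1 m/s reading noise, then test agreement:

```bash
$ mitralflow phantom cohort --n 48 --seed 7 --bias 0.05 --noise-sd 0.1 --out cohort.csv
cohort (48 subjects) written to cohort.csv
$ mitralflow stats agree --pairs cohort.csv --group all --out report.json
n=48 bias=+0.080 m/s LoA [-0.157, 0.318] r=0.89 p=0.000117
```

The Bland–Altman bias (echo − CMR) estimates the injected +0.05 m/s
within its sampling error (the per-cohort SE here is ≈ 0.02 m/s); the
limits of agreement reflect the √2·0.1 m/s difference noise, and Spearman
r and the Wilcoxon p complete the standard agreement panel.

The same stages run end-to-end from one YAML config with
`mitralflow run --config pipeline.yaml --out rundir --seed 1`
(bit-identical outputs for the same config and seed).

As a library:

```python
from mitralflow import PhantomConfig, generate_phantom, trace_dataset
from mitralflow.pipeline import TraceOptions

ds, masks, truth = generate_phantom(PhantomConfig(noise_sigma=0.03, seed=1))
result = trace_dataset(ds, masks, TraceOptions())
print(result["peaks"])
```

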