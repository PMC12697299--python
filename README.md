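# mcfnano

Nanoscale morphometry and nanomechanics of mineralized collagen fibrils
(MCFs) — the basic mechanical unit of bone — from tapping-mode AFM images
and AFM nanoindentation records, with a synthetic-data generator that makes
every stage verifiable by parameter recovery.

## Who this is for

Bone biomechanics studies image demineralized cortical surfaces with AFM
and ask how aging, disuse and mechanical load change the fibrils
themselves: their ~67 nm axial D-band repeat, their orientation relative
to the loading axis, and their radial elastic modulus measured by pressing
a sharp probe into single fibrils.  This package implements that analysis
chain end to end:

1. **Scan post-processing** — per-scan-line second-order polynomial
   flattening (tilt + bow removal); an optional Gaussian low-pass
   (σ = 0.8 px) for amplitude *display only* — quantitative operations
   refuse filtered input.
2. **Fibril morphometry** — deterministic segmentation of D-banded ridges,
   sub-pixel axis tracing, along-axis amplitude-deviation profiles,
   peak-to-peak D-spacing with parabolic sub-sample refinement, and axial
   (mod-180°) orientation statistics normalized to the per-image mean
   direction.
3. **Nanoindentation** — conversion of force–displacement records to
   force–indentation curves and fitting of the conical Hertz contact model

   *F* = (2/π) · *E*/(1 − ν²) · tan α · δ²

   (cone half-angle α = 10°, Poisson ratio ν = 0.3) with joint estimation
   of baseline drift, contact point *z*₀ and modulus *E*: for every
   candidate contact sample the baseline is the least-squares line over
   the pre-contact segment and *E* is the closed-form least-squares
   amplitude of the δ² regressor; the total-residual minimizer wins and
   *z*₀ is refined continuously.
4. **Group statistics** — mean ± SD summaries, empirical CDFs, two-sample
   Kolmogorov–Smirnov distances, Holm–Šidák step-down multiple-comparison
   adjustment, 10° orientation-bin frequencies, percent differences and
   fold changes.
5. **Synthetic cohorts** — eight experimental groups (adult/aged ×
   control/hindlimb-unloading × 0 N/4 N axial load; n = 6 mice, 5 sites
   per tibia) rendered as D-banded fibril fields (5 μm scans) and Hertzian
   force curves (24,000 samples), with full ground-truth bookkeeping.

## Worked example

```python
from mcfnano import (CurveSpec, ImageSpec, ProbeParams, default_group_params,
                     render_fibril_image, simulate_force_curve,
                     fit_hertz_cone, flatten_lines, segment_fibrils,
                     trace_axis, profile_along_trace, dspacing_from_profile)

params = default_group_params("aged-control-0N")   # D = 77 ± 11 nm, E = 0.74 GPa
amp, height, truth = render_fibril_image(
    params, ImageSpec(n_pixels=512), seed=42, image_id="demo")
flat = flatten_lines(amp)                          # per-line order-2 flatten
labels, ids = segment_fibrils(flat)
trace = trace_axis(labels, ids[0], flat.pixel_size_nm)
s, v = profile_along_trace(flat, trace)
meas = dspacing_from_profile(s, v, fibril_id=ids[0])
print(f"D-spacing {meas.d_spacing_nm:.1f} nm from {meas.n_peaks} band peaks")

probe = ProbeParams()                              # alpha = 10 deg, nu = 0.3
curve, ctruth = simulate_force_curve(0.74, CurveSpec(), probe, seed=7)
fit = fit_hertz_cone(curve, probe)
print(f"E = {fit.E_gpa:.3f} GPa (truth {ctruth['E_gpa']:.3f}), "
      f"contact at {fit.z0_nm:.1f} nm (truth {ctruth['z0_nm']:.1f})")
```

Output:

```
D-spacing 75.3 nm from 30 band peaks
E = 0.735 GPa (truth 0.740), contact at 85.6 nm (truth 86.3)
```

The D-spacing is the mean of 29 consecutive sub-pixel band-peak intervals
along this fibril's traced axis (its true period, drawn from the
aged-control distribution, is 75.3 nm in the truth table); the Hertz fit
recovers the modulus and contact point from a record with 5% force noise
without being told where contact began.

## Analysis drivers

`analysis/01…05_*.py` narrate the full study on synthetic cohorts and
write tables under `results/`: cohort simulation to disk, D-spacing
recovery for all eight groups, orientation histograms and K-S load
comparisons, modulus recovery, and the statistical surface (summaries,
Holm–Šidák pairwise tests, percent/fold contrasts).  A `mcfnano` CLI with
`simulate / analyze / stats / full / report` subcommands exposes the same
stages over on-disk datasets (TIFF + YAML sidecars, per-indent TSV, CSV
tables).

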