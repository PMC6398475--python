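# ebtip

Subpixel microtubule plus-end tracking and EB comet analysis.

End-binding proteins (EB1, EB2, EB3) autonomously accumulate at growing
microtubule plus ends, forming comet-shaped fluorescence profiles whose
position and shape encode where each protein binds relative to the tip and
which nucleotide state of the lattice it recognises. Measuring those
offsets from TIRF movies requires localising the microtubule end to a few
tens of nanometres — well below the ~250 nm diffraction limit — and
comparing it with the EB signal under tightly controlled growth conditions.

`ebtip` implements that computational pipeline for researchers analysing
in vitro microtubule dynamics:

- **Synthetic data with ground truth** (`ebtip.simgen`) — image stacks of
  growing microtubules (8 nm dimer lattice, Poisson dye sampling, Gaussian
  PSF, background noise at a target SNR), single- and dual-colour comet
  kymographs, and FRAP traces, for benchmarking every stage.
- **Subpixel end localisation** (`ebtip.mtend`) — backbone detection by
  per-column Gaussian ridge fits, bi-cubic straightening, and end fitting
  with a Gauss error function
  `I(x) = b + (A/2)·(1 − erf((x − µ)/(σ√2)))`,
  where `µ` is the end position and `σ` the edge width (PSF plus tip
  taper); fits with `σ` outside 50–200 nm are flagged unreliable.
- **Growth-phase segmentation** (`ebtip.phases`) — recursive segment-line
  fitting of length traces (split at the farthest point until the mean
  deviation is ≤ 20 nm), keeping phases ≥ 10 s at 10–30 nm/s.
- **Comet-shape analysis** (`ebtip.comet`) — kymograph tip-line detection
  (90%-maximum threshold, ±5 px refinement, 1 px residual gate), aligned
  averaging at 8.1 nm resolution, superaveraging on the first half-maximal
  point, comet area (direct integral + exponential tail), dual-colour peak
  distances with the sequential-acquisition correction, and cell line-scan
  averaging.
- **Cap kinetics simulation** (`ebtip.nucsim`) — the hydrolysis cascade
  `dT/dL = −k₁T`, `dP/dL = k₁T − k₂P`, `dD/dL = k₂P` (T = GTP,
  P = GDP/Pi, D = GDP; L = subunits from the tip) solved with RK45, the
  six lateral nucleotide-pair densities (TT, TP, PP, PD, TD, DD scaled by
  13 protofilaments), PSF-convolved comet curves, and mixed-lattice
  binding-site statistics (fⁿ for n-mers, 2f(1−f) for mixed pairs).
- **Curve fits** (`ebtip.fits`) — the one-site tip-binding isotherm
  `I = I_max·[EB]/(K_D + [EB])` (optionally with fixed `I_max`),
  exponential competition decay `A·e^(−c/K)`, FRAP recovery
  `plateau·(1 − e^(−t/τ))`, and Gaussian peak localisation.
- **I/O and orchestration** (`ebtip.io`, `ebtip` CLI) — TIFF stacks with
  JSON sidecars, CSV kymographs and tables, validated run configs, and a
  seeded multi-stage pipeline runner.

## Worked example

```python
from ebtip import mtend, simgen

cfg = simgen.SimImageConfig(labeled_fraction=0.18, target_snr=6.0, seed=1)
stack = simgen.simulate_microtubule_stack(cfg)
report = mtend.benchmark_length_accuracy([stack])
print(f"bias {report['mean_error_nm']:+.1f} nm, "
      f"sd {report['sd_error_nm']:.1f} nm over {report['n_frames']} frames")
```

prints

```
bias -1.4 nm, sd 76.9 nm over 43 frames
```

— a single movie at SNR 6 (the hardest condition): the end position is
unbiased to a few nanometres, and a single frame's length estimate scatters
by ~77 nm; precision improves with SNR, and over the full SNR 6–11
benchmark ensemble the scatter is ~50 nm. The `examples/` directory holds
one short script per capability (end detection, cap kinetics, comet
analysis, dual-colour offsets, phase segmentation, curve fits, mixed
lattices), each printing the numbers it computes and what they mean. The
same operations are scriptable from the shell via the `ebtip` CLI
(`ebtip simulate-images`, `ebtip detect-ends`, `ebtip dual-colour`, ...).

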