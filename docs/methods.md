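# Methods

This note documents the models, algorithms and numerical choices behind
`ebtip`, in the order data flows through the pipeline.

## Synthetic image model (`simgen`)

A microtubule is modelled as a 13-protofilament lattice of tubulin dimers
with an 8 nm axial rise, laid horizontally with its minus (seed) end fixed.
The default length trajectory ramps 2 µm → 4 µm → 2 µm at 50 nm per frame
over 81 frames. Per lattice layer, the dye count is drawn from a Poisson
distribution with mean `protofilaments × labelled_fraction × dyes_per_dimer`
(defaults 13 × 0.18 × 1.5 ≈ 3.5 per layer, ≈ 35.5 per 81 nm pixel). An
alternative two-stage model (binomial dimer labelling, then a Poisson
number of dyes per labelled dimer, `labelling_model="binomial-poisson"`)
is provided for comparison; it has ~2.2× the per-pixel variance and
correspondingly worse end-localisation precision, and is not the default
because plain Poisson sampling of intensity values is the standard
benchmarking construction this generator reproduces.

Dyes are deposited on a 1 nm axial grid (far below the PSF width, so grid
effects are negligible), convolved with a unit-sum Gaussian kernel
(σ = 130 nm, truncated at 5σ), and integrated into 81 nm pixels; the
transverse PSF dimension is applied as exact per-row Gaussian integrals
(erf differences), which is equivalent to a full 2-D convolution for a
line source. Background noise is i.i.d. Gaussian with mean 50 counts and a
standard deviation chosen so that the measured SNR — (mean backbone − mean
background)/sd(background) — equals the requested target; round-trip
accuracy is within a few percent. Real camera noise is typically not
i.i.d. (EM gain, spatial correlation), so absolute precision numbers from
this generator should be read as the i.i.d.-noise case; a hook accepts
user-supplied noise frames instead. A `noise_free` switch replaces all
sampling by expectations, giving an exact PSF-blurred step at the end for
oracle tests.

What the generator does *not* emulate: camera gain/read-noise statistics,
stage drift, multiple or crossing microtubules, out-of-focus light, and
photobleaching. Passing tests therefore demonstrate correctness of the
algorithms under the stated image model, not robustness to every
real-microscope artefact.

Synthetic kymographs place a comet profile (sharp leading edge,
exponential tail of decay length 300 nm by default, or a PSF-convolved
nucleotide-pair curve) at `x₀(t) = start + v·(t + i·delay) − offsetᵢ` per
channel `i`, with i.i.d. Gaussian noise; `delay` models sequential
two-colour acquisition and `offsetᵢ` the ground-truth peak shift behind
the tip. FRAP traces are `plateau·(1 − e^(−t/τ))` plus noise, normalised
to 1 at the last pre-bleach and 0 at the first post-bleach point — the
same rule the FRAP fit assumes.

## End localisation (`mtend`)

Frames are oriented by image reflection/transposition so the axis angle
(from intensity second moments) lies in [0°, 45°] and the seed end is
nearest the origin. Backbone detection fits a four-parameter Gaussian
(amplitude, centre, width, baseline) to every column; the fits run as one
vectorised damped Gauss–Newton iteration over all columns (25 iterations,
steps clamped to 2 px in centre and 1 px in width), initialised from
background-subtracted moments. Columns whose fitted amplitude is below 2×
the background sd (estimated from the top/bottom three rows) are excluded
— the *fitted* amplitude is used because the raw column maximum of ~25
noise draws exceeds 2 sd about half the time on empty columns. A straight
line is fitted through the centres with two rounds of 2σ residual
clipping; if the residual RMS still exceeds 0.5 px, a cubic is used
instead. A 21-row image is resampled along the backbone by bi-cubic
interpolation, and the axial profile is the mean of the central 9 rows
minus the mean of the 8 extreme rows.

Each end is fitted with
`I(x) = b + (A/2)·(1 ± erf((x − µ)/(σ√2)))` by least squares, seeded from
the longest smoothed run above half-maximum (robust to isolated noise
crossings) with plateau/floor levels estimated ≥ 1.5σ away from the
presumed edge. The fit window extends ±1600 nm around the rough edge
(clipped at the profile midpoint); wide windows pin amplitude and baseline
and measurably improve µ precision. Failed or degenerate fits return a
rejected `TipFit` with a diagnostic instead of raising. Fits are accepted
when 50 nm ≤ σ ≤ 200 nm: below that the fit is narrower than the PSF
(noise artefact), above it the end is tapered or the fit diverged; σ is
the Gaussian-width parameter in nm throughout.

The length-accuracy benchmark measures both ends of every frame of
ground-truth stacks and reports the bias (mean signed error), mean
absolute error, and sd of the signed error over σ-accepted frames.
Applying the acceptance gate mirrors the analysis proper, where only gated
timepoints are used; without it, rare diverged fits dominate the sd. At
the default conditions (10 stacks × 81 frames, 18% labelled, SNR 6–11) the
pipeline is unbiased to a few nm — the residual bias is dominated by the
8 nm lattice discretisation of the true end — with an error sd near 50 nm.

## Phase segmentation (`phases`)

Length traces are segmented by recursive bisection: fit a least-squares
line; if the mean deviation exceeds 20 nm, split at the point of greatest
deviation (earliest on ties; the split point is shared by both halves) and
recurse; pieces smaller than 3 points are discarded. Deviation is the
vertical residual |length − fit| in nm. The geometric point-to-line
distance in raw (s, nm) coordinates — dividing by √(1 + m²) with m in
nm/s — would shrink every distance ~20-fold at typical growth speeds,
making the 20 nm threshold unreachable by design; the vertical-residual
reading keeps the threshold commensurate with the nm-scale noise of the
trace (a `time_scale_nm_per_s` argument restores the geometric form for
comparison). Terminal segments become phases; phases are kept when they
last ≥ 10 s with a velocity of 10–30 nm/s (float-tolerant at the
boundaries), and within kept phases only timepoints with accepted end fits
(σ in 50–200 nm) are analysed further.

## Comet analysis (`comet`)

Kymographs are oriented seed-left/tip-right; profiles are reported on a
tip-relative axis with positive positions behind the tip. The tip line is
the linear fit through per-row positions of the first pixel (scanning from
the tip-proximal side) at ≥ 90% of the row maximum, refitted inside a
±5 px confidence band and rejected above 1 px residual RMS. The row-wise
maximum is the default threshold reference (robust to bleaching); a
global-maximum mode exists. Rows are cubic-spline interpolated 10-fold
(8.1 nm), aligned at the reference line rounded to the nearest interpolated
pixel, averaged over positions covered by every row, background-subtracted
(mean over positions ≥ 15 raw pixels ahead of the tip; the window length is
configurable and the choice is uncritical as that region is structureless),
and normalised to peak 1.

Superaveraging registers each profile at its first half-maximal point
scanning from the tip side. For dual-colour data the registration shifts
come from the reference channel and are applied to both, so inter-channel
offsets survive. Comet area splits at the first post-peak 85%-of-maximum
crossing: the head is integrated trapezoidally, the tail is an unweighted
exponential fit from the crossing to the last point above 2% of maximum
(log-linear initialisation) contributing its analytic area `A·λ`.

Dual-colour pairs are interpolated 2× in time (linear; cubic interpolation
is reserved for the spatial axis), then the first row of the reference
channel and last row of the second are dropped, cancelling the half-frame
sequential-acquisition offset (~10 nm at 20 nm/s); the tip line is
detected on the reference channel and applied to both. Peak distance is
the argmax difference of the aligned averaged profiles (ties break toward
the tip), positive when the second channel sits deeper in the lattice.

Tip-relative averaging uses `µ` as the microtubule-channel reference and
`µ − 0.5 s·v_growth` for the EB channel — the 0.5 is the inter-channel
acquisition delay in seconds, so the correction is a distance; the sign
convention implies the EB channel is acquired first. EB intensity is
cubic-spline sampled every 8 nm around the reference and averaged; a
Gaussian is also fitted per timepoint and the median peak-to-tip distance
reported, giving the two estimates (ensemble argmax vs per-frame fit) that
should agree for symmetric noise. Cell line scans are aligned either at
the midpoint of two channels' first half-maximal points ("fixed" mode) or
at a single reference channel's half-max ("live" mode), shifted jointly,
averaged, and max-normalised per channel.

## Cap kinetics (`nucsim`)

The cascade `T → P → D` with uncoupled first-order rates k₁ (hydrolysis)
and k₂ (phosphate release) is expressed per lattice layer via
`κᵢ = kᵢ·rise/v` (a layer at depth L was incorporated `L·rise/v` seconds
ago) and integrated with RK45 at rtol 1e-12 and atol 1e-60 — the tiny
absolute floor keeps error control effectively relative, so the
exponentially decaying fractions stay accurate over many decades and match
the closed form to better than 1e-6 over 1000 layers. Defaults k₁ = 0.3,
k₂ = 0.13 s⁻¹ at v = 20 nm/s reflect measured hydrolysis and
phosphate-release rates and a typical in vitro growth speed; 2-fold rate
variations are ordinary parameter choices, not special cases. Pair
densities assume independent lateral neighbours (seam ignored):
TT = T², TP = 2TP, PP = P², PD = 2PD, TD = 2TD, DD = D², each ×13
interfaces per layer, so the six states sum exactly to 13.

PSF convolution is true spatial convolution with a unit-sum Gaussian
kernel (σ = 130 nm) on a grid extended 5σ beyond both ends of the profile
— the tip region ahead of the lattice carries zero density but receives
blurred signal, as in an image; a pointwise-multiplication mode exists for
comparison, and normalisation to peak 1 is optional so area conservation
can be verified. Mixed-lattice theory returns fⁿ (n = 1..4) and 2f(1−f)
per analogue fraction f.

## Curve fits (`fits`)

All fits are unweighted nonlinear least squares (scipy `curve_fit`)
initialised from closed-form linearisations (log-linear slopes,
half-saturation crossings, intensity moments), with positivity bounds on
rate/affinity parameters and standard errors from the covariance diagonal.
The binding isotherm supports fixing `I_max`, mirroring the protocol where
saturation is determined on one substrate and held fixed on others. The
competition decay uses `A·e^(−c/K)` — the decay constant carries
concentration units, and no baseline offset is included by default (the
data leave it unconstrained). The FRAP model is `plateau·(1 − e^(−t/τ))`
on post-bleach points of a normalised trace; 1 − plateau is the immobile
fraction. Gaussian peak fits include a baseline and reject monotone
windows. Convergence tolerances are scipy defaults; parameters of the
noise-free self-tests are recovered to ~1e-8 relative.

## Problem sizes and determinism

Default test and benchmark sizes — 10 stacks × 81 frames for the length
benchmark, 50 kymograph pairs per offset for the dual-colour round trip,
100 replicates for noisy-fit statistics — are the package's standard
study conditions and complete in a few minutes on one CPU. Every random
choice flows from explicit integer seeds (`numpy.random.default_rng`; the
pipeline runner derives per-stage substreams from one root seed via
`SeedSequence`), so identical configurations reproduce identical outputs
bit for bit.

## Known limitations

Backbone fitting assumes one microtubule per ROI and no crossings;
orientation relies on a single dominant elongated structure. The comet
tip-line detector expects one linear growth phase per kymograph crop. The
kinetic model has no neighbour coupling, no catastrophe/rescue, and no
stochastic per-subunit simulation — it describes average steady-state
growth. Sub-pixel dual-colour distances are quantised at one interpolated
pixel (8.1 nm) per phase; sub-8 nm offsets are resolved only in the median
over many phases.
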