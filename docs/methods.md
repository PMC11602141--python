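# Methods

## The measurement and its model

The package analyses space–time intensity matrices (kymographs) of single,
doubly-tethered DNA molecules imaged in two alternately-excited channels:
an intercalator-stained DNA channel in which plectonemes (supercoiled DNA
loops) appear as mobile high-intensity spots, and a protein channel showing
fluorescently labeled ParB dimers. All positions are expressed in genomic
kilobases from the left tether using a linear pixel→kb calibration
(`kb_per_pixel = dna_length_kb / n_pixels`); time is `frame ×
frame_interval_s` with 0-based frames and half-open lifetimes.

## Preprocessing

Raw stacks are median-filtered per frame (square 10 px window) and
background-subtracted with a flat white top-hat (default structuring
element 15 px, chosen larger than the PSF so diffraction-limited peaks
survive while smooth background is removed). Filter borders use
reflection, which avoids edge darkening that would bias end-proximal
peaks. Kymographs sum 11 pixels (±5) across the DNA axis per frame; the
protein channel is aligned to the DNA channel by a single-frame shift
(alternating excitation). Whether the median window is square or linear
along the axis is an open choice in the protocol; it is square here and
isolated behind the `window_px` parameter. 1-D signals (window-D traces,
size traces) are smoothed with a 9-frame running median whose window
shrinks at the ends.

## Tracking and sizing

Peaks are strict local maxima above a prominence threshold, by default 3×
the frame's robust noise SD (1.4826 × MAD); plateau ties resolve to the
leftmost pixel. Peaks are linked greedily to the track whose **last**
observation lies within 7 px and at most 5 frames earlier; nearest wins,
ties go to the earlier-born track. (The alternative reading — compare to
*any* track member within 5 frames — coincides with this one whenever
tracks are separated, which is the regime in which linking is well
defined.) A feature's DNA content is the background-subtracted intensity
inside a ±2 px window around the peak, divided by the whole molecule's
intensity, times the molecule length; overlapping windows assign shared
pixels to the nearer peak so fractions never double-count. By default the
stretched-backbone baseline (the median per-pixel intensity of the span)
is subtracted inside the window, so the fraction measures the *excess* DNA
stored in the feature; without this correction a 5-px window over a 100-px
molecule inherits ~1.3 kb of backbone signal per feature.

## Diffusion estimation

Per-track D comes from the time-averaged MSD over lag times 2–20 frames
fit through the origin to `MSD = 2Dτ` (no intercept; the pure 1-D Brownian
form). The fit is weighted least squares with weights inverse to the
standard variance of the time-averaged MSD of a Brownian track,
`Var[MSD(τ)]/MSD(τ)² ≈ (2τ²+1)/(3τ(N−τ+1))`, which does not depend on D;
an unweighted fit is available (`weighting="uniform"`). At the benchmark
conditions (400-frame tracks, D between 0.1 and 20 kb²/s) the weighted fit
recovers D with a median relative error of 8–10% versus ~15% unweighted.
Negative fitted slopes are clipped to zero and flagged. The apparent D
over time uses a centered 11-frame moving window with lags 1–4 (all a
short window supports), then the 9-frame median smoothing.

Two caveats, visible in synthetic data and inherent to the method rather
than this implementation: (1) apparent D of *tracked peaks* includes a
localization-noise floor of a few tenths of kb²/s, since no intercept
absorbs it; (2) for fast features (D ≈ 20 kb²/s, frame-to-frame step SD
≈ 2 kb ≈ 5 px) the 7-px linking radius censors large steps, fragmenting
tracks and biasing their apparent D downward severalfold. Diffusion
benchmarks therefore run on simulated position series; the condensate
screen is unaffected because fast features also fail its 200-frame
persistence requirement.

## Residence-time kinetics

A clamped ParB dimer releases after both CTPs hydrolyse and the opened
clamp dissociates, so dwell times are hypoexponential. Two variants are
implemented:

- **independent** (default): `T = max(E₁,E₂) + E₃`, `E₁,E₂ ~ Exp(k_ctp)`,
  `E₃ ~ Exp(k_off)` — equivalently a chain with stage rates
  `(2k_ctp, k_ctp, k_off)`. At the measured rate pairs this variant's
  mean/median/mode reproduce the reported per-condition summaries, so it
  is the default.
- **sequential**: `T = E₁ + E₂ + E₃` (Erlang(2, k_ctp) then Exp(k_off)).

Densities and survivals use cancellation-safe closed forms (series
expansions near confluent rates; all exponentials have nonpositive
arguments, so nothing overflows). The mean is closed-form
(`2/k_ctp + 1/k_off` sequential; `1.5/k_ctp + 1/k_off` independent), the
median comes from root-finding on the survival, the mode from bounded
maximisation of the density seeded by a grid scan.

Fitting is maximum likelihood on raw dwell times (not histogram least
squares, which would be bin-sensitive), with optional right-censoring at
the observation limit (survival terms) and left-truncation for the minimum
observable dwell (default 1 s in the pipeline — shorter tracks are not
reliably detectable at 10 Hz). Standard errors come from the observed
information (numerical Hessian in log-rate coordinates, delta method).

**Identifiability.** The likelihood surface is bimodal: a near-mirror mode
swaps which stage is rate-limiting. The optimiser is therefore
multi-start (moment seeds plus a coarse log-grid scan). For the
*independent* variant the mirror mode's density matches the truth's first
three cumulants to ~0.1%, so `(k_ctp, k_off)` are not recoverable from
dwell times of any realistic size — fits of that variant should be read as
a density estimate, not rate measurements. The *sequential* variant is
identified, though at n = 5000 a minority (~15%) of samples still favor
the mirror mode; replicate fits with a median are the recommended
protocol and are what `scripts/acceptance.py` reports. For the same
reason the two variants cannot be told apart by AIC at these sample sizes
(best-fit log-likelihoods differ by < 1 unit); selecting the hydrolysis
scheme requires orthogonal (structural or biochemical) evidence.

Condition comparisons use two-sided Mann–Whitney U and two-sample KS tests
(exact or asymptotic p as appropriate per SciPy). Both are calibrated at
the 1% level at n = 60 (type-I rate 0.7–1.4% over 1000 replicate pairs).
At the experimental sample sizes (n ≈ 60 vs 80) the non-coiled vs
positively supercoiled residence models separate at p < 0.05 in ~70% and
at p < 0.01 in ~45% of replicates.

## Condensate classification

A molecule is *condensed* when some sized DNA track keeps its
moving-window D below 10 kb²/s for at least 200 consecutive frames (up to
5 missing frames tolerated inside the run, matching the linking gap
limit), **and** the time-averaged ParB intensity within ±7 px of the track
exceeds 2× the molecule-wide ParB level, **and** the track's mean
intensity fraction is at least 1.5× the molecule's typical ±2 px window
fraction. The original screen was manual; the 2× and 1.5× enrichment
factors are this package's reproducible numeric surrogates, exposed as
parameters and recorded in the call's evidence block. Lowering the D
threshold or raising the required run length can only turn positives
negative (monotonicity, property-tested). Condensed fractions are
reported with exact (Clopper–Pearson) binomial 95% intervals — the
interval choice is ours; the coverage guarantee (≥95%) is property-tested.

## The synthetic generator

The generator emulates the study conditions: a 38 kb molecule with *parS*
at relative position 0.4, 10 Hz imaging, 12 kb of plectonemic DNA
(|σ| ≈ 0.05 enters only through this number), plectonemes diffusing at
20 kb²/s, ParB dimers loading at *parS* (0.05 events/s by default),
diffusing at 0.69 kb²/s and dwelling per the positive-supercoiling rate
pair (0.017, 0.047 s⁻¹), with 74% per-monomer labeling (93% visible
dimers). Plectoneme number kinetics are not constrained by published
rates, so two modes are provided: *fixed* (default) keeps a constant
count with Dirichlet-partitioned sizes — DNA conservation is exact — and
*birth–death* maintains the configured mean count with repartitioning on
every change. Positions follow reflected Brownian motion; an unbounded
helper (`brownian_track(..., length_kb=None)`) exists for estimator
benchmarks where boundary effects are not the quantity under test.

The pinned condensation scenario replaces all plectonemes from an onset
frame with a single static cluster whose DNA content ramps 8 → 11.5 kb
(~44% growth) and which carries stationary labeled ParB dimers. Free ParB
and plectonemes are otherwise independent (single dimers do not pin
plectonemes).

Rendering deposits each feature's kb content at its sub-pixel position
(linear interpolation), adds the stretched-backbone baseline across the
tether span, blurs with a Gaussian PSF (σ = 1.0 px, the diffraction limit
for ~90 nm pixels on a ~9 µm stretched molecule), and applies Poisson shot
noise on the expected signal plus a constant camera offset plus Gaussian
read noise. Twelve empty margin pixels are rendered beyond each tether
end, as in real cropped molecules, so background can be estimated from
signal-free pixels. Defaults: 50 photons/kb/frame (DNA), 200 photons per
labeled dimer per frame, offset 20, read noise SD 2.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: plectoneme nucleation/hopping kinetics
(free parameters here), polymer/elastic supercoiling physics,
intercalation-dependent twist, photobleaching and blinking, focus drift,
and intensity nonuniformity along the molecule. Tests validate the
*analysis chain* against a ground truth with the assumed statistical
structure, not the biology.

## Numerical and design choices

- One global seed fans out to per-stage child seeds
  (`SeedSequence.spawn`), so outputs are byte-identical under a fixed
  config and stage order never perturbs another stage's stream.
- Sub-pixel localization is deliberately absent (the method operates on
  pixel maxima); positions are integer pixels.
- Degenerate inputs: tracks shorter than the minimum lag raise; windows
  with undefined MSD yield NaN; all-NaN smoothing windows yield NaN;
  n = 0 molecules raise on fraction estimation.
- The per-molecule pipeline on the default 600-frame synthetic
  configuration runs in under a second; the full validation suite and the
  acceptance script each run in well under a minute on one CPU.
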