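# Methods

This note documents the models, defaults, and numerical choices behind
`eggcircuit`, and what the synthetic benchmark does and does not establish.

## Ratio extraction from image stacks

Background is estimated per frame from the mCherry channel in two passes:
mean/SD over all pixels, then mean/SD over pixels at or below the pass-1
mean + 2 SD. The two-pass form makes the estimate robust to bright ROIs
occupying a few percent of the frame; per-recording background is available
by option. Pixels above background mean + 2 SD form the object mask;
8-connected components of ≥ 5 px (`min_object_px`) become objects, which
suppresses single-pixel noise. When a cell is split across several
components, the joined ratio is the area-weighted mean of per-object mean
pixel ratios — algebraically identical to the mean pixelwise ratio over the
union of object pixels, and invariant to how components are split or labeled.
Frames with no object become missing values; gaps of ≤ 10 frames are linearly
interpolated, longer gaps stay missing, and extraction aborts if more than
half the frames are missing. Because both channels share any multiplicative
gain (motion, focus, illumination), the extracted ratio is exactly invariant
to per-frame global gain; the test suite asserts this to float precision.

## Trace conditioning and transient detection

Ratio traces are smoothed with a centered 150 ms rolling average (3 points at
20 frames/s; shrunken windows at the edges). The ΔR/R baseline is the mean of
the lowest 10% of smoothed ratio values over the whole recording (computed
post-smoothing; a pre-smoothing option exists). This floor estimator sits
~1.75σ below the noise mean by construction, which (a) inflates amplitudes by
~2%, a bias well inside the 10% recovery tolerance the tests enforce, and
(b) matters for detection thresholds, below.

Peaks are local maxima of ΔR/R with minimum separation 0.5 s and both
**prominence** and **height** at least `min_prominence_sigmas` (default 4)
times a robust noise scale. The noise scale is 1.4826 × MAD of the first
difference / √2, multiplied by √window to undo the variance reduction and
autocorrelation introduced by the rolling average. The height criterion is
referenced to the median of ΔR/R (the robust noise-floor location) rather
than zero because of the baseline offset noted above. Prominence alone does
not bound the false-positive rate — in pure Gaussian noise, hundreds of local
maxima per 10 minutes carry ≥ 4σ prominence because excursion minima are
deep — while the joint height + prominence criterion measured 0.4
false positives per 10 minutes at default settings; the suite asserts < 1.
The detection floor is 1e-4 ΔR/R, far below any physiological transient but
above numerical ripple in noise-free renders.

Each peak's extent is its width at half-maximum: the trace is walked outward
from the peak to the half-amplitude crossings with linear interpolation
between samples, and overlapping spans are truncated at the inter-peak
minimum. Amplitude normalization (max peak = 1 per recording) supports
cross-reporter comparisons.

## States, intervals, egg coincidence

Active states are built from egg-event times only: each egg contributes a
±60 s window, overlapping windows merge (merge_gap defaults to 0 s, so eggs
≤ 2 min apart share a state), and the complement is inactive. Membership is
half-open [start, end) for deterministic boundary assignment. Inter-transient
intervals are successive-peak differences within one state interval;
cross-boundary pairs are excluded (option to include). When a recording has
inactive time before its first or after its last transient, those elapsed
times enter the inactive sample — the operational rule for quiet stretches —
so reported inactive intervals are a lower bound on true quiet-state pacing.
A transient is egg-coupled iff an egg time falls inside its half-max span
(closed interval); coverage is reported in both directions (fraction of
transients with an egg; fraction of eggs inside a span).

## Rhythm analysis

Active-state ΔR/R segments (≥ 30 s; shorter segments are flagged
low-resolution) are mean-subtracted and FFT-transformed with zero-padding to
the next power of two ≥ 4× the segment length, giving ≤ ~1.2 mHz bin spacing
for a 2-minute segment at 20 frames/s. No taper is applied by default
(segments are short and the quantity of interest is a peak location); Hann is
available by option. The dominant rhythm is the argmax of power on
(0, 250] mHz excluding the zero-frequency bin, ties broken toward lower
frequency. Lomb–Scargle (scipy) runs on the same grid for uneven sampling or
binarized event trains, and an autocorrelation estimate (first significant
positive peak, 2/√n bound) provides a third route; the suite checks all three
agree on evenly sampled periodic inputs.

## Locomotor phase

Landmark times of maximal ventral contraction (0°/360°) and relaxation (180°)
bracket each peak; the phase is base + 180° × elapsed fraction between the
flanking landmarks, reduced to [0, 360). The construction is invariant to
time translation and uniform rescaling — hence independent of animal speed
and locomotion direction — and monotone between landmarks. Landmarks can be
extracted from a 1-D bend signal by alternating peak finding (sign convention
configurable); non-alternating detections are repaired by keeping the more
extreme of adjacent same-kind extrema, with repairs counted.

Phase histograms use eight half-open 45° bins; the uniform null is 12.5% per
bin. For uniformity testing the package reports two constructions. The
bin-count construction (observed counts vs an equal-n uniform draw,
Kruskal–Wallis across bins) reproduces the published recipe, but with only
2 × 8 count observations its p-value resolution bottoms out near 1.5e-4 and
Monte-Carlo calibration during development measured a type-I rate of ~0 at
α = 0.05 — it is deeply conservative and cannot calibrate smoothly. The
primary p-value is therefore a Rayleigh test on the circular sample
(flagged in the output metadata as an addition to the published
construction); its measured type-I rate is 0.046 at α = 0.05 with full power
on concentrated samples, and those calibration properties are asserted in the
suite.

## Egg-triggered alignment

Snippets of ΔR/R in a ±10 s window (chosen to contain the known peri-event
dynamics; events without a full window are excluded and counted) are each
normalized to peak = 100% and synchronized at egg release; the ensemble
median and per-event peak offsets (from detected peaks when available,
snippet argmax otherwise) summarize relative timing. Object-size snippets
normalize to the pre-event mean instead. Peri-event speed comes from centroid
displacement per frame, 3-point smoothed, with a pointwise t-based 95% CI and
paired t comparisons of speed at 0 s vs ±1 s. No resampling is needed when
recordings share a frame rate; linear interpolation otherwise.

## The synthetic generator

The generator is the package's study condition, not a fitting device. Its
defaults encode the circuit's published statistical structure:

| parameter | default | basis |
|---|---|---|
| frame rate | 20 /s | recording rate |
| inactive / active state mean | 1200 s / 120 s (exponential) | ~20 min quiet, ~2 min active |
| body-bend period | 10 s, CV 0.05 (Gamma per half-period) | locomotor rhythm; crawling is regular |
| HSN | 4 s FWHM; 20 s rhythm (CV 0.12), 17 s mean active interval, 41 s inactive | reported widths, rhythm and interval means |
| VC | 2 s FWHM; 10 s active intervals; sparse inactive (120 s) | reported widths/intervals; inactive rate unreported, chosen sparse |
| vm | 2 s twitch FWHM, one twitch per bend cycle in the active state (40 s inactive mean), egg transients 4× and 4 s | twitch phasing, 4× egg amplitude |
| uv1 | egg-triggered only, rise at egg + ~0.5 s lag, peak ~2 s after egg, p = 0.9 per egg | post-egg activation, occasional silent events |
| phase preferences | vm twitch 270°, vm egg 225°, HSN egg transient 180° (von Mises) | reported modal phases |
| egg rate | 0.03 /s inside active-state interiors | ~3–5 eggs per active state |
| noise | additive SD 2 per channel on baselines 100/200; shared artifact amplitude 0.1, 5 s timescale | ~1–2% ratio noise, slow motion artifact |

Two structural choices deserve explanation. First, the HSN active-state train
must express a ~50 mHz rhythm *and* a 17 s mean interval simultaneously;
these are reconciled exactly as the biology suggests — transients ride a 20 s
oscillator and sometimes arrive as short trains: a doublet follows the cycle
peak at +7 s with probability 20/17 − 1 ≈ 0.18, making the mean interval
17 s while the spectral fundamental stays at 50 mHz. Second, eggs are drawn
(homogeneous rate, thinned onto HSN transients) only in the *interior* of
active states, inset by 60 s: circuit activity ramps up about a minute before
the first egg and persists about a minute past the last, which is precisely
why the ±1 min egg-based definition reconstructs the underlying state. With
the inset, the egg-defined active state is a subset of the true one, so
active-state statistics recovered through the pipeline estimate the true
active-state parameters. Active states too short (< 2 min) to contain an
interior simply lay no eggs and are scored inactive by the egg-based
segmentation, as in real recordings.

Transient kernels are Gaussians parameterized by FWHM (the only kinetic
statistic available); overlaps add linearly. Renewal trains carry a
refractory floor of 1.4 × FWHM — two Gaussians closer than ~3σ fuse into a
single local maximum, so the generator never emits peak pairs the waveform
cannot represent; for the same reason transients closer than 1.4 × FWHM are
merged (egg-coupled peaks win a merge), and egg-bearing HSN peaks are kept at
least that far apart. The HSN peak leads egg release by 1.8 s (reported
"~2 s"): with a symmetric 4 s kernel, a 2.0 s lead would sit exactly on the
half-max boundary and make egg coverage a coin flip under noise, whereas the
real waveform decays slowly past its peak.

Randomness flows from one seed through named `SeedSequence` substreams
(timeline, bends, eggs, one per cell type, noise per channel), so editing one
cell's parameters leaves the other trains unchanged and identical configs are
bit-reproducible.

What the generator does *not* emulate: posture and morphology (no worm video,
no vm1/vm2 anatomy), bleaching, focus drift beyond the shared multiplicative
artifact, asymmetric transient kinetics, mechanically coupled VC/vm
deformation artifacts, optogenetic perturbations, and correlated noise
between channels. Passing recovery tests on this benchmark therefore
establishes that the analysis is correct for data with the assumed
statistical structure, not that it is robust to every artifact of real
recordings.

## Benchmark problem sizes

The cohort benchmark pools 70 simulated hour-long recordings (spawned seeds
from one master seed, as published analyses pool animals), yielding roughly
50 egg-bearing active states, ~500 active-state HSN intervals and ~130 eggs —
comfortably above the ≥ 20 segments / ≥ 300 transients the recovery checks
require, with the whole run completing in seconds. The genotype power study
(17 s vs 13 s active intervals, ≥ 100 intervals per group, 100 seeded
Mann–Whitney runs) operates on simulator ground-truth transient times run
through the state/interval machinery; detection is exercised by the other
benchmarks and adds nothing to a test of the statistical comparison.

## Group comparisons

Pairwise comparisons use Mann–Whitney; three or more groups use
Kruskal–Wallis with Dunn's pairwise z statistics (standard rank-sum form with
tie correction) under Bonferroni adjustment — Dunn's correction is computed
in-repo because no installed library provides it; the omnibus tests come from
scipy. Medians and quartiles accompany every comparison; empty samples skip a
comparison with a note rather than erroring.

## Known limitations

* Inactive-interval estimates are downward-biased by recording truncation
  (acknowledged operational rule); the pipeline reports uncropped values and
  offers cropping as an option rather than guessing a cropping convention.
* The FFT dominant peak is reported on the zero-padded grid; segments of
  different lengths have slightly different grids, and medians across
  segments inherit that quantization.
* `uniformity_test`'s primary p-value is not the published construction (see
  above); both are always reported.
* The object detector assumes a single cell per frame neighborhood; it does
  not track identities across frames or register motion.
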