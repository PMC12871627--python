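# Methods

## Signal model

Each surface-tethered molecule carries one donor and one acceptor dye and is
imaged in two channels at a fixed frame interval (default 0.1 s, 800
frames). Before any photobleaching, a molecule in state E emits

    I_A = T·E + b,        I_D = T·(1 − E)/γ + b

where T is the total photon budget per frame, b the background, and γ the
per-molecule detection-imbalance factor (relative detection efficiency ×
quantum yield of the two channels). When the acceptor bleaches, its photons
return to the donor channel (I_D rises to T/γ); when the donor bleaches,
both channels fall to background. The identity E = I_A/(I_A + γ·I_D) holds
exactly under this model, which is what makes the jump-ratio γ estimate and
the efficiency formula mutually consistent.

The simulator (`trace_sim`) draws per-molecule state assignments from a
discrete state list, γ from a truncated normal, and bleach times from
exponential waiting-time distributions, then adds Gaussian read noise per
channel (a Poisson shot-noise flag exists for stress tests, as does an
optional two-state Markov switching mode; both are off by default because
the summed histograms are treated as static mixtures). Defaults: T = 100
photons/frame, noise sd 5 (5% of T), b = 0, γ ~ N(1.0, 0.1) truncated
positive, acceptor bleach rate 0.05 s⁻¹, donor 0.015 s⁻¹. The acquisition
parameters mirror a typical objective-TIRF smFRET recording; the intensity
and noise magnitudes are generic EM-CCD-scale values chosen once for the
recovery benchmarks, and the faster acceptor rate reflects the relative
photostability of common donor/acceptor cyanine-class pairs — it also
produces the bleach ordering the selection rule requires in roughly half
the molecules. Per-molecule randomness is seeded by (master seed, molecule
index), so ensembles are reproducible and order-independent.

What the simulator does **not** emulate: spectral crosstalk and direct
acceptor excitation (the analysis assumes a γ-only correction), dye
blinking, intensity drift, aggregates, and baseline fluctuations. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to every artifact of real
recordings — the QC reject codes are the hook for those.

## Photobleach detection and molecule selection

Change points are found per channel by greedy binary segmentation of a
piecewise-constant least-squares fit: the split with the largest
sum-of-squares reduction is accepted while the reduction exceeds
`penalty · σ² · log n`, with σ estimated robustly from the median absolute
first difference (MAD × 1.4826 / √2). The default penalty of 10 puts the
threshold well above the expected maximum spurious gain under Gaussian
noise (≈ 2σ²·log n) while leaving genuine bleach steps — tens of photons
against σ ≈ 5 — orders of magnitude above it. Detection is deterministic;
`min_segment` (default 3 frames) bounds the resolution at trace edges.

A molecule is accepted when the acceptor channel shows exactly one downward
step, the donor exactly one downward step, and the acceptor step comes
first. Upward donor steps (the recovery at acceptor bleach) never count
against a molecule. Everything else is rejected with a coded reason
(`no_acceptor_bleach`, `no_donor_bleach`, `multi_step`, `order_violation`,
`too_short`, `gamma_invalid`); the codes partition every input ensemble.
Note one physical subtlety: if the donor dies first, sensitized acceptor
emission stops at the same frame, so both channels step together and the
trace is rejected as an order violation — a genuinely missing acceptor
instead leaves the acceptor channel flat.

γ is the jump ratio at acceptor bleaching, (mean I_A before − after) /
(mean I_D after − before), with 20-frame windows on each side, the step
frame ± 1 excluded, and the window capped at the donor bleach. Common
additive background cancels in both differences. Estimates outside
[0.2, 5] reject the molecule — such values only arise from pathological
traces and would corrupt distances. The per-trace baseline for efficiency
computation is the mean of both channels after donor bleach.

## Histogram and mixture decomposition

Efficiencies are computed frame-by-frame over the pre-acceptor-bleach
region only, not clipped (the histogram range −0.25 to 1.25 absorbs noise
excursions). Frames with non-positive corrected total are dropped; more
than 20% dropped frames discards the molecule. Traces longer than 20
points enter the summed histogram, 40 equal bins over [−0.25, 1.25),
half-open with the last bin closed; each trace's frames carry weight
1/(trace length), so each molecule contributes total weight 1 and the
histogram total equals the molecule count. Out-of-range values are
discarded — with the 0.75-width margins on both sides this does not occur
under the default noise model, preserving exact weight conservation.

The histogram is fitted with a sum of 1–4 Gaussians by unweighted nonlinear
least squares on the bin heights (Levenberg–Marquardt via lmfit). Means are
bounded to the histogram range; widths are bounded below at half a bin
width and flagged if they hit the bound. Unless explicit initial means are
supplied, fits start from weighted quantiles of the histogram plus five
deterministically jittered restarts, keeping the lowest-SSE solution.
Fractional areas are analytic Gaussian area shares, amp·sd / Σ amp·sd, the
convention under which a figure legend's areas sum to ~100%. The number of
components is always user-chosen per dataset; SSE is non-increasing in the
component count, so an automatic criterion would be a model-selection
choice we deliberately leave to the analyst.

`shared_sd=True` ties all component widths to one fitted value. This is an
identifiability constraint, not a convenience: on a finite-sample histogram
a minor component overlapping a major one (separation ≈ 2σ) can trade its
mean against its width almost freely, and the global least-squares optimum
itself wanders by ±0.05 in the minor component's mean between random
samples. When the physical widths are expected to be equal — broadening
dominated by shot noise rather than state heterogeneity, as in the
synthetic recovery benchmarks — the constraint removes that degeneracy
(maximum highest-mean error across seeds drops from ≈0.07 to ≈0.02 in our
benchmarks). The default remains free widths.

## Förster model

R = R₀·((1−E)/E)^(1/6) and its inverse, with R₀ = 5.8 nm as the working
default for the maleimide Alexa Fluor 555/647 pair. Distances are reported
round-half-up at 0.1 nm; fitted peak efficiencies outside [0.01, 0.99] are
clamped for distance reporting only and flagged. Calibration of R₀ from
reference (E, R) pairs uses the closed form for a single pair and bounded
least squares on efficiency residuals for several; per-pair closed-form
estimates are always reported alongside the pooled value so the analyst
can pin either as the working R₀.

## Dye accessible volume

Mean inter-dye distances on a structure are predicted by a single-sphere
accessible-volume model: dye centers are sampled uniformly within a sphere
of radius `linker_length` (default 21 Å, generic maleimide-linker reach)
about the attachment atom (Cβ; Cα + 1.5 Å extra reach for glycine),
rejecting positions within `dye_radius + 2 Å` (defaults 5 + 2) of any
protein atom, with the attachment residue's own side chain exempt since
the linker replaces it. The default 100 samples per site match common
practice for dye-position averaging; the mean distance is taken over all
A×B cross pairs (samples are independent) and reported in nm. Acceptance
below 1% raises a buried-site error rather than returning a biased mean.

Sampling offsets live in a local frame built from the residue's backbone
atoms, so a rigid motion of the structure transports the sampled cloud
with it and predicted distances are exactly invariant under seed re-use.
The model is deterministic and is validated against dense-grid brute-force
oracles applying the same clash rule; it deliberately ignores dye-specific
energetics, orientation factors (κ²), and per-atom dye shape, so its
absolute distances are geometric approximations suited to ranking
candidate structures against measured distances.

## Puncta and crosslinking

Footprint time courses: per frame, the mean of (intensity − background)
over the footprint mask, divided by the first frame (first element exactly
1 by construction, making the series invariant to expression level).
Background is a user-supplied cell-free region's per-frame mean, falling
back to the per-frame 5th-percentile pixel value — the correction is
applied per frame rather than as a static offset, which also absorbs slow
illumination drift. The footprint mask is user-supplied or
Otsu-thresholded from the temporal-mean image. Cell aggregation reports
the pointwise mean and SEM (sd/√n). Crosslink efficiency is
dimer/(monomer + dimer) per gel lane, reported as integer percent.

## Problem sizes and determinism

Recovery benchmarks use 500-molecule ensembles (≈200 accepted after QC),
5000-sample histograms for mixture recovery, and 10⁵-point grids for the
accessible-volume oracles — sizes at which Monte-Carlo error sits well
inside the assertion tolerances while a full run of the suite stays
interactive. All randomness flows from explicit seeds; reruns of the same
configuration produce byte-identical outputs.

## Known limitations

- The γ-only efficiency correction assumes negligible spectral crosstalk
  and direct acceptor excitation; data needing full α/β/γ/δ corrections
  are out of scope.
- Binary segmentation with a global noise estimate can mis-localize steps
  within ~2 frames of a segment edge and assumes roughly stationary noise.
- Histogram mixture fits quantify state populations only up to the
  identifiability limits discussed above; populations of components
  separated by less than about one σ should not be trusted regardless of
  fit diagnostics.
- The accessible-volume model uses a single sphere rather than the
  three-radius dye ellipsoid; predicted distances for tightly occluded
  sites are more approximate than for exposed ones.
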