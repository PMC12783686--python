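# Methods

This note documents the models, conventions and numerical choices behind
`condensquant`, and what the synthetic-data validation does and does not
demonstrate about real microscopy data.

## Droplet-field quantification

Droplets are segmented per channel as connected components (8-connected)
above an intensity threshold, filtered by area bounds and circularity.
The threshold rule defaults to per-channel Otsu; a fixed value or a
"k robust standard deviations above the median" rule can be selected for
sparse fields where the histogram is not bimodal. Circularity is
4π·area/perimeter² with the perimeter estimated by the Crofton formula
(4 directions), which is markedly less biased on small discretised disks
than chain-code perimeters; values are clipped at 1.05 because a
discretised disk can slightly exceed 1. Defaults: minimum area 10 px,
maximum 10⁴ px, minimum circularity 0.8. These values are declared
package defaults — segmentation parameters are rarely printed in assay
descriptions and should be set explicitly in the run config.

The bulk mean `C_out` is taken over pixels belonging to no droplet; when
several channels are segmented the driver excludes the union of all
droplet masks, so the bulk estimate is condensate-free. One bulk
estimate serves all droplets of a field. The partition ratio is
per-droplet `C_in / C_out`; a zero bulk mean leaves ratios flagged NaN
rather than raising, since empty control channels are routine.

The condensed fraction divides the intensity sum over droplet pixels by
the intensity sum of the whole field (not of the bulk only), so
condensed fraction plus bulk share is exactly 1. The bleedthrough filter
removes droplets from a *channel's statistics* — never from the droplet
geometry — when their partition ratio in that channel falls below the
channel-class floor (green/red 1.1, blue 1.35, reflecting green→blue
spectral spillover). Keeping the geometry intact matters because a
scaffold channel's mask is reused for co-condensed fractions. Unknown
channel names require an explicit floor rather than guessing a class.

Reference normalisation divides each value by the mean of the reference
condition *within the same channel*, making conditions comparable while
leaving channels independent.

## Junction line profiles

Profiles are sampled along a user-supplied polyline at 1-px arc-length
spacing; at each sample the intensity is the mean of `width` (default 4)
bilinearly interpolated reads spaced 1 px apart along the local normal.
Polylines are consumed from CSV/JSON sidecars (0-based pixel
coordinates, origin top-left); the package never auto-traces junctions,
mirroring how contacts are selected manually in practice.

The baseline is the mean of the 20th–40th lowest samples (1-based,
inclusive: 21 values). Ranks rather than percentiles are used; this
choice is deliberate and fixed. Skipping ranks 1–19 avoids anchoring on
the darkest noise outliers, and as long as clusters occupy a minority of
samples the rank window sits entirely in cluster-free baseline, which is
why the estimator recovers a synthetic baseline to within 2 % even with
three clusters present. Normalisation divides by the baseline (no
subtraction) so the peak-amplitude thresholds act on fold-over-baseline
contrast. Profiles must contain at least 40 samples (4 µm at 100 nm/px).

"Minimal peak amplitude" is implemented as peak *prominence* relative to
the normalised profile's dynamic range (max − min), computed with a
standard topographic prominence routine; plateau peaks report their
centre sample. Prominence, unlike absolute height, is unaffected by a
sloping baseline and makes the 50 %/25 % settings directly comparable
across contacts. Peak positions are integer sample indices — no
sub-pixel refinement — so the overlap criterion counts index distance.
Overlap is inclusive (|Δ| ≤ 3 px) and one-to-many: a partner peak may
satisfy several reference peaks. A contact with zero reference peaks
yields an undefined overlap (`None`), propagated as not-applicable
rather than 0, since the two are biologically different outcomes.

Cluster sizes come from a least-squares fit of
`offset + A·exp(−(x−μ)²/2σ²)` in a window of ±10 px (configurable)
around the peak, initialised at the peak position with σ = window/4,
with σ bounded positive. The diameter is FWHM = 2√(2 ln 2)·σ in nm. On
noiseless Gaussians with σ ≥ 1.5 px the estimator is exact to ≤ 0.5 %;
under 5 % amplitude noise the ensemble mean stays within 3 % of truth.
Non-convergent fits are flagged and excluded from size statistics.
The profile correlation is the square of Pearson's r, so perfect
anti-correlation also scores 1 — acceptable here because paired junction
channels are never anti-correlated, but a documented caveat.

## FRAP

Traces are extracted from time-lapse stacks by maximum-intensity
z-projection followed by ROI means (half-open rectangles, 0-based).
Normalisation is the double (full-scale) convention: with
background-subtracted intensities, the pre-bleach mean maps to 1 and the
*single* first post-bleach frame to 0 — at 10-s sampling the bleach
occupies one frame, so averaging several "post" frames would already
contain recovery. This construction cancels any affine gain/offset of
the acquisition (verified by metamorphic tests). No acquisition
photobleaching correction is applied by default.

The recovery model `Y(t) = Y(0) + (F_mob − Y(0))(1 − e^(−t ln2/τ½))` is
fitted by bounded nonlinear least squares over (Y0, F_mob, τ½) with
Y0 ∈ [−0.2, 0.5], F_mob ∈ [0, 1.5], τ½ ∈ (0, 10 × duration]; initial
values are the first post-bleach sample, the last-decile mean, and the
first time the trace crosses halfway between them. Y0 is fitted freely
even though normalisation anchors the first post-bleach frame at 0: with
noise the anchor frame is a single noisy sample, and letting Y0 absorb
it removes that bias. A half-time pinned at a bound is flagged
unreliable. Two modes exist: `ensemble-mean` (default; average replicate
traces pointwise, fit once — the convention for reporting a condition's
kinetics, with lower parameter variance than averaging per-trace fits)
and `per-trace`.

The unbleached reference region is normalised on the **cluster's**
pre-bleach scale, `(I_ref − bg)/I'_pre`, not its own: the point of the
comparison is to plot the junction level and the cluster's recovery on
one axis, so a junction dimmer than the cluster sits below 1 and the
plateau-to-reference ratio `F_mob / ⟨ref⟩` reads directly as "recovered
to x of the surrounding junction level".

## Synthetic data: what it emulates, and what it does not

The generator renders the *statistical structure the estimators assume*,
with exact ground truth:

- droplet fields: hard-edged disks (analytic two-level truth) with a
  source→target bleedthrough matrix and additive Gaussian noise clipped
  at 0. An optional Gaussian edge blur (σ ≈ 1 px is realistic for
  diffraction-limited droplets) trades analytic truth for realism.
- junction profiles: baseline + Gaussian clusters with FWHM drawn from
  250–600 nm, second-channel co-occurrence per cluster with positional
  jitter (default sd 1 px, chosen so the 3-px overlap window is
  meaningfully exercised rather than trivially satisfied).
- FRAP traces: exact forward simulation of the recovery model with a
  pre-bleach plateau, Gaussian noise, and a constant reference trace.

Default pixel sizes are 100 nm/px for junction images and 120 nm/px for
droplet fields (typical of 60× spinning-disk confocal acquisition) and
are always explicit in configs. Noise is additive Gaussian, not
Poisson/mixed shot–read noise; droplets are circles, not spheres imaged
through a PSF; profiles have stationary baselines. Passing the
parameter-recovery suites therefore demonstrates estimator correctness
under the stated models — it does not certify performance on real images
with structured background, uneven illumination or clustered noise.

## Problem sizes and determinism

The validation suites use ensembles sized for tight Monte-Carlo error at
interactive runtimes: 200 traces for the FRAP half-time recovery
(standard error of the ensemble-mean fit ≪ the 5 % check), 200 profiles
per co-occurrence probability for overlap recovery (binomial sd of the
mean ≈ 0.02), 100 repetitions for the noisy FWHM ensemble. Every random
draw flows through `numpy.random.default_rng` seeded explicitly;
identical seeds give bit-identical outputs, and pipeline outputs contain
no timestamps so reruns are byte-identical.

## Known limitations

- No droplet tracking, fusion kinetics, 3-D segmentation or
  reaction–diffusion FRAP models (single-exponential only).
- Peak calling has no sub-pixel localisation; overlap is counted in
  integer pixels.
- Manual steps of the original workflow (polyline drawing, blind peak
  verification, movie scoring) are consumed as input tables, not
  automated; an exclusion list can reproduce manual peak rejection.
- R² conflates correlation sign; the bleedthrough floors are fixed
  per spectral class rather than estimated from single-fluorophore
  controls.
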