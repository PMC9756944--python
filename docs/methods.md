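# Methods

This note documents the models implemented in hyphachrom, their
assumptions and defaults, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Single-particle tracking and diffusion states

**Linking.** Localizations in consecutive frames are linked when within
0.6 µm, by greedy matching in ascending distance; track ends unmatched
at frame *f* are retried against frame *f*+2 with the same radius (one
missing frame allowed, covering fluorophore blinking).  Greedy matching
is what common trackers do; the test suite compares it against the
minimum-total-distance assignment on sparse instances and requires
near-perfect agreement rather than silently assuming it.  Gap-spanning
steps carry Δt = 2·dt and are excluded from mixture fitting by default.

**Diffusion mixture.** For 2D Brownian motion sampled at interval dt
with i.i.d. Gaussian localization error σ_loc per coordinate, the
squared lag-1 displacement is exponentially distributed with mean
4·D·dt + 4·σ_loc².  A K-component exponential mixture on the pooled
squared displacements is therefore the likelihood-exact analogue of the
Gaussian-mixture analyses used by single-molecule tracking tools, and
is fit by EM with quantile-spread initialisation plus random restarts
(best log-likelihood kept; the log-likelihood is monotone per
iteration, which the tests assert).  Components are reported in
ascending D; D_k = (mean_k − 4σ_loc²)/(4·dt), clipped at zero.  The
weight-averaged apparent D is reported as the headline average; a
per-track MSD-based estimate with a Gaussian mixture on log D is
available as a cross-check (`msd_track_diffusion`).  σ_loc defaults to
0 in the estimator (correction off) and is exposed everywhere.

**Mobility classes.** Each lag-1 step is labelled by its
maximum-posterior state under the two-state fit; a track with at least
3 steps is *confined* if every sliding 3-step (90 ms at 30 ms frames)
window is entirely slow, *free* if entirely fast, *mixed* otherwise.
Tracks shorter than 3 steps are not classified.

*Known limitation.* Per-step maximum-posterior labelling of
exponential mixtures is intrinsically asymmetric: a fast-state step is
small with appreciable probability (P ≈ 0.16 of falling under the slow
label at the default parameters), so the *free* fraction is biased low
and *mixed* high even with perfect tracking; the *confined* fraction is
accurate to a few percent provided the slow-state displacement is not
dominated by localization noise.  Recovery validation therefore runs at
10 nm localization error (the precision achievable for long-dwelling,
unblurred molecules) and with short tracks (mean ≈ 2 frames,
photoactivatable-fluorophore-like bleaching); at 20–30 nm error and
long tracks the confined fraction degrades by several percent more.
This mirrors the behaviour of the field's classifiers; the bias is a
property of the rule, not of the implementation.

## Hyphal focus quantification

Coordinates are 1D positions along the hyphal axis measured **from the
current tip** (µm), matching how tip-to-focus and inter-focus distances
are defined in tip-growing filaments; no 2D imagery is handled — inputs
are already-traced intensity profiles.

**Peak detection.**  Background: SNIP-style iterative clipping
(decreasing window, half-width = background_window/2, default 2 µm).
Noise: σ from sigma-clipped first differences of the profile —
profiles are short (tens of pixels) and peaks can cover a large
fraction of them, so plain MAD estimators of either the residual or the
differences are inflated by the peaks themselves; iterative 3σ clipping
of the differences rejects peak slopes.  Detection: local maxima of the
Gaussian-smoothed (σ = 0.1 µm) residual above snr_threshold (default
5) × noise σ; maxima closer than min_separation (default 0.5 µm,
roughly the optical resolution) keep the higher; positions refined by
3-point parabolic interpolation (sub-pixel).

**Focus tracking and duplications.** Foci are linked frame-to-frame by
along-axis nearest neighbour within max_move (0.5 µm per 10-min frame);
exact ties break toward the tip.  A focus appearing within split_radius
(1.0 µm) of a continuing trajectory starts a sister trajectory; sisters
persisting ≥2 frames define a duplication event, with both sisters'
tip-distances recorded at 10-min intervals for 90 min and stacked into
the event × timepoint matrix (column means give the average-position
trace).  Sisters closer than the optical separation limit are detected
as one focus, so events are dated ~1–2 frames after the true split and
the first resolvable separation is ≈ min_separation.

**Phenotype rules** (boundary-exact, validated at the thresholds):
no emergence during the 960-min observation → *nongerminating*; after
emergence, any gap between successive extension observations strictly
longer than 60 min → *inhibited*; a branch with ≥120 min without
extension and no re-initiation before the series end →
*stalled_branch*.  Extension means a length increase above
extension_epsilon = 0.2 µm (sub-pixel motion is not growth; chosen, not
taken from data).  Series too short for a rule return *unclassifiable*.
The stalled-versus-growing comparison samples each stalled hypha 10 min
before arrest and pairs it with a distinct normally growing hypha at
the frame of closest matching length.

**Loess.** Local linear regression with tricube weights
(statsmodels lowess, robustifying iterations off), evaluated at the
input abscissae.

## Sliding-window differential binding

Windows of 69 bp every 23 bp tile each contig from zero (69/23 = 3, so
every internal base lies in exactly three windows); a contig shorter
than one window yields a single truncated window.  A fragment adds one
count to every window it overlaps by ≥1 bp.  The local filter computes,
per window, the fragment count of the surrounding 2000 bp interval
minus the window's own count, rescaled by width/(bg − width), and
retains windows with log2((count+0.5)/(background+0.5)) > 2 on the
average across samples; note that with fragments longer than the window
the overlap-count ratio of a *uniform* library sits near
log2((width+fragment)/width) ≈ 1.96, i.e. just below the threshold, so
the filter is permissive by design and final error control rests with
the count test.

Counts are modelled as NB(µ, φ) with log µ = η_group + log-library-size
offset.  The common dispersion φ maximises the Cox–Reid adjusted
profile likelihood, computed by vectorised Fisher scoring of the
per-window group means inside a golden-section search on log φ (with an
explicit comparison against the Poisson boundary).  The condition
effect is tested per window by likelihood ratio against χ²₁; a
simplified quasi-likelihood F-variant (per-window deviance scale shrunk
halfway to the across-window mean, F(1, n−2)) is available, but the
full trended/shrunken QL dispersion machinery of the established
count-model packages is deliberately not reimplemented — the LRT's
validity is demonstrated by type-I-error calibration on null
simulations instead.  Tested windows whose gaps are strictly smaller
than 100 bp merge transitively into regions; the region p-value is
Simes' combination over member windows (valid under the positive
dependence of overlapping windows); regions are BH-adjusted and
reported below FDR 0.05 with their fold change (prior-damped group-mean
ratio), direction and AT fraction (A+T over unambiguous bases).
Normalisation is by total fragment counts as offsets; TMM-style
compositional correction is out of scope.  Binned coverage divides
per-bin overlap counts (200 bp bins) by the library total and averages
replicates.

## Growth curves and small statistics

The three-parameter log-logistic OD(t) = d/(1+exp(b(log t − log e)))
(lower asymptote 0) is fit by multi-start Levenberg–Marquardt
(b₀ ∈ {−1, −5, −10}; d₀ = max OD; e₀ = first time above half-max) with
standard errors from the Jacobian; the drc-style sign convention keeps
b negative for increasing curves.  First-reading blank subtraction is
available as preprocessing.  The Wilcoxon test is the unpaired
two-sided rank-sum (groups are independent strains), exact for
min(n) ≤ 8 without ties, otherwise normal approximation with mid-ranks
and continuity correction.  ΔΔCt follows the comparative formula with
relative level 2^(−ΔΔCt).

## Synthetic data: what it emulates, and what it does not

* **SPT**: two-state Markov switching parameterised by an overall rate
  `switch_prob` and stationary slow fraction `f_slow`
  (p_slow→fast = switch_prob·(1−f_slow), p_fast→slow =
  switch_prob·f_slow — a literally symmetric chain could not hold a
  75% stationary fraction); Gaussian per-axis steps; localization error
  added after trajectory simulation; blinking removes single frames;
  bleaching is geometric; optional staggered photoactivation keeps
  per-frame density realistic for linking.  Defaults: Δt 30 ms,
  D 0.015/0.400 µm²/s, f_slow 0.75, σ_loc 20 nm.  No PSF/camera model,
  no motion blur, no drift.
* **Hyphae**: 1D axes growing 0.3 µm per 10-min frame from 3 µm; a
  tip-anchored focus at 1 µm from the tip (drifting at `tip_drift` when
  anchorage is lost) and body foci every 1.55 µm that recede with
  growth; duplication splits the tip focus with the sister separating
  0.3 µm/frame to a 1.75 µm plateau; branches appear with a configured
  probability and receive their first focus 3 frames (30 min) later;
  stalls are permanent; profiles are Gaussian peaks (σ 0.15 µm,
  amplitude 100) on Gaussian noise at 0.065 µm pixels.  No lysis, no
  2D geometry, no intensity bleaching.
* **ChIP**: genome with per-base AT probability 1−gc plus `site_at_boost`
  inside non-overlapping sites; per-sample counts for each site and
  each 1-kb background tile are Gamma–Poisson with shared per-block
  gamma multipliers, so windowed counts inherit the NB dispersion under
  thinning (windows spanning block boundaries mix multipliers — a mild
  dilution); site fragments centre uniformly in the site, background
  fragments uniformly in the tile; fragment length fixed (200 bp),
  strand random.  Consequence of the block design: window-level tests
  within a block are positively correlated, so null calibration pools
  the rejection rate over independent simulations.  No sequencing
  errors, no mappability structure, no input-library model.
* **Growth**: the exact log-logistic mean plus i.i.d. Gaussian noise
  (σ 0.02 OD) on a quarter-hour grid over 48 h, five replicates.

Passing recovery tests on these generators demonstrates correctness of
the estimators under their stated models — not robustness to the many
properties of real data the generators omit (aberrations, drift,
segmentation errors, compositional bias, heteroscedastic OD noise).

## Validation problem sizes

Recovery studies run at: ≥50 000 tracked steps across 5 seeds
(diffusion mixture, tolerances 10% on D and ±0.03 on weights); ~18–30 k
molecules at sparse activation for mobility classes (±0.05 on the
confined fraction); 100 hyphae at SNR 8 (recall ≥0.95, FP ≤5%); 2000
null windows × 20 seeds and 20 sites at 8-fold enrichment for the
binding pipeline (type-I 3–7%, sensitivity ≥90%, FDP within the
binomial envelope of FDR 0.05); 200 replicate growth experiments (ED50
bias <2%, ≥90% coverage of ±2 SE).  These sizes make every recovery
check statistically meaningful while keeping the full suite to a few
minutes on one CPU.
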