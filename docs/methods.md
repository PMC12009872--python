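# Methods

## Overview

`facemms` turns per-frame facial landmark tables (the OpenFace dialect:
68 tracked points, 18 binary action-unit presence columns, 17 continuous
intensity columns, nominally 30 Hz for 5 s) into stochastic signatures of
facial micro-movement and distribution-level similarity structure. The
processing chain is:

1. **Per-frame normalization.** Each frame's 68 coordinates are z-scored
   per axis, `zx = (x − μx)/σx`, `zy = (y − μy)/σy`, with the population
   standard deviation (n = 68). This removes translation and the
   subject's distance to the camera; it does not correct head rotation or
   lens distortion. The whole pipeline then runs in normalized
   coordinate units per second.
2. **Trigeminal parcellation.** The grid splits into V1 (ophthalmic:
   indices 17–30 ∪ 36–47, 26 points), V2 (maxillary: 31–35 ∪ 48–54 ∪
   60–64, 17 points), V3 (mandibular: 0–16 ∪ 55–59 ∪ 65–67, 25 points).
   Landmark 33, the nose tip, is maxillary and sits in V2; this is the
   unique assignment under which the region sizes 26/17/25 and the glued
   totals 3,900/2,550/3,750 at F = 150 are all simultaneously consistent.
3. **Smoothing and differentiation.** Each coordinate trajectory is
   interpolated with a cubic spline (not-a-knot ends — interpolation, not
   penalized smoothing, so no free smoothing parameter) and the spline is
   differentiated analytically. Speed `√(żx² + ży²)` is evaluated at the
   original frame times, so each landmark contributes exactly F samples.
4. **Gluing and peaks.** Within a region, per-landmark speed segments are
   concatenated in ascending landmark order. Strict interior local
   maxima are the speed peaks (plateaus count once, at their first
   index; endpoints never count). Gluing order is immaterial for the
   amplitude statistics up to segment-boundary effects, and a permuted
   order reproduces the fitted signature within fit tolerance.
5. **Micro-movement spikes.** The Gamma family is fitted by maximum
   likelihood to the speed-peak amplitudes, giving the empirical Gamma
   mean Γμ = a·b. Absolute deviations |s − Γμ| of the full glued series
   are peak-extracted, and each deviation peak P is standardized by its
   nearest flanking local minima, `spike = P / (P + (m_left + m_right)/2)`,
   which lies in (0, 1]. Boundary peaks with a single flanking minimum
   use that one; flanking minima of exactly 0 push the spike to its
   upper bound 1. A boundary sample counts as a minimum when it is ≤ its
   single neighbour, so flat descents into an endpoint still provide a
   flank.
6. **Stochastic signature.** A second Gamma MLE on the MMS spike values
   yields the signature (shape a, scale b) with the derived quantities
   mean a·b, noise-to-signal ratio NSR = sd/mean = b, and skewness
   2/√a. Per participant, the three region NSRs and skewnesses form
   vectors whose Euclidean norms span the scalar parameter plane.
7. **Similarity and subtypes.** Pairwise 1-D Earth Mover's Distances
   (first-order Wasserstein, equal weight per sample; computed as the
   integrated |ΔCDF|) between MMS spike distributions over
   (participant, region) keys feed agglomerative hierarchical clustering
   with average linkage on the precomputed distances; the dendrogram is
   cut into the requested number of subtype leaves and each leaf reports
   its group composition in percent.
8. **Action units.** Presence is the modal full-frame 18-bit pattern
   (ties to the earliest frame). Pattern switching is measured with the
   edit distance of consecutive frame patterns, which for equal-length
   binary strings is the Hamming distance: per-AU flip rate in [0, 1]
   and whole-face mean Hamming distance in [0, 18]. Intensities at or
   above 0.001 (inclusive) are pooled per group; Freedman–Diaconis bins
   summarize the pools.

## Gamma fitting

The two-parameter MLE solves the profile-likelihood shape equation
`log a − ψ(a) = log(mean) − mean(log)`, bracketed around the standard
closed-form starting point and solved with Brent's method (xtol 1e-12);
the scale follows as b = mean/a. 95% confidence intervals are asymptotic
normal intervals from the inverse observed Fisher information
`n · [[ψ′(a), 1/b], [1/b, a/b²]]`. Fits require at least 30 strictly
positive samples with non-zero variance; fitting speed peaks tolerates up
to 5% non-positive amplitudes (excluded), more is a data-quality error.
The floor of 30 is where the asymptotic intervals stop being meaningful;
the nominal recording (150 frames × ≥17 landmarks) yields on the order
of a thousand peaks per region, far above it.

## Statistical comparisons

Group contrasts use the two-sided Wilcoxon rank-sum (Mann–Whitney U)
test. Cohort-level runs test participant-level NSR scalars per
(group, task, region); spike-level pooling is available by calling
`pairwise_ranksum` with that grouping. No multiplicity correction is
applied by default; Benjamini–Hochberg is available behind a flag.

## Synthetic cohort

The generator emulates 5-s, 30-Hz, 68-landmark recordings. Each
landmark performs a random walk around a schematic face template: step
lengths are i.i.d. Gamma(a, b) draws per region, directions uniform on
the circle. Because consecutive positions differ by exactly one step,
the frame-to-frame speed the pipeline recovers carries the injected
amplitude law (an earlier design using independent per-frame jitter does
not have this property: spline differentiation mixes neighbouring draws
and destroys the regime). Defaults define the study conditions:

| group          | V1, V2       | V3           | interpretation            |
|----------------|--------------|--------------|---------------------------|
| TD             | Γ(8, 0.1)    | Γ(8, 0.1)    | concentrated, low noise   |
| ASD-LS         | Γ(3, 0.4)    | Γ(3, 0.4)    | intermediate              |
| ASD-HS         | Γ(1.5, 0.8)  | Γ(1.5, 0.8)  | noisy, heavy-tailed       |
| ASD-HS-apraxia | Γ(1.5, 0.8)  | Γ(1.5, 1.6)  | mandibular scale doubled  |

Action units are two-state Markov chains per AU (stationary presence
probability 0.3 everywhere; flip propensity 0.05 for TD, 0.10/0.15 for
the ASD profiles, reflecting less stable patterns) with intensities
drawn from scaled Beta distributions on [0, 5] (TD Beta(2,5): low,
peaked; ASD Beta(2,2): flatter). Cohort generation derives each
recording's seed from the master seed through a `SeedSequence` over
(master, group index, participant, task index), so any recording can be
regenerated in isolation.

What the generator does *not* emulate: temporal autocorrelation of real
muscle dynamics (a correlation knob is deliberately absent by default),
head pose, camera and lens effects, OpenFace tracking failures, or
anatomically realistic AU co-activation. Passing recovery tests
therefore demonstrates that the estimator chain is consistent — injected
amplitude regimes survive smoothing, differentiation, gluing, and
standardization — not that real ASD/TD cohorts separate.

## Scale invariance and where regimes are audited

MMS standardization divides each deviation peak by a local amplitude, so
the spike values are exactly invariant to a global rescaling of the
speed series (checked by property test at ×0.1 and ×10). This has a
consequence for recovery audits: the apraxia profile differs from ASD-HS
only by the V3 Gamma *scale* (Γ(1.5, 1.6) = 2 · Γ(1.5, 0.8)), and a
scale-only regime is invisible to the MMS signature by construction.
The recovery experiment therefore audits scale-sensitive regimes at the
speed-peak Gamma fit (the fit behind Γμ, which retains units), and
shape-driven group orderings (TD vs ASD NSR and skewness) at the MMS
signatures. Both fits are first-class pipeline outputs.

## Numerical and policy choices

- Frames with tracking `success = 0` or `confidence < 0.75` are linearly
  interpolated from neighbours when they are under 10% of the recording,
  otherwise the recording is rejected: 5-s clips cannot absorb large
  gaps, and interpolation of a short run biases speed less than dropping
  frames (which would corrupt the spline's time base).
- Tables are comma-delimited UTF-8 with one header row; floats print
  with 12 significant digits so that write→read round-trips within 1e-9
  relative (9 digits falls just short of that near mantissa 1.0).
- EMD matrix normalization divides by the maximum off-diagonal entry,
  per matrix.
- Average linkage is used on the precomputed EMD matrix because it is
  well defined for arbitrary (non-Euclidean) dissimilarities and is less
  chain-prone than single linkage; the cut uses `maxclust` at the
  requested subtype count.
- Ties in the modal AU pattern go to the pattern whose first occurrence
  is earliest in time; plateau peaks take their first index.

## Problem sizes

Recovery and clustering checks run on cohorts of 10 participants per
group, resting task, 20 seeded replicates — large enough that group
medians are stable (orderings reproduce in 20/20 replicates; the
step-length refits recover injected parameters to ~1.5% median relative
error) while a full verification run completes in a couple of minutes on
one core.

## Known limitations

- The MMS signature compresses amplitude information by design; regimes
  that differ only in scale must be read from the speed-peak fit (see
  above).
- Asymptotic Fisher CIs undercover slightly for shape at small n; the
  coverage test pins ≥ 90% empirical coverage at n = 1000, not the
  nominal 95% at all n.
- The spline is an interpolant: measurement noise in real landmark
  tracks propagates into speed. With synthetic data there is no tracker
  noise; with real OpenFace output, high-frequency jitter inflates speed
  amplitudes uniformly — the MMS standardization removes the uniform
  part but not frequency-dependent effects.
- `fcluster(maxclust=k)` can return fewer than k leaves on degenerate
  distance matrices (exact ties); compositions are reported for the
  leaves actually formed.
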