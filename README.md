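# facemms

Stochastic signatures of facial micro-movement from 68-point landmark
trajectories.

Brief face videos, once passed through a landmark tracker such as
OpenFace, yield per-frame tables of 68 grid coordinates and facial
action units (AUs). `facemms` analyzes the *variability* of the motion
rather than its gross trajectory: it extracts **micro-movement spikes
(MMS)** — standardized peaks of the deviation of landmark speed from its
empirically fitted Gamma mean — and characterizes each face region's
spike distribution by a maximum-likelihood **Gamma signature**
(shape *a*, scale *b*), with derived mean Γμ = a·b, noise-to-signal
ratio NSR = Γσ/Γμ = b, and skewness 2/√a. This is aimed at
computational behavioral phenotyping: typically-developing motion tends
toward high-shape/low-scale (predictive, low-noise) signatures, while
autistic motor patterns sit closer to the memoryless exponential corner
(a → 1) with heavier tails.

The pipeline, per recording (nominally 5 s at 30 Hz, F ≈ 150 frames):

1. z-score each frame's coordinates per axis (camera-distance invariance);
2. parcel the grid into trigeminal regions V1/V2/V3 (26/17/25 points:
   ophthalmic, maxillary, mandibular);
3. spline-interpolate trajectories, differentiate analytically, and
   evaluate speed at the frame times;
4. glue each region's speed segments (V1 → 3,900 samples at F = 150),
   extract strict local maxima, and fit their amplitudes with a Gamma
   MLE to get Γμ;
5. standardize deviation peaks into MMS spikes
   `P / (P + (m_left + m_right)/2) ∈ (0, 1]` and fit the Gamma signature;
6. compare participants by 1-D Earth Mover's Distance between MMS
   distributions, cluster the matrix with an average-linkage tree cut
   into *k* subtypes, and report per-leaf group composition;
7. profile AUs: modal presence pattern, Hamming switching rate, pooled
   intensities ≥ 0.001.

A synthetic-cohort generator (`facemms.synthetic_cohort`) emulates
recordings whose per-region speed fluctuations follow group-specific
Gamma laws, enabling end-to-end parameter-recovery validation without
any video data. See `docs/methods.md` for models, assumptions, and
design choices.

## Worked example

```python
from facemms import (
    default_profiles, generate_recording, analyze_recording,
)

rec = generate_recording(default_profiles()["TD"], "resting", seed=1)
an = analyze_recording(rec)
print(an.speed_peak_counts)
for region, sig in an.signatures.items():
    print(region, f"a={sig.shape:.1f} b={sig.nsr:.4f} skew={sig.skewness:.3f}")
```

prints

```
{'V1': 1328, 'V2': 867, 'V3': 1263}
V1 a=58.0 b=0.0134 skew=0.263
V2 a=62.5 b=0.0124 skew=0.253
V3 a=59.3 b=0.0131 skew=0.260
```

i.e. each region of the 5-second recording yields on the order of a
thousand speed peaks (far above the ~100 needed for a stable fit), and
the typically-developing profile produces tight, near-symmetric MMS
distributions (high shape ⇒ low skewness ≈ 0.26, NSR ≈ 0.013). The
same call on the `"ASD-HS"` profile gives systematically higher NSR and
skewness, and the scale-carrying speed-peak fit
(`an.speed_peak_fits[region].nsr`) separates the regimes by a factor of
about four (≈ 0.055 vs ≈ 0.22).

The same flow from a shell:

```
facemms simulate --out cohort/ --seed 0 --n-td 10 --n-asd 10
facemms analyze  --input cohort/ --out results/ --k 6
```

or as a scripted narrative, `analysis/01_simulate.py`,
`analysis/02_analyze.py`, `analysis/03_recovery.py` (tables under
`results/`). On the default synthetic cohort the k = 6 tree cut yields
leaves that are 100% TD or 100% ASD, and the recovery audit refits the
injected step-length Gamma parameters to ~1.5% median relative error.

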