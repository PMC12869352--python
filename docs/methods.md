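# Methods

This note documents the models and numerical choices behind `sonoscape`,
what the synthetic data generator does and does not emulate, and the known
limitations of both.

## The ΣPMN index

A minute of mono audio at 48 kHz is framed into 5625 non-overlapping
512-sample segments, Hann-windowed and Fourier-transformed; the Nyquist bin
is dropped, leaving 256 bands of 93.75 Hz spanning 0–24 kHz. Magnitudes are
converted to dB as 20·log10(max(|X|, 10^(−120/20))), i.e. with a −120 dB
floor. The non-overlapping hop is deliberate: it is the only framing that
yields exactly 5625 frames (~0.01067 s each) per minute.

Per band, the background noise BGNsp is the mode of the minute's dB values.
The mode is estimated on a histogram of 1-dB bins anchored at the band's
observed minimum: the maximal 5-bin moving count window is located first
(integer sums, ties toward the lowest bin), and the mode is the bin with
the highest raw count inside that window (ties again toward the lowest
bin), reported at its lower edge. Anchoring at the minimum makes the
estimator exactly equivariant under constant dB shifts; the window/raw
two-step keeps it stable on noisy histograms without the downward bias a
plain smoothed argmax has on sparse ones. A constant band returns its own
value.

De-noising subtracts BGNsp per band and clips negative residuals at zero
(configurable: an unclipped variant retains signed deviations, but summed
signed deviations from the mode can cancel, which contradicts the
power-above-background semantics of the index — clipping is the default).
Residuals are then smoothed along time with a centered 3-frame moving
average with replicated edges; smoothing can be disabled, which preserves
exact toy arithmetic. ΣPMN(b) is the frame sum of the residual, PMNsp(b)
its maximum. Consequences, all tested: ΣPMN ≥ PMNsp ≥ 0; ΣPMN is zero for
digital silence and any band-stationary signal; it is invariant under
constant dB offsets; and injecting a transient above the mode strictly
increases it.

Band aggregation sums ΣPMN over bands whose centers (at (b + ½)·93.75 Hz)
fall in a half-open interval [lo, hi), so adjacent ranges partition the
bands exactly (the eight 1-kHz aggregates between 1 and 9 kHz sum to the
1–9 kHz aggregate). Note that a tone between two DFT bins peaks in the
*nearest* bin, which may be one above the floor-division band of its
frequency. Temporal aggregation averages matching minutes across days, and
optionally into the 144 daily 10-min bins.

Standard exclusions: the first and last 30 minutes of each deployment
(fieldwork noise); three minute-of-day labels (385, 386, 1080, interpreted
as 1-based labels — internally minutes 384, 385, 1079 — with a
configuration switch for the 0-based reading); and, for similarity
analyses, bands whose centers lie below 1 kHz, where anthropophony
dominates and overlaps wild-mammal sound.

## Synthetic soundscapes

The generator emulates a four-archetype study design — reference forest,
natural regeneration, plantation, pasture — with per-site covariates and
multi-day continuous recording. Its fast mode emits per-minute dB
spectrograms directly; its audio mode renders 60-s waveforms with the same
component structure. Components:

* **Noise floor** — per site, a constant sensor floor (−85 dB ± a uniform
  per-site offset). Within a minute the floor is constant over frames.
* **Chorus** — transient pulses in the bird band (1.26–8 kHz), a
  configurable fraction (0.25) of frames raised by ~12 dB, scaled by a
  raised-cosine diel envelope with compact dawn (05:30 ± 50 min) and dusk
  (17:50 ± 50 min) windows, by the land-use effect size, and by a small
  hardware gain (×1.05 for v1.2 recorders).
* **Ambient biophony** — class-independent pulses across 1.1–9 kHz all day
  (6 dB, 6% of frames), with ±15% per-site intensity variation; this is the
  null-minute "statistical noise" the selection stage must reject.
* **Stationary components** — a constant insect drone band (4.83–12.32
  kHz, +8 dB), whole-spectrum rain (+10 dB) on random minutes, low-band
  wind; all flat over frames, hence absorbed into BGNsp by construction.
* **Anthropophony** — pulses below 1 kHz scaled by the site's human
  modification.

Default effect sizes are 1.0 / 0.85 / 0.7 / 0.25 (forest / regeneration /
plantation / pasture). The ladder is deliberately non-linear: plantations
sit closer to reference forests than to pastures in index space, so the
generated world reproduces the qualitative field finding that both
restoration classes skew toward forest, with regeneration closer than
plantation. The ground-truth effect schedule — used to score the selection
stage — is the set of 10-min bins whose mean chorus envelope is at least
0.5 (the land-use contrast at half strength or more).

Covariates: precipitation, EVI and elevation are uniform over the same
plausible ranges for every class; only canopy height and human modification
carry class shifts. Hardware is assigned per site (60/40 between v1.1 and
v1.2). Everything is a pure function of (config, seed); per-purpose rng
substreams keyed on (seed, tag, site, day[, minute]) make each site-day
reproducible in isolation.

**What fast mode does not emulate.** Real backgrounds fluctuate frame to
frame (wind gusts, rain intensity, electronics); the generator's constant
within-minute floor idealizes this, which is what makes the index
identities exact rather than statistical. Real choruses are species
mixtures with spectrotemporal structure, not amplitude-modulated pulse
fields; propagation, distance attenuation and site geometry are absent.
Passing tests therefore demonstrate that the pipeline recovers structure
it is pointed at, not that it is robust to every field nuisance.

Fast-mode spectrograms default to 48 frames per minute (1.25 s effective
frames); frame sums are rescaled by 5625/48 in the pipeline so ΣPMN is
reported in the dB·frame units of a full-resolution minute, keeping the
similarity constant k meaningful in both modes. The choice of 48 frames
keeps a full multi-site study at desk scale while leaving the per-band mode
estimate well determined (≥70% of frames at the floor level).

## Acoustic-space selection

Per minute of day, the response is each site's across-day mean ΣPMN
aggregated over 1–9 kHz (the frequency range for this stage is not uniquely
determined by the analysis design; full-spectrum aggregation is available
as a switch). All 128 subsets of the seven predictors are fitted as linear
mixed models with a random intercept for hardware, by maximum likelihood —
ML, not REML, because AIC comparisons across fixed-effect structures are
invalid under REML. Land use enters as a single all-or-nothing block of
three indicator columns; continuous predictors are standardized for
conditioning (AIC and subset choice are invariant to this).

The fitting engine profiles the likelihood over the variance ratio
λ = τ²/σ² on a fixed grid (0 plus 57 log-spaced points in [10⁻⁴, 10³]);
given λ, fixed effects and σ² are closed-form, and the whitening of the
response and full design is shared by all 128 candidates, which then cost
one small normal-equation solve each. The λ = 0 boundary (zero hardware
variance) is an admissible, frequently selected value; singular fits are
accepted rather than discarded, since discarding them with only two
hardware levels would bias selection. AIC = −2ℓ + 2(p + 2), counting the
two variance parameters; AICc is available as a switch. The engine is
validated against the closed-form multivariate-normal likelihood (exact)
and against statsmodels' MixedLM subset selection (agreement on test
problems, likelihood within the grid's resolution).

A minute retains land use iff the block appears in the minimum-AIC subset;
a 10-min bin is retained iff strictly more than half (threshold
configurable) of its valid minutes retain it — 6 of 10 qualifies, 5 of 10
does not. Under a pure-noise response, AIC over-selection retains land use
in well under half of minutes (tested by simulation), so null bins are
rejected; note that because the same sites underlie every minute, per-site
level differences make minute-wise selections correlated, and with very few
sites per class (≲3) chance alignment of site effects with class can
inflate retention — the standard synthetic study uses 10 sites per class.

The boosted validation model (xgboost, 300 trees, depth 3, learning rate
0.1, single thread for determinism) regresses 10-min aggregated ΣPMN on the
seven predictors with time as a bin index and land use as four binary
indicators; per-feature importance is the mean absolute TreeSHAP
attribution, with the four indicators summed into one undirected land-use
importance.

## Similarity

Distributions entering the Wasserstein computation are per-site per-minute
values (cross-day means), pooled over the bin's minutes and the class's
sites; pooling 10-min site means instead is available as a switch. The
order-1 distance is computed by the quantile-integral formulation (exact
and deterministic for unequal sample sizes; no subsampling). Similarity is
y = e^(−kx), k = 0.00001 by default. Skews are arithmetic means of
per-intersection similarity ratios (geometric/log-ratio averaging is a
switch). The Friedman test treats 10-min bins as blocks and the per-bin
mean distances of the three to-forest comparisons as treatments; the
degenerate all-identical table returns statistic 0 by convention. Wilcoxon
signed-rank post hocs are Bonferroni-corrected within the set of pairs
tested in one analysis mode, the narrowest defensible family; all-zero
difference vectors return p = 1 with a warning.

## Numerical and degenerate-input conventions

* dB floor −120; magnitudes clamped before the log.
* Quantiles (taxon ranges, biophonic range) interpolate linearly between
  order statistics; the range rule is [q₀.₀₅ of f_min, q₀.₉₅ of f_max] for
  90% coverage, the simplest rule that brackets 90% of call extents
  (midpoint quantiles are available as an option).
* Empty aggregation intervals return 0 with a warning; empty groups are
  omitted; empty class samples skip the intersection with a log entry;
  annotation rows with inverted frequencies are dropped with a logged
  count.
* A constant response makes the boosted importance model meaningless and
  raises; a minute where every mixed-model candidate fails numerically is
  marked invalid and excluded from bin retention.
* Pipeline outputs carry a config hash in every table header; a rerun with
  the same config and seed is byte-identical.

## Problem sizes

The standard synthetic study is 4 classes × 10 sites × 2 days in fast mode
(115,200 site-minutes; ~2 min to index, ~3 min for the 1437 × 128 mixed-model
fits on one CPU). The demo configuration used in the pipeline tests is 3
sites per class with the selection stage driven by a supplied bin list.

## Known limitations

* The constant-floor fast mode understates background nonstationarity;
  mode estimation on real recordings will carry residual noise into ΣPMN.
* The exact smoothing used by upstream background-removal implementations
  is not standardized; the 3-frame default here is a documented choice.
* With two hardware levels the random-intercept variance is weakly
  identified; λ estimates are noisy (selection, which compares fixed
  effects at matched random structure, is insensitive to this).
* Wasserstein distances are computed per intersection independently; no
  joint time × frequency transport is attempted.
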