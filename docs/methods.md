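# Methods

`subplate` implements two analysis arms for developmental cortical
connectivity questions, plus the synthetic generators needed to validate
them end to end: (1) burst-coincidence and directionality analysis of
multi-electrode multi-unit activity (MUA) against surrogate nulls, and
(2) normalized-depth laminar assignment and enrichment statistics of
retrogradely labeled neurons. This note records the models, the parameters
that matter, the numerical choices, and the limits of what the synthetic
validation shows.

## Spike trains and MUA extraction

A `SpikeTrain` is a strictly increasing array of spike times in seconds with
a region label (S1Bf, M1, S2), a layer label (SP or L5/6), and a recording
span. MUA extraction from raw extracellular traces follows the standard
recipe for neonatal slice recordings sampled at 20 kHz:

- **Band-pass 200–5,000 Hz.** Realized as a 4th-order Butterworth applied
  forward-backward (`scipy.signal.sosfiltfilt`), so the pass band is flat to
  within a few percent and no phase shift biases spike times. Only the band
  edges are externally prescribed; filter family and order are package
  choices.
- **Noise floor.** Sample SD of a user-designated spike-free baseline
  interval (minimum 100 ms). A kurtosis far from the Gaussian value triggers
  a warning that the baseline may contain spikes.
- **Threshold detection.** One spike per negative-going crossing of −k·SD
  (default k = 5), timed at the first sample beyond threshold, with a 1 ms
  dead time. Polarity, k and dead time are configurable; negative polarity
  is the default because extracellular spikes are predominantly negative.

## Burst analysis

A **burst** is a maximal run of ≥ 3 successive spikes with every
inter-spike interval ≤ 300 ms (the boundary value is inside the burst).
Burst statistics are occurrence (bursts per minute), mean duration, mean
spike count, and mean intra-burst frequency, defined per burst as
(n_spikes − 1)/duration — the only frequency definition consistent with a
count of intervals over a duration.

**Coincidence.** Two bursts on different electrodes coincide when at least
one spike of either burst falls inside the other burst's [onset, offset]
interval (the rule is applied symmetrically). Bursts are paired one-to-one:
bursts of the first channel are visited in onset order and greedily matched
to the earliest-onset unmatched coincident partner. The **coincidence
ratio** divides the number of coincident pairs by the burst count of the
less active electrode, so it is 1 for perfectly co-active channels and for
a channel paired with itself. **Directionality** compares the onsets (first
spikes) of coinciding bursts; exact ties are a separate category, never
assigned arbitrarily, and lead + lag + tie = 1.

**Surrogate null and significance.** The null hypothesis is that burst
timing on the two electrodes is unrelated. Surrogates displace spikes by
U(−750 ms, +750 ms) — roughly one burst duration — clip to the span,
re-detect bursts, and recompute the ratio; the observed ratio is flagged
significant when it exceeds the empirical 99th percentile of the surrogate
ratios. Two granularities are provided:

- `unit="burst"` (default): every detected burst is displaced rigidly by one
  common draw; isolated spikes move independently. This preserves the
  train's burst census (count, sizes, durations) while destroying
  cross-channel alignment, so under independence the surrogate ratio is
  exchangeable with the observed one. Measured false-positive rate at the
  99th-percentile threshold: 0/300 independent pairs (conservative — the
  ratio is discrete, and occasional surrogate burst mergers raise the
  threshold).
- `unit="spike"`: every spike moves independently. This is the more literal
  jitter but it splits bursts (a jittered train typically has *more*,
  sparser bursts), which changes the ratio's denominator and inflates the
  false-positive rate an order of magnitude above nominal. It is retained
  for comparison, not as the default.

By default the jittered train is the one with the lower burst count (the
ratio's denominator train); jittering the other or both is configurable.

## Cross-correlograms and joint-ISI dithering

CCGs histogram target-minus-reference spike time differences in 1 ms bins
centered on integer lags over ±50 ms; positive lags mean the target fires
after the reference. Self-pairs at zero lag appear only in autocorrelation
diagnostics (a train against itself); distinct channels produce none.

The per-bin null uses **joint-ISI dithering** of the target train: each
interior spike moves within the open interval between its original
neighbours, capped at ±25 ms, with the landing point drawn proportional to
the kernel-smoothed empirical joint-ISI density along the anti-diagonal
l + r = const (2-D Gaussian kernel, 5 ms bandwidth; uniform fallback when
fewer than 50 ISI pairs exist). The sum of each spike's two adjacent ISIs,
measured against its original neighbours, is conserved exactly; first and
last spikes stay fixed and the spike count is preserved. Displaced spikes
may swap order with a neighbour and are re-sorted.

Two numerical choices matter here:

- **Dither window.** Restricting each spike to half the gap toward each
  neighbour (which would avoid re-sorting) leaves spikes in dense stretches
  nearly frozen and narrows the surrogate null: per-bin exceedance measured
  2.1% instead of ~1%. The full neighbour window restores calibration
  (1.2–1.5% with 200 surrogates, consistent with the ~1.2% expected from a
  finite surrogate set; band 1% ± 3 SE).
- **Kernel bandwidth.** The 5 ms default assumes the ISI distribution is
  broad relative to the kernel. For highly regular trains (ISI spread
  ≲ bandwidth) the density estimate is biased and the surrogate ISI
  distribution drifts measurably; reduce `smoothing` in that regime.

Significance is per bin: the threshold is the empirical 99th percentile of
the surrogate CCGs, and the summary reports whether the above-threshold
bins concentrate inside the 5–15 ms monosynaptic analysis window (one-sided
binomial test of the in-window count against the window's share of bins).

## Synthetic electrophysiology

The generator reproduces the kind of activity the analyses target, with
ground truth attached:

- Burst onsets are a homogeneous Poisson process (default 1.5 min⁻¹, the
  middle of the observed 0.9–2.0 min⁻¹ range), thinned so a new burst may
  not begin within 300 ms of the previous burst's offset — otherwise the
  detector would merge them and ground truth would not match any detector
  output. The thinning costs ~2–5% of nominal occurrence, well inside the
  sampling error of a 30-minute recording.
- Spikes per burst: 3 + negative binomial (default mean 12, within the
  observed 8–30 range). Intra-burst ISIs: gamma with mean 50 ms (≈ 20 Hz
  intra-burst rate, within the observed 15–28 Hz), resampled if a draw
  reaches the 300 ms break threshold so a generated burst is always
  detectable as one burst.
- Isolated background spikes are an independent Poisson process (default
  0.1 s⁻¹) and may fall inside bursts; ground-truth membership is recorded
  regardless.
- Directed coupling: each source burst triggers, with probability
  `coupling_prob`, an induced burst in the target at onset + lag (default
  lag normal, mean 150 ms, SD 20 ms). Induced bursts use the target's burst
  shape; couplings act one pass from each source's own bursts, so chains do
  not cascade implicitly.
- One global seed expands into per-component substreams
  (`numpy.random.SeedSequence.spawn`), so identical seeds give bit-identical
  outputs and modules can be re-run independently.

What this does **not** emulate: non-stationary excitability drifts,
electrode cross-talk, spike-sorting artifacts, or oscillatory (spindle-like)
structure — the analyses under test deliberately use only MUA timing, so
passing tests show the estimators are correct for burst-structured point
processes, not that real recordings meet those assumptions.

## Anatomy: depth normalization and laminar statistics

Boundary point clouds (pial and lower-subplate) are fitted with least-squares
quadratics z = c₀ + c₁x + c₂y + c₃x² + c₄xy + c₅y², with coordinates
centered internally for conditioning and coefficients reported in raw
space. z increases with depth. A cell's **normalized depth** is its
Euclidean distance to the pial surface divided by the local cortical
thickness, measured along the ray from the cell's nearest pial point
through the cell to the lower-subplate surface (the ray-quadratic
intersection is solved in closed form). Depth 0 is the pia, 1 the
subplate/white-matter boundary; values outside [0, 1] are clipped, with a
warning when the excursion exceeds 0.01. Nearest points are found by a
vectorized 2-D Newton iteration with a dense-grid fallback. For shallow
curvature the along-ray and vertical thickness definitions agree to well
under 1% of depth, which the generator round-trip confirms (max error
~7 × 10⁻⁴ at zero surface noise).

Layers are assigned by cumulative relative thicknesses (renormalized to sum
to 1), half-open bins from the pia down with the deepest bin closed at 1; a
depth exactly on a boundary belongs to the deeper layer. The bundled S2
thickness row contains an L6 value (0.867) that makes the row sum to 1.602
while all others sum to ~1.0; the default scheme uses the corrected 0.267
(row sum 1.002) and the verbatim row remains loadable.

**Counting and enrichment.** Per-layer percentages are floored integers
(the convention of the published tallies, e.g. 41/111 → 36%). Enrichment of
backlabeled cells against expected neuron proportions uses a chi-square
goodness of fit over the included layers — the cell-sparse marginal zone is
excluded and expected proportions renormalized — followed by per-layer
exact two-sided binomial tests (minimum-likelihood two-sided convention, as
in `scipy.stats.binomtest`). No multiple-testing correction is applied by
default, matching how such per-layer follow-ups are conventionally
reported; a Bonferroni option exists. Expected counts below 1 trigger a
warning and a fallback flag rather than a silent test.

## Group-level reporting

Pairwise results aggregate into region+layer matrices of mean ± SEM with
the pooled coincident-burst count; SEM is computed across per-slice values
(a single slice gets SEM 0 by convention) while the pooled n is reported
separately, because the two conventions answer different questions.
Paired comparisons use the Wilcoxon signed-rank test: exact null
distribution up to 25 non-zero differences, normal approximation with
continuity correction above, p = 1 when all differences are zero.
Directionality reports test per-pair lead ratios against the 0.5 chance
level with significance stars at 0.05 (*) and 0.01 (**).

## Problem sizes used in validation

The test suite and the acceptance script regenerate everything from seeds:
300 independent electrode pairs with 200 surrogates each for the
coincidence null (the percentile threshold stabilizes well below 1,000
surrogates, which remain the analysis default), 12 Poisson pairs × 200
dithered surrogates for the per-bin CCG null, 20 coupled pairs for
directionality recovery, 30-minute single-channel recordings for parameter
recovery, 2,000-cell volumes for geometry and layer-assignment accuracy,
and 1,000/200 multinomial replicates for enrichment calibration/power.

## Known limitations

- The coincidence-significance default (rigid-burst jitter) is mildly
  conservative; exact calibration at 1% would need a continuity correction
  for the discrete ratio.
- Joint-ISI dithering assumes the smoothing bandwidth is small relative to
  the ISI spread (see above).
- Depth normalization assumes the subplate boundary is reachable along the
  nearest-pial-point ray; for violently folded surfaces (not the regime of
  a 350 μm flattened volume) the ray may miss, and such cells are flagged
  invalid rather than guessed.
- The one-to-one greedy burst matching is order-dependent in principle;
  for physiological burst rates ties between candidate partners are rare
  and the earliest-onset rule makes the result deterministic.
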