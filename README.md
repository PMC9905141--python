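# subplate

Burst-coincidence connectivity and laminar-depth statistics for the
neonatal cortex.

In newborn rodents the subplate (SP) — a transient layer beneath the
developing cortical plate — acts as a hub that relays and synchronizes
activity between cortical areas before mature circuits exist. Two kinds of
evidence speak to that role, and this package implements the quantitative
pipeline for both:

1. **Electrophysiology.** Multi-unit activity (MUA) on multi-electrode
   arrays in slices is bursty rather than continuously active. Whether two
   electrodes (e.g. S1 barrel field SP vs motor cortex L5/6) are
   functionally coupled is asked at the burst level: a *burst* is a maximal
   run of ≥ 3 spikes with inter-spike intervals ≤ 300 ms; two bursts
   *coincide* when a spike of one falls inside the other's time span; the
   *coincidence ratio* is the number of coincident burst pairs divided by
   the burst count of the less active electrode. Whether coupling is
   directed is asked by comparing burst onsets (lead/lag ratios).
   Significance comes from surrogate data — spike trains jittered by
   ±750 ms (about one burst duration) with bursts re-detected per surrogate
   and the observed ratio compared to the 99th percentile of the surrogate
   ratios. Fine-timescale coupling is probed separately with spike
   cross-correlograms (1 ms bins, ±50 ms window, 5–15 ms monosynaptic
   analysis window) against joint-ISI-dithering surrogates that conserve
   each spike's adjacent inter-spike-interval sum.

2. **Anatomy.** Neurons retrogradely labeled by a tracer placed at the
   SP–L6 border are located in 3-D, and each cell's *normalized cortical
   depth* is its Euclidean distance to the pial surface divided by the
   local pial-to-subplate thickness (0 = pia, 1 = subplate/white-matter
   boundary), with both surfaces fitted as least-squares quadratics to
   manually drawn boundary points. Depths map to layers (MZ, CP, L5, L6,
   SP) via per-area relative-thickness schemes, and enrichment of labeled
   cells against expected neuron proportions is tested with a chi-square
   goodness of fit followed by per-layer exact binomial tests (marginal
   zone excluded).

Because raw recordings and confocal volumes of such studies are rarely
public, the package ships first-class synthetic generators — bursty spike
trains with known directional couplings, and cell clouds between analytic
cortical surfaces — so every estimator is validated against ground truth.
See `docs/methods.md` for the models and numerical choices.

## Worked example

```python
import subplate as sp

# a coupled SP -> L5/6 electrode pair, 20 min of bursty MUA
src = sp.BurstModel(burst_rate=2.0, recording_span=1200.0)
tgt = sp.BurstModel(burst_rate=1.2, recording_span=1200.0)
coupling = sp.CouplingSpec("sp_shank", "l56_shank", coupling_prob=0.5,
                           lag_dist=("norm", {"loc": 0.15, "scale": 0.02}))
sp_train, l56_train = sp.generate_coupled_ensemble(
    {"sp_shank": src, "l56_shank": tgt}, [coupling], seed=13,
    labels={"sp_shank": ("S1Bf", "SP"), "l56_shank": ("S1Bf", "L5/6")})

stats = sp.burst_stats(sp.detect_bursts(sp_train), sp_train.span)
result = sp.coincidence_significance(sp_train, l56_train, n_surrogates=200, seed=113)
```

Formatting the two result objects prints:

```
SP bursts: 40 (2.00 per min, mean duration 499 ms)
coincidence ratio 0.53 (surrogate 99th pct 0.51) -> significant: True
SP leads in 90% of coincident burst pairs
```

The SP channel bursts twice a minute; 53% of its bursts coincide with L5/6
bursts, more than the 99th percentile of the jitter-surrogate null (0.51),
so the coupling is called significant — and the SP burst starts first in
90% of coincident pairs, the expected signature of an SP → L5/6 drive with
a ~150 ms lag.

The anatomy arm on a synthetic S1Bf volume with labeling probability
doubled in L5 relative to its neuron share:

```python
scheme = sp.load_scheme("S1Bf")
cloud, pial_pts, sp_pts = sp.generate_cortical_volume(
    sp.VolumeSpec(area="S1Bf", n_neurons=2000), scheme, seed=9)
cloud = sp.sample_backlabeled(
    cloud, {"MZ": 0.0, "CP": 0.01, "L5": 0.06, "L6": 0.03, "SP": 0.03}, seed=10)
cells = sp.normalized_depths(cloud, sp.fit_surface(pial_pts),
                             sp.fit_surface(sp_pts), scheme)
res = sp.enrichment_test(sp.anatomy.count_layers(cells).to_dict(), scheme)
```

```
chi-square 24.0 (df 3), p = 2.5e-05
  CP: depleted, binomial p = 4.47e-06
  L5: enriched, binomial p = 0.000777
  L6: enriched, binomial p = 0.792
  SP: enriched, binomial p = 0.127
```

The laminar distribution of labeled cells deviates from the neuron-number
expectation (chi-square p ≈ 2.5 × 10⁻⁵); the per-layer follow-ups localize
the effect to depletion in CP and enrichment in L5 — exactly the labeling
probabilities the generator used.

A command-line interface wraps the same functions
(`subplate simulate-ephys | detect | bursts | coincidence | ccg | anatomy | run`);
`subplate run --outdir out --seed 1` executes the whole
simulate → detect → coincidence → anatomy pipeline and writes TSV/JSON
tables plus a manifest with parameter echo and output hashes.

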