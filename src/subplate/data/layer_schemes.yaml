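# Laminar schemes for the P0 mouse cortex: per-area relative layer thickness
# (from NeuN/DAPI-stained coronal sections) and expected proportions of all
# neurons per layer. Layer order runs from the pia downward.
#
# The verbatim S2 thickness row contains L6 = 0.867, which makes that row sum
# to 1.602 while every other row sums to ~1.0; the corrected variant uses
# 0.267 (row sum 1.002). The corrected variant is the default; the verbatim
# row remains loadable for exact reproduction of the published table.
layers: [MZ, CP, L5, L6, SP]
thickness:
  M1:   {MZ: 0.079, CP: 0.215, L5: 0.276, L6: 0.320, SP: 0.107}
  S1Bf: {MZ: 0.070, CP: 0.245, L5: 0.301, L6: 0.263, SP: 0.088}
  S2:   {MZ: 0.112, CP: 0.218, L5: 0.273, L6: 0.267, SP: 0.132}
thickness_verbatim:
  M1:   {MZ: 0.079, CP: 0.215, L5: 0.276, L6: 0.320, SP: 0.107}
  S1Bf: {MZ: 0.070, CP: 0.245, L5: 0.301, L6: 0.263, SP: 0.088}
  S2:   {MZ: 0.112, CP: 0.218, L5: 0.273, L6: 0.867, SP: 0.132}
neuron_proportions:
  M1:   {MZ: 0.06, CP: 0.29, L5: 0.24, L6: 0.34, SP: 0.07}
  S1Bf: {MZ: 0.06, CP: 0.33, L5: 0.24, L6: 0.31, SP: 0.06}
  S2:   {MZ: 0.08, CP: 0.32, L5: 0.22, L6: 0.30, SP: 0.09}
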