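# Out-of-Africa bottleneck, European deme, "duchen" slot.
# PLACEHOLDER PARAMETERS: the source publication's full parameter set is
# not transcribed here; only the bottleneck age (~19,000 years, ~10
# generations/year, N0 = 1e6) anchors the timing. Suitable for property
# and directional tests, not for reproducing published p-values.
name: duchen
placeholder: true
description: >
  European out-of-Africa bottleneck, bottleneck onset ~19 kya
  (0.0475 x 4N0 generations at N0 = 1e6, 10 gen/yr); severity and
  ancestral size are placeholders.
epochs:
  - [0.0, 1.0]
  - [0.0475, 0.03]
  - [0.0555, 1.5]
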