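# Out-of-Africa bottleneck, European deme, "werzner" slot.
# PLACEHOLDER PARAMETERS: only the bottleneck age (~13,000 years) is
# anchored; severity and ancestral size are placeholders. Suitable for
# property and directional tests only.
name: werzner
placeholder: true
description: >
  European out-of-Africa bottleneck, bottleneck onset ~13 kya
  (0.0325 x 4N0 generations at N0 = 1e6, 10 gen/yr); severity and
  ancestral size are placeholders.
epochs:
  - [0.0, 1.0]
  - [0.0325, 0.03]
  - [0.0405, 1.5]
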