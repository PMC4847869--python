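# Out-of-Africa bottleneck, European deme, "thornton-andolfatto" slot.
# PLACEHOLDER PARAMETERS: only the bottleneck age (~16,000 years) is
# anchored; severity and ancestral size are placeholders. Suitable for
# property and directional tests only.
name: thornton-andolfatto
placeholder: true
description: >
  European out-of-Africa bottleneck, bottleneck onset ~16 kya
  (0.04 x 4N0 generations at N0 = 1e6, 10 gen/yr); severity and
  ancestral size are placeholders.
epochs:
  - [0.0, 1.0]
  - [0.04, 0.03]
  - [0.048, 1.5]
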