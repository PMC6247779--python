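"""Run the molecular-phenotyping image pipeline on a synthetic phantom.

The phantom renders three soma populations in a ganglion-cell layer: high-
GABA starburst amacrine cells (5-10 mM), provisionally coupled γ+ ganglion
cells (0.3-0.6 mM, evidence of coupling to GABAergic amacrine cells), and
γ− ganglion cells. Pixel value is log-linear in concentration.
"""

import numpy as np

from retcouple import (
    CalibrationModel,
    cluster_theme_map,
    colocalization_rgb,
    count_objects,
    masked_histogram,
    segment_gaba_classes,
    separability,
    fig1_phantom_config,
    generate_cmp_phantom,
)

stack, truth, objects = generate_cmp_phantom(fig1_phantom_config(seed=7))
print(f"phantom: {len(objects)} somas, channels {sorted(stack.channels)}")

# theme map: joint k-means over (glutamate, GABA) signatures
theme = cluster_theme_map(stack, k=4, seed=0)
print(f"theme map k=4, per-cluster {theme.channel_order} signatures:\n"
      f"{theme.signatures.round(1)}")

# GABA-band segmentation: γ− (<0.1 mM) / γ+ GC (0.1-1) / amacrine (1-10)
model = CalibrationModel()
bands = segment_gaba_classes(stack.channels["γ"], model)
somas = count_objects(bands, target_label=1, min_area_px=20)
print(f"\nprovisional γ+ ganglion cells found: {len(somas)}")

# glutamate histograms: γ+ and γ− ganglion cells are indistinguishable
h_pos = masked_histogram(stack.channels["E"], truth == 2)
h_neg = masked_histogram(stack.channels["E"], truth == 3)
sep = separability(h_pos, h_neg)
print(f"glutamate histogram overlap γ+ vs γ− GC: {sep['overlap']:.2f} "
      f"(KS D = {sep['ks_D']:.2f})")

# colocalization display: GABA as yellow (R+G), glutamate as blue
rgb = colocalization_rgb(stack, "γE::yb")
print(f"γE::yb colocalization image shape {rgb.shape}")
# Reading: γ+ ganglion cells carry an intermediate GABA signal on top of a
# normal ganglion-cell glutamate signature — the phenotypic marker of
# heterocellular coupling.
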