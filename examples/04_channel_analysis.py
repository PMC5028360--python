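"""Inspect the channel-selection stage on one phantom.

Prints the per-channel histogram entropy, the Otsu threshold of the blue
channel, and the CIELAB decomposition ranges — the quantities behind the
choice of the blue channel for lesion/skin separation.
"""

import dermseg as ds

case = ds.generate_phantom(ds.PhantomSpec(seed=7))

ce = ds.channel_entropy(case.image)
names = ("red", "green", "blue")
for name, h in zip(names, ce.per_channel):
    print(f"{name:5s} entropy: {h:.3f} bits")
print(f"max-entropy channel: {names[ce.argmax_channel]}")

blue = ds.extract_channel(case.image, "blue")
res = ds.otsu(blue)
print(f"\nblue-channel Otsu threshold: level {res.threshold} "
      f"(objective {res.objective:.1f}, class weights {res.class_weights[0]:.2f}/{res.class_weights[1]:.2f})")

L, a, b = ds.split_lab(case.image)
print(f"\nCIELAB ranges on this image: "
      f"L [{L.pixels.min():.1f}, {L.pixels.max():.1f}], "
      f"a [{a.pixels.min():.1f}, {a.pixels.max():.1f}], "
      f"b [{b.pixels.min():.1f}, {b.pixels.max():.1f}]")
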