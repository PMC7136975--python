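"""Gradient surface metrics on an ellipse-clipped suitability surface.

The landscape between a site pair is delineated as an ellipse aligned
with the inter-site bearing; nine surface-metrology statistics then
summarise the roughness, height distribution and Fourier texture of the
suitability surface inside the clip.
"""

from gradscape import (SurfaceSpec, clip_to_ellipse, ellipse_from_axis_ratio,
                       generate_surface, gsm_vector)

surface = generate_surface(SurfaceSpec(256, 256, hurst=0.6, cell_size=100.0,
                                       seed=9))
a, b = (5_000.0, 12_000.0), (20_000.0, 14_000.0)
ellipse = ellipse_from_axis_ratio(a, b, axis_ratio=0.5)
clip = clip_to_ellipse(surface, ellipse, ensure=(a, b))
print(f"clip: {clip.shape} bounding box, {int((~clip.mask).sum())} cells inside")

metrics = gsm_vector(clip)
for name, value in metrics.items():
    print(f"  {name:5s} = {value:8.3f}")
print("Sa is the mean absolute height (roughness); Std/Stdi describe the "
      "dominant texture direction and how dominant it is; Sfd is the "
      "spectral fractal dimension (2 = smooth plane, 3 = space-filling).")
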