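"""Generate a synthetic study scene: suitability surface, cover mosaic, sites.

The suitability surface is a fractional-Brownian field smoothed with a
2.1 km moving window (mimicking a moving-window habitat-suitability
model); the land-cover mosaic is a three-class thresholding of a rougher
companion field; 17 sites are packed with a minimum separation.
"""

import numpy as np

from gradscape import ComparisonConfig, build_scene

cfg = ComparisonConfig(seed=42)
scene = build_scene(cfg, with_genotypes=False)

print(f"suitability surface: {scene.hsm.shape} cells of "
      f"{scene.hsm.cell_size:.0f} m, range "
      f"[{scene.hsm.values.min():.2f}, {scene.hsm.values.max():.2f}]")
classes, counts = np.unique(scene.landcover.values, return_counts=True)
for c, n in zip(classes, counts):
    label = {1: "forest habitat", 2: "complementary habitat",
             3: "non-habitat"}[int(c)]
    print(f"  cover class {c} ({label}): {100 * n / counts.sum():.1f} % of cells")
print(f"sites: {scene.sites.n} -> {len(scene.pairs)} unordered pairs")
d = np.hypot(scene.sites.x[:, None] - scene.sites.x,
             scene.sites.y[:, None] - scene.sites.y)
off = d[np.triu_indices(scene.sites.n, 1)]
print(f"inter-site distances: {off.min() / 1000:.1f} - {off.max() / 1000:.1f} km")
# each pair's predictors are measured inside an ellipse landscape; the
# class shares and pair count mirror the study design this emulates
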