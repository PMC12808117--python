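"""Internal holdout splitting and cross-slide stain normalization.

Two supporting utilities: (1) withholding a spatially distinct slide region
for internal testing, snapped to the tile grid so no tile straddles the
boundary; (2) histogram matching a slide onto a reference slide's color
distribution, a light stain-normalization step for slides digitized under
different protocols.
"""

import numpy as np

from pollenset import SlideImage, TilingConfig, match_histograms
from pollenset.dataset import split_regions
from pollenset.synthetic import make_fixture

# --- region split -----------------------------------------------------------
slide = SlideImage(
    raster=np.zeros((1036, 2590, 3), np.uint8), slide_id="demo", species="ambrosia"
)
split = split_regions(slide, holdout_fraction=0.2, axis="vertical",
                      tiling=TilingConfig(patch_size=518))
print("region split (patch 518, holdout 20%):")
print(f"  train: x in [{split.train_region.x}, "
      f"{split.train_region.x + split.train_region.width})")
print(f"  test:  x in [{split.test_region.x}, "
      f"{split.test_region.x + split.test_region.width})")
print("  the holdout is a whole number of tiles anchored at the far edge\n")

# --- histogram matching -----------------------------------------------------
fx = make_fixture("hard", seed=3, grains_per_species=4, with_stacks=False)
a, b = fx.pure_slides[0].reference, fx.pure_slides[1].reference
matched = match_histograms(a, b)
print("stain normalization (channel means before/after matching slide A to B):")
print(f"  slide A: {a.reshape(-1, 3).mean(axis=0).round(1)}")
print(f"  slide B: {b.reshape(-1, 3).mean(axis=0).round(1)}")
print(f"  A->B   : {matched.reshape(-1, 3).mean(axis=0).round(1)}")
print("  after matching, A's per-channel distribution approximates B's,\n"
      "  reducing the stain shift between differently prepared slides.")
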