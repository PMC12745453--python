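"""From segmentation label maps to a plot's landscape profile.

A scene-parsing network assigns each photo pixel an ADE20K class id;
remapping collapses those ids onto 11 park landscape features, and a
plot's profile averages the per-photo fractions.
"""

import numpy as np

from parkscape import aggregate_plot, photo_protocol_plan, remap_labels

rng = np.random.default_rng(0)

# two fake 60x40 "photos": ids 2=sky, 4=tree, 11=sidewalk, 12=person
photos = [rng.choice([2, 4, 4, 11, 12], size=(40, 60)) for _ in range(2)]
vectors = [remap_labels(grid) for grid in photos]
for i, v in enumerate(vectors, 1):
    print(f"photo {i}: sky={v['sky']:.3f} tree={v['tree']:.3f} "
          f"pavement={v['pavement']:.3f} other={v.other:.3f}")

profile = aggregate_plot(vectors, plot_id="plot-A")
print(f"plot profile (mean of {profile.n_images} photos): "
      f"tree fraction = {profile.fractions['tree']:.3f}")

count, _ = photo_protocol_plan(n_plots=68)
print(f"standard field campaign: 68 plots x 9 points x 4 directions = {count} photos")
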