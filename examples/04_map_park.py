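"""Map predicted behavior intensity over a whole park.

Synthesizes a ~7.7 ha park with crowdsourced-style geotagged image
points, filters them, builds a 30 m fishnet, averages features per
cell, predicts the four indices with the packaged reference equations
and classifies each index with Jenks natural breaks.
"""

from parkscape import GeneratorConfig
from parkscape.pipeline import RunConfig, run_mapping

cfg = RunConfig(out_dir="scratch/example_map", seed=7, jenks_k=5,
                use_reference_models=True,
                generator=GeneratorConfig(seed=7, n_images=467))
bundle = run_mapping(cfg)

log = bundle["log"]
print(f"input points: {log['n_points_input']}, retained "
      f"{log['rejections']['retained']} "
      f"(rejected: {log['rejections']['low_resolution']} low-res, "
      f"{log['rejections']['duplicate']} duplicate, "
      f"{log['rejections']['non_landscape']} non-landscape)")
print(f"fishnet: {log['n_cells']} cells of 30 m, {log['n_data_cells']} with data")
for outcome, br in bundle["breaks"].items():
    print(f"{outcome}: {br.k} Jenks classes, GVF = {br.gvf:.3f}")
print(f"maps written to {bundle['paths']['geojson']}")
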