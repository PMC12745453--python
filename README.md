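# parkscape

Plot-scale analysis of how urban-park landscape composition supports
health behavior, and park-wide mapping of predicted behavior intensity.

## The problem

Park users, designers and managers want to know *where inside a park*
specific health-promoting activities — exercise, leisure, social
interaction — are best supported, not just whether the park as a whole
is used. `parkscape` implements an analysis pipeline built around
30 m × 30 m measurement plots:

1. **Landscape quantification.** Plot photographs are semantically
   segmented upstream (ADE20K-style class ids per pixel); the package
   remaps label maps onto 11 landscape features (sky, water, tree,
   shrub, grass, building, pavement, rough/uneven ground, resting /
   service / shading facilities) and averages pixel fractions into a
   per-plot profile.
2. **Behavior intensity scoring.** Systematic observation (SOPARC-style)
   codes each observed activity with a 3-digit code — 1xx exercise (EB),
   2xx leisure (LB), 3xx social (SB) — and a participant count. Each
   plot's intensity indices weight counts by the activity's Metabolic
   Equivalent of Task:

   EBI = Σᵢ MET(EB,i) · N(EB,i),   LBI and SBI analogously,
   OBI = EBI + LBI + SBI    (units: MET·persons).

3. **Association models.** Spearman correlation screening, iterative
   VIF filtering (drop features with VIF = 1/(1−R²ⱼ) ≥ 10), and an
   ordinary-least-squares fit per index. The package also ships the
   published reference equations estimated from a seven-park,
   68-plot Shanghai field campaign, e.g.

   OBI = 281.63 + 857.13·Sky + 1040.91·Pavement − 1736.40·RoughGround
   LBI = 119.00 + 585.04·Shrub

4. **Spatial mapping.** Crowdsourced geotagged photos are filtered
   (resolution ≥ 1080 px, de-duplicated, landscape-related), a 30 m
   fishnet is tiled over the park boundary, points are spatially joined
   to cells, per-cell mean features feed the four models, and each
   index is classified with Jenks natural breaks (exact Fisher
   dynamic-programming partition) for mapping.

A calibrated synthetic-data generator stands in for the unreleased
field data, so every stage is runnable and testable end to end. A
reliability module (ANOVA-based ICC forms, percent agreement) covers
observer quality control.

## Worked example

```bash
python examples/04_map_park.py
```

```
input points: 467, retained 423 (rejected: 23 low-res, 7 duplicate, 14 non-landscape)
fishnet: 88 cells of 30 m, 88 with data
OBI: 5 Jenks classes, GVF = 0.950
EBI: 5 Jenks classes, GVF = 0.941
LBI: 5 Jenks classes, GVF = 0.946
SBI: 5 Jenks classes, GVF = 0.945
maps written to scratch/example_map/intensity_map.geojson
```

467 synthetic geotagged photos are generated over a ~7.7 ha park; 44
fail quality filtering, mirroring real crowdsourced data. Every 30 m
cell receives at least one photo here, so all 88 cells get predictions
from the reference equations, and each index partitions into 5 natural
classes explaining ≥94% of its variance (GVF = goodness of variance
fit). The GeoJSON output carries, per cell, the four predicted
intensities (MET·persons) and their Jenks classes — the data behind a
behavior-intensity map.

Scoring a single plot (`examples/01_score_behavior.py`):

```
EBI = 120.0  LBI = 15.6  SBI = 7.5  OBI = 143.1  (MET.persons)
```

18 social dancers at MET 5.5 plus 7 tai chi practitioners at MET 3.0
give EBI = 120.0; the indices are additive by construction.

Other examples: `02_landscape_profiles.py` (label-map remapping),
`03_fit_models.py` (full statistical chain on synthetic data),
`05_reliability.py` (ICC recovery). The CLI mirrors the same stages:
`parkscape synth|profiles|score|fit|map|report|run-all`.

## Caveats

The packaged MET table is a stand-in assembled from 2011 Adult
Compendium conventions (the original per-code values were not
published), and the default ADE20K remap is a documented
reconstruction; supply your own tables for real analyses. Boundary and
point coordinates must be projected in meters — geographic coordinates
are rejected, not reprojected. See `docs/methods.md` for the full
model description, generator calibration and limitations.
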