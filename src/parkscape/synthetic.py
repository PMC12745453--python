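"""Synthetic study generator calibrated to the published field conditions.

The original raw data (plot photographs, observation sheets, crowdsourced
points) were never released, so every pipeline stage is exercised on
synthetic data with the same statistical structure:

* landscape profiles drawn per feature from independent truncated
  normals at the published 68-plot means/SDs (a Dirichlet joint
  alternative is available for sum-constrained realism),
* behavior records whose category intensities follow the published
  prediction equations plus Gaussian residual noise (defaulting to the
  residual SDs implied by the published R2 and outcome SDs), decomposed
  into integer (code, count) observation records,
* geotagged image points scattered in a park polygon with spatially
  smooth feature fields and configurable quality flaws to exercise
  filtering, and
* dual-observer rating matrices at a chosen true intraclass correlation.

All generators are bit-reproducible under a fixed seed and draw from
independent sub-streams, so e.g. changing n_images never perturbs the
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box

from . import reference
from .behavior import (
    AGE_GROUPS,
    GENDERS,
    BehaviorRecord,
    BehaviorTaxonomy,
    METTable,
    default_met_table,
    default_taxonomy,
)
from .landscape import FeatureVector, LandscapeProfile
from .mapping import GeoImagePoint
from .reference import FEATURES
from .regression import RegressionModel, predict, reference_models
from .reliability import RatingMatrix

__all__ = [
    "GeneratorConfig",
    "gen_behavior_records",
    "gen_geo_images",
    "gen_profiles",
    "gen_rating_matrix",
]

# fixed sub-stream tags so the generators are mutually independent
_STREAM_PROFILES = 11
_STREAM_BEHAVIOR = 22
_STREAM_GEO = 33
_STREAM_RATINGS = 44

#: Residual SDs implied by the published fits: sd_outcome * sqrt(1 - R2).
_DEFAULT_NOISE_SD = {
    o: reference.INTENSITY_SUMMARY["Overall"][o][1]
    * math.sqrt(1.0 - reference.MODEL_DIAGNOSTICS[o]["r2"])
    for o in ("EBI", "LBI", "SBI")
}

#: Weekday/weekend x three observation windows, weighted by the observed
#: 44/56 day-type split (uniform across windows within a day type).
_SESSIONS = [
    f"{day}-{slot}"
    for day in ("weekday", "weekend")
    for slot in ("08:00-10:00", "12:00-14:00", "15:00-17:00")
]
_SESSION_P = np.array(
    [reference.DEMOGRAPHIC_SHARES["day_type"][s.split("-")[0]] / 3.0
     for s in _SESSIONS]
)
_AGE_P = np.array([reference.DEMOGRAPHIC_SHARES["age_group"][a] for a in AGE_GROUPS])
_GENDER_P = np.array([reference.DEMOGRAPHIC_SHARES["gender"][g] for g in GENDERS])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs; defaults reproduce the published design."""

    seed: int = 0
    n_plots: int = 68
    feature_means: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.LANDSCAPE_MEANS))
    feature_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.LANDSCAPE_SDS))
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    true_models: Mapping[str, RegressionModel] | None = None
    park_extent: tuple[float, float] = (320.0, 240.0)  # ~7.7 ha, a mid-size park
    n_images: int = 467
    image_noise_sd: float = 0.05
    frac_low_res: float = 0.05
    frac_duplicate: float = 0.02
    frac_non_landscape: float = 0.03
    max_feature_sum: float = 0.95  # leave >= 5% "other" in every composition
    other_sd: float | None = None  # default: mean of the feature SDs
    use_dirichlet: bool = False
    dirichlet_concentration: float = 60.0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.n_images < 0:
            raise ValueError("n_plots must be >= 1 and n_images >= 0")
        means = {f: self.feature_means.get(f, 0.0) for f in FEATURES}
        if any(not 0 <= m <= 1 for m in means.values()):
            raise ValueError("feature means must lie in [0, 1]")
        if sum(means.values()) > 1:
            raise ValueError("feature means sum to more than 1: infeasible composition")
        if any(self.feature_sds.get(f, 0.0) < 0 for f in FEATURES):
            raise ValueError("feature SDs must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")

    def models(self) -> Mapping[str, RegressionModel]:
        return self.true_models if self.true_models is not None else reference_models()


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed), stream]))


def _calibrated_truncnorm_loc(mean: float, sd: float) -> float:
    """Location making a [0, 1]-truncated normal's mean equal ``mean``.

    Truncating a normal centred at a small mean inflates it (the mass
    below zero folds upward), which would distort compositions whose
    target mean is comparable to its SD; solving for the underlying
    location removes that bias.
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    if sd == 0:
        return mean

    def truncated_mean(loc: float) -> float:
        a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    lo, hi = mean - 12 * sd, mean + 12 * sd
    return float(brentq(lambda L: truncated_mean(L) - mean, lo, hi, xtol=1e-12))


def _truncnorm_draws(rng: np.random.Generator, loc: float, sd: float,
                     size: int) -> np.ndarray:
    from scipy.stats import truncnorm

    if sd == 0:
        return np.full(size, loc)
    a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _cap_sum(values: np.ndarray, cap: float) -> np.ndarray:
    s = values.sum()
    return values * (cap / s) if s > cap else values


def gen_profiles(cfg: GeneratorConfig) -> list[LandscapeProfile]:
    """Draw per-plot landscape compositions at the configured moments.

    Features are drawn from independent truncated normals, then the
    whole composition (features plus the fixed "other" budget
    ``1 - sum(means)``: people, vehicles, unmapped pixels) is
    renormalized to sum to 1.  The renormalization keeps compositions
    feasible with only a second-order effect on the marginal means, so
    the sample means track the configured (published) values; with all
    SDs zero every profile equals the mean vector exactly.  A final
    rescale enforces ``max_feature_sum`` in extreme configurations.
    """
    rng = _rng(cfg.seed, _STREAM_PROFILES)
    means = np.array([cfg.feature_means.get(f, 0.0) for f in FEATURES])
    sds = np.array([cfg.feature_sds.get(f, 0.0) for f in FEATURES])
    locs = np.array([_calibrated_truncnorm_loc(m, s)
                     for m, s in zip(means, sds)])
    other_budget = max(0.0, 1.0 - means.sum())
    # "other" (people, vehicles, unmapped pixels) varies like a typical
    # feature; without this the 11 fractions would be near-collinear
    other_sd = cfg.other_sd if cfg.other_sd is not None else float(sds.mean())
    other_loc = _calibrated_truncnorm_loc(other_budget, other_sd)
    profiles = []
    for i in range(cfg.n_plots):
        if cfg.use_dirichlet:
            alpha = np.append(means, max(other_budget, 1e-6)) \
                * cfg.dirichlet_concentration
            draw = rng.dirichlet(np.maximum(alpha, 1e-6))[:-1]
        else:
            draw = np.array([
                _truncnorm_draws(rng, loc, s, 1)[0]
                for loc, s in zip(locs, sds)
            ])
            other = _truncnorm_draws(rng, other_loc, other_sd, 1)[0]
            total = draw.sum() + other
            if total > 0:
                draw = draw / total
        draw = _cap_sum(draw, cfg.max_feature_sum)
        fv = FeatureVector.from_array(draw)
        profiles.append(LandscapeProfile(plot_id=f"plot-{i + 1:03d}",
                                         fractions=fv, n_images=36))
    return profiles


def _decompose_target(
    target: float,
    codes: Sequence[int],
    met: METTable,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Greedy split of an intensity target into integer (code, count) pairs.

    Leaves a residual below the smallest MET in the category, i.e. the
    realized sum lands within one MET unit of the target.
    """
    mets = {c: met[c] for c in codes}
    min_met = min(mets.values())
    remaining = float(target)
    out: list[tuple[int, int]] = []
    while remaining >= min_met:
        affordable = [c for c in codes if mets[c] <= remaining]
        code = int(rng.choice(affordable))
        max_count = int(remaining // mets[code])
        count = int(rng.integers(1, max_count + 1))
        out.append((code, count))
        remaining -= mets[code] * count
    return out


def gen_behavior_records(
    profiles: Sequence[LandscapeProfile],
    cfg: GeneratorConfig,
    met: METTable | None = None,
    taxonomy: BehaviorTaxonomy | None = None,
) -> list[BehaviorRecord]:
    """Simulate observation records whose scores track the true models.

    Per plot and category, the target intensity is
    ``max(0, model(features) + N(0, noise_sd))``; the target is then
    decomposed into records with codes drawn from that category.
    Demographics and sessions follow the published marginal shares.
    """
    met = met or default_met_table()
    taxonomy = taxonomy or default_taxonomy()
    models = cfg.models()
    rng = _rng(cfg.seed, _STREAM_BEHAVIOR)
    cat_codes = {
        cat: [c for c in taxonomy.codes_in(cat) if c in met]
        for cat in ("EB", "LB", "SB")
    }
    for cat, codes in cat_codes.items():
        if not codes:
            raise ValueError(f"taxonomy category {cat} has no MET-covered codes")

    records: list[BehaviorRecord] = []
    for profile in profiles:
        for cat, outcome in (("EB", "EBI"), ("LB", "LBI"), ("SB", "SBI")):
            mu = predict(models[outcome], profile.fractions)
            sd = cfg.noise_sd.get(outcome, 0.0)
            target = max(0.0, mu + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            for code, count in _decompose_target(target, cat_codes[cat], met, rng):
                records.append(BehaviorRecord(
                    plot_id=profile.plot_id,
                    session=str(rng.choice(_SESSIONS, p=_SESSION_P)),
                    code=code,
                    count=count,
                    age_group=str(rng.choice(AGE_GROUPS, p=_AGE_P)),
                    gender=str(rng.choice(GENDERS, p=_GENDER_P)),
                    observer_id=f"obs-{int(rng.integers(1, 4))}",
                ))
    return records


def gen_geo_images(
    cfg: GeneratorConfig,
    boundary: Polygon | None = None,
) -> tuple[Polygon, list[GeoImagePoint]]:
    """Scatter geotagged image points over a park with smooth feature fields.

    Each feature varies across the park as a low-frequency sinusoidal
    field centred on its configured mean with amplitude equal to its SD,
    plus white noise of ``image_noise_sd``.  A configurable fraction of
    points is flagged low-resolution, duplicate or non-landscape so the
    filtering stage has something to reject.
    """
    rng = _rng(cfg.seed, _STREAM_GEO)
    w, h = cfg.park_extent
    if boundary is None:
        boundary = box(0.0, 0.0, w, h)
    xmin, ymin, xmax, ymax = boundary.bounds

    # per-feature field parameters (direction, frequency, phase)
    means = np.array([cfg.feature_means.get(f, 0.0) for f in FEATURES])
    sds = np.array([cfg.feature_sds.get(f, 0.0) for f in FEATURES])
    theta = rng.uniform(0, 2 * np.pi, len(FEATURES))
    freq = rng.uniform(0.5, 1.5, len(FEATURES))
    phase = rng.uniform(0, 2 * np.pi, len(FEATURES))

    def field_at(x: float, y: float) -> np.ndarray:
        u = ((x - xmin) / max(xmax - xmin, 1e-9)) * np.cos(theta) \
            + ((y - ymin) / max(ymax - ymin, 1e-9)) * np.sin(theta)
        vals = means + sds * np.sin(2 * np.pi * freq * u + phase)
        if cfg.image_noise_sd > 0:
            vals = vals + rng.normal(0, cfg.image_noise_sd, len(FEATURES))
        return _cap_sum(np.clip(vals, 0.0, 1.0), cfg.max_feature_sum)

    n = cfg.n_images
    n_low = int(round(cfg.frac_low_res * n))
    n_dup = int(round(cfg.frac_duplicate * n))
    n_nonland = int(round(cfg.frac_non_landscape * n))
    flags = (["low_res"] * n_low + ["duplicate"] * n_dup
             + ["non_landscape"] * n_nonland)
    flags += ["ok"] * (n - len(flags))
    rng.shuffle(flags)

    points: list[GeoImagePoint] = []
    for i in range(n):
        while True:  # rejection-sample into the boundary
            x = rng.uniform(xmin, xmax)
            y = rng.uniform(ymin, ymax)
            if boundary.contains(Point(x, y)):
                break
        flag = flags[i]
        key = f"uniq-{i + 1:04d}"
        if flag == "duplicate" and points:
            # reuse an earlier point's content hash: an exact re-upload
            key = points[int(rng.integers(0, len(points)))].duplicate_key
        fv = FeatureVector.from_array(field_at(x, y))
        points.append(GeoImagePoint(
            image_id=f"img-{i + 1:04d}",
            x=float(x), y=float(y),
            resolution=720 if flag == "low_res" else 1920,
            features=fv,
            is_landscape=flag != "non_landscape",
            duplicate_key=key,
        ))
    return boundary, points


def gen_rating_matrix(
    cfg: GeneratorConfig,
    true_icc: float,
    n_targets: int = 200,
    n_raters: int = 2,
) -> RatingMatrix:
    """Ratings with a chosen true intraclass correlation.

    Target effects have variance ``true_icc`` and residuals
    ``1 - true_icc`` (unit total variance), so the population
    ICC(1,1)/ICC(2,1) equals ``true_icc``.  ``true_icc=1`` gives
    noiseless ratings (ICC exactly 1).
    """
    if not 0.0 <= true_icc <= 1.0:
        raise ValueError(f"true_icc must be in [0, 1], got {true_icc}")
    if n_targets < 2 or n_raters < 2:
        raise ValueError("need >= 2 targets and >= 2 raters")
    rng = _rng(cfg.seed, _STREAM_RATINGS)
    sigma_b = math.sqrt(true_icc)
    sigma_w = math.sqrt(1.0 - true_icc)
    targets = rng.normal(0.0, sigma_b, n_targets)[:, None]
    values = targets + rng.normal(0.0, sigma_w, (n_targets, n_raters))
    return RatingMatrix(
        values,
        target_labels=tuple(f"t{i}" for i in range(n_targets)),
        rater_labels=tuple(f"obs-{j + 1}" for j in range(n_raters)),
    )
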