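"""Landscape composition profiles from semantic-segmentation outputs.

An upstream scene-parsing network (trained on an ADE20K-style vocabulary)
assigns every pixel of a plot photograph one integer class id.  This
module remaps those ids onto the study's 11 landscape features --

    sky, water, tree, shrub, grass, building, pavement, rough_ground,
    resting_facility, service_facility, shading_facility

-- computes per-image pixel fractions, averages them into per-plot
profiles, and produces descriptive statistics tables.  Pixels whose class
maps to no feature (people, vehicles, indoor classes, ...) are the
"other" remainder, so the 11 fractions plus "other" always sum to 1.

The segmentation itself is out of scope: the pipeline consumes label
maps (integer PNG or integer-matrix CSV) or pre-computed fraction tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import FEATURES, PHOTO_DIRECTIONS, PHOTO_POINTS_PER_PLOT

__all__ = [
    "FeatureVector",
    "LandscapeProfile",
    "RemapError",
    "RemapTable",
    "accept_fraction_table",
    "aggregate_plot",
    "default_remap_table",
    "descriptive_stats",
    "fraction_table_from_csv",
    "photo_protocol_plan",
    "profiles_from_frame",
    "profiles_to_frame",
    "read_label_map",
    "remap_labels",
]

OTHER = "other"
_SUM_TOL = 1e-6


class RemapError(KeyError):
    """A label-map class id with no remap entry (strict mode)."""


@dataclass(frozen=True)
class FeatureVector:
    """Fractions of the 11 landscape features for one image or cell.

    ``other`` holds the unmapped remainder so the full composition sums
    to 1 for label-map input (for tabular input it is inferred as
    1 - sum of the 11 features).
    """

    fractions: Mapping[str, float]
    other: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown landscape features: {sorted(unknown)}")
        full = {f: float(self.fractions.get(f, 0.0)) for f in FEATURES}
        object.__setattr__(self, "fractions", full)
        for f, v in full.items():
            if not -_SUM_TOL <= v <= 1 + _SUM_TOL:
                raise ValueError(f"fraction {f}={v} outside [0, 1]")
        if sum(full.values()) > 1 + _SUM_TOL:
            raise ValueError(
                f"feature fractions sum to {sum(full.values()):.6f} > 1"
            )

    def __getitem__(self, feature: str) -> float:
        return self.fractions[feature]

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[f] for f in FEATURES])

    @classmethod
    def from_array(cls, values: Sequence[float], other: float | None = None) -> "FeatureVector":
        fr = dict(zip(FEATURES, map(float, values)))
        if other is None:
            other = max(0.0, 1.0 - sum(fr.values()))
        return cls(fr, other=float(other))


@dataclass(frozen=True)
class LandscapeProfile:
    """Average landscape composition of a plot over its photographs."""

    plot_id: str
    fractions: FeatureVector
    n_images: int

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("a profile needs at least one image")


@dataclass(frozen=True)
class RemapTable:
    """Source segmentation class id -> landscape feature (or 'other')."""

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        bad = {t for t in self.mapping.values() if t not in FEATURES and t != OTHER}
        if bad:
            raise ValueError(f"remap targets not among the 11 features: {sorted(bad)}")

    def target(self, class_id: int, strict: bool = False) -> str:
        if class_id in self.mapping:
            return self.mapping[class_id]
        if strict:
            raise RemapError(f"class id {class_id} has no remap entry")
        return OTHER

    @classmethod
    def from_csv(cls, path) -> "RemapTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["source_id"].astype(int), df["target"].astype(str))))


def default_remap_table() -> RemapTable:
    """Packaged ADE20K(150-class) -> 11-feature remap.

    A plausible reconstruction, not the original study's unpublished
    mapping; override for real analyses.
    """
    with resources.files("parkscape.data").joinpath("ade20k_remap.json").open() as fh:
        raw = json.load(fh)
    raw.pop("_comment", None)
    return RemapTable({int(k): str(v) for k, v in raw.items()})


def read_label_map(path) -> np.ndarray:
    """Load an integer label map from PNG (single channel) or CSV."""
    path = str(path)
    if path.lower().endswith(".csv"):
        grid = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    else:
        from PIL import Image

        grid = np.asarray(Image.open(path), dtype=np.int64)
        if grid.ndim == 3:  # palettized/multi-channel export: take first band
            grid = grid[..., 0]
    if grid.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {grid.shape}")
    return grid


def remap_labels(
    grid: np.ndarray,
    remap: RemapTable | None = None,
    strict: bool = False,
) -> FeatureVector:
    """Pixel fractions of the 11 features for one segmented image.

    Unknown class ids go to "other" with a warning, or raise under
    ``strict=True``.
    """
    remap = remap or default_remap_table()
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty label map")
    if grid.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {grid.shape}")
    if np.any(grid < 0):
        raise ValueError("label maps must contain non-negative class ids")

    ids, counts = np.unique(grid, return_counts=True)
    total = grid.size
    fractions = {f: 0.0 for f in FEATURES}
    other = 0.0
    unknown: list[int] = []
    for cid, n in zip(ids.tolist(), counts.tolist()):
        if cid not in remap.mapping:
            if strict:
                raise RemapError(f"class id {cid} has no remap entry")
            unknown.append(cid)
        tgt = remap.target(cid)
        if tgt == OTHER:
            other += n / total
        else:
            fractions[tgt] += n / total
    if unknown:
        warnings.warn(f"unmapped class ids sent to 'other': {unknown}", stacklevel=2)
    return FeatureVector(fractions, other=other)


def accept_fraction_table(row: Mapping[str, float]) -> FeatureVector:
    """Validate one row of pre-computed per-image feature fractions.

    Alternate ingest path for when only segmentation summaries, not
    label maps, are available; downstream semantics are identical to
    :func:`remap_labels` output.
    """
    fractions = {f: float(row.get(f, 0.0)) for f in FEATURES}
    s = sum(fractions.values())
    if s > 1 + _SUM_TOL:
        raise ValueError(f"feature fractions sum to {s:.6f} > 1")
    return FeatureVector(fractions, other=max(0.0, 1.0 - s))


def fraction_table_from_csv(path) -> dict[str, FeatureVector]:
    """Read a CSV of per-image fractions (image_id + 11 feature columns)."""
    df = pd.read_csv(path)
    return {
        str(r["image_id"]): accept_fraction_table(r)
        for _, r in df.iterrows()
    }


def aggregate_plot(
    vectors: Iterable[FeatureVector],
    plot_id: str = "",
) -> LandscapeProfile:
    """Average per-image feature vectors into one plot profile."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot aggregate zero images")
    arr = np.vstack([v.as_array() for v in vectors])
    other = float(np.mean([v.other for v in vectors]))
    mean = FeatureVector.from_array(arr.mean(axis=0), other=other)
    return LandscapeProfile(plot_id=plot_id, fractions=mean, n_images=len(vectors))


def photo_protocol_plan(
    n_plots: int,
    points_per_plot: int = PHOTO_POINTS_PER_PLOT,
    directions: int = PHOTO_DIRECTIONS,
) -> tuple[int, pd.DataFrame]:
    """Plan the field-photography slots for a campaign.

    The standard protocol photographs >= 9 points per 30 m plot in the
    four compass directions, i.e. >= 36 photos per plot.  Returns the
    total slot count and a manifest of (plot, point, direction) rows.
    """
    if n_plots < 1 or points_per_plot < 1 or directions < 1:
        raise ValueError("all protocol arguments must be >= 1")
    compass = ["E", "S", "W", "N"]
    manifest = pd.DataFrame(
        [
            {
                "plot": p,
                "point": q,
                "direction": compass[d] if directions == 4 else d,
            }
            for p in range(1, n_plots + 1)
            for q in range(1, points_per_plot + 1)
            for d in range(directions)
        ]
    )
    return n_plots * points_per_plot * directions, manifest


def profiles_to_frame(profiles: Iterable[LandscapeProfile]) -> pd.DataFrame:
    rows = [
        {"plot_id": p.plot_id, **p.fractions.fractions, "n_images": p.n_images}
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["plot_id", *FEATURES, "n_images"])


def profiles_from_frame(df: pd.DataFrame) -> list[LandscapeProfile]:
    return [
        LandscapeProfile(
            plot_id=str(r["plot_id"]),
            fractions=accept_fraction_table(r),
            n_images=int(r["n_images"]) if "n_images" in df.columns else 1,
        )
        for _, r in df.iterrows()
    ]


def descriptive_stats(
    profiles: Sequence[LandscapeProfile],
    grouping: Mapping[str, str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-park (and pooled) mean and SD of each landscape feature.

    ``grouping`` maps plot_id -> park id; ungrouped input reports only
    the pooled column.  ``ddof=1`` gives the sample SD (default); pass
    0 for the population SD.  Single-profile groups report SD 0 with an
    ``sd_undefined`` flag when the sample SD is requested.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    df = profiles_to_frame(profiles)
    groups: dict[str, pd.DataFrame] = {"Overall": df}
    if grouping:
        for pid in df["plot_id"]:
            if pid not in grouping:
                warnings.warn(f"plot {pid} missing from grouping; pooled only",
                              stacklevel=2)
        df = df.assign(park=[grouping.get(p, None) for p in df["plot_id"]])
        for park, sub in df.groupby("park", dropna=True):
            groups[str(park)] = sub

    rows = []
    for feature in FEATURES:
        row: dict[str, object] = {"feature": feature}
        for name, sub in groups.items():
            vals = sub[feature].to_numpy(dtype=float)
            row[f"{name}_mean"] = vals.mean()
            if len(vals) <= ddof:
                row[f"{name}_sd"] = 0.0
                row[f"{name}_sd_undefined"] = True
            else:
                row[f"{name}_sd"] = vals.std(ddof=ddof)
        rows.append(row)
    return pd.DataFrame(rows)
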