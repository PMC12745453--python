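"""Behavior taxonomy, MET weighting and intensity indices.

Field observers code every activity seen in a 30 m x 30 m plot with a
3-digit subcategory code whose leading digit gives the health-behavior
category: 1xx exercise (EB), 2xx leisure (LB), 3xx social (SB).  Each
record carries a participant count.  A plot's intensity indices weight
those counts by the activity's Metabolic Equivalent of Task (MET):

    EBI = sum over exercise records of MET(code) * count
    LBI, SBI analogously; OBI = EBI + LBI + SBI.

Units are MET.persons.  The packaged default MET table is a synthetic
stand-in assembled from 2011 Adult Compendium conventions (the original
study's per-code values were not released); supply a measured table via
:func:`met_table_from_csv` / :func:`met_table_from_json` for real work.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CATEGORIES",
    "BehaviorRecord",
    "BehaviorTaxonomy",
    "IntensityScores",
    "METTable",
    "MissingMETError",
    "UnknownCodeError",
    "behavior_summary",
    "category_of",
    "default_met_table",
    "default_taxonomy",
    "demographic_summary",
    "met_table_from_csv",
    "met_table_from_json",
    "read_records_csv",
    "round_half_up",
    "score_plot",
    "score_plots",
]

CATEGORIES = ("EB", "LB", "SB")
AGE_GROUPS = ("child", "adolescent", "adult", "older_adult")
GENDERS = ("female", "male")

_CATEGORY_BY_LEADING_DIGIT = {1: "EB", 2: "LB", 3: "SB"}


class UnknownCodeError(KeyError):
    """A behavior code outside the taxonomy (or the 100-399 range)."""


class MissingMETError(ValueError):
    """Scored records reference codes absent from the MET table."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as report tables conventionally do.

    Python's built-in ``round`` is banker's rounding, which would print
    e.g. 50.005 -> 50.0; shares in the observation reports use half-up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def category_of(code: int) -> str:
    """Return the behavior category (EB/LB/SB) encoded in a 3-digit code."""
    if not isinstance(code, (int,)) or isinstance(code, bool):
        raise UnknownCodeError(f"behavior code must be an integer, got {code!r}")
    if not 100 <= code <= 399:
        raise UnknownCodeError(f"behavior code {code} outside the 100-399 range")
    return _CATEGORY_BY_LEADING_DIGIT[code // 100]


@dataclass(frozen=True)
class BehaviorTaxonomy:
    """Map from 3-digit code to activity name and category."""

    entries: Mapping[int, dict]

    def __post_init__(self) -> None:
        for code, entry in self.entries.items():
            expected = category_of(code)
            if entry["category"] != expected:
                raise ValueError(
                    f"code {code} declared {entry['category']} but its leading "
                    f"digit implies {expected}"
                )

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> list[int]:
        return sorted(self.entries)

    def name_of(self, code: int) -> str:
        self._require(code)
        return self.entries[code]["name"]

    def codes_in(self, category: str) -> list[int]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return sorted(c for c, e in self.entries.items() if e["category"] == category)

    def _require(self, code: int) -> None:
        if code not in self.entries:
            raise UnknownCodeError(f"behavior code {code} not in taxonomy")


@dataclass(frozen=True)
class METTable:
    """Per-code MET values (strictly positive multiples of resting rate)."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        for code, met in self.values.items():
            if not (met > 0 and met == met and met != float("inf")):
                raise ValueError(f"MET for code {code} must be positive finite, got {met}")

    def __contains__(self, code: int) -> bool:
        return code in self.values

    def __getitem__(self, code: int) -> float:
        try:
            return self.values[code]
        except KeyError:
            raise MissingMETError(f"no MET value for code {code}") from None

    def missing_codes(self, codes: Iterable[int]) -> list[int]:
        return sorted({c for c in codes if c not in self.values})


@dataclass(frozen=True)
class BehaviorRecord:
    """One observed activity within a plot during one observation session."""

    plot_id: str
    session: str
    code: int
    count: int
    age_group: str = "adult"
    gender: str = "female"
    observer_id: str = "obs-1"

    def __post_init__(self) -> None:
        category_of(self.code)  # validates range
        if self.count < 0:
            raise ValueError(f"participant count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class IntensityScores:
    """MET-weighted intensity indices for one plot (or grid cell)."""

    plot_id: str
    OBI: float
    EBI: float
    LBI: float
    SBI: float

    def as_dict(self) -> dict[str, float]:
        return {"OBI": self.OBI, "EBI": self.EBI, "LBI": self.LBI, "SBI": self.SBI}


def _load_packaged_json(name: str) -> dict:
    with resources.files("parkscape.data").joinpath(name).open() as fh:
        raw = json.load(fh)
    raw.pop("_comment", None)
    return raw


def default_taxonomy() -> BehaviorTaxonomy:
    """The packaged 34-code taxonomy (16 EB, 11 LB, 7 SB)."""
    raw = _load_packaged_json("taxonomy.json")
    return BehaviorTaxonomy({int(k): v for k, v in raw.items()})


def default_met_table() -> METTable:
    """Packaged stand-in MET table (see module docstring)."""
    raw = _load_packaged_json("met_table.json")
    return METTable({int(k): float(v) for k, v in raw.items()})


def met_table_from_csv(path) -> METTable:
    """Read a ``code,met`` CSV into a MET table."""
    df = pd.read_csv(path)
    return METTable(dict(zip(df["code"].astype(int), df["met"].astype(float))))


def met_table_from_json(path) -> METTable:
    with open(path) as fh:
        raw = json.load(fh)
    raw.pop("_comment", None)
    return METTable({int(k): float(v) for k, v in raw.items()})


def read_records_csv(path) -> list[BehaviorRecord]:
    """Read observation records from the standard CSV layout.

    Columns: plot_id, session, code, count, age_group, gender, observer_id.
    """
    df = pd.read_csv(path)
    return [
        BehaviorRecord(
            plot_id=str(r.plot_id), session=str(r.session), code=int(r.code),
            count=int(r.count), age_group=str(r.age_group), gender=str(r.gender),
            observer_id=str(r.observer_id),
        )
        for r in df.itertuples()
    ]


def records_to_frame(records: Iterable[BehaviorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"plot_id": r.plot_id, "session": r.session, "code": r.code,
             "count": r.count, "age_group": r.age_group, "gender": r.gender,
             "observer_id": r.observer_id}
            for r in records
        ],
        columns=["plot_id", "session", "code", "count",
                 "age_group", "gender", "observer_id"],
    )


def score_plot(
    records: Iterable[BehaviorRecord],
    met: METTable,
    plot_id: str | None = None,
    taxonomy: BehaviorTaxonomy | None = None,
) -> IntensityScores:
    """Compute EBI/LBI/SBI (and their sum OBI) for one plot's records.

    All sessions pool into one score; filter the records first for
    per-session scoring.  An empty record list scores zero everywhere.
    OBI is formed as the literal sum EBI + LBI + SBI so the category
    partition holds to machine precision.
    """
    records = list(records)
    taxonomy = taxonomy or default_taxonomy()
    for r in records:
        if r.code not in taxonomy:
            raise UnknownCodeError(f"behavior code {r.code} not in taxonomy")
    missing = met.missing_codes(r.code for r in records)
    if missing:
        raise MissingMETError(f"MET table lacks entries for codes: {missing}")
    if plot_id is None:
        plots = {r.plot_id for r in records}
        if len(plots) > 1:
            raise ValueError(f"records span multiple plots {sorted(plots)}; pass plot_id")
        plot_id = plots.pop() if plots else ""

    terms: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for r in records:
        terms[category_of(r.code)].append(met[r.code] * r.count)
    # fsum: exactly rounded, so record order can never change a score
    ebi, lbi, sbi = (math.fsum(terms[c]) for c in CATEGORIES)
    return IntensityScores(plot_id=plot_id, OBI=ebi + lbi + sbi,
                           EBI=ebi, LBI=lbi, SBI=sbi)


def score_plots(
    records: Iterable[BehaviorRecord],
    met: METTable,
    taxonomy: BehaviorTaxonomy | None = None,
) -> pd.DataFrame:
    """Score every plot present in a record set; one row per plot."""
    records = list(records)
    by_plot: dict[str, list[BehaviorRecord]] = {}
    for r in records:
        by_plot.setdefault(r.plot_id, []).append(r)
    rows = []
    for plot_id in sorted(by_plot):
        s = score_plot(by_plot[plot_id], met, plot_id=plot_id, taxonomy=taxonomy)
        rows.append({"plot_id": plot_id, **s.as_dict()})
    return pd.DataFrame(rows, columns=["plot_id", "OBI", "EBI", "LBI", "SBI"])


def behavior_summary(
    records: Iterable[BehaviorRecord],
    taxonomy: BehaviorTaxonomy | None = None,
) -> pd.DataFrame:
    """Per-subcategory participant counts and percentage shares.

    Percentages are 100 * code_count / total_count, rounded half-up to
    two decimals (so they sum to 100 up to rounding).
    """
    records = list(records)
    taxonomy = taxonomy or default_taxonomy()
    counts: dict[int, int] = {}
    for r in records:
        counts[r.code] = counts.get(r.code, 0) + r.count
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no participants observed: summary undefined")
    rows = [
        {
            "code": code,
            "name": taxonomy.name_of(code) if code in taxonomy else "",
            "category": category_of(code),
            "count": n,
            "percent": round_half_up(100.0 * n / total),
        }
        for code, n in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values("count", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def demographic_summary(records: Iterable[BehaviorRecord]) -> dict[str, pd.DataFrame]:
    """Participant-weighted shares by age group, gender and session."""
    df = records_to_frame(list(records))
    total = df["count"].sum()
    if total == 0:
        raise ValueError("no participants observed: summary undefined")
    out: dict[str, pd.DataFrame] = {}
    for stratum in ("age_group", "gender", "session"):
        g = df.groupby(stratum)["count"].sum().sort_values(ascending=False)
        out[stratum] = pd.DataFrame(
            {
                stratum: g.index,
                "count": g.to_numpy(),
                "percent": [round_half_up(100.0 * n / total) for n in g],
            }
        )
    return out
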