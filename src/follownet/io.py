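"""Reading, validation and daily aggregation of focal-follow observation tables.

Three delimited tables describe a study: focal follows (one row per follow,
with the party composition observed during the follow plus the closing scan),
dyadic behaviour events (proximity or grooming, directionality dropped), and
demographics (origin, sex, age, arrival age, rank, matriline).

The daily one-zero reduction implemented here scores, per calendar day and
group, which individuals were captured on video ("identified": focal subject,
party member, or participant in a coded event) and which unordered dyads had
at least one event of the behaviour in question.  Repeated same-day events for
a dyad collapse to a single association, which is the sampling unit every
association index downstream is built on.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections import defaultdict
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

BEHAVIOURS = ("proximity", "grooming")
ORIGINS = ("wild", "sanctuary")
#: follows shorter than this many seconds in view are excluded by default
DEFAULT_MIN_IN_VIEW = 300.0

_PARTY_SEP = ";"


class DataValidationError(ValueError):
    """Raised when an input table violates the schema or referential integrity."""


@dataclasses.dataclass(frozen=True)
class DailyRecord:
    """One-zero summary of a (date, group) sampling period for one behaviour."""

    date: _dt.date
    group_id: str
    behaviour: str
    identified_ids: frozenset
    associated_dyads: frozenset  # frozenset of sorted (id, id) tuples

    def __post_init__(self):
        for a, b in self.associated_dyads:
            if a not in self.identified_ids or b not in self.identified_ids:
                raise DataValidationError(
                    f"dyad ({a},{b}) associated on {self.date} but not identified"
                )


@dataclasses.dataclass
class ObservationDataset:
    """Validated focal follows, behaviour events and demographics.

    ``demographics`` is indexed by individual id; ``follows`` holds one row per
    retained follow with ``party_member_ids`` as a tuple of ids; ``events`` one
    row per dyadic behaviour event.  ``excluded_follows`` logs follows removed
    by the minimum in-view filter.
    """

    demographics: pd.DataFrame
    follows: pd.DataFrame
    events: pd.DataFrame
    excluded_follows: pd.DataFrame

    @property
    def ids(self) -> list:
        return list(self.demographics.index)

    def group_of(self, individual: str) -> str:
        return self.demographics.at[individual, "group_id"]

    def individuals_in_group(self, group_id: str) -> list:
        dem = self.demographics
        return list(dem.index[dem["group_id"] == group_id])

    @property
    def group_ids(self) -> list:
        return sorted(self.demographics["group_id"].unique())

    @classmethod
    def from_frames(
        cls,
        follows: pd.DataFrame,
        events: pd.DataFrame,
        demographics: pd.DataFrame,
        min_in_view: float | None = DEFAULT_MIN_IN_VIEW,
    ) -> "ObservationDataset":
        demographics = _validate_demographics(demographics.copy())
        follows = _validate_follows(follows.copy(), demographics)
        events = _validate_events(events.copy(), demographics)
        if min_in_view is not None:
            keep = follows["in_view_seconds"] >= float(min_in_view)
            excluded = follows.loc[~keep].copy()
            follows = follows.loc[keep].reset_index(drop=True)
        else:
            excluded = follows.iloc[0:0].copy()
        return cls(
            demographics=demographics,
            follows=follows,
            events=events.reset_index(drop=True),
            excluded_follows=excluded.reset_index(drop=True),
        )


def load_dataset(
    focal_path,
    events_path,
    demographics_path,
    min_in_view: float | None = DEFAULT_MIN_IN_VIEW,
) -> ObservationDataset:
    """Read the three CSV tables and return a validated dataset.

    Files are UTF-8, comma-delimited, with a mandatory header row; missing
    values are empty fields; dates are ISO-8601; the follow table's
    ``party_member_ids`` column is a ``;``-separated list of ids.
    """
    demographics = pd.read_csv(demographics_path, dtype={"id": str})
    follows = pd.read_csv(focal_path, dtype={"follow_id": str, "focal_id": str})
    events = pd.read_csv(events_path, dtype={"id_a": str, "id_b": str})
    party = follows.get("party_member_ids")
    if party is None:
        raise DataValidationError("follow table lacks a party_member_ids column")
    follows["party_member_ids"] = [
        tuple(p for p in str(cell).split(_PARTY_SEP) if p)
        if isinstance(cell, str) and cell
        else ()
        for cell in party.fillna("")
    ]
    return ObservationDataset.from_frames(
        follows, events, demographics, min_in_view=min_in_view
    )


def write_dataset(dataset: ObservationDataset, out_dir) -> dict:
    """Write the three CSV tables; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    follows = dataset.follows.copy()
    follows["party_member_ids"] = [
        _PARTY_SEP.join(p) for p in follows["party_member_ids"]
    ]
    paths = {
        "focal": out / "focal_follows.csv",
        "events": out / "behaviour_events.csv",
        "demographics": out / "demographics.csv",
    }
    follows.to_csv(paths["focal"], index=False)
    dataset.events.to_csv(paths["events"], index=False)
    dataset.demographics.reset_index().to_csv(paths["demographics"], index=False)
    return paths


# ---------------------------------------------------------------------------
# validation helpers


def _parse_dates(series: pd.Series, table: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna())[0])
        raise DataValidationError(
            f"{table}: malformed date {series.iloc[row]!r} in row {row}"
        )
    return parsed.dt.date


def _validate_demographics(dem: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "group_id", "origin", "sex", "age_years", "rank"}
    missing = required - set(dem.columns)
    if missing:
        raise DataValidationError(f"demographics: missing columns {sorted(missing)}")
    if dem["id"].duplicated().any():
        dup = dem.loc[dem["id"].duplicated(), "id"].iloc[0]
        raise DataValidationError(f"demographics: duplicate id {dup!r}")
    if not dem["origin"].isin(ORIGINS).all():
        bad = dem.loc[~dem["origin"].isin(ORIGINS)].index[0]
        raise DataValidationError(f"demographics: unknown origin in row {bad}")
    if not dem["sex"].isin(("F", "M")).all():
        raise DataValidationError("demographics: sex must be F or M")
    if (dem["age_years"] < 0).any():
        raise DataValidationError("demographics: negative age_years")
    if "arrival_age_years" not in dem.columns:
        dem["arrival_age_years"] = np.nan
    sanctuary_with_arrival = (dem["origin"] == "sanctuary") & dem[
        "arrival_age_years"
    ].notna()
    if sanctuary_with_arrival.any():
        bad = dem.loc[sanctuary_with_arrival, "id"].iloc[0]
        raise DataValidationError(
            f"demographics: sanctuary-born {bad!r} has an arrival age"
        )
    if "matriline_id" not in dem.columns:
        dem["matriline_id"] = pd.NA
    return dem.set_index("id")


def _validate_follows(follows: pd.DataFrame, dem: pd.DataFrame) -> pd.DataFrame:
    required = {"follow_id", "focal_id", "date", "group_id", "in_view_seconds",
                "party_member_ids"}
    missing = required - set(follows.columns)
    if missing:
        raise DataValidationError(f"follows: missing columns {sorted(missing)}")
    if follows["follow_id"].duplicated().any():
        dup = follows.loc[follows["follow_id"].duplicated(), "follow_id"].iloc[0]
        raise DataValidationError(f"follows: duplicate follow_id {dup!r}")
    follows["date"] = _parse_dates(follows["date"], "follows")
    if (follows["in_view_seconds"] <= 0).any():
        raise DataValidationError("follows: in_view_seconds must be positive")
    known = set(dem.index)
    for row, (focal, party, group) in enumerate(
        zip(follows["focal_id"], follows["party_member_ids"], follows["group_id"])
    ):
        if focal not in known:
            raise DataValidationError(f"follows: unknown focal {focal!r} in row {row}")
        if dem.at[focal, "group_id"] != group:
            raise DataValidationError(
                f"follows: focal {focal!r} listed under group {group!r} in row {row}"
            )
        for member in party:
            if member not in known:
                raise DataValidationError(
                    f"follows: unknown party member {member!r} in row {row}"
                )
            if member == focal:
                raise DataValidationError(
                    f"follows: focal {focal!r} appears in its own party (row {row})"
                )
    return follows


def _validate_events(events: pd.DataFrame, dem: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "behaviour", "id_a", "id_b", "group_id"}
    missing = required - set(events.columns)
    if missing:
        raise DataValidationError(f"events: missing columns {sorted(missing)}")
    if len(events) == 0:
        events["date"] = pd.Series(dtype=object)
        return events
    events["date"] = _parse_dates(events["date"], "events")
    if not events["behaviour"].isin(BEHAVIOURS).all():
        bad = events.loc[~events["behaviour"].isin(BEHAVIOURS)].index[0]
        raise DataValidationError(f"events: unknown behaviour in row {bad}")
    known = set(dem.index)
    for row, (a, b) in enumerate(zip(events["id_a"], events["id_b"])):
        if a == b:
            raise DataValidationError(f"events: self-dyad {a!r} in row {row}")
        for i in (a, b):
            if i not in known:
                raise DataValidationError(f"events: unknown id {i!r} in row {row}")
    return events


# ---------------------------------------------------------------------------
# daily one-zero aggregation


def aggregate_daily(dataset: ObservationDataset, behaviour: str) -> list[DailyRecord]:
    """Collapse follows and events into per-(date, group) one-zero records.

    An individual is *identified* on a day if it was a focal subject, appeared
    in any focal's party composition, or participated in a coded event that
    day.  A dyad is *associated* if it had at least one event of ``behaviour``
    that day, regardless of the event count.  Days with no observation in a
    group produce no record.
    """
    if behaviour not in BEHAVIOURS:
        raise ValueError(f"unknown behaviour {behaviour!r}")
    identified: dict = defaultdict(set)
    for focal, party, date, group in zip(
        dataset.follows["focal_id"],
        dataset.follows["party_member_ids"],
        dataset.follows["date"],
        dataset.follows["group_id"],
    ):
        key = (group, date)
        identified[key].add(focal)
        identified[key].update(party)
    dyads: dict = defaultdict(set)
    events = dataset.events
    mask = events["behaviour"] == behaviour if len(events) else slice(0, 0)
    for a, b, date, group in zip(
        events.loc[mask, "id_a"],
        events.loc[mask, "id_b"],
        events.loc[mask, "date"],
        events.loc[mask, "group_id"],
    ):
        key = (group, date)
        identified[key].update((a, b))
        dyads[key].add((a, b) if a < b else (b, a))
    records = [
        DailyRecord(
            date=date,
            group_id=group,
            behaviour=behaviour,
            identified_ids=frozenset(identified[(group, date)]),
            associated_dyads=frozenset(dyads.get((group, date), ())),
        )
        for (group, date) in sorted(identified)
    ]
    return records


def daily_to_frame(records: Iterable[DailyRecord]) -> pd.DataFrame:
    """Long-format export of daily records (one row per id or dyad per day)."""
    rows = []
    for rec in records:
        for i in sorted(rec.identified_ids):
            rows.append(
                (rec.date, rec.group_id, rec.behaviour, "identified", i, "")
            )
        for a, b in sorted(rec.associated_dyads):
            rows.append((rec.date, rec.group_id, rec.behaviour, "associated", a, b))
    return pd.DataFrame(
        rows, columns=["date", "group_id", "behaviour", "status", "id_a", "id_b"]
    )


# ---------------------------------------------------------------------------
# inter-observer reliability


def cohens_kappa(codes_a: Sequence, codes_b: Sequence) -> float:
    """Cohen's kappa for two coders' categorical sequences.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the product
    of the coders' marginal category frequencies.  Perfect agreement returns
    1.0 even when a single category makes p_e = 1.
    """
    a = np.asarray(codes_a, dtype=object)
    b = np.asarray(codes_b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("code sequences must be one-dimensional and equal length")
    if len(a) == 0:
        raise ValueError("empty code sequences")
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
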