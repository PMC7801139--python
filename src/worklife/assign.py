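"""Daily labor-market state assignment from overlapping register episodes.

Register spells (earnings periods, sickness allowances, pensions,
unemployment benefits ...) overlap freely: a person can draw an
unemployment benefit while having an earnings period, or a partial
disability pension with or without concurrent earnings.  This module
resolves each calendar day to exactly one of the seven labor-market
states and run-length-encodes the result into a gap-free trajectory.

Resolution rules for a day, in order of increasing priority (a later
rule overrides an earlier one), with the residual state being economic
inactivity when no episode covers the day:

1. earnings or part-time sickness allowance        -> work
   (part-time sickness beneficiaries must work part-time, so they count
   as being at work; a partial disability pension with concurrent
   earnings also resolves to work via the earnings spell)
2. any unemployment benefit or unemployment pension -> unemployment
   (unemployment overrules concurrent earnings)
3. full sickness allowance, vocational rehabilitation, temporary
   disability pension, or partial disability pension WITHOUT concurrent
   earnings                                         -> time-restricted
                                                       work disability
4. permanent full disability pension               -> disability retirement
5. old-age or early pension                        -> retirement
6. death                                           -> death

Priority is given to non-working states to avoid understating working
years lost; among non-working states, ill health ranks above
unemployment (configurable by reordering ``_OVERLAYS``).

Trajectories are clipped at the study window and at age 63: the last
included day is the day before the 63rd-birthday anniversary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import (
    CANONICAL_STATES,
    DEATH,
    DISABILITY_RETIREMENT,
    INACTIVITY,
    RETIREMENT,
    TRWD,
    UNEMPLOYMENT,
    WORK,
    TransitionStructure,
)

DAYS_PER_YEAR = 365.25

EPISODE_TYPES = (
    "earnings",
    "sickness_allowance_full",
    "sickness_allowance_parttime",
    "vocational_rehabilitation",
    "temporary_disability_pension",
    "partial_disability_pension",
    "full_disability_pension",
    "unemployment_benefit",
    "unemployment_pension",
    "oldage_or_early_pension",
    "death",
)

_TYPE_CODE = {t: i for i, t in enumerate(EPISODE_TYPES)}
_STATE_CODE = {s: i for i, s in enumerate(CANONICAL_STATES)}


class DataError(ValueError):
    """Episode data violating the input contract."""


def add_years(d: dt.date, years: int) -> dt.date:
    """Calendar anniversary; Feb 29 maps to Mar 1 in non-leap years."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return dt.date(d.year + years, 3, 1)


def age_years(birth_date: dt.date, on: dt.date) -> float:
    """Age in fractional years, day grain: days alive / 365.25."""
    return (on - birth_date).days / DAYS_PER_YEAR


@dataclass
class EpisodeRecord:
    """One raw register spell; dates are closed (both days included)."""

    person_id: int
    episode_type: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self):
        if self.episode_type not in _TYPE_CODE:
            raise DataError(f"unknown episode type {self.episode_type!r}")
        if self.start_date > self.end_date:
            raise DataError(
                f"episode for person {self.person_id} ends before it starts"
            )


@dataclass
class StateTrajectory:
    """A person's gap-free daily-state sequence, run-length encoded.

    ``intervals`` holds (state, start_day, end_day) triples in day offsets
    from ``baseline_date`` with closed endpoints; consecutive intervals
    abut and carry different states.
    """

    person_id: int
    baseline_date: dt.date
    birth_date: dt.date
    intervals: list[tuple[str, int, int]]
    censor_reason: str  # age_63 | study_end | death

    @property
    def entry_date(self) -> dt.date:
        return self.baseline_date + dt.timedelta(days=int(self.intervals[0][1]))

    @property
    def censor_day(self) -> int:
        return int(self.intervals[-1][2])

    @property
    def censor_date(self) -> dt.date:
        return self.baseline_date + dt.timedelta(days=self.censor_day)

    @property
    def n_days(self) -> int:
        return self.censor_day - int(self.intervals[0][1]) + 1

    def age_at_day(self, day: int) -> float:
        """Age in fractional years at a day offset from baseline."""
        return ((self.baseline_date - self.birth_date).days + day) / DAYS_PER_YEAR

    def to_frame(self) -> pd.DataFrame:
        base = self.baseline_date
        return pd.DataFrame(
            {
                "person_id": self.person_id,
                "state": [s for s, _, _ in self.intervals],
                "start_date": [base + dt.timedelta(days=int(a)) for _, a, _ in self.intervals],
                "end_date": [base + dt.timedelta(days=int(b)) for _, _, b in self.intervals],
            }
        )


def validate_trajectory(traj: StateTrajectory, structure: TransitionStructure) -> None:
    """Check contiguity, state alternation and allowed transitions."""
    iv = traj.intervals
    for i, (state, a, b) in enumerate(iv):
        if a > b:
            raise DataError(f"person {traj.person_id}: interval {i} reversed")
        if i > 0:
            prev_state, _, prev_end = iv[i - 1]
            if a != prev_end + 1:
                raise DataError(f"person {traj.person_id}: gap before interval {i}")
            if state == prev_state:
                raise DataError(f"person {traj.person_id}: repeated state at {i}")
            if not structure.is_allowed(prev_state, state):
                raise DataError(
                    f"person {traj.person_id}: disallowed transition "
                    f"{prev_state} -> {state}"
                )


# masks consumed by the overlay rules
_EARNINGS = _TYPE_CODE["earnings"]
_PT_SICK = _TYPE_CODE["sickness_allowance_parttime"]
_ILL_FULL = (
    _TYPE_CODE["sickness_allowance_full"],
    _TYPE_CODE["vocational_rehabilitation"],
    _TYPE_CODE["temporary_disability_pension"],
)
_PARTIAL_DIS = _TYPE_CODE["partial_disability_pension"]
_FULL_DIS = _TYPE_CODE["full_disability_pension"]
_UNEMP = (_TYPE_CODE["unemployment_benefit"], _TYPE_CODE["unemployment_pension"])
_OLDAGE = _TYPE_CODE["oldage_or_early_pension"]
_DEATH = _TYPE_CODE["death"]


def _assign_one(
    person_id: int,
    birth_date: dt.date,
    baseline_date: dt.date,
    study_end_date: dt.date,
    types: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> StateTrajectory:
    """Resolve one person's episodes (day offsets from baseline) to a trajectory."""
    study_end_day = (study_end_date - baseline_date).days
    age63_last_day = (add_years(birth_date, 63) - baseline_date).days - 1
    censor_day = min(study_end_day, age63_last_day)
    censor_reason = "age_63" if age63_last_day <= study_end_day else "study_end"
    if censor_day < 0:
        raise DataError(f"person {person_id} is 63 or older at baseline")

    death_rows = types == _DEATH
    death_day = None
    if death_rows.any():
        death_day = int(starts[death_rows].min())
        if (starts[~death_rows] > death_day).any():
            raise DataError(f"person {person_id} has episodes after death")
        if death_day <= censor_day:
            censor_day = death_day
            censor_reason = "death"

    n_days = censor_day + 1
    # per-day boolean masks over the clipped window
    masks = {
        key: np.zeros(n_days, dtype=bool)
        for key in ("earn", "pt", "ill", "part", "unemp", "fdis", "old")
    }
    for t, a, b in zip(types, starts, ends):
        if b < 0 or a > censor_day:
            continue
        a = max(int(a), 0)
        b = min(int(b), censor_day)
        if t == _EARNINGS:
            masks["earn"][a : b + 1] = True
        elif t == _PT_SICK:
            masks["pt"][a : b + 1] = True
        elif t in _ILL_FULL:
            masks["ill"][a : b + 1] = True
        elif t == _PARTIAL_DIS:
            masks["part"][a : b + 1] = True
        elif t in _UNEMP:
            masks["unemp"][a : b + 1] = True
        elif t == _FULL_DIS:
            masks["fdis"][a : b + 1] = True
        elif t == _OLDAGE:
            masks["old"][a : b + 1] = True
        # death handled via censor_day

    state = np.full(n_days, _STATE_CODE[INACTIVITY], dtype=np.int8)
    state[masks["earn"] | masks["pt"]] = _STATE_CODE[WORK]
    state[masks["unemp"]] = _STATE_CODE[UNEMPLOYMENT]
    state[masks["ill"] | (masks["part"] & ~masks["earn"])] = _STATE_CODE[TRWD]
    state[masks["fdis"]] = _STATE_CODE[DISABILITY_RETIREMENT]
    state[masks["old"]] = _STATE_CODE[RETIREMENT]
    if death_day is not None and death_day <= censor_day:
        state[death_day] = _STATE_CODE[DEATH]

    # run-length encode
    cuts = np.flatnonzero(np.diff(state)) + 1
    bounds = np.concatenate(([0], cuts, [n_days]))
    intervals = [
        (CANONICAL_STATES[state[a]], int(a), int(b - 1))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return StateTrajectory(
        person_id=person_id,
        baseline_date=baseline_date,
        birth_date=birth_date,
        intervals=intervals,
        censor_reason=censor_reason,
    )


def assign_daily_states(
    episodes: Iterable[EpisodeRecord] | pd.DataFrame,
    person: Mapping,
    window: tuple[dt.date, dt.date],
) -> StateTrajectory:
    """Resolve one person's episodes into a gap-free daily-state trajectory.

    Parameters
    ----------
    episodes
        The person's register spells (EpisodeRecord list or a DataFrame
        with ``episode_type``/``start_date``/``end_date`` columns).
    person
        Mapping with at least ``person_id`` and ``birth_date``.
    window
        (baseline_date, study_end_date); the trajectory covers the window
        clipped at age 63 and at death.
    """
    baseline, study_end = window
    if isinstance(episodes, pd.DataFrame):
        recs = [
            EpisodeRecord(
                person_id=r.person_id,
                episode_type=r.episode_type,
                start_date=_as_date(r.start_date),
                end_date=_as_date(r.end_date),
            )
            for r in episodes.itertuples()
        ]
    else:
        recs = list(episodes)
    pid = person["person_id"]
    for r in recs:
        if r.person_id != pid:
            raise DataError(f"episode for person {r.person_id} passed as {pid}")
    types = np.array([_TYPE_CODE[r.episode_type] for r in recs], dtype=np.int16)
    starts = np.array([(r.start_date - baseline).days for r in recs], dtype=np.int64)
    ends = np.array([(r.end_date - baseline).days for r in recs], dtype=np.int64)
    return _assign_one(
        pid, _as_date(person["birth_date"]), baseline, study_end, types, starts, ends
    )


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def assign_population(
    persons: pd.DataFrame,
    episodes: pd.DataFrame,
    window: tuple[dt.date, dt.date],
) -> list[StateTrajectory]:
    """Vectorized assignment for a whole persons/episodes table pair."""
    baseline, study_end = window
    ep = episodes
    bad = ~ep["episode_type"].isin(EPISODE_TYPES)
    if bad.any():
        raise DataError(
            f"unknown episode types: {sorted(ep.loc[bad, 'episode_type'].unique())}"
        )
    types = ep["episode_type"].map(_TYPE_CODE).to_numpy(dtype=np.int16)
    base = np.datetime64(baseline, "D")
    starts = (ep["start_date"].to_numpy(dtype="datetime64[D]") - base).astype(np.int64)
    ends = (ep["end_date"].to_numpy(dtype="datetime64[D]") - base).astype(np.int64)
    pids = ep["person_id"].to_numpy()

    order = np.argsort(pids, kind="stable")
    types, starts, ends, pids = types[order], starts[order], ends[order], pids[order]
    # slice boundaries per person
    uniq, first = np.unique(pids, return_index=True)
    slices = {
        u: slice(a, b)
        for u, a, b in zip(uniq, first, np.append(first[1:], len(pids)))
    }
    empty = (np.array([], dtype=np.int16), np.array([], dtype=np.int64), np.array([], dtype=np.int64))

    out = []
    for row in persons.itertuples():
        sl = slices.get(row.person_id)
        if sl is None:
            t, s, e = empty
        else:
            t, s, e = types[sl], starts[sl], ends[sl]
        out.append(
            _assign_one(
                row.person_id, _as_date(row.birth_date), baseline, study_end, t, s, e
            )
        )
    return out


def trajectories_to_frame(trajectories: Sequence[StateTrajectory]) -> pd.DataFrame:
    """Long table (person_id, state, start_date, end_date) for CSV export."""
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
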