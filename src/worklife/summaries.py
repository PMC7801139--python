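"""Expected length of stay, WLE/WYL decomposition, and bootstrap CIs.

The expected length of stay (ELOS) in state j over the window from the
start age s to the horizon, for someone in the work state at s, is

    ELOS_j = integral_s^horizon P_{work,j}(s, u) du.

Because the Aalen-Johansen estimator of P is a right-continuous step
function on the pooled event-age grid, the integral is computed exactly
as a left-endpoint sum over grid intervals.  Working life expectancy
(WLE) is ELOS in the work state; working years lost (WYL) are the ELOS
of each of the six non-work states, and the total WYL equals the window
length (13 years for ages 50-63) minus WLE — the seven components sum
to the window length because the rows of P sum to one at every age.

Uncertainty is quantified by a percentile bootstrap: persons (not
records) are resampled with replacement, the whole estimation is re-run
per resample, and the 2.5th/97.5th percentiles of each quantity across
replicates form the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assign import StateTrajectory
from .estimation import (
    HORIZON_AGE,
    START_AGE,
    TransitionProbabilityMatrix,
    aalen_johansen,
    fit_all_transitions,
    to_transition_records,
)
from .states import WORK, TransitionStructure

#: order in which WYL components are reported
WYL_STATES = (
    "time_restricted_work_disability",
    "disability_retirement",
    "death",
    "unemployment",
    "economic_inactivity",
    "retirement",
)


def elos(
    P: TransitionProbabilityMatrix,
    start_state: str = WORK,
    horizon: float | None = None,
) -> pd.Series:
    """Expected years in each state over [s, horizon], starting in ``start_state``.

    Exact left-endpoint integration of the step-function estimator:
    sum over grid intervals of P_{start,j}(s, left endpoint) x width.
    """
    if horizon is None:
        horizon = P.horizon
    if horizon > P.horizon + 1e-12:
        raise ValueError(
            f"probability grid covers [{P.start_age}, {P.horizon}], "
            f"requested horizon {horizon}"
        )
    row = P.states.index(start_state)
    lefts = P.grid
    rights = np.append(P.grid[1:], horizon)
    widths = np.clip(rights, None, horizon) - np.clip(lefts, None, horizon)
    occ = P.matrices[:, row, :]  # P_{start,j}(s, left endpoint)
    years = occ.T @ widths
    return pd.Series(years, index=list(P.states), name="elos_years")


@dataclass
class LifecourseSummary:
    """WLE and its WYL decomposition for one covariate profile.

    All quantities are years within the window [start_age, horizon_age];
    ``ci`` maps a quantity name ("wle", "total_wyl", or a WYL state) to
    its (2.5th, 97.5th) percentile bootstrap bounds.
    """

    gender: str
    profile_label: str
    covariate_profile: tuple[float, ...]
    wle: float
    wyl_by_state: dict[str, float]
    start_age: float = START_AGE
    horizon_age: float = HORIZON_AGE
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def window_years(self) -> float:
        return self.horizon_age - self.start_age

    @property
    def total_wyl(self) -> float:
        return self.window_years - self.wle

    def validate(self, tol: float = 1e-8) -> None:
        """Person-time conservation and nonnegativity checks."""
        total = self.wle + sum(self.wyl_by_state.values())
        if abs(total - self.window_years) > tol:
            raise AssertionError(
                f"WLE + WYL components = {total!r}, window is {self.window_years!r}"
            )
        if self.wle < -tol or any(v < -tol for v in self.wyl_by_state.values()):
            raise AssertionError("negative expected length of stay")

    def as_dict(self) -> dict[str, float]:
        out = {"wle": self.wle}
        out.update({s: self.wyl_by_state[s] for s in WYL_STATES})
        out["total_wyl"] = self.total_wyl
        return out


def wle_wyl(
    elos_years: pd.Series,
    gender: str = "",
    profile_label: str = "",
    covariate_profile: Sequence[float] = (),
    start_age: float = START_AGE,
    horizon_age: float = HORIZON_AGE,
) -> LifecourseSummary:
    """Split per-state ELOS into WLE (work) and the six WYL components."""
    return LifecourseSummary(
        gender=gender,
        profile_label=profile_label,
        covariate_profile=tuple(covariate_profile),
        wle=float(elos_years[WORK]),
        wyl_by_state={s: float(elos_years[s]) for s in WYL_STATES},
        start_age=start_age,
        horizon_age=horizon_age,
    )


def wyl_difference(a: LifecourseSummary, b: LifecourseSummary) -> dict[str, float]:
    """Componentwise a - b: Delta WLE and Delta WYL per non-work state.

    Used for exposed-minus-nonexposed contrasts; both summaries must
    come from the same gender stratum and age window.
    """
    if a.gender != b.gender:
        raise ValueError(f"gender mismatch: {a.gender!r} vs {b.gender!r}")
    if (a.start_age, a.horizon_age) != (b.start_age, b.horizon_age):
        raise ValueError("age windows differ")
    out = {"wle": a.wle - b.wle}
    for s in WYL_STATES:
        out[s] = a.wyl_by_state[s] - b.wyl_by_state[s]
    out["total_wyl"] = a.total_wyl - b.total_wyl
    return out


def bootstrap_ci(
    persons: pd.DataFrame,
    trajectories: Sequence[StateTrajectory],
    structure: TransitionStructure,
    covariate_columns: Sequence[str],
    profiles: Mapping[str, Sequence[float]],
    B: int = 100,
    seed: int = 0,
    start_state: str = WORK,
    s: float = START_AGE,
    horizon: float = HORIZON_AGE,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Percentile bootstrap over persons for every profile's summary.

    Persons are resampled with replacement (original size); the full
    pipeline — all transition Cox fits, the product integral, ELOS — is
    re-run per resample via case weights (a person drawn k times enters
    with weight k).  A resample where some transition has zero events is
    legitimate: that transition contributes no flow.  Returns, per
    profile label, {quantity: (2.5th, 97.5th percentile)}.

    One master seed spawns an independent stream per replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    records = to_transition_records(trajectories, persons, structure, covariate_columns)
    pids = persons["person_id"].to_numpy()
    n = len(pids)
    quantities = ["wle", *WYL_STATES, "total_wyl"]
    draws = {label: np.empty((B, len(quantities))) for label in profiles}

    streams = [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(B)]
    for b, rng in enumerate(streams):
        counts = np.bincount(rng.integers(0, n, n), minlength=n).astype(float)
        weights = pd.Series(counts, index=pids)
        fits = fit_all_transitions(
            records, structure, covariate_columns, person_weights=weights
        )
        for label, prof in profiles.items():
            P = aalen_johansen(fits, structure, profile=prof, s=s, horizon=horizon)
            summ = wle_wyl(
                elos(P, start_state=start_state),
                profile_label=label,
                covariate_profile=prof,
                start_age=s,
                horizon_age=horizon,
            )
            draws[label][b] = [summ.as_dict()[q] for q in quantities]

    out: dict[str, dict[str, tuple[float, float]]] = {}
    for label, mat in draws.items():
        lo = np.percentile(mat, 2.5, axis=0)
        hi = np.percentile(mat, 97.5, axis=0)
        out[label] = {q: (float(lo[i]), float(hi[i])) for i, q in enumerate(quantities)}
    return out


def summaries_to_frame(summaries: Sequence[LifecourseSummary]) -> pd.DataFrame:
    """Table-shaped output: one row per profile, WLE and six WYL columns
    with CI bounds (full precision; round on presentation only)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "gender": s.gender,
            "profile": s.profile_label,
            "wle": s.wle,
        }
        if "wle" in s.ci:
            row["wle_lo"], row["wle_hi"] = s.ci["wle"]
        for st in WYL_STATES:
            row[f"wyl_{st}"] = s.wyl_by_state[st]
            if st in s.ci:
                row[f"wyl_{st}_lo"], row[f"wyl_{st}_hi"] = s.ci[st]
        row["total_wyl"] = s.total_wyl
        if "total_wyl" in s.ci:
            row["total_wyl_lo"], row["total_wyl_hi"] = s.ci["total_wyl"]
        rows.append(row)
    return pd.DataFrame(rows)
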