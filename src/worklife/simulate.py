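"""Synthetic register-data generator.

Emulates the structure of Finnish register extracts without any real
data: persons aged 50-63 who are in the workforce (work state) at a
common baseline date, followed to a study end date with administrative
censoring at age 63.  Latent labor-market careers are drawn from a
continuous-time Markov chain on the seven-state space with
piecewise-constant baseline intensities over age bands and proportional
covariate effects (occupational class, physical-workload exposure
category).  The latent career is then rendered back into raw register
spells — earnings periods for work, benefit spells for the other states
— and a configurable fraction of benefit spells is deliberately
overlapped by spurious earnings periods so the day-level priority rules
downstream are exercised.

The default scenario's intensities and log hazard ratios are test
fixtures chosen to be epidemiologically plausible (return-to-work rates
dominate exits; manual work and high physical workload raise ill-health
exit intensities; retirement intensity jumps at the early-retirement
age of 62).  They are not estimates of any real population's rates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assign import DAYS_PER_YEAR, StateTrajectory, add_years
from .design import add_design_columns
from .exposure import FACTORS, JEMTable, attach_exposure
from .states import (
    CANONICAL_STATES,
    DEATH,
    DISABILITY_RETIREMENT,
    INACTIVITY,
    RETIREMENT,
    TRWD,
    UNEMPLOYMENT,
    WORK,
    ConfigurationError,
    TransitionStructure,
    canonical_state_space,
    build_transition_structure,
)

Pair = tuple[str, str]


@dataclass
class SimulationConfig:
    """Scenario definition for the synthetic register generator.

    ``intensities`` maps an allowed transition to either a constant rate
    (events per person-year) or a piecewise-constant ``(breaks, rates)``
    pair where ``breaks`` are ascending ages and ``rates[i]`` applies on
    ``[breaks[i], breaks[i+1])`` (the last band is open-ended).
    ``effects`` maps a transition to {covariate column: log hazard ratio}.
    """

    n_persons: int
    seed: int
    baseline_date: dt.date = dt.date(2005, 1, 1)
    study_end_date: dt.date = dt.date(2014, 10, 31)
    age_range_at_entry: tuple[float, float] = (50.0, 63.0)
    intensities: Mapping[Pair, object] = field(default_factory=dict)
    effects: Mapping[Pair, Mapping[str, float]] = field(default_factory=dict)
    class_distribution: Mapping[str, float] = field(
        default_factory=lambda: {
            "manual": 0.31,
            "lower_non_manual": 0.33,
            "upper_non_manual": 0.21,
            "self_employed": 0.15,
        }
    )
    class_occupations: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_OCCUPATIONS)
    )
    jem_table: pd.DataFrame | None = None
    overlap_rate: float = 0.2
    exposure_threshold: float = 0.40

    def __post_init__(self):
        if self.jem_table is None:
            self.jem_table = default_jem_frame()
        total = sum(self.class_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_distribution sums to {total}, expected 1"
            )


# occupation codes per class (loosely ISCO-styled labels; synthetic)
_DEFAULT_CLASS_OCCUPATIONS = {
    "manual": ("9330", "7129"),
    "lower_non_manual": ("4190", "5123"),
    "upper_non_manual": ("2310",),
    "self_employed": ("6110", "1310"),
}

# synthetic JEM rows: occupation -> five exposure probabilities, by gender
_DEFAULT_JEM_ROWS = [
    # code, gender, heavy, kneel, loads, shoulder, trunk
    ("9330", "man", 0.85, 0.55, 0.60, 0.45, 0.70),
    ("9330", "woman", 0.80, 0.50, 0.30, 0.35, 0.72),
    ("7129", "man", 0.60, 0.48, 0.35, 0.44, 0.55),
    ("7129", "woman", 0.55, 0.42, 0.15, 0.30, 0.58),
    ("4190", "man", 0.05, 0.03, 0.02, 0.04, 0.08),
    ("4190", "woman", 0.10, 0.15, 0.05, 0.03, 0.18),
    ("5123", "man", 0.42, 0.20, 0.25, 0.15, 0.45),
    ("5123", "woman", 0.45, 0.35, 0.20, 0.10, 0.41),
    ("2310", "man", 0.02, 0.01, 0.01, 0.03, 0.04),
    ("2310", "woman", 0.01, 0.04, 0.00, 0.06, 0.09),
    ("6110", "man", 0.70, 0.60, 0.55, 0.30, 0.65),
    ("6110", "woman", 0.55, 0.45, 0.42, 0.25, 0.60),
    ("1310", "man", 0.20, 0.10, 0.12, 0.10, 0.22),
    ("1310", "woman", 0.18, 0.12, 0.08, 0.12, 0.25),
]


def default_jem_frame() -> pd.DataFrame:
    return pd.DataFrame(
        _DEFAULT_JEM_ROWS, columns=["occupation_code", "gender", *FACTORS]
    )


def default_intensities() -> dict[Pair, object]:
    """Baseline transition intensities (per person-year) for the default scenario.

    Chosen so the reference profile spends roughly 10 of the 13 potential
    years at work, with short, mostly-reversible sickness spells and an
    early-retirement surge from age 62 — the occupancy pattern a cohort
    of 50-63-year-old workers plausibly shows.
    """
    ret_band = ([50.0, 62.0], [0.007, 0.55])  # early retirement opens at 62
    return {
        (WORK, TRWD): 0.12,
        (WORK, UNEMPLOYMENT): 0.045,
        (WORK, INACTIVITY): 0.016,
        (WORK, DISABILITY_RETIREMENT): 0.005,
        (WORK, RETIREMENT): ret_band,
        (WORK, DEATH): 0.002,
        (TRWD, WORK): 3.0,
        (TRWD, UNEMPLOYMENT): 0.08,
        (TRWD, INACTIVITY): 0.04,
        (TRWD, DISABILITY_RETIREMENT): 0.15,
        (TRWD, RETIREMENT): ret_band,
        (TRWD, DEATH): 0.01,
        (UNEMPLOYMENT, WORK): 0.42,
        (UNEMPLOYMENT, TRWD): 0.07,
        (UNEMPLOYMENT, INACTIVITY): 0.06,
        (UNEMPLOYMENT, DISABILITY_RETIREMENT): 0.02,
        (UNEMPLOYMENT, RETIREMENT): ret_band,
        (UNEMPLOYMENT, DEATH): 0.005,
        (INACTIVITY, WORK): 0.32,
        (INACTIVITY, TRWD): 0.05,
        (INACTIVITY, UNEMPLOYMENT): 0.10,
        (INACTIVITY, DISABILITY_RETIREMENT): 0.015,
        (INACTIVITY, RETIREMENT): ret_band,
        (INACTIVITY, DEATH): 0.005,
        (DISABILITY_RETIREMENT, RETIREMENT): 0.02,
        (DISABILITY_RETIREMENT, DEATH): 0.03,
        (RETIREMENT, DEATH): 0.015,
    }


def default_effects() -> dict[Pair, dict[str, float]]:
    """Log hazard ratios for the default scenario (fixtures, not estimates)."""
    return {
        (WORK, TRWD): {
            "class_manual": 0.20,
            "class_lower_non_manual": 0.08,
            "class_self_employed": -0.15,
            "exp_one_to_three": 0.15,
            "exp_four_to_five": 0.30,
        },
        (WORK, DISABILITY_RETIREMENT): {
            "class_manual": 0.30,
            "class_lower_non_manual": 0.10,
            "class_self_employed": -0.25,
            "exp_one_to_three": 0.20,
            "exp_four_to_five": 0.40,
        },
        (WORK, UNEMPLOYMENT): {
            "class_manual": 0.40,
            "class_lower_non_manual": 0.18,
            "class_self_employed": -1.00,
            "exp_one_to_three": 0.08,
            "exp_four_to_five": 0.15,
        },
        (TRWD, DISABILITY_RETIREMENT): {
            "class_manual": 0.15,
            "exp_four_to_five": 0.25,
        },
        (UNEMPLOYMENT, WORK): {
            "class_manual": -0.10,
            "class_self_employed": 0.25,
        },
        (WORK, DEATH): {"class_manual": 0.20},
    }


def default_config(n_persons: int = 2000, seed: int = 0, **overrides) -> SimulationConfig:
    """The standard test scenario: all 27 transitions active, class and
    exposure effects in the directions reported for real registers."""
    kw = dict(
        n_persons=n_persons,
        seed=seed,
        intensities=default_intensities(),
        effects=default_effects(),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class SimulatedData:
    """Bundle returned by :func:`simulate_population`."""

    persons: pd.DataFrame
    episodes: pd.DataFrame
    jem: JEMTable
    latent: list[StateTrajectory]
    config: SimulationConfig


class _Rates:
    """Per-transition piecewise-constant rates compiled against a structure."""

    def __init__(self, config: SimulationConfig, structure: TransitionStructure):
        self.breaks = set()
        self.per_state: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {}
        for (frm, to), spec in config.intensities.items():
            if not structure.is_allowed(frm, to):
                raise ConfigurationError(
                    f"intensity set for disallowed transition {frm} -> {to}"
                )
            if isinstance(spec, (int, float)):
                breaks = np.array([0.0])
                rates = np.array([float(spec)])
            else:
                b, r = spec
                breaks = np.asarray(b, dtype=float)
                rates = np.asarray(r, dtype=float)
                if len(breaks) != len(rates) or np.any(np.diff(breaks) <= 0):
                    raise ConfigurationError(
                        f"bad piecewise intensity for {frm} -> {to}"
                    )
            if np.any(rates < 0):
                raise ConfigurationError(
                    f"negative intensity for {frm} -> {to}"
                )
            self.breaks.update(breaks.tolist())
            self.per_state.setdefault(frm, []).append((to, breaks, rates))
        self.grid = np.array(sorted(b for b in self.breaks if b > 0.0))

    def rates_at(self, state: str, age: float) -> tuple[list[str], np.ndarray]:
        entries = self.per_state.get(state, [])
        tos, vals = [], []
        for to, breaks, rates in entries:
            i = np.searchsorted(breaks, age, side="right") - 1
            if i >= 0:
                tos.append(to)
                vals.append(rates[i])
        return tos, np.asarray(vals)

    def next_break(self, age: float) -> float:
        i = np.searchsorted(self.grid, age, side="right")
        return float(self.grid[i]) if i < len(self.grid) else np.inf


def _simulate_trajectory(
    rng: np.random.Generator,
    rates: _Rates,
    hr: Mapping[str, Mapping[str, float]],
    entry_age_days: int,
    birth_date: dt.date,
    baseline: dt.date,
    study_end: dt.date,
) -> StateTrajectory:
    """One latent career: competing exponentials within age bands, day grain."""
    study_end_day = (study_end - baseline).days
    age63_last_day = (add_years(birth_date, 63) - baseline).days - 1
    censor_day = min(study_end_day, age63_last_day)
    censor_reason = "age_63" if age63_last_day <= study_end_day else "study_end"

    a0 = entry_age_days / DAYS_PER_YEAR
    a_max = (entry_age_days + censor_day + 1) / DAYS_PER_YEAR

    intervals: list[tuple[str, int, int]] = []
    state = WORK
    age = a0
    seg_start = 0
    died = False
    while age < a_max:
        tos, base = rates.rates_at(state, age)
        lam = (
            np.array([base[i] * hr.get(state, {}).get(t, 1.0) for i, t in enumerate(tos)])
            if len(tos)
            else base
        )
        total = float(lam.sum()) if len(lam) else 0.0
        band_end = min(rates.next_break(age), a_max)
        if total <= 0.0:
            age = band_end
            continue
        wait = rng.exponential(1.0 / total)
        if age + wait >= band_end:
            age = band_end
            continue
        age += wait
        dest = tos[rng.choice(len(tos), p=lam / total)]
        # transition takes effect on the next day boundary; sojourns last >= 1 day
        day = max(int(np.floor((age - a0) * DAYS_PER_YEAR)) + 1, seg_start + 1)
        if day > censor_day:
            break
        intervals.append((state, seg_start, day - 1))
        seg_start = day
        state = dest
        if state == DEATH:
            censor_day = day
            censor_reason = "death"
            intervals.append((DEATH, day, day))
            died = True
            break
    if not died:
        intervals.append((state, seg_start, censor_day))
    return StateTrajectory(
        person_id=-1,
        baseline_date=baseline,
        birth_date=birth_date,
        intervals=intervals,
        censor_reason=censor_reason,
    )


# rendering: latent state -> register episode types
_TRWD_TYPES = (
    "sickness_allowance_full",
    "vocational_rehabilitation",
    "temporary_disability_pension",
    "partial_disability_pension",
)
_TRWD_P = (0.4, 0.2, 0.2, 0.2)


def _render_episodes(
    rng: np.random.Generator,
    traj: StateTrajectory,
    overlap_rate: float,
) -> list[tuple[int, str, int, int]]:
    """Render a latent trajectory as raw (possibly overlapping) spells.

    Returns (person_id, episode_type, start_day, end_day) tuples.  The
    rendering is constructed so that day-level priority resolution of the
    rendered spells recovers the latent trajectory exactly, including
    when spurious overlapping earnings spells are added.
    """
    out = []
    pid = traj.person_id
    entry_days = (traj.baseline_date - traj.birth_date).days

    def maybe_overlap(a: int, b: int):
        if overlap_rate > 0 and rng.random() < overlap_rate:
            s = int(rng.integers(a, b + 1))
            e = int(rng.integers(s, b + 1))
            out.append((pid, "earnings", s, e))

    for state, a, b in traj.intervals:
        if state == WORK:
            if b - a >= 60 and rng.random() < 0.15:
                cut = int(rng.integers(a + 1, b))
                out.append((pid, "earnings", a, cut))
                out.append((pid, "earnings", cut + 1, b))
            else:
                out.append((pid, "earnings", a, b))
            if b - a >= 30 and rng.random() < 0.10:
                s = int(rng.integers(a, b - 10))
                e = min(b, s + int(rng.integers(5, 30)))
                out.append((pid, "sickness_allowance_parttime", s, e))
        elif state == TRWD:
            kind = _TRWD_TYPES[rng.choice(4, p=_TRWD_P)]
            out.append((pid, kind, a, b))
            # a partial disability pension with earnings would resolve to
            # work, so spurious overlaps only go on the other spell kinds
            if kind != "partial_disability_pension":
                maybe_overlap(a, b)
        elif state == UNEMPLOYMENT:
            age_at_start = (entry_days + a) / DAYS_PER_YEAR
            kind = (
                "unemployment_pension"
                if age_at_start >= 60 and rng.random() < 0.3
                else "unemployment_benefit"
            )
            out.append((pid, kind, a, b))
            maybe_overlap(a, b)
        elif state == DISABILITY_RETIREMENT:
            out.append((pid, "full_disability_pension", a, b))
            maybe_overlap(a, b)
        elif state == RETIREMENT:
            out.append((pid, "oldage_or_early_pension", a, b))
            maybe_overlap(a, b)
        elif state == DEATH:
            out.append((pid, "death", a, a))
        # economic inactivity is the residual state: no episode

    return out


def simulate_population(config: SimulationConfig) -> SimulatedData:
    """Generate persons, latent careers, and raw overlapping episodes.

    Every person starts in the work state at the baseline date (the
    sampled population is the workforce) with entry age uniform over the
    configured range, and is censored at the earlier of age 63 and the
    study end date.
    """
    rng = np.random.default_rng(config.seed)
    structure = build_transition_structure(canonical_state_space())
    rates = _Rates(config, structure)
    jem = JEMTable(config.jem_table)

    lo, hi = config.age_range_at_entry
    lo_days = int(np.ceil(lo * DAYS_PER_YEAR))
    hi_days = int(np.floor(hi * DAYS_PER_YEAR))

    classes = list(config.class_distribution)
    probs = np.array([config.class_distribution[c] for c in classes])

    n = config.n_persons
    person_rows = []
    for pid in range(1, n + 1):
        gender = "man" if rng.random() < 0.5 else "woman"
        occ_class = classes[rng.choice(len(classes), p=probs)]
        codes = config.class_occupations[occ_class]
        code = codes[rng.integers(len(codes))]
        entry_age_days = int(rng.integers(lo_days, hi_days))
        birth = config.baseline_date - dt.timedelta(days=entry_age_days)
        person_rows.append(
            {
                "person_id": pid,
                "gender": gender,
                "occupational_class": occ_class,
                "occupation_code": code,
                "birth_date": birth,
                "entry_age": entry_age_days / DAYS_PER_YEAR,
            }
        )
    persons = pd.DataFrame(person_rows)

    # covariates driving the latent intensities
    with_exp, _ = attach_exposure(persons, jem, config.exposure_threshold)
    with_exp = add_design_columns(with_exp)
    cov_cols = [
        c
        for c in (
            "class_lower_non_manual",
            "class_manual",
            "class_self_employed",
            "exp_one_to_three",
            "exp_four_to_five",
        )
        if c in with_exp.columns
    ]
    cov = with_exp.set_index("person_id")[cov_cols]

    latent = []
    episode_rows = []
    for row in persons.itertuples():
        if row.person_id in cov.index:
            z = cov.loc[row.person_id]
        else:  # no JEM row: latent hazards use reference covariates
            z = pd.Series(dtype=float)
        hr: dict[str, dict[str, float]] = {}
        for (frm, to), eff in config.effects.items():
            lin = sum(float(z.get(c, 0.0)) * b for c, b in eff.items())
            hr.setdefault(frm, {})[to] = float(np.exp(lin))
        entry_age_days = (config.baseline_date - row.birth_date).days
        traj = _simulate_trajectory(
            rng,
            rates,
            hr,
            entry_age_days,
            row.birth_date,
            config.baseline_date,
            config.study_end_date,
        )
        traj.person_id = row.person_id
        latent.append(traj)
        episode_rows.extend(_render_episodes(rng, traj, config.overlap_rate))

    base = config.baseline_date
    episodes = pd.DataFrame(
        [
            {
                "person_id": pid,
                "episode_type": kind,
                "start_date": base + dt.timedelta(days=a),
                "end_date": base + dt.timedelta(days=b),
            }
            for pid, kind, a, b in episode_rows
        ],
        columns=["person_id", "episode_type", "start_date", "end_date"],
    )
    return SimulatedData(
        persons=persons, episodes=episodes, jem=jem, latent=latent, config=config
    )


# ---------------------------------------------------------------------------
# file formats


def write_outputs(data: SimulatedData, outdir) -> dict[str, str]:
    """Write persons.csv, episodes.csv and jem.csv (ISO dates, closed intervals)."""
    import os

    paths = {}
    os.makedirs(outdir, exist_ok=True)
    for name, df in (("persons", data.persons), ("episodes", data.episodes)):
        p = os.path.join(outdir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p
    p = os.path.join(outdir, "jem.csv")
    data.jem.to_csv(p)
    paths["jem"] = p
    return paths


def read_persons_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["birth_date"], dtype={"occupation_code": str})
    df["birth_date"] = df["birth_date"].dt.date
    return df


def read_episodes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start_date", "end_date"])
    df["start_date"] = df["start_date"].dt.date
    df["end_date"] = df["end_date"].dt.date
    return df


_PAIR_SEP = " -> "


def config_to_yaml(config: SimulationConfig) -> str:
    """Serialize a scenario to YAML (transition pairs as 'from -> to' keys)."""

    def pairkey(p: Pair) -> str:
        return f"{p[0]}{_PAIR_SEP}{p[1]}"

    intensities = {}
    for pair, spec in config.intensities.items():
        if isinstance(spec, (int, float)):
            intensities[pairkey(pair)] = float(spec)
        else:
            b, r = spec
            intensities[pairkey(pair)] = {
                "breaks": [float(x) for x in b],
                "rates": [float(x) for x in r],
            }
    obj = {
        "n_persons": config.n_persons,
        "seed": config.seed,
        "baseline_date": config.baseline_date.isoformat(),
        "study_end_date": config.study_end_date.isoformat(),
        "age_range_at_entry": list(config.age_range_at_entry),
        "overlap_rate": config.overlap_rate,
        "exposure_threshold": config.exposure_threshold,
        "class_distribution": dict(config.class_distribution),
        "class_occupations": {k: list(v) for k, v in config.class_occupations.items()},
        "intensities": intensities,
        "effects": {
            pairkey(p): dict(eff) for p, eff in config.effects.items()
        },
        "jem": default_jem_rows_from(config.jem_table),
    }
    return yaml.safe_dump(obj, sort_keys=False)


def default_jem_rows_from(jem_frame: pd.DataFrame) -> list[dict]:
    return jem_frame.to_dict(orient="records")


def config_from_yaml(text: str) -> SimulationConfig:
    obj = yaml.safe_load(text)

    def unpair(key: str) -> Pair:
        frm, to = key.split(_PAIR_SEP)
        return frm, to

    intensities: dict[Pair, object] = {}
    for key, spec in obj.get("intensities", {}).items():
        if isinstance(spec, dict):
            intensities[unpair(key)] = (spec["breaks"], spec["rates"])
        else:
            intensities[unpair(key)] = float(spec)
    effects = {unpair(k): dict(v) for k, v in obj.get("effects", {}).items()}
    jem = pd.DataFrame(obj["jem"]) if "jem" in obj else None
    return SimulationConfig(
        n_persons=int(obj["n_persons"]),
        seed=int(obj["seed"]),
        baseline_date=dt.date.fromisoformat(obj["baseline_date"]),
        study_end_date=dt.date.fromisoformat(obj["study_end_date"]),
        age_range_at_entry=tuple(obj.get("age_range_at_entry", (50.0, 63.0))),
        intensities=intensities,
        effects=effects,
        class_distribution=obj.get(
            "class_distribution",
            SimulationConfig(1, 0).class_distribution,
        ),
        class_occupations=obj.get(
            "class_occupations", dict(_DEFAULT_CLASS_OCCUPATIONS)
        ),
        jem_table=jem,
        overlap_rate=float(obj.get("overlap_rate", 0.2)),
        exposure_threshold=float(obj.get("exposure_threshold", 0.40)),
    )
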