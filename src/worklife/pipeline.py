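"""End-to-end orchestration: simulate/load -> assign -> expose -> fit ->
summarize -> bootstrap, with a manifest recording counts and exclusions.

The pipeline runs separately per gender (no gender covariate), mirrors
the register analysis's exclusion of persons with no occupational code
(missing JEM row), and optionally drops the self-employed (sensitivity
analysis).  Outputs are table-shaped CSVs of WLE and the six WYL
components with bootstrap CI bounds, a tidy coefficient table, an
optional per-factor CSV of exposed-minus-nonexposed WYL differences,
and a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .assign import StateTrajectory, assign_population, trajectories_to_frame
from .design import (
    CLASS_LEVELS,
    add_design_columns,
    design_columns,
    profile_for,
)
from .exposure import CATEGORIES, FACTORS, JEMTable, attach_exposure
from .estimation import (
    aalen_johansen,
    baselines_to_frame,
    fit_all_transitions,
    fits_to_frame,
    to_transition_records,
)
from .simulate import read_episodes_csv, read_persons_csv
from .states import ConfigurationError, build_transition_structure, canonical_state_space
from .summaries import (
    LifecourseSummary,
    WYL_STATES,
    bootstrap_ci,
    elos,
    summaries_to_frame,
    wle_wyl,
    wyl_difference,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    persons_csv: str
    episodes_csv: str
    jem_csv: str
    output_dir: str
    gender: str = "both"  # man | woman | both
    covariate_mode: str = "class"  # none | class | exposure | joint
    exclude_self_employed: bool = False
    start_age: float = 50.0
    horizon_age: float = 63.0
    B: int = 100
    seed: int = 0
    baseline_date: dt.date = dt.date(2005, 1, 1)
    study_end_date: dt.date = dt.date(2014, 10, 31)
    exposure_threshold: float = 0.40
    per_factor_differences: bool = False

    def __post_init__(self):
        if self.start_age >= self.horizon_age:
            raise ConfigurationError("start_age must be below horizon_age")
        if self.B < 1:
            raise ConfigurationError("B must be >= 1")
        if self.gender not in ("man", "woman", "both"):
            raise ConfigurationError(f"unknown gender filter {self.gender!r}")
        design_columns(self.covariate_mode)  # validates the mode

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        for key in ("baseline_date", "study_end_date"):
            if key in obj and isinstance(obj[key], str):
                obj[key] = dt.date.fromisoformat(obj[key])
        return cls(**obj)


@dataclass
class PipelineResult:
    """Everything one run produced."""

    summaries: list[LifecourseSummary]
    fits: dict[str, dict]  # gender -> {transition_id: TransitionCoxFit}
    differences: pd.DataFrame | None
    manifest: dict
    output_files: dict[str, str]


def _profiles_for_mode(mode: str) -> dict[str, Sequence[float]]:
    cols = design_columns(mode)
    if mode == "none":
        return {"all": ()}
    if mode == "class":
        return {c: profile_for(cols, occupational_class=c) for c in CLASS_LEVELS}
    if mode == "exposure":
        return {c: profile_for(cols, exposure_category=c) for c in CATEGORIES}
    # joint: class x exposure grid
    return {
        f"{c}|{e}": profile_for(cols, occupational_class=c, exposure_category=e)
        for c in CLASS_LEVELS
        for e in CATEGORIES
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Deterministic given the config's seed; emits summaries, coefficient
    tables and a manifest under ``config.output_dir``.
    """
    structure = build_transition_structure(canonical_state_space())
    persons = read_persons_csv(config.persons_csv)
    episodes = read_episodes_csv(config.episodes_csv)
    jem = JEMTable.from_csv(config.jem_csv)
    log.info("loaded %d persons, %d episodes", len(persons), len(episodes))

    manifest: dict = {
        "config": _config_dict(config),
        "package_version": __version__,
        "n_persons_read": int(len(persons)),
        "n_episodes_read": int(len(episodes)),
        "genders": {},
    }

    persons, excluded = attach_exposure(persons, jem, config.exposure_threshold)
    manifest["n_excluded_missing_jem"] = int(len(excluded))
    if config.exclude_self_employed:
        n0 = len(persons)
        persons = persons[persons["occupational_class"] != "self_employed"]
        manifest["n_excluded_self_employed"] = int(n0 - len(persons))
        log.info("sensitivity analysis: excluded %d self-employed", n0 - len(persons))
    persons = add_design_columns(persons)

    genders = [config.gender] if config.gender != "both" else ["man", "woman"]
    cov_cols = design_columns(config.covariate_mode)
    profiles = _profiles_for_mode(config.covariate_mode)
    window = (config.baseline_date, config.study_end_date)

    all_summaries: list[LifecourseSummary] = []
    all_fits: dict[str, dict] = {}
    diff_rows: list[dict] = []
    trajectories_frames = []

    for gender in genders:
        sub = persons[persons["gender"] == gender].reset_index(drop=True)
        eps = episodes[episodes["person_id"].isin(sub["person_id"])]
        log.info("gender %s: %d persons", gender, len(sub))
        trajectories = assign_population(sub, eps, window)
        trajectories_frames.append(trajectories_to_frame(trajectories))
        records = to_transition_records(trajectories, sub, structure, cov_cols)
        log.info(
            "gender %s: %d transition records, %d events",
            gender,
            len(records),
            int(records["status"].sum()),
        )
        fits = fit_all_transitions(records, structure, cov_cols)
        all_fits[gender] = fits

        cis = bootstrap_ci(
            sub,
            trajectories,
            structure,
            cov_cols,
            profiles,
            B=config.B,
            seed=config.seed,
            s=config.start_age,
            horizon=config.horizon_age,
        )
        for label, prof in profiles.items():
            P = aalen_johansen(
                fits, structure, profile=prof, s=config.start_age, horizon=config.horizon_age
            )
            summ = wle_wyl(
                elos(P),
                gender=gender,
                profile_label=label,
                covariate_profile=prof,
                start_age=config.start_age,
                horizon_age=config.horizon_age,
            )
            summ.ci = cis[label]
            summ.validate()
            all_summaries.append(summ)

        if config.per_factor_differences:
            diff_rows.extend(
                _per_factor_differences(
                    trajectories, sub, structure, gender, config
                )
            )

        manifest["genders"][gender] = {
            "n_persons": int(len(sub)),
            "n_records": int(len(records)),
            "n_events": int(records["status"].sum()),
        }

    differences = pd.DataFrame(diff_rows) if diff_rows else None

    os.makedirs(config.output_dir, exist_ok=True)
    outputs = {}
    summary_df = summaries_to_frame(all_summaries)
    outputs["summaries"] = os.path.join(config.output_dir, "summaries.csv")
    summary_df.to_csv(outputs["summaries"], index=False)
    coef_frames = []
    for gender, fits in all_fits.items():
        f = fits_to_frame(fits)
        f.insert(0, "gender", gender)
        coef_frames.append(f)
    outputs["coefficients"] = os.path.join(config.output_dir, "coefficients.csv")
    pd.concat(coef_frames, ignore_index=True).to_csv(outputs["coefficients"], index=False)
    base_frames = []
    for gender, fits in all_fits.items():
        f = baselines_to_frame(fits)
        f.insert(0, "gender", gender)
        base_frames.append(f)
    outputs["baseline_hazards"] = os.path.join(config.output_dir, "baseline_hazards.csv")
    pd.concat(base_frames, ignore_index=True).to_csv(
        outputs["baseline_hazards"], index=False
    )
    outputs["trajectories"] = os.path.join(config.output_dir, "trajectories.csv")
    pd.concat(trajectories_frames, ignore_index=True).to_csv(
        outputs["trajectories"], index=False
    )
    if differences is not None:
        outputs["wyl_differences"] = os.path.join(
            config.output_dir, "wyl_differences.csv"
        )
        differences.to_csv(outputs["wyl_differences"], index=False)
    manifest["output_files"] = outputs
    outputs["manifest"] = os.path.join(config.output_dir, "manifest.json")
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("wrote %d output files to %s", len(outputs), config.output_dir)

    return PipelineResult(
        summaries=all_summaries,
        fits=all_fits,
        differences=differences,
        manifest=manifest,
        output_files=outputs,
    )


def _per_factor_differences(
    trajectories: Sequence[StateTrajectory],
    persons: pd.DataFrame,
    structure,
    gender: str,
    config: RunConfig,
) -> list[dict]:
    """Exposed-minus-nonexposed Delta WYL per workload factor.

    For each of the five factors, refit all transitions with that
    factor's dichotomized exposure flag as the single covariate, then
    difference the exposed and non-exposed summaries.
    """
    rows = []
    for factor in FACTORS:
        col = f"exposed_{factor}"
        pers = persons.copy()
        pers[col] = pers[col].astype(float)
        records = to_transition_records(trajectories, pers, structure, (col,))
        fits = fit_all_transitions(records, structure, (col,))
        summs = {}
        for label, prof in (("exposed", (1.0,)), ("non_exposed", (0.0,))):
            P = aalen_johansen(
                fits, structure, profile=prof, s=config.start_age, horizon=config.horizon_age
            )
            summs[label] = wle_wyl(
                elos(P),
                gender=gender,
                profile_label=label,
                covariate_profile=prof,
                start_age=config.start_age,
                horizon_age=config.horizon_age,
            )
        delta = wyl_difference(summs["exposed"], summs["non_exposed"])
        row = {"gender": gender, "factor": factor, "delta_wle": delta["wle"]}
        row.update({f"delta_wyl_{s}": delta[s] for s in WYL_STATES})
        rows.append(row)
    return rows


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["baseline_date"] = config.baseline_date.isoformat()
    d["study_end_date"] = config.study_end_date.isoformat()
    return d
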