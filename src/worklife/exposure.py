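"""Physical-workload exposure from a gender-specific job-exposure matrix.

A JEM assigns each (occupation code, gender) pair the probability of
exposure to each of five physical workload factors.  Each probability is
dichotomized at a threshold (default 0.40: non-exposed below, exposed at
or above), the exposed factors are counted, and the count is classified
into three categories: no exposure, 1-3 factors, 4-5 factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

#: The five physical workload factors carried by the JEM.
FACTORS = (
    "heavy_physical_work",
    "kneeling_squatting",
    "manual_handling_heavy_loads",
    "hands_above_shoulder",
    "awkward_trunk_posture",
)

#: Exposure-count categories; "none" is the reference group.
CATEGORIES = ("none", "one_to_three", "four_to_five")

DEFAULT_THRESHOLD = 0.40


class JEMError(ValueError):
    """Invalid JEM table content."""


def dichotomize(jem_value: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff the exposure probability is at or above the threshold.

    The boundary is inclusive: a value of exactly 0.40 counts as exposed.
    """
    if not 0.0 <= jem_value <= 1.0:
        raise JEMError(f"JEM value {jem_value} outside [0, 1]")
    return jem_value >= threshold


def categorize(n_exposed: int) -> str:
    """Map an exposed-factor count 0-5 to its category label."""
    if n_exposed == 0:
        return "none"
    if 1 <= n_exposed <= 3:
        return "one_to_three"
    if 4 <= n_exposed <= 5:
        return "four_to_five"
    raise JEMError(f"exposed-factor count {n_exposed} outside 0-5")


@dataclass(frozen=True)
class ExposureProfile:
    """Per-factor exposure flags with their count and category."""

    flags: dict[str, bool]
    n_exposed: int
    category: str


class JEMTable:
    """Job-exposure matrix keyed by (occupation_code, gender).

    Wraps a DataFrame with one row per key and one column per factor,
    values in [0, 1].
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        missing = [c for c in ("occupation_code", "gender", *FACTORS) if c not in df.columns]
        if missing:
            raise JEMError(f"JEM table missing columns: {missing}")
        df["occupation_code"] = df["occupation_code"].astype(str)
        vals = df[list(FACTORS)].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise JEMError("JEM values must lie in [0, 1]")
        df = df.set_index(["occupation_code", "gender"], verify_integrity=True)
        self._df = df[list(FACTORS)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        code, gender = key
        return (str(code), gender) in self._df.index

    def values_for(self, occupation_code: str, gender: str) -> pd.Series:
        key = (str(occupation_code), gender)
        if key not in self._df.index:
            raise KeyError(f"no JEM row for occupation {occupation_code!r}, {gender}")
        return self._df.loc[key]

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.reset_index()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "JEMTable":
        return cls(pd.read_csv(path, dtype={"occupation_code": str}))


def exposure_profile(
    jem: JEMTable,
    occupation_code: str,
    gender: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> ExposureProfile:
    """Dichotomize each factor for one occupation and classify the count."""
    values = jem.values_for(occupation_code, gender)
    flags = {f: dichotomize(float(values[f]), threshold) for f in FACTORS}
    n = sum(flags.values())
    return ExposureProfile(flags=flags, n_exposed=n, category=categorize(n))


def attach_exposure(
    persons: pd.DataFrame,
    jem: JEMTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append exposure columns to a persons table.

    Persons whose (occupation_code, gender) has no JEM row are excluded,
    mirroring the register practice of dropping records with missing
    occupational codes; exclusions are logged and returned.

    Returns
    -------
    (included, excluded)
        ``included`` has added columns ``n_exposed``, ``exposure_category``
        and one boolean column per factor; ``excluded`` lists the dropped
        persons with an ``exclusion_reason`` column.
    """
    rows = []
    keep = []
    for _, p in persons.iterrows():
        key = (str(p["occupation_code"]), p["gender"])
        if key not in jem:
            keep.append(False)
            rows.append(None)
            continue
        keep.append(True)
        rows.append(exposure_profile(jem, key[0], key[1], threshold))

    keep = pd.Series(keep, index=persons.index)
    included = persons[keep].copy()
    profs = [r for r in rows if r is not None]
    included["n_exposed"] = [p.n_exposed for p in profs]
    included["exposure_category"] = [p.category for p in profs]
    for f in FACTORS:
        included[f"exposed_{f}"] = [p.flags[f] for p in profs]

    excluded = persons[~keep].copy()
    excluded["exclusion_reason"] = "missing JEM row for occupation code"
    if len(excluded):
        log.warning(
            "excluded %d of %d persons with no JEM row (missing occupation code)",
            len(excluded),
            len(persons),
        )
    return included, excluded
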