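"""Covariate design columns shared by the simulator and the estimator.

Occupational class enters as three indicators against the upper
non-manual reference; physical-workload exposure enters as two
indicators against the no-exposure reference.  The three covariate
modes mirror the reported analyses: class-only, exposure-only, and the
joint model; ``none`` fits covariate-free (pooled) models.
"""

from __future__ import annotations

import pandas as pd

CLASS_LEVELS = ("upper_non_manual", "lower_non_manual", "manual", "self_employed")
CLASS_REFERENCE = "upper_non_manual"

CLASS_COLUMNS = ("class_lower_non_manual", "class_manual", "class_self_employed")
EXPOSURE_COLUMNS = ("exp_one_to_three", "exp_four_to_five")

COVARIATE_MODES = ("none", "class", "exposure", "joint")


def design_columns(mode: str) -> tuple[str, ...]:
    """Covariate column names for an analysis mode."""
    if mode == "none":
        return ()
    if mode == "class":
        return CLASS_COLUMNS
    if mode == "exposure":
        return EXPOSURE_COLUMNS
    if mode == "joint":
        return CLASS_COLUMNS + EXPOSURE_COLUMNS
    raise ValueError(f"unknown covariate mode {mode!r}")


def add_design_columns(persons: pd.DataFrame) -> pd.DataFrame:
    """Append indicator columns for class and (if present) exposure category."""
    out = persons.copy()
    cls = out["occupational_class"]
    unknown = set(cls.unique()) - set(CLASS_LEVELS)
    if unknown:
        raise ValueError(f"unknown occupational classes: {sorted(unknown)}")
    out["class_lower_non_manual"] = (cls == "lower_non_manual").astype(float)
    out["class_manual"] = (cls == "manual").astype(float)
    out["class_self_employed"] = (cls == "self_employed").astype(float)
    if "exposure_category" in out.columns:
        cat = out["exposure_category"]
        out["exp_one_to_three"] = (cat == "one_to_three").astype(float)
        out["exp_four_to_five"] = (cat == "four_to_five").astype(float)
    return out


def profile_for(
    columns: tuple[str, ...],
    occupational_class: str = CLASS_REFERENCE,
    exposure_category: str = "none",
) -> list[float]:
    """Covariate vector for a (class, exposure) profile under ``columns``."""
    values = {
        "class_lower_non_manual": float(occupational_class == "lower_non_manual"),
        "class_manual": float(occupational_class == "manual"),
        "class_self_employed": float(occupational_class == "self_employed"),
        "exp_one_to_three": float(exposure_category == "one_to_three"),
        "exp_four_to_five": float(exposure_category == "four_to_five"),
    }
    return [values[c] for c in columns]
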