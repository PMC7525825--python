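"""Cohort tables: observed line means and their standard errors.

A cohort table supplies the response vector ``y`` (one mean phenotype per
line, a proportion in [0, 1]) and the weight matrix ``V = diag(se^2)`` of
the weighted least-squares model.  Expected columns: ``cohort``, ``mean``,
``se``, ``n``, ``dam``, ``sire`` and optionally ``sex`` (pooled/F/M).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_cohort_table", "validate_cohorts", "se_floor"]

REQUIRED = ("cohort", "mean", "se")


def se_floor(n: np.ndarray | float) -> np.ndarray | float:
    """Smallest admissible standard error for a proportion measured on n
    individuals: half a count, 1/(2n).  Keeps V invertible when a cohort
    shows zero observed variance (e.g. a fixed line at small n)."""
    return 1.0 / (2.0 * np.asarray(n, float))


def validate_cohorts(table: pd.DataFrame, floor_zero_se: bool = True) -> pd.DataFrame:
    """Validate (and lightly repair) a cohort table.

    Means must lie in [0, 1]; at least 3 cohorts are required; standard
    errors must be positive.  A zero or missing SE is floored at 1/(2n)
    when ``floor_zero_se`` and ``n`` is available, otherwise rejected.
    """
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks column(s): {missing}")
    out = table.copy()
    out["cohort"] = out["cohort"].astype(str)
    if out["cohort"].duplicated().any():
        dup = out.loc[out["cohort"].duplicated(), "cohort"].tolist()
        raise ValueError(f"duplicated cohort id(s): {dup}")
    if len(out) < 3:
        raise ValueError(f"need at least 3 cohorts, got {len(out)}")
    means = pd.to_numeric(out["mean"], errors="raise").to_numpy(float)
    if np.any(~np.isfinite(means)) or means.min() < 0 or means.max() > 1:
        raise ValueError("cohort means must be finite proportions in [0, 1]")
    out["mean"] = means
    ses = pd.to_numeric(out["se"], errors="raise").to_numpy(float)
    bad = ~np.isfinite(ses) | (ses <= 0)
    if bad.any():
        if floor_zero_se and "n" in out.columns:
            n = pd.to_numeric(out["n"], errors="raise").to_numpy(float)
            ses = np.where(bad, se_floor(n), ses)
        else:
            which = out.loc[bad, "cohort"].tolist()
            raise ValueError(f"non-positive standard error for cohort(s): {which}")
    out["se"] = ses
    return out.reset_index(drop=True)


def load_cohort_table(path, sep: str | None = None, floor_zero_se: bool = True) -> pd.DataFrame:
    """Read a delimited cohort table (TSV default, CSV detected)."""
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "," if ("," in first and "\t" not in first) else "\t"
    table = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    try:
        return validate_cohorts(table, floor_zero_se=floor_zero_se)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
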