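"""The C-matrix: cohorts x composite-effects coefficient table.

The C-matrix is the design matrix of the line-cross linear model
``y = C beta + e``: one row per cohort, one column per composite genetic
effect, each entry the expected opportunity for that effect to move that
cohort's mean.  Epistatic columns are elementwise products of their two
factor columns (the standard digenic approximation for unlinked loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import (
    SIMPLE_EFFECTS,
    CompositeEffect,
    LinePedigree,
    default_effect_set,
    simple_effect_coefficient,
)

__all__ = ["CMatrix", "build_cmatrix", "load_cmatrix"]


@dataclass
class CMatrix:
    """Coefficient table with cohort and effect bookkeeping."""

    frame: pd.DataFrame  # index: cohort ids, columns: effect tokens
    effects: list[CompositeEffect] = field(default_factory=list)

    def __post_init__(self):
        if not self.effects:
            self.effects = [CompositeEffect.from_token(t) for t in self.frame.columns]
        tokens = [e.effect_id for e in self.effects]
        if tokens != list(self.frame.columns):
            raise ValueError("effect list does not match frame columns")
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate effect tokens in C-matrix")
        if not np.all(np.isfinite(self.frame.to_numpy(float))):
            raise ValueError("C-matrix contains non-finite coefficients")

    @property
    def cohort_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def effect_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    def category(self, token: str) -> str:
        for e in self.effects:
            if e.effect_id == token:
                return e.category
        raise KeyError(token)

    @property
    def epistatic_tokens(self) -> list[str]:
        return [e.effect_id for e in self.effects if e.category == "epistatic"]

    def aligned(self, cohort_ids: list[str]) -> "CMatrix":
        """Reorder rows to match a cohort table (by id, not file order)."""
        missing = [c for c in cohort_ids if c not in self.frame.index]
        if missing:
            raise ValueError(f"C-matrix lacks cohort row(s): {missing}")
        return CMatrix(self.frame.loc[list(cohort_ids)].copy(), list(self.effects))

    def columns(self, tokens) -> np.ndarray:
        return self.frame[list(tokens)].to_numpy(float)

    def write(self, path) -> None:
        out = self.frame + 0.0  # normalises negative zeros from products
        out.index.name = "cohort"
        out.to_csv(path, sep="\t", float_format="%.10g")


def build_cmatrix(pedigrees: list[LinePedigree],
                  effect_set: list[CompositeEffect] | None = None,
                  sex_mode: str = "pooled") -> CMatrix:
    """Build the C-matrix for a pedigree under the default conventions.

    Simple columns come from :func:`simple_effect_coefficient`; each
    epistatic column is the elementwise product of its factor columns.
    """
    if effect_set is None:
        effect_set = default_effect_set(pedigrees, sex_mode)
    if not effect_set:
        raise ValueError("effect_set is empty")
    tokens = [e.effect_id for e in effect_set]
    if len(set(tokens)) != len(tokens):
        dup = sorted({t for t in tokens if tokens.count(t) > 1})
        raise ValueError(f"duplicate effect tokens: {dup}")
    simple_cols = {
        e: np.array([simple_effect_coefficient(p, e, sex_mode) for p in pedigrees])
        for e in SIMPLE_EFFECTS
    }
    cols = {}
    for eff in effect_set:
        if eff.category == "simple":
            if eff.effect_id not in simple_cols:
                raise ValueError(f"unknown simple effect {eff.effect_id!r}")
            cols[eff.effect_id] = simple_cols[eff.effect_id]
        else:
            fa, fb = eff.factor_ids
            for f in (fa, fb):
                if f not in simple_cols:
                    raise ValueError(
                        f"epistatic effect {eff.effect_id!r}: factor {f!r} is not a simple effect")
            cols[eff.effect_id] = simple_cols[fa] * simple_cols[fb]
    frame = pd.DataFrame(cols, index=[p.line_code for p in pedigrees])
    return CMatrix(frame, list(effect_set))


def load_cmatrix(path, sep: str | None = None) -> CMatrix:
    """Load a C-matrix from delimited text.

    Expected layout: header ``cohort<TAB>effect1<TAB>...``, one row per
    cohort, decimal point ``.``.  Tab is the default delimiter; comma is
    detected automatically.  Blank or non-numeric cells, duplicate cohort
    ids and ragged rows are rejected with their location.
    """
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "," if ("," in first and "\t" not in first) else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a cohort column plus effect columns")
    cohort_col = raw.columns[0]
    cohorts = raw[cohort_col].astype(str).str.strip()
    dups = cohorts[cohorts.duplicated()].tolist()
    if dups:
        raise ValueError(f"{path}: duplicated cohort id(s): {sorted(set(dups))}")
    data = {}
    for col in raw.columns[1:]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            row = bad[0]
            cell = raw.loc[row, col]
            what = "blank" if (pd.isna(cell) or str(cell).strip() == "") else repr(cell)
            raise ValueError(
                f"{path}: non-numeric cell ({what}) at cohort "
                f"{cohorts.iloc[row]!r}, column {col!r}")
        data[col] = vals.to_numpy(float)
    frame = pd.DataFrame(data, index=list(cohorts))
    frame.index.name = None
    return CMatrix(frame)
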