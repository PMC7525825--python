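"""Post-analysis statistics: significance calls, the epistatic-to-additive
ratio, pseudo-R^2 ladders and transgressive-segregation checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmatrix import CMatrix
from .lca import AveragedResult, InestimableModelError, cox_snell_r2, fit_wls

__all__ = [
    "RatioResult",
    "significance_call",
    "epistatic_additive_ratio",
    "transgressive_check",
    "pseudo_r2_ladder",
]


def significance_call(result: AveragedResult) -> pd.DataFrame:
    """One call per effect: significant iff variable importance exceeds
    0.5 and the model-averaged confidence interval excludes zero."""
    t = result.effects_table
    excludes = (t["ci_low"] > 0) | (t["ci_high"] < 0)
    excludes &= t["ci_low"].notna() & t["ci_high"].notna()
    out = pd.DataFrame({
        "effect": t.index,
        "importance": t["importance"].to_numpy(),
        "ci_low": t["ci_low"].to_numpy(),
        "ci_high": t["ci_high"].to_numpy(),
        "ci_excludes_zero": excludes.to_numpy(),
        "significant": ((t["importance"] > 0.5) & excludes).to_numpy(),
    })
    return out.reset_index(drop=True)


@dataclass
class RatioResult:
    """Sum of |epistatic estimates| over |autosomal additive estimate|."""

    ratio: float
    additive_magnitude: float
    epistatic_magnitude_sum: float
    effects_used: list[str] = field(default_factory=list)
    defined: bool = True


def epistatic_additive_ratio(result: AveragedResult,
                             mode: str = "significant_only",
                             additive_token: str = "Aa") -> RatioResult:
    """Balance of inferred epistasis against the additive component.

    ``significant_only`` (default) sums the significant epistatic
    estimates; ``all_in_set`` sums every epistatic effect estimated in
    the confidence set.  Undefined (never a division error) when the
    additive effect is absent or its estimate is zero.
    """
    if mode not in ("significant_only", "all_in_set"):
        raise ValueError("mode must be 'significant_only' or 'all_in_set'")
    t = result.effects_table
    if additive_token not in t.index or not np.isfinite(t.loc[additive_token, "estimate"]):
        return RatioResult(np.nan, np.nan, np.nan, [], defined=False)
    add = abs(float(t.loc[additive_token, "estimate"]))
    epi = t[(t["category"] == "epistatic") & t["estimate"].notna()]
    if mode == "significant_only":
        calls = significance_call(result).set_index("effect")["significant"]
        epi = epi[calls.reindex(epi.index).fillna(False).to_numpy(bool)]
    s = float(epi["estimate"].abs().sum())
    if add == 0:
        return RatioResult(np.nan, 0.0, s, list(epi.index), defined=False)
    return RatioResult(s / add, add, s, list(epi.index), defined=True)


def transgressive_check(cohorts: pd.DataFrame) -> tuple[bool, pd.DataFrame]:
    """Flag derived cohorts whose mean lies outside the parental range."""
    t = cohorts.set_index("cohort")
    for p in ("P1", "P2"):
        if p not in t.index:
            raise ValueError(f"cohort table lacks parental line {p}")
    lo = min(t.loc["P1", "mean"], t.loc["P2", "mean"])
    hi = max(t.loc["P1", "mean"], t.loc["P2", "mean"])
    derived = t.drop(index=["P1", "P2"])
    outside = derived[(derived["mean"] > hi) | (derived["mean"] < lo)]
    out = outside.reset_index()[["cohort", "mean"]].copy()
    out["direction"] = np.where(out["mean"] > hi, "above", "below")
    return bool(len(out)), out


def pseudo_r2_ladder(cohorts: pd.DataFrame, cmatrix: CMatrix,
                     tokens: list[str], v_mode: str = "variance") -> pd.DataFrame:
    """Cox-Snell pseudo R^2 of nested models grown one effect at a time.

    ``tokens`` should be ordered by descending variable importance; step k
    fits the first k tokens against the mean-only null.  Inestimable
    steps are recorded and skipped.
    """
    null = fit_wls(cohorts, cmatrix, (), v_mode)
    n = len(cohorts)
    rows = []
    for k in range(1, len(tokens) + 1):
        subset = tuple(tokens[:k])
        try:
            mf = fit_wls(cohorts, cmatrix, subset, v_mode)
            rows.append({"step": k, "effects": "+".join(subset),
                         "r2": cox_snell_r2(mf, null, n), "estimable": True})
        except InestimableModelError:
            rows.append({"step": k, "effects": "+".join(subset),
                         "r2": np.nan, "estimable": False})
    return pd.DataFrame(rows)
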