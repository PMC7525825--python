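"""High-level modelling interface.

:class:`LineCrossModel` bundles a cohort table with a C-matrix and the
analysis settings; :meth:`LineCrossModel.fit` runs the exhaustive model
search and returns a :class:`LineCrossResults` carrying model-averaged
estimates, their unconditional standard errors, the confidence set of
models and diagnostic summaries.

    >>> from linecross import LineCrossModel
    >>> res = LineCrossModel(cohort_table).fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats
from .cmatrix import CMatrix, build_cmatrix, load_cmatrix
from .cohorts import load_cohort_table, validate_cohorts
from .lca import (
    AveragedResult,
    ModelFit,
    SearchResult,
    cox_snell_r2,
    model_average,
    model_search,
)
from .pedigree import standard_pedigree

__all__ = ["LineCrossModel", "LineCrossResults"]


class LineCrossModel:
    """Line-cross analysis of composite genetic effects.

    Parameters
    ----------
    cohorts
        Cohort table (``cohort``, ``mean``, ``se``, optionally ``n``,
        ``dam``, ``sire``, ``sex``); means are proportions, SEs the
        standard errors of the cohort means.
    cmatrix
        Optional C-matrix.  By default the 27-effect matrix of the
        standard 8-line design is built and aligned to the cohort ids.
    max_effects
        Cap on the number of composite effects per model (the mean term
        ``mu`` is always estimated and not counted).
    collinearity_threshold
        Pairwise |Pearson r| at or above which a subset is dropped.
    confidence_level
        Cumulative Akaike weight defining the model confidence set.
    sex_mode
        ``pooled`` (default), ``female`` or ``male``; affects only a
        default-built C-matrix.
    v_mode
        ``variance`` puts the squared SEs on the diagonal of V (the
        statistically coherent reading); ``se`` is a compatibility switch
        placing the SEs themselves there.
    averaging
        ``natural`` (estimates averaged over models containing the
        effect) or ``zero`` (absent models contribute zero estimates).
    renormalize_weights
        Whether importances/averages use weights renormalised within the
        confidence set (default) or raw weights.
    """

    def __init__(self, cohorts: pd.DataFrame, cmatrix: CMatrix | None = None, *,
                 max_effects: int = 7, collinearity_threshold: float = 0.90,
                 confidence_level: float = 0.95, sex_mode: str = "pooled",
                 v_mode: str = "variance", averaging: str = "natural",
                 renormalize_weights: bool = True):
        self.cohorts = validate_cohorts(cohorts)
        if cmatrix is None:
            cmatrix = build_cmatrix(standard_pedigree(), sex_mode=sex_mode)
        self.cmatrix = cmatrix.aligned(list(self.cohorts["cohort"]))
        self.max_effects = int(max_effects)
        self.collinearity_threshold = float(collinearity_threshold)
        self.confidence_level = float(confidence_level)
        self.sex_mode = sex_mode
        self.v_mode = v_mode
        self.averaging = averaging
        self.renormalize_weights = bool(renormalize_weights)
        n_eff = len(self.cmatrix.effect_ids)
        if not 1 <= self.max_effects <= n_eff:
            raise ValueError(f"max_effects must be in [1, {n_eff}]")

    @classmethod
    def from_files(cls, cohort_path, cmatrix_path=None, **kwargs) -> "LineCrossModel":
        cohorts = load_cohort_table(cohort_path)
        cmatrix = load_cmatrix(cmatrix_path) if cmatrix_path else None
        return cls(cohorts, cmatrix, **kwargs)

    def fit(self) -> "LineCrossResults":
        search = model_search(self.cohorts, self.cmatrix,
                              max_size=self.max_effects,
                              threshold=self.collinearity_threshold,
                              v_mode=self.v_mode)
        averaged = model_average(search, level=self.confidence_level,
                                 renormalize=self.renormalize_weights,
                                 averaging=self.averaging)
        return LineCrossResults(model=self, search=search, averaged=averaged)


@dataclass
class LineCrossResults:
    """Fitted line-cross analysis."""

    model: LineCrossModel
    search: SearchResult = field(repr=False)
    averaged: AveragedResult = field(repr=False)

    # -- basic accessors ------------------------------------------------
    @property
    def effects(self) -> pd.DataFrame:
        """Per-effect table: importance, estimate, unconditional SE, CI."""
        return self.averaged.effects_table

    @property
    def confidence_set(self) -> list[ModelFit]:
        return self.averaged.confidence_set

    @property
    def n_models_evaluated(self) -> int:
        return self.search.n_models_evaluated

    @property
    def n_models_dropped(self) -> int:
        return self.search.n_models_dropped

    @property
    def best_model(self) -> ModelFit:
        return self.confidence_set[0]

    @property
    def confidence_set_table(self) -> pd.DataFrame:
        rows = [{"rank": r + 1, "effects": "+".join(f.effect_subset),
                 "k": f.k, "aic": f.aic, "delta_aic": f.delta_aic,
                 "weight": f.weight}
                for r, f in enumerate(self.confidence_set)]
        return pd.DataFrame(rows)

    # -- derived statistics ---------------------------------------------
    def significance_calls(self) -> pd.DataFrame:
        return _stats.significance_call(self.averaged)

    def epistatic_additive_ratio(self, mode: str = "significant_only") -> _stats.RatioResult:
        return _stats.epistatic_additive_ratio(self.averaged, mode=mode)

    def transgressive(self):
        return _stats.transgressive_check(self.model.cohorts)

    def pseudo_r2_ladder(self, tokens: list[str] | None = None) -> pd.DataFrame:
        """R^2 ladder over effects in descending-importance order; by
        default the significant effects, or the best model's subset when
        nothing is significant."""
        if tokens is None:
            calls = self.significance_calls()
            sig = calls[calls["significant"]].copy()
            if len(sig):
                tokens = list(sig.sort_values("importance", ascending=False)["effect"])
            else:
                tokens = list(self.best_model.effect_subset)
        return _stats.pseudo_r2_ladder(self.model.cohorts, self.model.cmatrix,
                                       tokens, v_mode=self.model.v_mode)

    def cox_snell_r2(self, fit: ModelFit | None = None) -> float:
        fit = fit if fit is not None else self.best_model
        return cox_snell_r2(fit, self.search.null_fit, len(self.model.cohorts))

    # -- reporting -------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = [
            "Line-cross analysis of composite genetic effects",
            "=" * 64,
            f"Cohorts: {len(m.cohorts)}   Effects: {len(m.cmatrix.effect_ids)}   "
            f"Max effects/model: {m.max_effects}",
            f"Models evaluated: {self.n_models_evaluated:,}   "
            f"dropped: {self.n_models_dropped:,} "
            f"(|r| >= {m.collinearity_threshold} or rank deficient)",
            f"{m.confidence_level:.0%} confidence set: {len(self.confidence_set)} model(s), "
            f"best-model weight {self.best_model.weight:.3f}, "
            f"best-model pseudo-R2 {self.cox_snell_r2():.3f}",
            "",
            "Model-averaged effects (within the confidence set)",
            "-" * 64,
        ]
        t = self.effects.sort_values("importance", ascending=False)
        lines.append(f"{'effect':<8}{'importance':>11}{'estimate':>11}"
                     f"{'se':>9}{'ci_low':>9}{'ci_high':>9}  sig")
        calls = self.significance_calls().set_index("effect")["significant"]
        for tok, row in t.iterrows():
            if row["importance"] == 0 and not np.isfinite(row["estimate"]):
                continue
            star = "*" if calls.get(tok, False) else ""
            lines.append(
                f"{tok:<8}{row['importance']:>11.3f}{row['estimate']:>11.4f}"
                f"{row['unconditional_se']:>9.4f}{row['ci_low']:>9.4f}"
                f"{row['ci_high']:>9.4f}  {star}")
        lines += ["", f"Top models (of the confidence set, first {top})", "-" * 64]
        ct = self.confidence_set_table.head(top)
        for _, r in ct.iterrows():
            lines.append(f"  #{int(r['rank']):<3} w={r['weight']:.3f} "
                         f"dAIC={r['delta_aic']:.2f}  {r['effects']}")
        sig_note = ("* importance > 0.5 and CI excluding zero")
        lines += ["", sig_note]
        return "\n".join(lines)

    def save(self, out_dir, prefix: str = "lca") -> dict[str, str]:
        """Write the per-effect table and confidence-set model table as TSV."""
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        eff = self.effects.reset_index(names="effect")
        paths["effects"] = os.path.join(out_dir, f"{prefix}_effects.tsv")
        eff.to_csv(paths["effects"], sep="\t", index=False, float_format="%.10g")
        paths["models"] = os.path.join(out_dir, f"{prefix}_models.tsv")
        self.confidence_set_table.to_csv(paths["models"], sep="\t", index=False,
                                         float_format="%.10g")
        return paths
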