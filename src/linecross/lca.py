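"""Weighted least-squares line-cross engine.

Fits ``y = C beta + e`` by minimising the weighted sum of squares
``(y - C b)' V^-1 (y - C b)`` for every admissible subset of composite
effects, scores each model by AIC under a Gaussian likelihood with known
cohort-mean variances, and model-averages over the 95% confidence set.

The exhaustive search is vectorised: subsets are enumerated once per
(C-matrix, threshold, cap) and screened for pairwise collinearity and
exact rank deficiency; the surviving designs are then solved in batches
from gathered sub-blocks of the full weighted normal-equations matrix,
so a 1.28-million-model space takes seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cmatrix import CMatrix

__all__ = [
    "InestimableModelError",
    "ModelFit",
    "AveragedResult",
    "SearchResult",
    "fit_wls",
    "count_model_space",
    "collinearity_check",
    "model_search",
    "model_average",
    "cox_snell_r2",
]

#: Relative eigenvalue cutoff declaring a normal-equations matrix rank
#: deficient.  Exact linear dependencies among C-matrix columns land at
#: ~1e-16 relative, well-conditioned designs at >=1e-5; any value in the
#: gap gives identical decisions.
RANK_RTOL = 1e-10

LOG2PI = float(np.log(2.0 * np.pi))


class InestimableModelError(ValueError):
    """Design is rank deficient: the model cannot be fitted and is dropped."""


@dataclass
class ModelFit:
    """One WLS fit: an effect subset plus the reference mean term ``mu``."""

    effect_subset: tuple[str, ...]
    estimates: dict[str, float]
    cond_se: dict[str, float]
    loglik: float
    aic: float
    cohort_ids: tuple[str, ...] = ()
    delta_aic: float = np.nan
    weight: float = np.nan

    @property
    def k(self) -> int:
        """Number of estimated parameters (effects + mu)."""
        return len(self.effect_subset) + 1


@dataclass
class CollinearityDecision:
    drop: bool
    offending_pair: tuple[str, str] | None = None
    reason: str | None = None

    def __bool__(self) -> bool:  # truthy == keep
        return not self.drop


def _weights_from_se(se: np.ndarray, v_mode: str) -> np.ndarray:
    """Known error variances per cohort.  ``variance`` reads the table's
    ``se`` column as a standard error (V = diag(se^2)); ``se`` is a
    compatibility mode that places the SEs themselves on the diagonal."""
    if v_mode == "variance":
        return se.astype(float) ** 2
    if v_mode == "se":
        return se.astype(float)
    raise ValueError(f"v_mode must be 'variance' or 'se', got {v_mode!r}")


def _gaussian_loglik(wss: np.ndarray | float, variances: np.ndarray) -> np.ndarray | float:
    n = len(variances)
    return -0.5 * (n * LOG2PI + np.log(variances).sum() + wss)


def count_model_space(n_effects: int, max_size: int) -> int:
    """Number of non-empty effect subsets of size at most ``max_size``."""
    if not 1 <= max_size <= n_effects:
        raise ValueError("need 1 <= max_size <= n_effects")
    return sum(comb(n_effects, k) for k in range(1, max_size + 1))


def _prepare(cohorts: pd.DataFrame, cmatrix: CMatrix):
    cohort_ids = list(cohorts["cohort"])
    cm = cmatrix.aligned(cohort_ids)
    y = cohorts["mean"].to_numpy(float)
    se = cohorts["se"].to_numpy(float)
    return cohort_ids, cm, y, se


def fit_wls(cohorts: pd.DataFrame, cmatrix: CMatrix,
            subset: Iterable[str], v_mode: str = "variance") -> ModelFit:
    """Fit one model: ``mu`` plus the given composite effects.

    Minimises the weighted sum of squares with V built from the cohort
    SEs; the log-likelihood treats those variances as known, so
    ``aic = -2 loglik + 2 (|subset| + 1)`` is well defined even for
    saturated models.  Raises :class:`InestimableModelError` when the
    design (including the mean column) is rank deficient.
    """
    subset = tuple(subset)
    cohort_ids, cm, y, se = _prepare(cohorts, cmatrix)
    variances = _weights_from_se(se, v_mode)
    w = 1.0 / variances
    X = np.column_stack([np.ones(len(y))] + ([cm.columns(subset)] if subset else []))
    G = (X * w[:, None]).T @ X
    ev = np.linalg.eigvalsh(G)
    if ev[0] <= RANK_RTOL * ev[-1]:
        raise InestimableModelError(
            f"design for subset {subset} is rank deficient (model dropped)")
    b = (X * w[:, None]).T @ y
    beta = np.linalg.solve(G, b)
    cov = np.linalg.inv(G)
    resid = y - X @ beta
    wss = float(resid @ (w * resid))
    ll = float(_gaussian_loglik(wss, variances))
    names = ("mu",) + subset
    return ModelFit(
        effect_subset=subset,
        estimates=dict(zip(names, beta.tolist())),
        cond_se=dict(zip(names, np.sqrt(np.diag(cov)).tolist())),
        loglik=ll,
        aic=-2.0 * ll + 2.0 * len(names),
        cohort_ids=tuple(cohort_ids),
    )


def _bad_pair_matrix(values: np.ndarray, threshold: float) -> np.ndarray:
    """Pairwise drop rule: |Pearson r| >= threshold.  Constant columns
    cannot be separated from the mean term, so they pair badly with
    everything."""
    n, p = values.shape
    sd = values.std(axis=0)
    const = sd == 0
    centred = values - values.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(const, 0.0, centred / np.where(const, 1.0, sd))
    r = z.T @ z / n
    bad = np.abs(r) >= threshold - 1e-12
    bad[const, :] = True
    bad[:, const] = True
    np.fill_diagonal(bad, False)
    return bad


def collinearity_check(cmatrix: CMatrix, subset: Sequence[str],
                       threshold: float = 0.90) -> CollinearityDecision:
    """Keep/drop decision for one subset.

    Drops when any column pair is correlated at |r| >= threshold, when a
    column is constant, or when the design including ``mu`` is rank
    deficient; reports the offending pair where one exists.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    subset = list(subset)
    vals = cmatrix.columns(subset)
    bad = _bad_pair_matrix(vals, threshold)
    const = vals.std(axis=0) == 0
    for i in np.flatnonzero(const):
        return CollinearityDecision(True, (subset[i], subset[i]),
                                    "constant column (confounded with mu)")
    for i, j in itertools.combinations(range(len(subset)), 2):
        if bad[i, j]:
            return CollinearityDecision(True, (subset[i], subset[j]),
                                        f"|r| >= {threshold}")
    X = np.column_stack([np.ones(vals.shape[0]), vals])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return CollinearityDecision(True, None, "rank-deficient design (with mu)")
    return CollinearityDecision(False)


# Cache of screened subsets keyed by (matrix bytes, threshold, max_size).
# The screen depends only on the C-matrix: pairwise correlation is a
# column property, and rank(X' W X) = rank(X) for any positive weights.
_SCREEN_CACHE: dict = {}


def _screened_subsets(cm: CMatrix, threshold: float, max_size: int):
    values = cm.values
    key = (values.tobytes(), values.shape, threshold, max_size)
    hit = _SCREEN_CACHE.get(key)
    if hit is not None:
        return hit
    n_eff = values.shape[1]
    bad = _bad_pair_matrix(values, threshold)
    X = np.column_stack([np.ones(values.shape[0]), values])
    A0 = X.T @ X
    survivors = {}
    n_coll = n_rank = 0
    for k in range(1, max_size + 1):
        combos = np.array(list(itertools.combinations(range(n_eff), k)), dtype=np.int64)
        combos = combos.reshape(-1, k)
        keep = np.ones(len(combos), bool)
        for a, b in itertools.combinations(range(k), 2):
            keep &= ~bad[combos[:, a], combos[:, b]]
        n_coll += int((~keep).sum())
        combos = combos[keep]
        # exact rank screen on the unweighted Gram blocks
        rows = np.concatenate(
            [np.zeros((len(combos), 1), np.int64), combos + 1], axis=1)
        ok = np.ones(len(combos), bool)
        for lo in range(0, len(rows), 200_000):
            r = rows[lo:lo + 200_000]
            ev = np.linalg.eigvalsh(A0[r[:, :, None], r[:, None, :]])
            ok[lo:lo + 200_000] = ev[:, 0] > RANK_RTOL * ev[:, -1]
        n_rank += int((~ok).sum())
        survivors[k] = combos[ok]
    result = (survivors, n_coll, n_rank)
    _SCREEN_CACHE[key] = result
    if len(_SCREEN_CACHE) > 8:  # keep the cache tiny
        _SCREEN_CACHE.pop(next(iter(_SCREEN_CACHE)))
    return result


@dataclass
class SearchResult:
    """Outcome of the exhaustive model search, ranked by AIC.

    Per-model arrays are aligned: ``subsets[i]`` (token tuple), ``aic[i]``,
    ``loglik[i]``, ``weight[i]``.  ``order`` ranks models by AIC with ties
    broken by enumeration (size, then lexicographic index) order.
    """

    effect_tokens: list[str]
    subset_idx: np.ndarray  # (n_models, max_size) int, -1 padded
    subset_size: np.ndarray
    loglik: np.ndarray
    aic: np.ndarray
    order: np.ndarray
    weight: np.ndarray
    null_fit: ModelFit
    n_models_evaluated: int
    n_models_dropped: int
    n_dropped_collinear: int
    n_dropped_rank: int
    threshold: float
    max_size: int
    v_mode: str
    cohorts: pd.DataFrame = field(repr=False)
    cmatrix: CMatrix = field(repr=False)

    def subset_tokens(self, i: int) -> tuple[str, ...]:
        idx = self.subset_idx[i, : self.subset_size[i]]
        return tuple(self.effect_tokens[j] for j in idx)

    @property
    def delta_aic(self) -> np.ndarray:
        return self.aic - self.aic.min()

    def fit(self, i: int) -> ModelFit:
        """Re-fit model ``i`` exactly, attaching its weight and delta."""
        mf = fit_wls(self.cohorts, self.cmatrix, self.subset_tokens(i), self.v_mode)
        mf.delta_aic = float(self.delta_aic[i])
        mf.weight = float(self.weight[i])
        return mf

    def top(self, n: int = 10) -> list[ModelFit]:
        return [self.fit(i) for i in self.order[:n]]

    def batch_estimates(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Estimates and conditional SEs for many models at once.

        Returns ``(beta, cond_se)`` of shape (m, 1 + max_size): column 0
        is ``mu``, column 1+j the model's j-th effect, NaN-padded.
        """
        y = self.cohorts["mean"].to_numpy(float)
        se = self.cohorts["se"].to_numpy(float)
        variances = _weights_from_se(se, self.v_mode)
        w = 1.0 / variances
        X = np.column_stack([np.ones(len(y)), self.cmatrix.values])
        A = (X * w[:, None]).T @ X
        v = (X * w[:, None]).T @ y
        m = len(indices)
        beta = np.full((m, self.max_size + 1), np.nan)
        cse = np.full((m, self.max_size + 1), np.nan)
        sizes = self.subset_size[indices]
        for k in np.unique(sizes):
            sel = np.flatnonzero(sizes == k)
            rows = np.concatenate(
                [np.zeros((len(sel), 1), np.int64),
                 self.subset_idx[indices[sel], :k] + 1], axis=1)
            G = A[rows[:, :, None], rows[:, None, :]]
            b = v[rows]
            beta[sel, : k + 1] = np.linalg.solve(G, b[..., None])[..., 0]
            cov = np.linalg.inv(G)
            cse[sel, : k + 1] = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
        return beta, cse

    def fits_for(self, indices: np.ndarray) -> list[ModelFit]:
        """Materialise :class:`ModelFit` objects for the given models."""
        beta, cse = self.batch_estimates(indices)
        delta = self.delta_aic
        cohort_ids = tuple(self.cohorts["cohort"])
        out = []
        for r, i in enumerate(indices):
            toks = ("mu",) + self.subset_tokens(i)
            k = len(toks)
            out.append(ModelFit(
                effect_subset=toks[1:],
                estimates=dict(zip(toks, beta[r, :k].tolist())),
                cond_se=dict(zip(toks, cse[r, :k].tolist())),
                loglik=float(self.loglik[i]), aic=float(self.aic[i]),
                cohort_ids=cohort_ids,
                delta_aic=float(delta[i]), weight=float(self.weight[i]),
            ))
        return out

    def confidence_set_indices(self, level: float = 0.95) -> np.ndarray:
        cum = np.cumsum(self.weight[self.order])
        m = int(np.searchsorted(cum, level)) + 1
        return self.order[:min(m, len(self.order))]


def model_search(cohorts: pd.DataFrame, cmatrix: CMatrix,
                 max_size: int = 7, threshold: float = 0.90,
                 v_mode: str = "variance") -> SearchResult:
    """Enumerate, screen and fit every model of 1..max_size effects.

    Subsets failing the pairwise-collinearity rule or exact rank check
    are dropped (mirroring the treatment of highly correlated predictors
    in line-cross software); the remainder are fitted in vectorised
    batches and given Akaike weights ``exp(-delta/2)`` normalised over
    all fitted models.  Deterministic given its inputs.
    """
    cohort_ids, cm, y, se = _prepare(cohorts, cmatrix)
    variances = _weights_from_se(se, v_mode)
    w = 1.0 / variances
    values = cm.values
    n = len(y)
    survivors, n_coll, n_rank = _screened_subsets(cm, threshold, max_size)
    n_total = count_model_space(values.shape[1], max_size)
    n_fit = sum(len(v) for v in survivors.values())
    if n_fit == 0:
        raise ValueError(
            f"all {n_total} candidate models were dropped at collinearity "
            f"threshold {threshold}; nothing to fit")

    X = np.column_stack([np.ones(n), values])
    A = (X * w[:, None]).T @ X
    v = (X * w[:, None]).T @ y
    c0 = float(y @ (w * y))
    const = -0.5 * (n * LOG2PI + float(np.log(variances).sum()))

    subset_idx = np.full((n_fit, max_size), -1, np.int64)
    subset_size = np.empty(n_fit, np.int64)
    loglik = np.empty(n_fit)
    aic = np.empty(n_fit)
    pos = 0
    for k in range(1, max_size + 1):
        combos = survivors[k]
        if not len(combos):
            continue
        rows = np.concatenate(
            [np.zeros((len(combos), 1), np.int64), combos + 1], axis=1)
        for lo in range(0, len(rows), 200_000):
            r = rows[lo:lo + 200_000]
            G = A[r[:, :, None], r[:, None, :]]
            b = v[r]
            beta = np.linalg.solve(G, b[..., None])[..., 0]
            wss = c0 - np.einsum("ij,ij->i", b, beta)
            ll = const - 0.5 * np.maximum(wss, 0.0)
            m = len(r)
            subset_idx[pos:pos + m, :k] = r[:, 1:] - 1
            subset_size[pos:pos + m] = k
            loglik[pos:pos + m] = ll
            aic[pos:pos + m] = -2.0 * ll + 2.0 * (k + 1)
            pos += m
    assert pos == n_fit

    order = np.argsort(aic, kind="stable")
    delta = aic - aic.min()
    raw = np.exp(-0.5 * delta)
    weight = raw / raw.sum()

    null_fit = fit_wls(cohorts, cmatrix, (), v_mode)
    return SearchResult(
        effect_tokens=list(cm.effect_ids),
        subset_idx=subset_idx, subset_size=subset_size,
        loglik=loglik, aic=aic, order=order, weight=weight,
        null_fit=null_fit,
        n_models_evaluated=n_fit,
        n_models_dropped=n_coll + n_rank,
        n_dropped_collinear=n_coll, n_dropped_rank=n_rank,
        threshold=threshold, max_size=max_size, v_mode=v_mode,
        cohorts=cohorts.reset_index(drop=True), cmatrix=cm,
    )


@dataclass
class AveragedResult:
    """Model-averaged inference over the confidence set of models."""

    effects_table: pd.DataFrame  # index: effect token
    confidence_set: list[ModelFit]
    level: float
    weight_covered: float  # cumulative (un-renormalised) weight of the set
    n_models_evaluated: int
    n_models_dropped: int
    categories: dict[str, str] = field(default_factory=dict)

    def importance(self, token: str) -> float:
        return float(self.effects_table.loc[token, "importance"])

    def estimate(self, token: str) -> float:
        return float(self.effects_table.loc[token, "estimate"])


def _as_fits(fits) -> list[ModelFit]:
    if isinstance(fits, SearchResult):
        return [fits.fit(i) for i in fits.order]
    return list(fits)


def model_average(fits, level: float = 0.95,
                  renormalize: bool = True,
                  averaging: str = "natural",
                  effect_tokens: Sequence[str] | None = None,
                  categories: dict[str, str] | None = None) -> AveragedResult:
    """Model-average estimates over the smallest AIC-ranked set of models
    whose cumulative Akaike weight reaches ``level``.

    Within the (by default renormalised) set, an effect's importance is
    the summed weight of the models containing it; its estimate is the
    weight-averaged estimate over those models (natural averaging); its
    unconditional standard error follows Buckland/Burnham-Anderson,
    ``sum w_i sqrt(se_i^2 + (b_i - bbar)^2)`` with weights renormalised
    over the containing models.  CI = estimate +/- z(0.975) * se.
    """
    if averaging not in ("natural", "zero"):
        raise ValueError("averaging must be 'natural' or 'zero'")
    n_eval = n_drop = 0
    if isinstance(fits, SearchResult):
        return _model_average_search(fits, level, renormalize, averaging)
    else:
        allfits = sorted(_as_fits(fits), key=lambda f: f.aic)
        if not allfits:
            raise ValueError("no fitted models to average")
        n_eval = len(allfits)
        amin = min(f.aic for f in allfits)
        raw = np.array([np.exp(-0.5 * (f.aic - amin)) for f in allfits])
        wts = raw / raw.sum()
        for f, d, w in zip(allfits, (f.aic - amin for f in allfits), wts):
            f.delta_aic, f.weight = float(d), float(w)
        cum = np.cumsum(wts)
        m = int(np.searchsorted(cum, level)) + 1
        cset = allfits[:min(m, len(allfits))]
        if effect_tokens is None:
            seen = dict.fromkeys(t for f in allfits for t in f.effect_subset)
            effect_tokens = list(seen)
        if categories is None:
            categories = {}

    w_set = np.array([f.weight for f in cset])
    covered = float(w_set.sum())
    w_use = w_set / covered if renormalize else w_set

    z = float(norm.ppf(0.975))
    rows = {}
    for tok in effect_tokens:
        contains = np.array([tok in f.effect_subset for f in cset])
        imp = float(w_use[contains].sum())
        imp_raw = float(w_set[contains].sum())
        if averaging == "zero":
            b = np.array([f.estimates.get(tok, 0.0) for f in cset])
            s = np.array([f.cond_se.get(tok, 0.0) for f in cset])
            ww = w_use
        else:
            b = np.array([f.estimates[tok] for f in cset if tok in f.effect_subset])
            s = np.array([f.cond_se[tok] for f in cset if tok in f.effect_subset])
            ww = w_use[contains]
        if len(b) == 0 or ww.sum() == 0:
            rows[tok] = (imp, imp_raw, np.nan, np.nan, np.nan, np.nan)
            continue
        ww = ww / ww.sum()
        bbar = float(ww @ b)
        use = float(ww @ np.sqrt(s ** 2 + (b - bbar) ** 2))
        rows[tok] = (imp, imp_raw, bbar, use, bbar - z * use, bbar + z * use)

    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["importance", "importance_raw", "estimate",
                 "unconditional_se", "ci_low", "ci_high"])
    table["category"] = [categories.get(t, "simple") for t in table.index]
    return AveragedResult(
        effects_table=table, confidence_set=cset, level=level,
        weight_covered=covered,
        n_models_evaluated=n_eval, n_models_dropped=n_drop,
        categories=dict(categories),
    )


def _model_average_search(search: SearchResult, level: float,
                          renormalize: bool, averaging: str) -> AveragedResult:
    """Vectorised averaging directly over the search arrays."""
    idx = search.confidence_set_indices(level)
    beta, cse = search.batch_estimates(idx)
    sizes = search.subset_size[idx]
    sub = search.subset_idx[idx]
    w_set = search.weight[idx]
    covered = float(w_set.sum())
    w_use = w_set / covered if renormalize else w_set

    m, n_eff = len(idx), len(search.effect_tokens)
    contains = np.zeros((m, n_eff), bool)
    bmat = np.full((m, n_eff), np.nan)
    smat = np.full((m, n_eff), np.nan)
    rows = np.arange(m)
    for j in range(search.max_size):
        valid = sizes > j
        cols = sub[valid, j]
        contains[rows[valid], cols] = True
        bmat[rows[valid], cols] = beta[valid, j + 1]
        smat[rows[valid], cols] = cse[valid, j + 1]

    z = float(norm.ppf(0.975))
    out = {}
    for t, tok in enumerate(search.effect_tokens):
        mask = contains[:, t]
        imp = float(w_use[mask].sum())
        imp_raw = float(w_set[mask].sum())
        if averaging == "zero":
            b = np.where(mask, bmat[:, t], 0.0)
            s = np.where(mask, smat[:, t], 0.0)
            ww = w_use
        else:
            b, s, ww = bmat[mask, t], smat[mask, t], w_use[mask]
        if len(b) == 0 or ww.sum() == 0:
            out[tok] = (imp, imp_raw, np.nan, np.nan, np.nan, np.nan)
            continue
        ww = ww / ww.sum()
        bbar = float(ww @ b)
        use = float(ww @ np.sqrt(s ** 2 + (b - bbar) ** 2))
        out[tok] = (imp, imp_raw, bbar, use, bbar - z * use, bbar + z * use)

    table = pd.DataFrame.from_dict(
        out, orient="index",
        columns=["importance", "importance_raw", "estimate",
                 "unconditional_se", "ci_low", "ci_high"])
    categories = {e.effect_id: e.category for e in search.cmatrix.effects}
    table["category"] = [categories.get(t, "simple") for t in table.index]
    return AveragedResult(
        effects_table=table, confidence_set=search.fits_for(idx),
        level=level, weight_covered=covered,
        n_models_evaluated=search.n_models_evaluated,
        n_models_dropped=search.n_models_dropped,
        categories=categories,
    )


def cox_snell_r2(model: ModelFit, null_model: ModelFit, n_cohorts: int | None = None) -> float:
    """Cox-Snell pseudo R^2 of a model against the mean-only null:
    ``1 - exp((2/n) (ll_null - ll_model))``, floored at zero."""
    if null_model.effect_subset:
        raise ValueError("null_model must be the mu-only fit")
    if model.cohort_ids and null_model.cohort_ids and \
            model.cohort_ids != null_model.cohort_ids:
        raise ValueError("model and null were fitted to different cohort sets")
    n = n_cohorts if n_cohorts is not None else len(model.cohort_ids)
    if not n:
        raise ValueError("number of cohorts unknown")
    return max(0.0, 1.0 - float(np.exp((2.0 / n) * (null_model.loglik - model.loglik))))
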