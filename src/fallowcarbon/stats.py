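"""Inferential layer: one-way ANOVA with Tukey HSD, and AICc-ranked
linear mixed-effect models with Akaike weights and variable importance.

The mixed models regress a per-site response (typically a recovery
percentage) on subsets of five site covariates — fallow age (FA),
distance to the nearest control forest (DIS), slope (SL), patch size
(PS) and soil organic carbon (SOC) — with a random intercept per
fallow category. With one response value per site, a site-level random
effect is indistinguishable from the residual, so the grouping factor
is the fallow category and the site level is absorbed into the
residual. Likelihoods are maximum likelihood (not REML) so that AICc
is comparable across different fixed structures; all 2⁵ covariate
subsets (including the intercept-only model) are ranked by AICc, with
models within 4 AICc units of the best flagged as an equivalence set.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CANDIDATE_VARS",
    "AnovaResult",
    "LmmFit",
    "anova_tukey",
    "fit_lmm",
    "aicc",
    "all_subsets_selection",
    "variable_importance",
    "collinearity_screen",
]

#: Default candidate fixed effects, in canonical order.
CANDIDATE_VARS = ("FA", "DIS", "SL", "PS", "SOC")


@dataclass
class AnovaResult:
    response: str
    F: float
    df_between: int
    df_within: int
    p: float
    #: (group_a, group_b, mean_diff, adjusted_p, significant)
    tukey_pairs: list = field(default_factory=list)


def anova_tukey(values, groups, *, alpha: float = 0.05,
                response: str = "response") -> AnovaResult:
    """Classical one-way ANOVA plus Tukey's HSD over all group pairs.

    ``values`` and ``groups`` are parallel sequences; every group needs
    at least two observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    arrays = [values[groups == g] for g in labels]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least two groups")
    for g, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")
    n, k = len(values), len(labels)
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(values) == 0:
        F, p = 0.0, 1.0  # all observations identical: no variance to partition
    else:
        F, p = sps.f_oneway(*arrays)
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = [
        (str(a), str(b), float(diff), float(padj), bool(rej))
        for a, b, diff, padj, rej in zip(
            hsd.groupsunique[hsd._multicomp.pairindices[0]],
            hsd.groupsunique[hsd._multicomp.pairindices[1]],
            hsd.meandiffs, hsd.pvalues, hsd.reject,
        )
    ]
    return AnovaResult(
        response=response, F=float(F), df_between=k - 1, df_within=n - k,
        p=float(p), tukey_pairs=pairs,
    )


@dataclass
class LmmFit:
    """A fitted mixed model: ML log-likelihood, parameter count and the
    fixed-effect estimates (intercept first)."""

    loglik: float
    df: int
    params: np.ndarray
    bse: np.ndarray
    converged: bool
    boundary: bool = False  # random-effect variance at (or collapsed to) 0


def _ols_boundary_fit(y: np.ndarray, X: np.ndarray) -> LmmFit:
    # ML fit with the random-intercept variance pinned at its 0 boundary.
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return LmmFit(
        loglik=llf, df=X.shape[1] + 2, params=beta,
        bse=np.sqrt(np.diag(cov)), converged=True, boundary=True,
    )


def fit_lmm(data: pd.DataFrame, response: str, fixed_subset,
            group_col: str = "category") -> LmmFit:
    """Fit ``response ~ 1 + fixed_subset`` with a random intercept per
    group, by maximum likelihood.

    Returns an :class:`LmmFit` whose ``df`` counts the intercept, each
    fixed effect and the two variance components (random intercept +
    residual). A singular fit is retained, with the random-effect
    variance at the boundary and a warning logged.
    """
    fixed = list(fixed_subset)
    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y))] + [data[v].to_numpy(dtype=float) for v in fixed]
    )
    groups = data[group_col].to_numpy()
    k = X.shape[1] + 2
    if float(np.var(y)) < 1e-14:
        warnings.warn("zero-variance response; degenerate constant-model fit")
        return _ols_boundary_fit(y, X)
    res = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(y, X, groups=groups).fit(reml=False, method=method)
            break
        except np.linalg.LinAlgError:
            # variance component at the 0 boundary: Hessian is singular
            res = None
        except Exception:
            res = None
    try:
        if res is None:
            raise ValueError("all optimizers failed")
        llf = float(res.llf)
        if not np.isfinite(llf):
            raise ValueError("non-finite likelihood")
        boundary = float(np.asarray(res.cov_re).ravel()[0]) <= 1e-10
        if boundary:
            warnings.warn("singular mixed-model fit: random-effect variance at 0")
        nb = len(fixed) + 1
        return LmmFit(
            loglik=llf, df=k, params=np.asarray(res.params[:nb], dtype=float),
            bse=np.asarray(res.bse[:nb], dtype=float),
            converged=bool(res.converged), boundary=boundary,
        )
    except Exception:
        warnings.warn(
            "mixed-model optimizer stopped at the variance boundary; "
            "using the boundary (random-effect variance = 0) ML fit"
        )
        return _ols_boundary_fit(y, X)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike Information Criterion with the small-sample correction:
    ``−2·loglik + 2k + 2k(k+1)/(n−k−1)``; requires ``n > k + 1``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def standardize(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the given columns (population sd); constant columns map to 0."""
    out = data.copy()
    for c in columns:
        v = out[c].to_numpy(dtype=float)
        sd = v.std()
        out[c] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def all_subsets_selection(
    data: pd.DataFrame,
    response: str,
    candidates=CANDIDATE_VARS,
    *,
    group_col: str = "category",
    delta_threshold: float = 4.0,
    standardize_covariates: bool = True,
) -> pd.DataFrame:
    """Fit every subset of the candidate fixed effects and rank by AICc.

    All ``2^len(candidates)`` subsets, including the intercept-only
    model, are fitted by ML; the table reports the parameter count, the
    log-likelihood, AICc, ΔAICc from the best model and Akaike weights
    ``w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`` normalised over every fitted
    model. Rows are sorted by AICc, ties broken by fewer parameters
    then lexicographic subset order; ``equivalent`` flags ΔAICc ≤ 4.

    A subset whose fit fails outright is recorded with NaN likelihood,
    excluded from the weight normalisation, and warned about.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    df = standardize(data, candidates) if standardize_covariates else data.copy()
    n = len(df)
    rows = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            try:
                fit = fit_lmm(df, response, subset, group_col=group_col)
                rows.append({
                    "subset": "+".join(subset) if subset else "(intercept)",
                    "vars": subset, "df": fit.df, "loglik": fit.loglik,
                    "aicc": aicc(fit.loglik, fit.df, n),
                })
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"subset {subset} failed to fit: {exc}")
                rows.append({
                    "subset": "+".join(subset) if subset else "(intercept)",
                    "vars": subset, "df": np.nan, "loglik": np.nan,
                    "aicc": np.nan,
                })
    table = pd.DataFrame(rows)
    ok = table["aicc"].notna()
    best = table.loc[ok, "aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    rel = np.exp(-0.5 * table.loc[ok, "delta_aicc"])
    table.loc[ok, "weight"] = rel / rel.sum()
    table["equivalent"] = table["delta_aicc"] <= delta_threshold
    table = table.sort_values(
        by=["aicc", "df", "subset"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def variable_importance(
    table: pd.DataFrame, candidates=CANDIDATE_VARS, *, scope: str = "full"
) -> pd.DataFrame:
    """Relative importance of each candidate variable.

    Sum of the Akaike weights of every model containing the variable,
    plus the count of such models, within ``scope`` — the ``"full"``
    candidate set or only the ΔAICc ``"equivalence_set"``.
    """
    if scope == "full":
        sub = table
    elif scope == "equivalence_set":
        sub = table.loc[table["equivalent"]]
    else:
        raise ValueError("scope must be 'full' or 'equivalence_set'")
    rows = []
    for var in candidates:
        mask = sub["vars"].apply(lambda t: var in t)
        rows.append({
            "variable": var,
            "importance": float(sub.loc[mask, "weight"].fillna(0.0).sum()),
            "n_models": int(mask.sum()),
        })
    return pd.DataFrame(rows)


def collinearity_screen(
    covariates: pd.DataFrame,
    *,
    threshold: float = 0.7,
    priority=CANDIDATE_VARS,
) -> tuple[list[str], list[str]]:
    """Greedy pairwise-|r| screen of candidate covariates.

    Variables are visited in priority order (defaults to the canonical
    five, then any remaining columns); a variable is retained iff its
    absolute Pearson correlation with every already-retained variable
    is below ``threshold``. Constant columns are excluded with a
    warning. Returns ``(retained, excluded)``.
    """
    cols = [c for c in priority if c in covariates.columns]
    cols += [c for c in covariates.columns if c not in cols]
    retained: list[str] = []
    excluded: list[str] = []
    for c in cols:
        v = covariates[c].to_numpy(dtype=float)
        if v.std() == 0:
            warnings.warn(f"covariate {c!r} is constant; excluded")
            excluded.append(c)
            continue
        r_max = max(
            (abs(sps.pearsonr(v, covariates[r].to_numpy(dtype=float))[0])
             for r in retained),
            default=0.0,
        )
        (retained if r_max < threshold else excluded).append(c)
    return retained, excluded
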