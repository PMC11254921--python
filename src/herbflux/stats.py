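"""Statistical machinery for the cross-biome analysis.

Transforms and z-scoring, variance-inflation screening, Gaussian linear
mixed models with a random intercept (site or site:plot), standardized
coefficients with parametric-bootstrap percentile confidence intervals,
marginal/conditional R2 from variance components, and rank-based group
comparisons (Kruskal-Wallis with Dunn post-hoc, Holm or Bonferroni
adjusted).

Mixed models are fitted by restricted maximum likelihood via
``statsmodels`` MixedLM.  The Kruskal-Wallis H statistic is computed
in-module with the tie-corrected rank formula (the per-call cost matters
for exhaustive small-sample verification); it is cross-checked against
``scipy.stats.kruskal`` in the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DEFAULT_SEED = 20240717
DEFAULT_BOOTSTRAP_N = 1000
DEFAULT_CI_LEVEL = 0.95
VIF_THRESHOLD = 2.0


class CollinearityError(ValueError):
    """Variance-inflation screening failed (VIF at or above threshold)."""


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform(values, kind: str = "none", eps: float = 1e-4) -> np.ndarray:
    """Elementwise none / log / logit transform.

    Under ``logit``, exact 0 and 1 are shifted inward by ``eps`` with a
    warning; anything else outside (0, 1) is an error.  ``log`` requires
    strictly positive values.
    """
    arr = np.asarray(values, dtype=float)
    if kind == "none":
        return arr.copy()
    if kind == "log":
        if (arr[~np.isnan(arr)] <= 0).any():
            raise ValueError("log transform requires values > 0")
        return np.log(arr)
    if kind == "logit":
        out = arr.copy()
        boundary = (out == 0) | (out == 1)
        if boundary.any():
            warnings.warn(
                f"logit: shifting {int(boundary.sum())} boundary value(s) by eps={eps}",
                stacklevel=2)
            out[out == 0] = eps
            out[out == 1] = 1 - eps
        valid = ~np.isnan(out)
        if ((out[valid] <= 0) | (out[valid] >= 1)).any():
            raise ValueError("logit transform requires values in (0, 1)")
        return np.log(out / (1 - out))
    raise ValueError(f"unknown transform kind {kind!r}")


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    sd = np.nanstd(arr, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zscore requires >= 2 distinct values")
    return (arr - np.nanmean(arr)) / sd


def default_transform_kind(name: str, values=None, skew_threshold: float = 2.0) -> str:
    """Transform assignment by variable role.

    Proportions (herbivory rate, incidence, resorption) are logit
    transformed; fluxes, production and concentrations are log transformed;
    climate and stoichiometric predictors stay untransformed unless heavily
    right-skewed.
    """
    base = name.lower()
    if base in ("h", "incidence") or base.startswith(("re", "incidence")):
        return "logit"
    if base.startswith(("fp", "h_c", "h_i", "hc", "hi", "f_", "l_h", "l_e")):
        return "log"
    if values is not None:
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size > 2 and (arr > 0).all() and sps.skew(arr) > skew_threshold:
            return "log"
    return "none"


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    R^2_j comes from regressing predictor j (with intercept) on the others.
    Perfect collinearity yields ``inf``.
    """
    X = predictors.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs >= 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs n > number of predictors")
    out = {}
    cols = list(X.columns)
    for col in cols:
        y = X[col].to_numpy()
        others = X.drop(columns=[col]).to_numpy()
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            out[col] = float("inf")
            continue
        r2 = 1 - (resid ** 2).sum() / ss_tot
        out[col] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def screen_collinearity(predictors: pd.DataFrame,
                        threshold: float = VIF_THRESHOLD) -> pd.Series:
    """Raise CollinearityError unless all VIFs fall below ``threshold``."""
    vifs = vif(predictors)
    if (vifs >= threshold).any():
        bad = vifs[vifs >= threshold]
        raise CollinearityError(
            "VIF screening failed: " +
            ", ".join(f"{k}={v:.3g}" for k, v in bad.items()))
    return vifs


# ---------------------------------------------------------------------------
# Linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """A fitted random-intercept Gaussian mixed model plus its design."""

    response: str
    predictors: list[str]
    endog: np.ndarray
    exog: np.ndarray            # intercept column first
    groups: np.ndarray
    params: np.ndarray          # fixed effects, intercept first
    re_var: float               # random-intercept variance
    resid_var: float            # residual variance
    converged: bool
    result: object = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return len(self.endog)

    @property
    def n_groups(self) -> int:
        return len(pd.unique(self.groups))


@dataclass
class MixedModelResult:
    """Standardized coefficients with bootstrap CIs and fit summaries."""

    response: str
    coefficients: pd.DataFrame  # predictor, estimate, ci_low, ci_high, significant
    re_var: float
    resid_var: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    group: str = "site_id",
) -> LMMFit:
    """REML fit of ``response ~ predictors + (1 | group)``.

    Expects variables already transformed and z-scored, so the fixed-effect
    estimates are standardized coefficients.  A singular fit (group variance
    collapsing to zero) is returned with a warning, not raised.
    """
    work = table[[response, *predictors, group]].dropna()
    y = work[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(work))] +
                        [work[p].to_numpy(dtype=float) for p in predictors])
    groups = work[group].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        result = model.fit(reml=True)
    converged = bool(getattr(result, "converged", True))
    if not converged:
        # MixedLM stalls on boundary cases (e.g. an exact linear fit with
        # zero residual variance); the profiled solver handles them
        warnings.warn(f"{response}: MixedLM did not converge, "
                      "using profiled REML solution", stacklevel=2)
        codes, _ = pd.factorize(groups)
        params, re_var, resid_var = profile_reml_intercept(y, X, codes)
        return LMMFit(
            response=response, predictors=list(predictors), endog=y, exog=X,
            groups=groups, params=params, re_var=re_var,
            resid_var=resid_var, converged=True, result=result)
    re_var = float(np.asarray(result.cov_re)[0, 0])
    if re_var <= 1e-10:
        warnings.warn(f"{response}: singular fit, group variance ~ 0", stacklevel=2)
    return LMMFit(
        response=response,
        predictors=list(predictors),
        endog=y,
        exog=X,
        groups=groups,
        params=np.asarray(result.fe_params, dtype=float),
        re_var=re_var,
        resid_var=float(result.scale),
        converged=converged,
        result=result,
    )


def r2_components(var_fixed: float, var_group: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R2 from variance components.

    r2m = var_f / (var_f + var_g + var_e); r2c adds the group variance to
    the numerator.
    """
    denom = var_fixed + var_group + var_resid
    if denom <= 0:
        return 0.0, 0.0
    return var_fixed / denom, (var_fixed + var_group) / denom


def r2_glmm(fit: LMMFit) -> tuple[float, float]:
    """Marginal/conditional R2 with var_fixed from the fixed linear predictor."""
    if fit.exog.shape[1] > 1:
        eta = fit.exog[:, 1:] @ fit.params[1:]
        var_fixed = float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0
    else:
        var_fixed = 0.0
    return r2_components(var_fixed, fit.re_var, fit.resid_var)


def profile_reml_intercept(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int | None = None
) -> tuple[np.ndarray, float, float]:
    """REML fit of a Gaussian random-intercept model by 1-D profiling.

    For ``y = X b + u[codes] + e`` with iid group intercepts, the REML
    criterion depends on the single variance ratio ``theta = var_u/var_e``
    once ``b`` and ``var_e`` are profiled out; group-sum identities make
    each evaluation O(n).  Returns ``(b, var_u, var_e)``.  Used for the
    thousands of parametric-bootstrap refits where a general-purpose fitter
    would dominate the runtime; agrees with the MixedLM optimum (verified
    in the test suite).
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_groups is None:
        n_groups = int(codes.max()) + 1
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)

    def components(theta: float):
        c = theta / (1.0 + theta * sizes)          # per-group shrinkage
        A = xtx - (Sx * c[:, None]).T @ Sx         # X' V^-1 X
        b_vec = xty - Sx.T @ (c * Sy)              # X' V^-1 y
        beta = np.linalg.solve(A, b_vec)
        q = yty - float(c @ (Sy ** 2)) - float(beta @ b_vec)
        return A, beta, max(q, 1e-300)

    def neg_reml(log_theta: float) -> float:
        theta = np.exp(log_theta)
        A, _, q = components(theta)
        sign, logdet_a = np.linalg.slogdet(A)
        logdet_v = float(np.log1p(theta * sizes).sum())
        return (n - p) * np.log(q) + logdet_v + logdet_a

    res = minimize_scalar(neg_reml, bounds=(-20.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    theta = float(np.exp(res.x))
    _, beta, q = components(theta)
    var_e = q / (n - p)
    # treat a boundary solution as a zero variance component
    var_u = 0.0 if res.x <= -19.0 else theta * var_e
    return beta, var_u, var_e


def bootstrap_ci(
    fit: LMMFit,
    n_sim: int = DEFAULT_BOOTSTRAP_N,
    level: float = DEFAULT_CI_LEVEL,
    seed: int | None = DEFAULT_SEED,
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile CIs for the fixed effects.

    Responses are simulated from the fitted Gaussian model (new random
    intercepts and residuals at the estimated variances), the model refitted
    and percentile intervals taken per coefficient.  An effect is flagged
    significant when its interval excludes zero.
    """
    rng = np.random.default_rng(seed)
    codes, _ = pd.factorize(fit.groups)
    n_g = codes.max() + 1
    mu = fit.exog @ fit.params
    sd_u = float(np.sqrt(max(fit.re_var, 0.0)))
    sd_e = float(np.sqrt(fit.resid_var))

    draws = np.full((n_sim, len(fit.params)), np.nan)
    failures = 0
    for i in range(n_sim):
        u = rng.normal(0.0, sd_u, n_g)
        y = mu + u[codes] + rng.normal(0.0, sd_e, len(mu))
        try:
            beta, _, _ = profile_reml_intercept(y, fit.exog, codes, n_g)
            draws[i] = beta
        except np.linalg.LinAlgError:
            failures += 1
    if failures > max_failure_rate * n_sim:
        raise RuntimeError(
            f"{failures}/{n_sim} bootstrap refits failed (> {max_failure_rate:.0%})")
    ok = ~np.isnan(draws).any(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(draws[ok], [100 * alpha, 100 * (1 - alpha)], axis=0)

    names = ["intercept", *fit.predictors]
    frame = pd.DataFrame({
        "predictor": names,
        "estimate": fit.params,
        "ci_low": lo,
        "ci_high": hi,
    })
    frame["significant"] = (frame["ci_low"] > 0) | (frame["ci_high"] < 0)
    return frame


def fit_standardized_lmm(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    group: str = "site_id",
    transforms: Mapping[str, str] | None = None,
    bootstrap_n: int = DEFAULT_BOOTSTRAP_N,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int | None = DEFAULT_SEED,
    vif_threshold: float = VIF_THRESHOLD,
) -> MixedModelResult:
    """Transform -> z-score -> VIF screen -> REML fit -> bootstrap CIs.

    ``transforms`` overrides the role-based default assignment per variable.
    """
    transforms = dict(transforms or {})
    work = table[[response, *predictors, group]].dropna().copy()
    for var in (response, *predictors):
        kind = transforms.get(var, default_transform_kind(var, work[var]))
        work[var] = zscore(transform(work[var], kind))
    if len(predictors) >= 2:
        screen_collinearity(work[list(predictors)], threshold=vif_threshold)
    fit = fit_lmm(work, response, predictors, group=group)
    coef = bootstrap_ci(fit, n_sim=bootstrap_n, level=ci_level, seed=seed)
    r2m, r2c = r2_glmm(fit)
    return MixedModelResult(
        response=response,
        coefficients=coef,
        re_var=fit.re_var,
        resid_var=fit.resid_var,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=fit.n_obs,
        n_groups=fit.n_groups,
    )


def driver_analysis(
    table: pd.DataFrame,
    responses: Sequence[str],
    abiotic: Sequence[str] = ("mat_c", "dryness"),
    group: str = "site_id",
    full: bool = True,
    simple: bool = True,
    soil_by_response: Mapping[str, str] | None = None,
    transforms: Mapping[str, str] | None = None,
    bootstrap_n: int = DEFAULT_BOOTSTRAP_N,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int | None = DEFAULT_SEED,
    on_error: str = "raise",
) -> dict[tuple[str, str], MixedModelResult]:
    """Fit the abiotic driver models for each response on a plot-level table.

    ``simple`` models regress the response on each abiotic variable alone;
    the ``full`` model includes all abiotic variables (plus the
    response-specific soil variable when given), always with a random site
    intercept.  With ``on_error='skip'`` a model whose screening or fit
    fails is dropped with a warning instead of aborting the set.
    Returns ``{(response, model_name): MixedModelResult}``.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    out: dict[tuple[str, str], MixedModelResult] = {}
    soil_by_response = dict(soil_by_response or {})

    def _fit(key, preds):
        try:
            out[key] = fit_standardized_lmm(
                table, key[0], preds, group=group, transforms=transforms,
                bootstrap_n=bootstrap_n, ci_level=ci_level, seed=seed)
        except (CollinearityError, ValueError, RuntimeError):
            if on_error == "raise":
                raise
            warnings.warn(f"driver model {key} skipped", stacklevel=3)

    for response in responses:
        preds_full = list(abiotic)
        soil_var = soil_by_response.get(response)
        if soil_var:
            preds_full.append(soil_var)
        if simple:
            for pred in preds_full:
                _fit((response, f"simple:{pred}"), [pred])
        if full and len(preds_full) >= 2:
            _fit((response, "full"), preds_full)
    return out


# ---------------------------------------------------------------------------
# Rank-based group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    chi_square: float
    df: int
    p_value: float
    pairwise: pd.DataFrame | None = None


def _average_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    ranks = np.empty(x.size)
    i = 0
    n = x.size
    while i < n:
        j = i
        while j + 1 < n and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def kruskal_h(groups: Sequence[Sequence[float]]) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H statistic and degrees of freedom."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    allv = np.concatenate(arrays)
    n = allv.size
    ranks = _average_ranks(allv)
    h = 0.0
    pos = 0
    for a in arrays:
        r = ranks[pos:pos + a.size]
        h += r.sum() ** 2 / a.size
        pos += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(allv, return_counts=True)
    tie = ((counts ** 3 - counts).sum()) / (n ** 3 - n) if n > 1 else 0.0
    d = 1.0 - tie
    if d == 0.0:  # all values identical
        return 0.0, len(arrays) - 1
    return float(h / d), len(arrays) - 1


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """k-sample Kruskal-Wallis test with chi-square reference distribution."""
    h, df = kruskal_h(groups)
    p = float(special.chdtrc(df, h)) if h > 0 else 1.0
    return GroupTestResult(chi_square=h, df=df, p_value=p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "holm",
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dunn pairwise mean-rank comparisons after a Kruskal-Wallis test.

    z uses the tie-corrected variance; two-sided p-values are adjusted by
    Holm (default) or Bonferroni.  Empty groups are excluded with a warning.
    """
    if adjustment not in ("holm", "bonferroni"):
        raise ValueError("adjustment must be 'holm' or 'bonferroni'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    keep = [i for i, a in enumerate(arrays) if a.size > 0]
    if len(keep) < len(arrays):
        warnings.warn("excluding empty group(s) from Dunn comparisons", stacklevel=2)
    arrays = [arrays[i] for i in keep]
    labels = [labels[i] for i in keep]
    if len(arrays) < 2:
        raise ValueError("need >= 2 non-empty groups")

    allv = np.concatenate(arrays)
    n = allv.size
    ranks = _average_ranks(allv)
    mean_ranks, sizes = [], []
    pos = 0
    for a in arrays:
        mean_ranks.append(ranks[pos:pos + a.size].mean())
        sizes.append(a.size)
        pos += a.size
    _, counts = np.unique(allv, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": float(z),
                     "p_raw": float(2.0 * sps.norm.sf(abs(z)))})
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = multipletests(frame["p_raw"], method=adjustment)[1]
    return frame


def compact_letters(
    labels: Sequence[str],
    pairwise: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display: groups not significantly different share a letter."""
    sets: list[set[str]] = [set(labels)]
    sig = pairwise[pairwise["p_adjusted"] < alpha]
    for row in sig.itertuples():
        new: list[set[str]] = []
        for s in sets:
            if row.group_a in s and row.group_b in s:
                new.append(s - {row.group_a})
                new.append(s - {row.group_b})
            else:
                new.append(s)
        # drop subsets and duplicates
        uniq: list[set[str]] = []
        for s in new:
            if s and not any(s < t or s == t for t in uniq):
                uniq = [t for t in uniq if not t < s]
                uniq.append(s)
        sets = uniq
    letters = {lab: "" for lab in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for lab in labels:
            if lab in s:
                letters[lab] += letter
    return letters
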