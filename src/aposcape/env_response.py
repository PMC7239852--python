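"""Environmental modulation of sexuality: screening, GLM and response model.

The central empirical question is how the proportion of sexual reproduction
in facultative apomictic populations responds to climate, in particular the
mean diurnal temperature range (MDR, bioclim 2, degrees C).  This module

* screens a table of bioclim-style covariates against per-population
  pathway proportions by Pearson correlation;
* fits a Gaussian GLM with inverse link, mu = 1/(b0 + b1 x), the classic
  first-pass model for a bounded, saturating response;
* fits a four-parameter bounded logistic response
  ``S(x) = s_lo + (s_hi - s_lo) / (1 + exp(-k (x - x0)))``
  by residual-sum-of-squares grid search with local least-squares
  refinement.  The upper bound ``s_hi < 1`` encodes the biological
  observation that full sexuality is never reached in these polyploids;
* tests the significance of the gradient parameter ``k`` by nonparametric
  case-resampling bootstrap (percentile CI, two-sided sign rule);
* predicts pathway proportions at unobserved MDR values and compares them
  with common-garden observations;
* groups populations of matched sexual reproductive potential to test the
  within-group trend of sexual efficiency along MDR.

The logistic mean function is pluggable: any callable ``f(x, *params)``
with a matching grid specification can be swapped in via ``fit_response``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .repro_stats import StageComparison

__all__ = [
    "GlmFit",
    "ResponseFit",
    "BootstrapResult",
    "PotentialGroup",
    "bounded_logistic",
    "default_grid",
    "pearson_screen",
    "fit_glm_inverse_gaussian",
    "fit_response",
    "bootstrap_gradient",
    "predict_response",
    "validate_against_garden",
    "potential_matched_groups",
]


# ---------------------------------------------------------------------------
# mean function and grids
# ---------------------------------------------------------------------------


def bounded_logistic(x, s_lo: float, s_hi: float, k: float, x0: float):
    """Bounded logistic S(x) = s_lo + (s_hi - s_lo) / (1 + exp(-k (x - x0)))."""
    z = np.clip(-k * (np.asarray(x, dtype=float) - x0), -700, 700)
    return s_lo + (s_hi - s_lo) / (1.0 + np.exp(z))


def default_grid(x: np.ndarray) -> dict[str, np.ndarray]:
    """Default parameter grid for the bounded logistic.

    Plateaus span the admissible proportion range; the gradient grid is
    log-spaced in magnitude over [0.1, 5] and symmetric in sign so that
    decreasing responses and the no-gradient null are representable;
    midpoints cover the observed covariate span.
    """
    mags = np.geomspace(0.1, 5.0, 20)
    return {
        "s_lo": np.arange(0.0, 0.30001, 0.02),
        "s_hi": np.arange(0.2, 0.95001, 0.05),
        "k": np.concatenate([-mags[::-1], mags]),
        "x0": np.linspace(float(np.min(x)), float(np.max(x)), 20),
    }


@dataclass
class GlmFit:
    """Gaussian inverse-link GLM results for one covariate."""

    intercept: float
    slope: float
    t_values: tuple[float, float]
    p_values: tuple[float, float]
    n: int
    converged: bool
    link: str = "inverse"
    family: str = "gaussian"

    def predict(self, x) -> np.ndarray:
        return 1.0 / (self.intercept + self.slope * np.asarray(x, dtype=float))


@dataclass
class BootstrapResult:
    ci_k: tuple[float, float]
    p_k: float
    k_samples: np.ndarray
    n_failures: int


@dataclass
class ResponseFit:
    """Fitted bounded-logistic response of sexual proportion to a covariate."""

    params: tuple[float, float, float, float]  # (s_lo, s_hi, k, x0)
    rss: float
    grid_params: tuple[float, float, float, float]
    grid_rss: float
    n: int
    x_span: tuple[float, float]
    k_identified: bool = True
    bootstrap: BootstrapResult | None = None

    @property
    def s_lo(self) -> float:
        return self.params[0]

    @property
    def s_hi(self) -> float:
        return self.params[1]

    @property
    def k(self) -> float:
        return self.params[2]

    @property
    def x0(self) -> float:
        return self.params[3]

    def __call__(self, x):
        return bounded_logistic(x, *self.params)


@dataclass(frozen=True)
class PotentialGroup:
    population_ids: tuple[str, ...]
    mean_potential: float
    mdr_span: tuple[float, float]
    trend_slope: float | None  # None when the group is too small for a trend


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------


def pearson_screen(
    env: pd.DataFrame,
    props: pd.DataFrame,
    stage: str = "ovule",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Correlate every covariate with sexual and apomictic proportions.

    ``env`` holds ``population_id`` plus covariate columns; ``props`` holds
    ``population_id`` and ``sexual``/``apomictic`` proportion columns (for
    the given stage).  Returns one row per covariate with r and two-sided p
    per pathway, ranked by |r_sexual|, and a ``selected`` flag for
    |r| >= threshold.  Constant covariates are skipped with a warning.
    When the proportions are complementary, r_apomictic = -r_sexual.
    """
    merged = env.merge(props, on="population_id", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least three populations with both records")
    rows = []
    covariates = [c for c in env.columns if c != "population_id"]
    for cov in covariates:
        x = merged[cov].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"covariate {cov!r} is constant; skipped", stacklevel=2)
            continue
        r_s, p_s = stats.pearsonr(x, merged["sexual"])
        r_a, p_a = stats.pearsonr(x, merged["apomictic"])
        rows.append(
            {
                "covariate": cov,
                "stage": stage,
                "r_sexual": float(r_s),
                "p_sexual": float(p_s),
                "r_apomictic": float(r_a),
                "p_apomictic": float(p_a),
                "selected": abs(r_s) >= threshold or abs(r_a) >= threshold,
            }
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["r_sexual"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def fit_glm_inverse_gaussian(x: Sequence[float], y: Sequence[float]) -> GlmFit:
    """Gaussian GLM with inverse link, mu = 1/(b0 + b1 x), fitted by IRLS.

    t statistics use the t distribution with df = n - 2.  Raises if the
    linear predictor crosses zero on the data range (mu would blow up) or
    IRLS fails to converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.any(y == 0):
        raise ValueError("response contains zeros; inverse link undefined — rescale or offset")
    if np.ptp(y) == 0.0:
        # constant response: mu = y exactly, no covariate effect
        return GlmFit(
            intercept=1.0 / float(y[0]),
            slope=0.0,
            t_values=(math.inf, 0.0),
            p_values=(0.0, 1.0),
            n=len(x),
            converged=True,
        )
    model = sm.GLM(
        y,
        sm.add_constant(x),
        family=sm.families.Gaussian(link=sm.families.links.InversePower()),
    )
    with warnings.catch_warnings():
        # noise-free data fits exactly; statsmodels reports it as perfect
        # prediction and never flags IRLS convergence
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-10, use_t=True)
    exact_fit = res.deviance <= 1e-12 * max(1.0, float(np.sum(y**2)))
    if not res.converged and not exact_fit:
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations (last params {res.params})"
        )
    eta = res.params[0] + res.params[1] * x
    if np.any(eta <= 0) and np.any(eta >= 0) and not (np.all(eta > 0) or np.all(eta < 0)):
        raise RuntimeError(
            "fitted linear predictor crosses zero on the data range; rescale the response"
        )
    return GlmFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        t_values=(float(res.tvalues[0]), float(res.tvalues[1])),
        p_values=(float(res.pvalues[0]), float(res.pvalues[1])),
        n=len(x),
        converged=bool(res.converged or exact_fit),
    )


# ---------------------------------------------------------------------------
# nonlinear response model
# ---------------------------------------------------------------------------


def _grid_search(
    x: np.ndarray,
    y: np.ndarray,
    grid: dict[str, np.ndarray],
    form: Callable = bounded_logistic,
) -> tuple[tuple[float, float, float, float], float]:
    s_lo, s_hi, k, x0 = (np.asarray(grid[p], dtype=float) for p in ("s_lo", "s_hi", "k", "x0"))
    combos = np.array(np.meshgrid(s_lo, s_hi, k, x0, indexing="ij")).reshape(4, -1).T
    combos = combos[combos[:, 0] < combos[:, 1]]
    if len(combos) == 0:
        raise ValueError("empty or degenerate grid (need s_lo < s_hi)")
    # vectorized RSS over the whole grid: (P, n)
    pred = form(x[None, :], combos[:, 0:1], combos[:, 1:2], combos[:, 2:3], combos[:, 3:4])
    rss = np.sum((y[None, :] - pred) ** 2, axis=1)
    best = int(np.argmin(rss))
    return tuple(combos[best]), float(rss[best])


def _refine(
    x: np.ndarray,
    y: np.ndarray,
    start: Sequence[float],
    form: Callable = bounded_logistic,
    xtol: float = 1e-12,
    max_nfev: int | None = None,
) -> tuple[tuple[float, float, float, float], float, bool]:
    """Bounded least-squares polish; reports success flag."""
    lo = [0.0, 1e-3, -20.0, float(np.min(x)) - 2 * np.ptp(x) - 1.0]
    hi = [0.999, 0.999, 20.0, float(np.max(x)) + 2 * np.ptp(x) + 1.0]
    start = np.clip(np.asarray(start, dtype=float), lo, hi)

    def resid(theta):
        return y - form(x, *theta)

    try:
        sol = optimize.least_squares(
            resid, start, bounds=(lo, hi), method="trf", xtol=xtol, max_nfev=max_nfev
        )
    except Exception:
        return tuple(start), float(np.sum(resid(start) ** 2)), False
    s_lo_hat, s_hi_hat, k_hat, x0_hat = sol.x
    if s_lo_hat > s_hi_hat:
        # S(x; a, b, k, x0) == S(x; b, a, -k, x0): normalize to a <= b
        s_lo_hat, s_hi_hat, k_hat = s_hi_hat, s_lo_hat, -k_hat
    params = (float(s_lo_hat), float(s_hi_hat), float(k_hat), float(x0_hat))
    rss = float(np.sum(sol.fun**2))
    # status 0 means the evaluation budget ran out; the iterate is still a
    # valid descent point (callers guard against RSS regressions)
    return params, rss, bool(sol.status >= 0)


def fit_response(
    x: Sequence[float],
    y: Sequence[float],
    grid: dict[str, np.ndarray] | None = None,
    form: Callable = bounded_logistic,
    refine: bool = True,
) -> ResponseFit:
    """Fit the bounded-logistic response by grid search + local refinement.

    The refined fit is only adopted when it does not increase the RSS, so
    ``fit.rss <= fit.grid_rss`` always holds.  When the fitted plateaus
    nearly coincide (flat response) the gradient is unidentifiable and
    ``k_identified`` is set False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least five populations")
    if grid is None:
        grid = default_grid(x)
    grid_params, grid_rss = _grid_search(x, y, grid, form)
    params, rss = grid_params, grid_rss
    if refine:
        r_params, r_rss, ok = _refine(x, y, grid_params, form)
        if ok and r_rss <= grid_rss:
            params, rss = r_params, r_rss
    # the gradient is unidentified whenever the fitted curve is nearly flat
    # over the observed span (either s_hi ~ s_lo or k ~ 0)
    spread = abs(
        float(form(np.max(x), *params)) - float(form(np.min(x), *params))
    )
    k_identified = spread > 0.02
    if not k_identified:
        warnings.warn(
            "fitted response is nearly flat over the data span; "
            "gradient k is unidentified",
            stacklevel=2,
        )
    return ResponseFit(
        params=params,
        rss=rss,
        grid_params=grid_params,
        grid_rss=grid_rss,
        n=len(x),
        x_span=(float(np.min(x)), float(np.max(x))),
        k_identified=k_identified,
    )


def bootstrap_gradient(
    x: Sequence[float],
    y: Sequence[float],
    fit: ResponseFit | None = None,
    B: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    form: Callable = bounded_logistic,
    max_failure_rate: float = 0.10,
) -> BootstrapResult:
    """Case-resampling bootstrap of the gradient parameter k.

    Pairs (x_i, y_i) are resampled with replacement and the model is refit
    per replicate (a bounded least-squares polish warm-started at the
    full-data estimate).  Returns the percentile 95% CI for k and the
    two-sided sign p-value ``2 min(Pr*(k<=0), Pr*(k>=0))`` clipped to
    [2/B, 1].  Raises if more than 10% of replicate fits fail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least five populations")
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if fit is None:
        fit = fit_response(x, y, form=form)
    # a coarse per-replicate grid keeps the sign of k free to flip when the
    # resampled data favor it; a warm start alone would inherit the
    # full-data sign even when the gradient is unidentified
    coarse = {
        "s_lo": np.array([0.0, 0.1, 0.2, 0.3]),
        "s_hi": np.array([0.2, 0.45, 0.7, 0.95]),
        "k": np.array([-5.0, -2.0, -0.7, -0.2, 0.2, 0.7, 2.0, 5.0]),
        "x0": np.linspace(float(np.min(x)), float(np.max(x)), 6),
    }
    ks, failures = [], 0
    n = len(x)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        g_params, g_rss = _grid_search(xb, yb, coarse, form)
        warm_rss = float(np.sum((yb - form(xb, *fit.params)) ** 2))
        start = fit.params if warm_rss <= g_rss else g_params
        params, _, ok = _refine(xb, yb, start, form, xtol=1e-8, max_nfev=40)
        if ok:
            ks.append(params[2])
        else:
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    ks = np.asarray(ks)
    ci = (float(np.percentile(ks, 2.5)), float(np.percentile(ks, 97.5)))
    p = 2.0 * min(np.mean(ks <= 0.0), np.mean(ks >= 0.0))
    p_k = float(np.clip(p, 2.0 / B, 1.0))
    result = BootstrapResult(ci_k=ci, p_k=p_k, k_samples=ks, n_failures=failures)
    fit.bootstrap = result
    return result


def predict_response(fit: ResponseFit, mdr: float) -> tuple[float, float]:
    """(sexual, apomictic) proportions predicted at one MDR value.

    The pair sums to 1; the sexual component stays strictly inside
    (s_lo, s_hi).  Extrapolation beyond the training span is allowed but
    flagged with a warning.
    """
    if not fit.x_span[0] <= mdr <= fit.x_span[1]:
        warnings.warn(
            f"MDR {mdr} outside the fitted span {fit.x_span}; extrapolating",
            stacklevel=2,
        )
    s = float(fit(mdr))
    return (s, 1.0 - s)


def validate_against_garden(
    fit: ResponseFit, garden_props: Sequence[float], mdr: float
) -> StageComparison:
    """One-sample t of common-garden sexual proportions against the prediction.

    df = n - 1, two-sided.  With zero variance an exact-match check is
    reported instead of a t statistic.
    """
    obs = np.asarray(garden_props, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least two garden observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = predict_response(fit, mdr)[0]
    if np.allclose(obs.std(ddof=1), 0.0):
        match = bool(np.allclose(obs.mean(), pred))
        return StageComparison(0.0 if match else np.inf, len(obs) - 1.0,
                               1.0 if match else 0.0, "exact_match")
    res = stats.ttest_1samp(obs, pred)
    return StageComparison(float(res.statistic), len(obs) - 1.0, float(res.pvalue), "one_sample_t")


def potential_matched_groups(
    populations: pd.DataFrame,
    tolerance: float = 0.02,
    min_group_size: int = 3,
) -> list[PotentialGroup]:
    """Group populations of similar sexual potential; trend of efficiency vs MDR.

    Populations are sorted by ``potential_sexual`` and greedily grouped so
    that every member stays within ``tolerance`` of the running group mean.
    For groups of at least ``min_group_size`` the least-squares slope of
    ``efficiency_sexual`` on ``mdr`` is reported; smaller groups get
    ``trend_slope=None`` (insufficient).  A positive slope within a group of
    equal potential is the signature of environmentally promoted sexuality.
    """
    req = {"population_id", "potential_sexual", "mdr", "efficiency_sexual"}
    missing = req - set(populations.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    if len(populations) < 3:
        raise ValueError("need at least three populations")
    df = populations.sort_values("potential_sexual").reset_index(drop=True)
    groups: list[list[int]] = []
    current: list[int] = []
    for i, pot in enumerate(df["potential_sexual"]):
        if not current:
            current = [i]
            continue
        mean_with = np.mean(df["potential_sexual"].iloc[current + [i]])
        members = df["potential_sexual"].iloc[current + [i]]
        if np.all(np.abs(members - mean_with) <= tolerance):
            current.append(i)
        else:
            groups.append(current)
            current = [i]
    if current:
        groups.append(current)
    out = []
    for idx in groups:
        sub = df.iloc[idx]
        slope = None
        if len(sub) >= min_group_size and sub["mdr"].nunique() > 1:
            slope = float(np.polyfit(sub["mdr"], sub["efficiency_sexual"], 1)[0])
        out.append(
            PotentialGroup(
                population_ids=tuple(sub["population_id"]),
                mean_potential=float(sub["potential_sexual"].mean()),
                mdr_span=(float(sub["mdr"].min()), float(sub["mdr"].max())),
                trend_slope=slope,
            )
        )
    return out
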