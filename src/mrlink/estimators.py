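"""Causal-effect estimators for two-sample Mendelian randomization.

Four models operate on harmonized exposure/outcome effect pairs:

* ``wald_ratio`` — the single-instrument estimate beta_out / beta_exp with a
  first-order delta-method standard error;
* ``ivw`` — inverse-variance-weighted regression of outcome on exposure
  effects through the origin (multiplicative random effects: the standard
  error is inflated by the residual scale when it exceeds 1);
* ``egger`` — the same weighted regression with a free intercept; the slope
  is robust to directional pleiotropy under InSIDE and the intercept
  estimates its average size;
* ``weighted_median`` — the median of the inverse-variance-weighted empirical
  distribution of per-SNP ratios, consistent while valid instruments carry
  more than half the weight; its standard error comes from a parametric
  bootstrap.

Estimates are log odds ratios for a binary outcome; ``to_odds_scale``
converts to OR with a 95% Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: z quantile used for 95% intervals throughout.
Z975 = 1.959964

_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class MREstimate:
    """One estimator's output on the log-odds and odds-ratio scales."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float
    ci_low: float
    ci_high: float
    extra: dict = field(default_factory=dict)


def to_odds_scale(beta: float, se: float) -> tuple[float, float, float]:
    """exp-transform a log-odds estimate: (OR, 95% CI low, 95% CI high)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z975 * se)),
        float(np.exp(beta + Z975 * se)),
    )


def _normal_p(beta: float, se: float) -> float:
    z = beta / se
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))


def _t_p(beta: float, se: float, df: int) -> float:
    t = beta / se
    return float(np.clip(2.0 * stats.t.sf(abs(t), df), _P_FLOOR, 1.0))


def _finish(method: str, beta: float, se: float, pval: float, n_snp: int,
            extra: dict | None = None) -> MREstimate:
    or_, lo, hi = to_odds_scale(beta, se)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      pval=pval, n_snp=n_snp, or_=or_, ci_low=lo, ci_high=hi,
                      extra=extra or {})


def _as_arrays(pairs: pd.DataFrame):
    bx = pairs["beta_exp"].to_numpy(dtype=float)
    sx = pairs["se_exp"].to_numpy(dtype=float)
    by = pairs["beta_out"].to_numpy(dtype=float)
    sy = pairs["se_out"].to_numpy(dtype=float)
    return bx, sx, by, sy


def wald_ratio(pair: pd.DataFrame | pd.Series) -> MREstimate:
    """Single-instrument ratio estimate beta_out/beta_exp.

    The standard error |se_out/beta_exp| is the first-order delta-method
    approximation (exposure-side uncertainty ignored); the p-value is a
    two-sided standard-normal test.
    """
    if isinstance(pair, pd.Series):
        pair = pair.to_frame().T
    if len(pair) != 1:
        raise ValueError("wald_ratio takes exactly one harmonized pair")
    bx = float(pair["beta_exp"].iloc[0])
    by = float(pair["beta_out"].iloc[0])
    sy = float(pair["se_out"].iloc[0])
    if bx == 0:
        raise ValueError("null instrument: exposure effect is zero")
    beta = by / bx
    se = abs(sy / bx)
    return _finish("wald_ratio", beta, se, _normal_p(beta, se), 1)


def ivw(pairs: pd.DataFrame, random_effects: bool = True,
        allow_single: bool = False) -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression).

    Weights are 1/se_out^2; the closed form is
    beta = sum(w * bx * by) / sum(w * bx^2).  Under the default multiplicative
    random-effects model the fixed-effect standard error is inflated by the
    residual scale when it exceeds 1.
    """
    bx, _, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j < 2 and not allow_single:
        raise ValueError("ivw needs >= 2 instruments; use wald_ratio for one")
    if j < 1:
        raise ValueError("ivw needs at least one instrument")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    scale = 1.0
    if random_effects and j > 1:
        rss = float(np.sum(w * (by - beta * bx) ** 2))
        scale = max(1.0, np.sqrt(rss / (j - 1)))
    se = se_fixed * scale
    return _finish("ivw", beta, se, _normal_p(beta, se), j,
                   extra={"residual_scale": scale, "se_fixed": se_fixed})


def egger(pairs: pd.DataFrame) -> MREstimate:
    """MR-Egger weighted regression with a free intercept.

    Exposure effects are re-oriented positive (outcome effects co-flipped)
    before fitting so the intercept is interpretable.  Slope and intercept
    standard errors carry the multiplicative residual-scale floor at 1;
    p-values use the t distribution with J-2 degrees of freedom.  The
    intercept, its SE and p (the horizontal-pleiotropy test) are returned in
    ``extra``.
    """
    bx, _, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j < 3:
        raise ValueError("egger needs >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    cov_unscaled = np.diag(fit.normalized_cov_params)
    scale = max(1.0, float(fit.scale))  # weighted RSS / (J - 2), floored
    se_int, se_slope = np.sqrt(cov_unscaled * scale)
    intercept, slope = fit.params
    return _finish(
        "egger", float(slope), float(se_slope),
        _t_p(float(slope), float(se_slope), j - 2), j,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_pval": _t_p(float(intercept), float(se_int), j - 2),
            "residual_scale": float(np.sqrt(scale)),
        },
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted empirical ratio distribution.

    Sorted ratios r_(1..J) with normalized weights w get cumulative positions
    s_j = sum_{k<=j} w_k - w_j/2; the estimate interpolates linearly between
    the ratios bracketing s = 0.5 (clamped to the extremes outside).
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000, *,
                    seed: int | np.random.Generator) -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap standard error.

    Per-SNP ratios beta_out/beta_exp are weighted by (beta_exp/se_out)^2.
    The bootstrap redraws each (beta_exp_j, beta_out_j) from normal
    distributions centred on the observed values with their reported standard
    errors; the SE is the standard deviation of the resampled medians.  A
    seed is mandatory so results are reproducible bit for bit.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j < 3:
        raise ValueError("weighted_median needs >= 3 instruments")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    rr = bys / bxs
    ww = (bxs / sy) ** 2
    order = np.argsort(rr, axis=1)
    rr = np.take_along_axis(rr, order, axis=1)
    ww = np.take_along_axis(ww, order, axis=1)
    ww = ww / ww.sum(axis=1, keepdims=True)
    s = np.cumsum(ww, axis=1) - ww / 2.0
    boots = np.array([np.interp(0.5, s[b], rr[b]) for b in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, _normal_p(beta, se), j,
                   extra={"n_boot": n_boot})
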