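"""Causal-effect estimators for two-sample MR and their inference.

Notation: for instrument *i*, ``gamma_hat`` (γ̂ᵢ) is the variant-exposure
effect and ``Gamma_hat`` (Γ̂ᵢ) the variant-outcome effect, harmonized to a
common effect allele; ``w_i = 1 / se_Gamma_i^2`` throughout (the outcome
effect's reported sampling variance; uncertainty in γ̂ is ignored, as in
the standard summary-data treatment).

* Wald ratio: per-variant estimate Γ̂ᵢ/γ̂ᵢ, SE by the first-order delta
  method se(Γ̂ᵢ)/|γ̂ᵢ| (a second-order version is available).
* IVW: β̂ = Σ wᵢ γ̂ᵢ Γ̂ᵢ / Σ wᵢ γ̂ᵢ² — the inverse-variance-weighted average
  of the Wald ratios, equivalently the no-intercept weighted regression of
  Γ̂ on γ̂.
* MR-Egger: weighted regression Γ̂ᵢ = β₀ + β γ̂ᵢ after orienting all γ̂ᵢ ≥ 0;
  the intercept β₀ estimates average directional horizontal pleiotropy and
  its z-test is the pleiotropy test.
* Cochran's Q: weighted residual sum of squares about the fixed-effect fit,
  chi-square with L−1 (IVW) or L−2 (Egger) df under homogeneity.

"Random-effect" variants use multiplicative overdispersion: SEs are scaled
by max(1, sqrt(Q/df)), so the point estimate is unchanged and the random
SE is never below the fixed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .harmonization import HarmonizedPair

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "egger",
    "cochran_q",
    "wald_inference",
    "heterogeneity_pvalue",
]


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its inference.

    Intercept fields are populated only for the Egger methods.
    """

    method: str  # wald | ivw_fixed | ivw_random | egger_fixed | egger_random
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("estimate SE must be positive")
        if not (self.ci_low <= self.beta_hat <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "ivw" | "egger"
    Q: float
    df: int
    pvalue: float


def heterogeneity_pvalue(Q: float, df: int) -> float:
    """Upper chi-square tail of the heterogeneity statistic."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(stats.chi2.sf(Q, df))


def wald_inference(
    beta_hat: float, se: float, level: float = 0.95, df: int | None = None
) -> tuple[float, float, float]:
    """Symmetric CI and two-sided p-value from an estimate and its SE.

    Normal-theory by default; Student-t with ``df`` degrees of freedom when
    given (used e.g. for Egger inference with L−2 df).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    z = abs(beta_hat) / se
    if df is None:
        crit = stats.norm.ppf(0.5 + level / 2.0)
        p = 2.0 * stats.norm.sf(z)
    else:
        if df <= 0:
            raise ValueError("df must be positive")
        crit = stats.t.ppf(0.5 + level / 2.0, df)
        p = 2.0 * stats.t.sf(z, df)
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return (beta_hat - crit * se, beta_hat + crit * se, p)


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([p.gamma_hat for p in pairs], dtype=float)
    G = np.array([p.Gamma_hat for p in pairs], dtype=float)
    w = np.array([1.0 / p.se_Gamma**2 for p in pairs], dtype=float)
    return g, G, w


def wald_ratio(
    pair: HarmonizedPair, level: float = 0.95, second_order: bool = False
) -> MREstimate:
    """Single-variant causal estimate Γ̂/γ̂.

    First-order delta-method SE by default; ``second_order`` adds the
    contribution of the exposure effect's uncertainty.
    """
    if pair.gamma_hat == 0:
        raise ZeroDivisionError(
            f"{pair.variant_id}: exposure effect is zero (irrelevant instrument)"
        )
    beta = pair.Gamma_hat / pair.gamma_hat
    se = pair.se_Gamma / abs(pair.gamma_hat)
    if second_order:
        se = math.sqrt(se**2 + (pair.Gamma_hat**2 * pair.se_gamma**2) / pair.gamma_hat**4)
    lo, hi, p = wald_inference(beta, se, level)
    return MREstimate("wald", beta, se, lo, hi, p, 1)


def _ivw_point(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Closed-form IVW estimate and fixed-effect SE."""
    denom = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / denom
    return beta, denom**-0.5


def ivw(
    pairs: Sequence[HarmonizedPair],
    effect_model: str = "fixed",
    level: float = 0.95,
    df_policy: str = "normal",
) -> MREstimate:
    """Inverse-variance-weighted estimate over the harmonized instruments.

    ``effect_model="random"`` keeps the same point estimate and inflates the
    SE by max(1, sqrt(Q/(L−1))); it needs at least two instruments.
    """
    if effect_model not in ("fixed", "random"):
        raise ValueError(f"unknown effect model {effect_model!r}")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("IVW needs at least one instrument")
    if effect_model == "random" and len(pairs) < 2:
        raise ValueError("random-effect IVW needs at least two instruments")
    g, G, w = _arrays(pairs)
    if np.any(g == 0):
        raise ZeroDivisionError("an instrument has zero exposure effect")
    beta, se = _ivw_point(g, G, w)
    if effect_model == "random":
        Q = float(np.sum(w * (G - beta * g) ** 2))
        se *= max(1.0, math.sqrt(Q / (len(pairs) - 1)))
    df = len(pairs) - 1 if (df_policy == "t" and len(pairs) > 1) else None
    lo, hi, p = wald_inference(beta, se, level, df=df)
    return MREstimate(f"ivw_{effect_model}", beta, se, lo, hi, p, len(pairs))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares via the normal equations.

    Returns (coef, cov) where cov is the unscaled (X'WX)^-1, i.e. the
    fixed-effect covariance assuming unit residual variance on the
    weighted scale.
    """
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ y)
    return coef, cov


def egger(
    pairs: Sequence[HarmonizedPair],
    effect_model: str = "fixed",
    level: float = 0.95,
    df_policy: str = "normal",
    constrain_intercept: bool = False,
) -> MREstimate:
    """MR-Egger regression: weighted fit of Γ̂ = β₀ + β γ̂ with weights 1/se_Γ².

    Pairs are first re-oriented so every γ̂ᵢ ≥ 0, making the intercept's sign
    convention deterministic.  ``constrain_intercept`` forces β₀ = 0, in which
    case the slope coincides with the IVW estimate (a consistency check).
    ``df_policy="t"`` uses Student-t inference with L−2 df.
    """
    if effect_model not in ("fixed", "random"):
        raise ValueError(f"unknown effect model {effect_model!r}")
    pairs = [p.oriented_positive() for p in pairs]
    L = len(pairs)
    if L < 3:
        raise ValueError("MR-Egger needs at least three instruments")
    g, G, w = _arrays(pairs)
    if constrain_intercept:
        coef, cov = _wls(g, G, w, intercept=False)
        b0, slope = 0.0, float(coef[0])
        se_slope = float(np.sqrt(cov[0, 0]))
        se_b0 = 0.0
        resid = G - slope * g
        q_df = L - 1
    else:
        coef, cov = _wls(g, G, w, intercept=True)
        b0, slope = float(coef[0]), float(coef[1])
        se_b0, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        resid = G - b0 - slope * g
        q_df = L - 2
    if effect_model == "random":
        Q = float(np.sum(w * resid**2))
        scale = max(1.0, math.sqrt(Q / q_df))
        se_slope *= scale
        se_b0 *= scale
    df = q_df if df_policy == "t" else None
    lo, hi, p = wald_inference(slope, se_slope, level, df=df)
    if constrain_intercept:
        b0_p = 1.0
    else:
        _, _, b0_p = wald_inference(b0, se_b0, level, df=df)
    return MREstimate(
        f"egger_{effect_model}",
        slope,
        se_slope,
        lo,
        hi,
        p,
        L,
        intercept=b0,
        intercept_se=se_b0,
        intercept_pvalue=b0_p,
    )


def cochran_q(pairs: Sequence[HarmonizedPair], fitted: MREstimate) -> HeterogeneityResult:
    """Cochran's Q about a fixed-effect IVW or Egger fit.

    Q = Σ wᵢ (Γ̂ᵢ − β̂₀·[egger] − β̂ γ̂ᵢ)², chi-square with L−1 (IVW) or
    L−2 (Egger) df under homogeneity.
    """
    if fitted.method not in ("ivw_fixed", "egger_fixed"):
        raise ValueError("Q is computed on a fixed-effect fit (ivw_fixed or egger_fixed)")
    pairs = list(pairs)
    is_egger = fitted.method == "egger_fixed"
    if is_egger:
        pairs = [p.oriented_positive() for p in pairs]
    g, G, w = _arrays(pairs)
    b0 = fitted.intercept if (is_egger and fitted.intercept is not None) else 0.0
    Q = float(np.sum(w * (G - b0 - fitted.beta_hat * g) ** 2))
    df = len(pairs) - (2 if is_egger else 1)
    if df <= 0:
        raise ValueError("not enough instruments for a heterogeneity test")
    return HeterogeneityResult("egger" if is_egger else "ivw", Q, df, heterogeneity_pvalue(Q, df))
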