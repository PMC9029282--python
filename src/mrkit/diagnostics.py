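"""Sensitivity analyses and outlier screening for two-sample MR.

* ``leave_one_out`` — refit with each instrument removed; the most
  influential variant is the one whose removal moves the estimate most.
* ``single_snp_table`` — per-variant Wald ratios with CIs (forest-plot data).
* ``funnel_data`` — Wald ratio versus precision 1/SE (funnel-plot data;
  asymmetry suggests directional pleiotropy).
* ``outlier_screen`` — a simulation-based global heterogeneity test with
  per-variant outlier p-values, in the style of MR-PRESSO: the observed
  residual sum of squares about leave-one-out IVW fits is ranked against
  parametric replicates drawn under the no-pleiotropy model.

All tables are pure functions of the harmonized pairs; the screen's only
randomness is the mandatory explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw, wald_ratio
from .harmonization import HarmonizedPair

__all__ = [
    "LeaveOneOutResult",
    "OutlierScreenResult",
    "leave_one_out",
    "single_snp_table",
    "funnel_data",
    "outlier_screen",
]


@dataclass
class LeaveOneOutResult:
    rows: list[tuple[str, MREstimate]]  # (excluded variant, estimate on the rest)
    full: MREstimate
    most_influential: str

    def to_frame(self) -> pd.DataFrame:
        data = [
            {
                "excluded": vid,
                "beta_hat": est.beta_hat,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "n_instruments": est.n_instruments,
            }
            for vid, est in self.rows
        ]
        return pd.DataFrame(data)


@dataclass
class OutlierScreenResult:
    rss_observed: float
    global_pvalue: float
    per_variant: list[tuple[str, float, bool]]  # (variant, outlier p, flagged)
    n_sim: int
    seed: int

    @property
    def flagged_ids(self) -> list[str]:
        return [vid for vid, _, flag in self.per_variant if flag]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_variant, columns=["variant_id", "outlier_pvalue", "flagged"]
        )


def leave_one_out(
    pairs: Sequence[HarmonizedPair], method: str = "ivw_fixed", level: float = 0.95
) -> LeaveOneOutResult:
    """Drop-one refits identifying the most influential instrument."""
    if method not in ("ivw_fixed", "ivw_random"):
        raise ValueError("leave-one-out supports ivw_fixed or ivw_random")
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("leave-one-out needs at least two instruments")
    effect_model = method.removeprefix("ivw_")
    full = ivw(pairs, effect_model=effect_model, level=level)
    rows = []
    for i, pair in enumerate(pairs):
        rest = pairs[:i] + pairs[i + 1 :]
        rows.append((pair.variant_id, ivw(rest, effect_model=effect_model, level=level)))
    most = max(rows, key=lambda r: (abs(r[1].beta_hat - full.beta_hat), r[0]))[0]
    return LeaveOneOutResult(rows=rows, full=full, most_influential=most)


def single_snp_table(pairs: Sequence[HarmonizedPair], level: float = 0.95) -> pd.DataFrame:
    """Per-variant Wald-ratio estimates (forest-plot data)."""
    rows = []
    for pair in pairs:
        est = wald_ratio(pair, level=level)
        rows.append(
            {
                "variant_id": pair.variant_id,
                "beta_hat": est.beta_hat,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
            }
        )
    return pd.DataFrame(rows)


def funnel_data(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Wald ratio versus precision (1/SE) per variant (funnel-plot data)."""
    rows = []
    for pair in pairs:
        est = wald_ratio(pair)
        rows.append(
            {"variant_id": pair.variant_id, "wald_ratio": est.beta_hat, "precision": 1.0 / est.se}
        )
    return pd.DataFrame(rows)


def _loo_ivw_beta(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vector of leave-one-out fixed-effect IVW estimates (one per variant)."""
    num = np.sum(w * g * G)
    den = np.sum(w * g * g)
    return (num - w * g * G) / (den - w * g * g)


def outlier_screen(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
) -> OutlierScreenResult:
    """Simulation-based global heterogeneity test with per-variant outlier p-values.

    The observed statistic is RSS = Σ wᵢ (Γ̂ᵢ − β̂₍₋ᵢ₎ γ̂ᵢ)² with
    wᵢ = 1/se_Γᵢ² and β̂₍₋ᵢ₎ the leave-one-out fixed IVW estimate.  Each of
    ``n_sim`` parametric replicates redraws Γ̂ᵢ* ~ N(β̂₍₋ᵢ₎ γ̂ᵢ, se_Γᵢ²) and
    recomputes the statistic (with its own leave-one-out fits); the global
    p-value is the +1-corrected rank of the observed RSS.  Per-variant
    p-values rank each observed term against its simulated distribution and
    are Bonferroni-corrected across the L instruments.  A variant is flagged
    only when the global test also rejects, as recommended for the
    simulation-based outlier procedure.
    """
    pairs = list(pairs)
    L = len(pairs)
    if L < 4:
        raise ValueError("insufficient instruments for outlier screening (need >= 4)")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    g = np.array([p.gamma_hat for p in pairs])
    G = np.array([p.Gamma_hat for p in pairs])
    se = np.array([p.se_Gamma for p in pairs])
    w = 1.0 / se**2

    beta_loo = _loo_ivw_beta(g, G, w)
    terms_obs = w * (G - beta_loo * g) ** 2
    rss_obs = float(np.sum(terms_obs))

    rng = np.random.default_rng(seed)
    # (n_sim, L) replicates under the no-pleiotropy model
    G_sim = beta_loo * g + rng.standard_normal((n_sim, L)) * se
    num = G_sim * (w * g)  # per-variant contributions to Σ w g Γ*
    den = w * g * g
    beta_loo_sim = (num.sum(axis=1, keepdims=True) - num) / (den.sum() - den)
    terms_sim = w * (G_sim - beta_loo_sim * g) ** 2
    rss_sim = terms_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_var = (1 + np.sum(terms_sim >= terms_obs, axis=0)) / (n_sim + 1)
    globally_sig = global_p < threshold
    per_variant = [
        (pairs[i].variant_id, float(p_var[i]), bool(globally_sig and p_var[i] * L < threshold))
        for i in range(L)
    ]
    return OutlierScreenResult(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        per_variant=per_variant,
        n_sim=n_sim,
        seed=seed,
    )
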