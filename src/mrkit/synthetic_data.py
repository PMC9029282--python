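"""Synthetic GWAS summary statistics from a linear structural model.

The generative model: with genotype dosage G_i in {0, 1, 2} at variant *i*,
an unobserved confounder U, and independent noise e_x, e_y,

    X = sum_i gamma_i G_i + xi_x U + e_x          (exposure)
    Y = beta X + sum_i alpha_i G_i + xi_y U + e_y (outcome)

so the per-variant variant-outcome effect is Gamma_i = alpha_i + beta
gamma_i.  gamma_i is the instrument strength, alpha_i horizontal pleiotropy,
and beta the causal effect of X on Y.  Two disjoint cohorts are generated —
exposure associations from one, outcome associations from the other — so
the two-sample design holds by construction.

Two paths produce summary statistics:

* ``generate_cohort_pair`` simulates individuals and runs per-variant
  least-squares regressions (slow, fully faithful; genotype LD via a
  Gaussian-copula threshold construction in blocks).
* ``generate_summary_direct`` draws the effect estimates directly from
  their asymptotic sampling distributions (fast; used for estimator
  calibration at scale).

Pleiotropy regimes for alpha: ``none`` (all zero), ``balanced``
(mean-zero), ``directional_inside`` (non-zero mean, independent of gamma —
InSIDE holds), and ``inside_violating`` (alpha correlated with gamma).

Default parameter values describe the emulated study: an exposure GWAS of
182,413 individuals, an outcome GWAS of 5,756, a thousand variants of which
5% are true instruments with per-allele effects of 0.08-0.15 SD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .summary_data import GeneMap, GwasTable, LdMatrix, SummaryRecord

__all__ = [
    "GammaSpec",
    "AlphaSpec",
    "SimulationConfig",
    "TruthRecord",
    "generate_cohort_pair",
    "generate_summary_direct",
    "generate_validation_set",
    "truth_gene_map",
    "block_ld_matrix",
    "truth_frame",
]

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = tuple(
    (a, b)
    for a, b in itertools.permutations("ACGT", 2)
    if {a, b} not in ({"A", "T"}, {"C", "G"})
)


@dataclass(frozen=True)
class GammaSpec:
    """Distribution of instrument strengths gamma_i.

    A fraction ``frac_nonnull`` of variants get |gamma| drawn uniformly from
    [min_mag, max_mag]; the rest are exactly zero.  ``sign`` is "positive"
    (all gamma >= 0) or "mixed" (random sign).
    """

    frac_nonnull: float = 0.05
    min_mag: float = 0.08
    max_mag: float = 0.15
    sign: str = "positive"

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_nonnull <= 1.0):
            raise ValueError("frac_nonnull must lie in [0, 1]")
        if not (0.0 <= self.min_mag <= self.max_mag):
            raise ValueError("need 0 <= min_mag <= max_mag")
        if self.sign not in ("positive", "mixed"):
            raise ValueError("sign must be 'positive' or 'mixed'")


@dataclass(frozen=True)
class AlphaSpec:
    """Distribution of horizontal-pleiotropy effects alpha_i.

    regimes: ``none`` — alpha = 0; ``balanced`` — alpha ~ N(0, sd²);
    ``directional_inside`` — alpha ~ N(mean, sd²), independent of gamma
    (InSIDE holds); ``inside_violating`` — alpha = mean +
    gamma_coupling * gamma + N(0, sd²) (InSIDE broken).
    Pleiotropy applies only to non-null instruments (null variants have no
    path to either trait).
    """

    regime: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    gamma_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("none", "balanced", "directional_inside", "inside_violating"):
            raise ValueError(f"unknown pleiotropy regime {self.regime!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the structural generative model."""

    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta: float = 0.5
    gamma_dist: GammaSpec = field(default_factory=GammaSpec)
    alpha_dist: AlphaSpec = field(default_factory=AlphaSpec)
    xi_x: float = 0.3
    xi_y: float = 0.3
    confounder_sd: float = 1.0
    e_x_sd: float = 1.0
    e_y_sd: float = 1.0
    n_exposure: int = 182_413
    n_outcome: int = 5_756
    palindromic_fraction: float = 0.2
    ld_block_size: int = 5
    ld_within_r2: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("confounder_sd", "e_x_sd", "e_y_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("cohort sizes must be at least 2")
        if self.n_snps < 1:
            raise ValueError("need at least one variant")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must lie in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_r2 < 1.0):
            raise ValueError("ld_within_r2 must lie in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Per-variant ground truth; Gamma = alpha + beta * gamma exactly."""

    variant_id: str
    gamma: float
    alpha: float
    Gamma: float
    maf: float
    gene: str
    palindromic: bool
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str


def truth_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    cols = [f.name for f in TruthRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in truth])


def _draw_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Ground-truth parameters; shared by both generation paths (same seed)."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_snps
    mafs = rng.uniform(*config.maf_range, size=n)
    if config.ld_block_size > 1 and config.ld_within_r2 > 0:
        # variants in a tight LD block share their allele frequency; this also
        # makes the copula r2 calibration exact (it is maf-matched)
        for start in range(0, n, config.ld_block_size):
            mafs[start : start + config.ld_block_size] = mafs[start]

    gs = config.gamma_dist
    n_nonnull = int(round(gs.frac_nonnull * n))
    gamma = np.zeros(n)
    nonnull = rng.choice(n, size=n_nonnull, replace=False) if n_nonnull else np.array([], int)
    mags = rng.uniform(gs.min_mag, gs.max_mag, size=n_nonnull)
    if gs.sign == "mixed":
        mags *= rng.choice([-1.0, 1.0], size=n_nonnull)
    gamma[nonnull] = mags

    al = config.alpha_dist
    alpha = np.zeros(n)
    if al.regime != "none" and n_nonnull:
        noise = rng.normal(0.0, al.sd, size=n_nonnull) if al.sd > 0 else 0.0
        if al.regime == "balanced":
            alpha[nonnull] = noise
        elif al.regime == "directional_inside":
            alpha[nonnull] = al.mean + noise
        else:  # inside_violating
            alpha[nonnull] = al.mean + al.gamma_coupling * gamma[nonnull] + noise

    palindromic = rng.random(n) < config.palindromic_fraction
    pal_idx = rng.integers(len(_PALINDROMIC_PAIRS), size=n)
    non_idx = rng.integers(len(_NONPALINDROMIC_PAIRS), size=n)

    block = config.ld_block_size
    records = []
    for i in range(n):
        ea, oa = (
            _PALINDROMIC_PAIRS[pal_idx[i]] if palindromic[i] else _NONPALINDROMIC_PAIRS[non_idx[i]]
        )
        records.append(
            TruthRecord(
                variant_id=f"rs{100000 + i}",
                gamma=float(gamma[i]),
                alpha=float(alpha[i]),
                Gamma=float(alpha[i] + config.beta * gamma[i]),
                maf=float(mafs[i]),
                gene=f"GENE{i // block:04d}",
                palindromic=bool(palindromic[i]),
                chrom=str(1 + (i // block) % 22),
                pos=1000 * (i + 1),
                effect_allele=ea,
                other_allele=oa,
            )
        )
    return records


def _latent_rho(target_r2: float, maf: float) -> float:
    """Latent Gaussian correlation giving haplotype correlation sqrt(target_r2).

    Alleles are thresholded bivariate normals, so the allele correlation is
    (P11(rho) - p^2) / (p (1 - p)) with P11 the orthant probability below the
    MAF quantile; invert numerically.
    """
    if target_r2 <= 0:
        return 0.0
    target_r = float(np.sqrt(target_r2))
    t = stats.norm.ppf(maf)

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([t, t], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        return (p11 - maf**2) / (maf * (1 - maf)) - target_r

    return float(optimize.brentq(gap, 0.0, 0.9999, xtol=1e-6))


def _sample_genotypes(
    mafs: np.ndarray, n: int, block: int, within_r2: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_snps) int8 dosages, blockwise-correlated when block > 1."""
    m = len(mafs)
    G = np.empty((n, m), dtype=np.int8)
    if block <= 1 or within_r2 <= 0:
        for j in range(m):
            G[:, j] = rng.binomial(2, mafs[j], size=n)
        return G
    thresholds = stats.norm.ppf(mafs)
    for start in range(0, m, block):
        stop = min(start + block, m)
        size = stop - start
        rho = _latent_rho(within_r2, float(np.mean(mafs[start:stop])))
        cov = np.full((size, size), rho)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        # two haplotypes per individual
        z = rng.standard_normal((2, n, size)) @ chol.T
        hap = z < thresholds[start:stop]
        G[:, start:stop] = (hap[0] + hap[1]).astype(np.int8)
    return G


def _marginal_regressions(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-variant simple least-squares of trait on dosage, vectorized.

    Returns (beta, se, pvalue, eaf).  Works on int8 genotypes in column
    chunks to bound memory.
    """
    n, m = G.shape
    yc = y - y.mean()
    beta = np.empty(m)
    gvar = np.empty(m)
    gbar = np.empty(m)
    chunk = 256
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        Gf = G[:, start:stop].astype(np.float64)
        mu = Gf.mean(axis=0)
        gbar[start:stop] = mu
        v = Gf.var(axis=0)
        gvar[start:stop] = v
        cov = (Gf - mu).T @ yc / n
        with np.errstate(divide="ignore", invalid="ignore"):
            beta[start:stop] = cov / v
    if np.any(gvar == 0):
        raise RuntimeError("monomorphic variant generated; enlarge the cohort or raise the MAF floor")
    yvar = float(np.var(y))
    resid_var = np.maximum(yvar - beta**2 * gvar, np.finfo(float).tiny) * n / (n - 2)
    se = np.sqrt(resid_var / (n * gvar))
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    return beta, se, p, gbar / 2.0


def _table_from_arrays(
    truth: Sequence[TruthRecord],
    beta: np.ndarray,
    se: np.ndarray,
    p: np.ndarray,
    eaf: np.ndarray,
    trait_id: str,
    role: str,
    n: int,
) -> GwasTable:
    records = [
        SummaryRecord(
            variant_id=t.variant_id,
            effect_allele=t.effect_allele,
            other_allele=t.other_allele,
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(p[i]),
            chrom=t.chrom,
            pos=t.pos,
            eaf=float(np.clip(eaf[i], 0.0, 1.0)),
            n=n,
        )
        for i, t in enumerate(truth)
    ]
    return GwasTable.from_records(records, trait_id=trait_id, role=role)


def generate_cohort_pair(
    config: SimulationConfig,
) -> tuple[GwasTable, GwasTable, list[TruthRecord]]:
    """Individual-level simulation of two disjoint cohorts.

    The exposure table comes from per-variant regressions of X on dosage in
    cohort 1; the outcome table from regressions of Y on dosage in cohort 2
    (whose Y is built from that cohort's own X).  Deterministic under the
    config seed.
    """
    truth = _draw_truth(config)
    rng = np.random.default_rng([config.seed, 1])
    mafs = np.array([t.maf for t in truth])
    gamma = np.array([t.gamma for t in truth])
    alpha = np.array([t.alpha for t in truth])

    def cohort_traits(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        G = _sample_genotypes(mafs, n, config.ld_block_size, config.ld_within_r2, rng)
        U = rng.normal(0.0, config.confounder_sd, size=n)
        X = G @ gamma + config.xi_x * U + rng.normal(0.0, config.e_x_sd, size=n)
        Y = config.beta * X + G @ alpha + config.xi_y * U + rng.normal(0.0, config.e_y_sd, size=n)
        return G, X, Y

    G1, X1, _ = cohort_traits(config.n_exposure)
    b, s, p, eaf = _marginal_regressions(G1, X1)
    exposure = _table_from_arrays(
        truth, b, s, p, eaf, "synthetic_exposure", "exposure", config.n_exposure
    )
    del G1, X1

    G2, _, Y2 = cohort_traits(config.n_outcome)
    b, s, p, eaf = _marginal_regressions(G2, Y2)
    outcome = _table_from_arrays(
        truth, b, s, p, eaf, "synthetic_outcome", "outcome", config.n_outcome
    )
    return exposure, outcome, truth


def _trait_variances(config: SimulationConfig, truth: Sequence[TruthRecord]) -> tuple[float, float]:
    """Approximate marginal trait variances implied by the model (LD ignored)."""
    gamma = np.array([t.gamma for t in truth])
    alpha = np.array([t.alpha for t in truth])
    vg = np.array([2 * t.maf * (1 - t.maf) for t in truth])
    u2 = config.confounder_sd**2
    var_x = float(np.sum(gamma**2 * vg) + config.xi_x**2 * u2 + config.e_x_sd**2)
    var_y = float(
        config.beta**2 * var_x
        + np.sum(alpha**2 * vg)
        + 2 * config.beta * np.sum(gamma * alpha * vg)
        + config.xi_y**2 * u2
        + config.e_y_sd**2
        + 2 * config.beta * config.xi_x * config.xi_y * u2
    )
    return var_x, var_y


def _direct_table(
    config: SimulationConfig,
    truth: Sequence[TruthRecord],
    true_effect: np.ndarray,
    trait_var: float,
    n: int,
    trait_id: str,
    role: str,
    rng: np.random.Generator,
) -> GwasTable:
    vg = np.array([2 * t.maf * (1 - t.maf) for t in truth])
    se = np.sqrt(trait_var / (n * vg))
    est = true_effect + rng.standard_normal(len(truth)) * se
    p = np.clip(2.0 * stats.norm.sf(np.abs(est / se)), 1e-300, 1.0)
    mafs = np.array([t.maf for t in truth])
    eaf = np.clip(mafs + rng.standard_normal(len(truth)) * np.sqrt(mafs * (1 - mafs) / (2 * n)), 0, 1)
    return _table_from_arrays(truth, est, se, p, eaf, trait_id, role, n)


def generate_summary_direct(
    config: SimulationConfig,
) -> tuple[GwasTable, GwasTable, list[TruthRecord]]:
    """Draw summary statistics directly from their sampling distributions.

    gamma_hat_i ~ N(gamma_i, se_i^2) and Gamma_hat_i ~ N(alpha_i + beta
    gamma_i, se_i^2) with the asymptotic single-variant regression SE
    sqrt(var(trait) / (n * 2 maf (1 - maf))).  Same truth as the
    individual-level path for the same seed.
    """
    truth = _draw_truth(config)
    rng = np.random.default_rng([config.seed, 2])
    gamma = np.array([t.gamma for t in truth])
    Gamma = np.array([t.Gamma for t in truth])
    var_x, var_y = _trait_variances(config, truth)
    exposure = _direct_table(
        config, truth, gamma, var_x, config.n_exposure, "synthetic_exposure", "exposure", rng
    )
    outcome = _direct_table(
        config, truth, Gamma, var_y, config.n_outcome, "synthetic_outcome", "outcome", rng
    )
    return exposure, outcome, truth


def generate_validation_set(
    config: SimulationConfig,
    truth: Sequence[TruthRecord],
    k: int,
    n_each: int | None = None,
) -> tuple[list[GwasTable], GeneMap]:
    """k additional exposure GWASs from the same truth with independent noise.

    Also returns the variant-to-gene map (one gene per LD block by default),
    which is what gene-level validation consumes.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    n = n_each if n_each is not None else config.n_exposure
    gamma = np.array([t.gamma for t in truth])
    var_x, _ = _trait_variances(config, truth)
    tables = []
    for j in range(k):
        rng = np.random.default_rng([config.seed, 3 + j])
        tables.append(
            _direct_table(
                config, truth, gamma, var_x, n, f"synthetic_exposure_rep{j + 1}", "exposure", rng
            )
        )
    return tables, truth_gene_map(truth)


def truth_gene_map(truth: Sequence[TruthRecord]) -> GeneMap:
    return GeneMap(entries={t.variant_id: t.gene for t in truth})


def block_ld_matrix(truth: Sequence[TruthRecord], config: SimulationConfig) -> LdMatrix:
    """The model's target r^2 matrix: ld_within_r2 within blocks, 0 between."""
    codes = pd.factorize(np.asarray([t.gene for t in truth]))[0]
    r2 = np.equal.outer(codes, codes) * config.ld_within_r2
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(ids=[t.variant_id for t in truth], r2=r2)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience copy with a different seed."""
    return replace(config, seed=seed)
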