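"""End-to-end orchestration of the two-sample MR analysis.

Stages: read inputs -> select instruments -> (optional) gene-level
validation against additional exposure GWASs -> (optional) LD pruning ->
harmonization -> (optional) simulation-based outlier screen ->
estimation (fixed/random IVW and MR-Egger, heterogeneity) ->
sensitivity diagnostics.  Every stage logs its input/output counts and
removal decisions; the run is deterministic given the configuration
(the outlier screen's seed is part of it).

``compare_runs`` gives the per-method percent change in the causal
estimate between two runs (e.g. validated versus unvalidated instrument
sets) — the recommended sensitivity analysis for gene-level validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from .harmonization import HarmonizationReport, HarmonizedPair, harmonize
from .instrument_selection import (
    InstrumentSet,
    ld_prune,
    select_instruments,
    validate_by_shared_genes,
)
from .summary_data import (
    GwasTable,
    read_gene_map,
    read_ld_matrix,
    read_summary_table,
)

__all__ = ["RunConfig", "RunReport", "run_analysis", "compare_runs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs, thresholds and options of one analysis run."""

    exposure_path: str
    outcome_path: str
    validation_paths: list[str] = field(default_factory=list)
    gene_map_path: str | None = None
    ld_path: str | None = None
    out_dir: str | None = None

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    palindromic_policy: str = "infer_by_eaf"
    eaf_ambiguity_band: float = 0.08

    validate: bool = True
    run_outlier_screen: bool = True
    remove_flagged: bool = True
    outlier_n_sim: int = 1000
    outlier_seed: int = 0
    outlier_threshold: float = 0.05
    drop_extreme_wald: bool = False  # manual analyst choice: drop min & max Wald ratio

    ci_level: float = 0.95
    df_policy: str = "normal"  # "normal" | "t"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in (0, 1]")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    """Everything one analysis run produced."""

    config: RunConfig
    stage_counts: dict[str, int]
    instruments: InstrumentSet
    harmonization: HarmonizationReport
    pairs: list[HarmonizedPair]
    estimates: list[est.MREstimate]
    heterogeneity: list[est.HeterogeneityResult]
    single_snp: pd.DataFrame
    funnel: pd.DataFrame
    leave_one_out: diag.LeaveOneOutResult | None
    outlier_screen: diag.OutlierScreenResult | None
    warnings: list[str] = field(default_factory=list)

    def estimate(self, method: str) -> est.MREstimate | None:
        return next((e for e in self.estimates if e.method == method), None)

    def estimates_frame(self) -> pd.DataFrame:
        q_by_model = {h.method: h for h in self.heterogeneity}
        rows = []
        for e in self.estimates:
            h = q_by_model.get(e.method.split("_")[0]) if e.method != "wald" else None
            rows.append(
                {
                    "method": e.method,
                    "beta_hat": e.beta_hat,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pvalue": e.pvalue,
                    "intercept": e.intercept,
                    "intercept_se": e.intercept_se,
                    "intercept_pvalue": e.intercept_pvalue,
                    "n_instruments": e.n_instruments,
                    "Q": h.Q if h else None,
                    "Q_df": h.df if h else None,
                    "Q_pvalue": h.pvalue if h else None,
                }
            )
        return pd.DataFrame(rows)

    def audit_frame(self) -> pd.DataFrame:
        rows = [
            {"variant_id": a.variant_id, "step": a.step, "action": a.action, "reason": a.reason}
            for a in self.instruments.audit
        ]
        rows += [
            {"variant_id": vid, "step": "harmonize", "action": "removed", "reason": reason}
            for vid, reason in self.harmonization.removed
        ]
        return pd.DataFrame(rows, columns=["variant_id", "step", "action", "reason"])


def _pairs_frame(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": p.variant_id,
                "gamma_hat": p.gamma_hat,
                "se_gamma": p.se_gamma,
                "Gamma_hat": p.Gamma_hat,
                "se_Gamma": p.se_Gamma,
                "eaf_exposure": p.eaf_exposure,
                "eaf_outcome": p.eaf_outcome,
                "action": p.action,
                "palindromic": p.palindromic,
            }
            for p in pairs
        ]
    )


def run_analysis(
    config: RunConfig,
    exposure: GwasTable | None = None,
    outcome: GwasTable | None = None,
    validation_tables: list[GwasTable] | None = None,
    gene_map=None,
    ld=None,
) -> RunReport:
    """Execute the full analysis.

    In-memory tables may be passed directly (as the numbered analysis
    drivers and the tests do); otherwise they are read from the configured
    paths.
    """
    warnings: list[str] = []
    if exposure is None:
        exposure = read_summary_table(config.exposure_path, role="exposure")
    if outcome is None:
        outcome = read_summary_table(config.outcome_path, role="outcome")
    if validation_tables is None:
        validation_tables = [
            read_summary_table(p, role="exposure") for p in config.validation_paths
        ]
    if gene_map is None and config.gene_map_path:
        gene_map = read_gene_map(config.gene_map_path)
    if ld is None and config.ld_path:
        ld = read_ld_matrix(config.ld_path)

    counts: dict[str, int] = {"exposure_variants": len(exposure)}
    instruments = select_instruments(exposure, config.p_threshold)
    counts["selected"] = len(instruments)
    if len(instruments) == 0:
        raise RuntimeError("selection stage: no instrument passes the significance threshold")

    if config.validate and validation_tables:
        if gene_map is None:
            raise RuntimeError("validation stage: gene-level validation requires a gene map")
        instruments = validate_by_shared_genes(
            instruments, exposure, validation_tables, gene_map, config.p_threshold
        )
        counts["validated"] = len(instruments)

    if ld is not None:
        instruments = ld_prune(instruments, exposure, ld, config.r2_threshold)
        counts["pruned"] = len(instruments)

    if len(instruments) == 0:
        raise RuntimeError("instrument set is empty before harmonization")
    report = harmonize(
        instruments,
        exposure,
        outcome,
        palindromic_policy=config.palindromic_policy,
        eaf_ambiguity_band=config.eaf_ambiguity_band,
    )
    pairs = list(report.kept)
    counts["harmonized"] = len(pairs)
    if not pairs:
        raise RuntimeError("harmonization stage: no variant could be harmonized")

    screen = None
    if config.run_outlier_screen:
        if len(pairs) >= 4:
            screen = diag.outlier_screen(
                pairs,
                n_sim=config.outlier_n_sim,
                seed=config.outlier_seed,
                threshold=config.outlier_threshold,
            )
            if config.remove_flagged and screen.flagged_ids:
                flagged = set(screen.flagged_ids)
                logger.info("outlier screen removed %d variant(s): %s", len(flagged), sorted(flagged))
                pairs = [p for p in pairs if p.variant_id not in flagged]
        else:
            warnings.append("outlier screen skipped: fewer than 4 instruments")
    counts["post_outlier_screen"] = len(pairs)

    if config.drop_extreme_wald and len(pairs) >= 3:
        ratios = {p.variant_id: p.Gamma_hat / p.gamma_hat for p in pairs}
        lo = min(ratios, key=ratios.get)
        hi = max(ratios, key=ratios.get)
        warnings.append(f"manual drop of extreme Wald ratios: {lo}, {hi}")
        pairs = [p for p in pairs if p.variant_id not in (lo, hi)]
    counts["analyzed"] = len(pairs)

    estimates: list[est.MREstimate] = []
    heterogeneity: list[est.HeterogeneityResult] = []
    level = config.ci_level
    if len(pairs) == 1:
        estimates.append(est.wald_ratio(pairs[0], level=level))
        warnings.append("single instrument: only the Wald ratio is reported")
    else:
        ivw_fixed = est.ivw(pairs, "fixed", level=level, df_policy=config.df_policy)
        estimates.append(ivw_fixed)
        estimates.append(est.ivw(pairs, "random", level=level, df_policy=config.df_policy))
        heterogeneity.append(est.cochran_q(pairs, ivw_fixed))
        if len(pairs) >= 3:
            egger_fixed = est.egger(pairs, "fixed", level=level, df_policy=config.df_policy)
            estimates.append(egger_fixed)
            estimates.append(est.egger(pairs, "random", level=level, df_policy=config.df_policy))
            heterogeneity.append(est.cochran_q(pairs, egger_fixed))
        else:
            warnings.append("fewer than 3 instruments: MR-Egger skipped")

    single = diag.single_snp_table(pairs, level=level)
    funnel = diag.funnel_data(pairs)
    loo = diag.leave_one_out(pairs, level=level) if len(pairs) >= 2 else None

    result = RunReport(
        config=config,
        stage_counts=counts,
        instruments=instruments,
        harmonization=report,
        pairs=pairs,
        estimates=estimates,
        heterogeneity=heterogeneity,
        single_snp=single,
        funnel=funnel,
        leave_one_out=loo,
        outlier_screen=screen,
        warnings=warnings,
    )
    for w in warnings:
        logger.warning(w)
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.estimates_frame().to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    report.audit_frame().to_csv(out_dir / "audit.tsv", sep="\t", index=False)
    _pairs_frame(report.pairs).to_csv(out_dir / "harmonized.tsv", sep="\t", index=False)
    report.single_snp.to_csv(out_dir / "single_snp.tsv", sep="\t", index=False)
    report.funnel.to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
    if report.leave_one_out is not None:
        report.leave_one_out.to_frame().to_csv(out_dir / "leave_one_out.tsv", sep="\t", index=False)
    if report.outlier_screen is not None:
        report.outlier_screen.to_frame().to_csv(out_dir / "outlier_screen.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(
            {
                "stage_counts": report.stage_counts,
                "warnings": report.warnings,
                "outlier_global_pvalue": (
                    report.outlier_screen.global_pvalue if report.outlier_screen else None
                ),
            },
            fh,
            indent=2,
        )
    if report.config.make_plots:
        from . import plots

        plots.render_all(report, out_dir)


def compare_runs(a: RunReport, b: RunReport) -> pd.DataFrame:
    """Per-method percent change in the causal estimate from run A to run B.

    percent change = 100 * (beta_B - beta_A) / |beta_A|, reported to 1 d.p.;
    undefined (None) when beta_A is zero.
    """
    methods_a = {e.method: e for e in a.estimates}
    methods_b = {e.method: e for e in b.estimates}
    common = [m for m in methods_a if m in methods_b]
    if not common:
        raise ValueError("runs share no estimation method")
    rows = []
    for m in common:
        ba, bb = methods_a[m].beta_hat, methods_b[m].beta_hat
        pct = None if ba == 0 else round(100.0 * (bb - ba) / abs(ba), 1)
        rows.append({"method": m, "beta_a": ba, "beta_b": bb, "percent_change": pct})
    return pd.DataFrame(rows)
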