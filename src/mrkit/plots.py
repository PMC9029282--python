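"""Presentation-only figures; every plotted number lives in a report table."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["render_all"]


def render_all(report, out_dir: str | Path) -> list[Path]:
    """Scatter (with fitted lines), forest, funnel and leave-one-out plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    g = [p.gamma_hat for p in report.pairs]
    G = [p.Gamma_hat for p in report.pairs]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        g, G,
        xerr=[p.se_gamma for p in report.pairs],
        yerr=[p.se_Gamma for p in report.pairs],
        fmt="o", ms=3, lw=0.8, color="0.3",
    )
    xs = [0, max(abs(v) for v in g) * 1.05]
    ivw = report.estimate("ivw_fixed")
    if ivw:
        ax.plot(xs, [ivw.beta_hat * x for x in xs], label=f"IVW (slope {ivw.beta_hat:.2f})")
    egger = report.estimate("egger_fixed")
    if egger:
        ax.plot(
            xs,
            [egger.intercept + egger.beta_hat * x for x in xs],
            label=f"MR-Egger (slope {egger.beta_hat:.2f})",
        )
    ax.set_xlabel("variant-exposure effect")
    ax.set_ylabel("variant-outcome effect")
    ax.legend(fontsize=8)
    path = out_dir / "scatter.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    tab = report.single_snp.sort_values("beta_hat")
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(tab) + 1.5))
    y = range(len(tab))
    ax.errorbar(
        tab["beta_hat"], list(y),
        xerr=[tab["beta_hat"] - tab["ci_low"], tab["ci_high"] - tab["beta_hat"]],
        fmt="o", ms=3, lw=0.8, color="0.3",
    )
    ax.set_yticks(list(y), tab["variant_id"], fontsize=7)
    if ivw:
        ax.axvline(ivw.beta_hat, color="red", lw=0.8)
    ax.set_xlabel("Wald ratio")
    path = out_dir / "forest.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.funnel["wald_ratio"], report.funnel["precision"], s=12, color="0.3")
    if ivw:
        ax.axvline(ivw.beta_hat, lw=0.8, label="IVW")
    if egger:
        ax.axvline(egger.beta_hat, lw=0.8, ls="--", label="MR-Egger")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    ax.legend(fontsize=8)
    path = out_dir / "funnel.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    if report.leave_one_out is not None:
        loo = report.leave_one_out.to_frame()
        fig, ax = plt.subplots(figsize=(5, 0.25 * len(loo) + 1.5))
        y = range(len(loo))
        ax.errorbar(
            loo["beta_hat"], list(y),
            xerr=[loo["beta_hat"] - loo["ci_low"], loo["ci_high"] - loo["beta_hat"]],
            fmt="o", ms=3, lw=0.8, color="0.3",
        )
        ax.set_yticks(list(y), loo["excluded"], fontsize=7)
        ax.axvline(report.leave_one_out.full.beta_hat, color="red", lw=0.8)
        ax.set_xlabel("IVW estimate without the named variant")
        path = out_dir / "leave_one_out.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
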