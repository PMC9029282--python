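"""Harmonize the instruments and estimate the causal effect.

Aligns the pruned instruments to the outcome GWAS (palindromic variants
oriented by allele frequency, 0.08 ambiguity band), then fits the Wald-ratio
ensemble: fixed- and random-effect IVW and MR-Egger with Cochran's Q for
each.  Writes results/estimates/.
"""

from pathlib import Path

import pandas as pd

from mrkit.estimators import cochran_q, egger, ivw
from mrkit.harmonization import harmonize
from mrkit.summary_data import read_summary_table

data = Path("results/data")
out = Path("results/estimates")
out.mkdir(parents=True, exist_ok=True)

exposure = read_summary_table(data / "exposure.tsv", role="exposure")
outcome = read_summary_table(data / "outcome.tsv", role="outcome")
instruments = pd.read_csv("results/instruments/instruments.tsv", sep="\t")["variant_id"]

report = harmonize(list(instruments), exposure, outcome)
print(f"harmonized {len(report.kept)}/{len(instruments)} instruments")
for vid, reason in report.removed:
    print(f"  removed {vid}: {reason}")

pairs = report.kept
rows = []
for fit in (ivw(pairs, "fixed"), ivw(pairs, "random"), egger(pairs, "fixed"), egger(pairs, "random")):
    q = cochran_q(pairs, fit) if fit.method.endswith("fixed") else None
    rows.append(
        {
            "method": fit.method,
            "beta_hat": round(fit.beta_hat, 4),
            "se": round(fit.se, 4),
            "ci_low": round(fit.ci_low, 4),
            "ci_high": round(fit.ci_high, 4),
            "pvalue": fit.pvalue,
            "intercept": None if fit.intercept is None else round(fit.intercept, 4),
            "intercept_pvalue": fit.intercept_pvalue,
            "n_instruments": fit.n_instruments,
            "Q": None if q is None else round(q.Q, 3),
            "Q_df": None if q is None else q.df,
            "Q_pvalue": None if q is None else round(q.pvalue, 3),
        }
    )
table = pd.DataFrame(rows)
print(table.to_string(index=False))
table.to_csv(out / "estimates.tsv", sep="\t", index=False)

pd.DataFrame(
    [
        {
            "variant_id": p.variant_id,
            "gamma_hat": p.gamma_hat,
            "se_gamma": p.se_gamma,
            "Gamma_hat": p.Gamma_hat,
            "se_Gamma": p.se_Gamma,
            "action": p.action,
            "palindromic": p.palindromic,
        }
        for p in pairs
    ]
).to_csv(out / "harmonized_pairs.tsv", sep="\t", index=False)
print(f"estimates and harmonized pairs written to {out}/")
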