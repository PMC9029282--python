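"""Build the instrument funnel: significance -> gene validation -> LD pruning.

Reads results/data/, applies genome-wide selection (p < 5e-8), gene-level
validation against the two replicate exposure GWASs, and greedy pruning to
pairwise r^2 < 0.001, and reports the funnel counts.  The audit trail and
the final instrument list go to results/instruments/.
"""

from pathlib import Path

import pandas as pd

from mrkit.instrument_selection import ld_prune, select_instruments, validate_by_shared_genes
from mrkit.summary_data import read_gene_map, read_ld_matrix, read_summary_table

data = Path("results/data")
out = Path("results/instruments")
out.mkdir(parents=True, exist_ok=True)

exposure = read_summary_table(data / "exposure.tsv", role="exposure")
replicates = [
    read_summary_table(data / f"exposure_rep{i}.tsv", role="exposure") for i in (1, 2)
]
gene_map = read_gene_map(data / "gene_map.tsv")
ld = read_ld_matrix(data / "ld.tsv")

selected = select_instruments(exposure, 5e-8)
validated = validate_by_shared_genes(selected, exposure, replicates, gene_map, 5e-8)
pruned = ld_prune(validated, exposure, ld, 0.001)

print(f"candidates: {len(exposure)}")
print(f"selected (p < 5e-8): {len(selected)}")
print(f"validated (gene replicated in >=1 of 2 GWASs): {len(validated)}")
print(f"pruned (pairwise r2 < 0.001): {len(pruned)}")

truth = pd.read_csv(data / "truth.tsv", sep="\t")
true_ids = set(truth.loc[truth["gamma"] != 0, "variant_id"])
planted_kept = true_ids & set(pruned.variant_ids)
print(
    f"{len(planted_kept)} of the {len(pruned)} surviving instruments are planted "
    f"true instruments ({len(true_ids)} were planted; LD partners of a planted "
    f"variant can replace it during pruning)"
)

pd.DataFrame({"variant_id": pruned.variant_ids}).to_csv(
    out / "instruments.tsv", sep="\t", index=False
)
pd.DataFrame(
    [
        {"variant_id": a.variant_id, "step": a.step, "action": a.action, "reason": a.reason}
        for a in pruned.audit
    ]
).to_csv(out / "audit.tsv", sep="\t", index=False)
print(f"instrument list and audit written to {out}/")
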