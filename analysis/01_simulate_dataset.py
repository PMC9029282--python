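"""Generate the synthetic study dataset.

Simulates two disjoint cohorts at the emulated study scale (exposure GWAS
of 182,413 individuals, outcome GWAS of 5,756) under the structural model
with a true causal effect of 0.5, plus two replicate exposure GWASs for
gene-level validation, the variant-to-gene map, the block LD matrix, and
the per-variant ground truth.  Everything downstream reads these files.

Writes results/data/*.tsv.  Run from the repository root:
    python analysis/01_simulate_dataset.py [--seed 11]
"""

import argparse
import time
from pathlib import Path

from mrkit.summary_data import write_gene_map, write_ld_matrix, write_summary_table
from mrkit.synthetic_data import (
    SimulationConfig,
    block_ld_matrix,
    generate_cohort_pair,
    generate_validation_set,
    truth_frame,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=11)
args = parser.parse_args()

out = Path("results/data")
out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(seed=args.seed)  # defaults are the study conditions
t0 = time.time()
exposure, outcome, truth = generate_cohort_pair(config)
print(
    f"simulated {config.n_snps} variants | exposure n={config.n_exposure:,} "
    f"outcome n={config.n_outcome:,} | true causal effect beta={config.beta} "
    f"({time.time() - t0:.1f}s)"
)
# additional exposure GWASs are typically far smaller than the main one,
# which is what gives gene-level validation its filtering effect
replicates, gene_map = generate_validation_set(config, truth, k=2, n_each=20_000)

write_summary_table(exposure, out / "exposure.tsv")
write_summary_table(outcome, out / "outcome.tsv")
for i, rep in enumerate(replicates, start=1):
    write_summary_table(rep, out / f"exposure_rep{i}.tsv")
write_gene_map(gene_map, out / "gene_map.tsv")
write_ld_matrix(block_ld_matrix(truth, config), out / "ld.tsv")
truth_frame(truth).to_csv(out / "truth.tsv", sep="\t", index=False)

n_instruments = sum(t.gamma != 0 for t in truth)
print(f"planted {n_instruments} true instruments among {config.n_snps} variants")
print(f"wrote exposure, outcome, 2 replicate GWASs, gene map, LD and truth to {out}/")
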