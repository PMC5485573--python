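"""Run the genotype QC chain on a panel with missing calls.

Order matters and mirrors standard practice: call-rate filters on the full
panel, then imputation; monomorphic/collinearity edits are training-only
decisions made later, per replicate, inside the experiment runner.
"""

import numpy as np

from phenonoise import (
    SimulationConfig,
    filter_call_rate,
    impute_modal,
    qc_training_loci,
    simulate_population,
)

cfg = SimulationConfig(n_individuals=600, n_snps=150, seed=7,
                       missing_rate=0.04)
panel, labels = simulate_population(cfg)
print(f"missing calls before QC: {np.isnan(panel.values).sum()}")

panel, rep_ind = filter_call_rate(panel, 0.95, axis="individual")
panel, rep_snp = filter_call_rate(panel, 0.95, axis="snp")
print(f"individuals removed (call rate < 95%): "
      f"{rep_ind.n_individuals_removed_callrate}")
print(f"SNPs removed (call rate < 95%): {rep_snp.n_snps_removed_callrate}")

panel, rep_imp = impute_modal(panel)
print(f"entries imputed (modal): {rep_imp.entries_imputed}; "
      f"missing now: {np.isnan(panel.values).sum()}")

# training-only edits, shown here on the first 70% of rows
train = panel.subset(rows=range(int(0.7 * panel.n_individuals)))
kept, rep_edit = qc_training_loci(train)
print(f"training edits keep {len(kept)}/{train.n_snps} loci "
      f"({len(rep_edit.snps_removed_monomorphic)} monomorphic, "
      f"{len(rep_edit.snps_removed_collinear)} collinear removed)")
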