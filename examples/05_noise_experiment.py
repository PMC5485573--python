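"""A small end-to-end noise-robustness experiment.

Grid: 2 noise levels x 2 replicates x 2 methods on a simulated panel.
Per cell: stratified 70/30 split, training-only locus edits, label flips in
the training set, CV tuning, prediction of the untouched test set, scoring
against the original labels. The full study design is the same loop at
10 noise levels x 10 replicates x 5 methods.
"""

from phenonoise import SimulationConfig, simulate_population, run_experiment

cfg = SimulationConfig(n_individuals=600, n_snps=150, carrier_frequency=0.05,
                       seed=9)
panel, labels = simulate_population(cfg)

result = run_experiment(
    panel, labels,
    noise_levels=[0.0, 0.20],
    methods=("svm_linear", "knn"),
    replicates=2,
    master_seed=1,
    cv_folds=5,
    exclude_loci=(panel.locus_ids[0],),  # the causal locus defines the label
    grids={"svm_linear": {"C": [0.1, 1.0, 10.0]}, "knn": {"K": [1, 5, 11]}},
)

print(result.aggregate().round(3).to_string(index=False))
print()
print("error-rate layout (rows: noise x TER/FPR/FNR, columns: methods):")
print(result.table1().round(3).to_string())
# TPR carries the signal: moderate for the margin-based method on clean
# labels, degrading as training noise grows, while KNN detects almost no
# carriers at any noise level. At this demonstration scale the noisy-label
# runs also show some false positives (FPR above 0); at study scale, with
# more carriers to stabilise CV tuning, specificity stays near 1.
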