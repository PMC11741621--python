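"""Simulate a multi-donor cohort and build the polynomial feature matrix.

Generates 40 donors with 200 cells each, where 5 of 50 genes carry a linear
age trend in their mean expression, then collapses each donor's cells into
per-gene means/variances and their squares — the 4n-column design the age
regressor consumes.
"""

import polyen as pe

dataset, truth = pe.generate_cohort(pe.preset_scenarios(seed=1)["strong_mean"])
print(f"cohort: {dataset.n_cells} cells, {dataset.n_genes} genes, "
      f"{len(dataset.donor_ids)} donors, ages "
      f"{dataset.ages().min():.0f}-{dataset.ages().max():.0f} years")
print(f"planted signal genes: {truth.signal_genes['TypeA']}")

fm = pe.gene_space_features(dataset, cell_type="TypeA")
print(f"\nfeature matrix: {fm.n_donors} donors x {fm.n_features} features "
      f"(4 kinds x {dataset.n_genes} genes)")
print("first donor, first signal gene:")
for kind in ("mean1", "var1", "mean2", "var2"):
    col = fm.column_names.index(f"G0001|{kind}")
    print(f"  {kind:>6}: {fm.X[0, col]:.4f}")
# mean1/var1 are the donor-level mean and cell-to-cell variance of the gene's
# log-normalized expression; mean2/var2 are their squares (the second-degree
# polynomial features).
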