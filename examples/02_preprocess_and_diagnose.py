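"""Quality-filter probes, call sample sex, estimate cell mix, run the PCA check.

The PCA diagnostic is the pre-training sanity check: survey structure (age
above all) should load strongly on the leading components of the
cluster-averaged inputs.
"""

import numpy as np

import cheekclock as cc

matrix, survey, manifest, cmap, truth = cc.generate_cohort(
    cc.CohortConfig(), seed=1)

filtered, report = cc.filter_probes(matrix, manifest)
print("probes removed per rule:", report.removed_counts)
print(f"surviving probes: {len(report.surviving)}")

sex = cc.predict_sex(matrix, manifest)
truth_sex = survey.demographics["gender"].map({1.0: "XX-like", -1.0: "XY-like"})
print(f"sex calls correct: {(sex == truth_sex).mean():.1%} "
      f"({(sex == 'undetermined').sum()} undetermined)")

props = cc.estimate_cell_proportions(matrix, truth.cell_profiles)
err = np.abs(props.to_numpy() - truth.cell_proportions.to_numpy()).mean()
print(f"cell-proportion recovery: mean |error| = {err:.3f}")

surviving = set(filtered.probe_ids)
keep = [c for c in cmap.cluster_ids if set(cmap.members(c)) <= surviving]
cm = cc.average_clusters(filtered, cmap.subset(keep))
diag = cc.pca_diagnostic(cm, survey, k=18)
age_row = diag.correlations.loc["age"].abs()
print(f"age loads most strongly on {age_row.idxmax()} "
      f"(|r| = {age_row.max():.2f})")
# A strong age-PC correlation before training means the cluster averages
# carry the signal the clock needs; a flat row here would mean filtering or
# clustering destroyed it.
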