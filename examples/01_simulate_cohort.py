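"""Generate a synthetic buccal-methylation cohort with planted structure.

Builds the standard 500-sample cohort (ages 18-93, 300 CpG clusters of which
20 drift with age and 5 additionally respond to smoking), adds 50 technical
replicate pairs, and prints what was planted.
"""

import numpy as np

import cheekclock as cc

matrix, survey, manifest, cmap, truth = cc.generate_cohort(
    cc.CohortConfig(), seed=1)
matrix, survey = cc.add_replicates(matrix, survey, n_pairs=50,
                                   tech_sd=0.1, seed=1)

print(f"matrix: {matrix.n_probes} probes x {matrix.n_samples} samples "
      f"({matrix.scale} scale)")
print(f"ages: {survey.age.min():.1f}-{survey.age.max():.1f} years")
print(f"clusters: {len(cmap)} total, "
      f"{len(truth.planted_age_clusters)} age-linked, "
      f"{sum(len(v) for v in truth.planted_lifestyle_effects.values())} "
      f"lifestyle-responsive")
slopes = np.array(list(truth.planted_age_clusters.values()))
print(f"planted age slopes: |median| = {np.median(np.abs(slopes)):.4f} M/yr")
print(f"replicate pairs: "
      f"{survey.replicate_group.notna().sum() // 2}")
# The slopes are the per-year M-value drift written into each age cluster;
# everything downstream must recover them from the noisy matrix alone.
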