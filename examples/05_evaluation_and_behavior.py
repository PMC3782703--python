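"""Evaluation layer: per-ROI accuracy, behavior correlations, site analysis.

The per-subject classification score is a continuous severity-like quantity;
besides thresholding it into labels we can ask which ROIs classify well on
their own, whether the score tracks behavioral measures, and whether sites
with longer scans classify better.
"""

import numpy as np

from fcloo import (
    SimParams,
    behavior_correlations,
    loo_scores,
    per_connection_loo,
    per_roi_accuracy,
    per_site_accuracy,
    simulate_cohort,
    site_accuracy_analysis,
)

vols = tuple(int(v) for v in np.linspace(50, 300, 15))
dataset, truth = simulate_cohort(
    SimParams(seed=3, effect_size=0.05, subject_noise_sd=0.02,
              n_sites=15, subjects_per_site=8, volumes_per_site=vols)
)
pre = per_connection_loo(dataset)
results = loo_scores(dataset, precomputed=pre)
scores = np.array([r.score for r in results])
labels = np.array([r.actual for r in results])
sites = np.array([p.site for p in dataset.phenotypes])

roi = per_roi_accuracy(dataset, precomputed=pre)
print(f"per-ROI accuracy: median {100*np.median(roi.accuracy):.1f}%, "
      f"best ROI {100*roi.accuracy.max():.1f}% "
      f"(display floor from the binomial FDR bound: {100*roi.display_floor:.1f}%)")

behav = behavior_correlations(scores, dataset.phenotypes)
for _, row in behav.iterrows():
    if row.measure in ("srs_total", "vineland_composite"):
        print(f"score vs {row.measure}: r = {row.r:+.2f} (p = {row.p:.1e}, n = {row.n})")
print("  -> severity-linked measures correlate positively (SRS) or negatively "
      "(Vineland) with the score, matching their clinical direction")

site_df = per_site_accuracy(scores, labels, sites)
corr = site_accuracy_analysis(
    site_df["accuracy"].to_numpy(), np.array(vols), site_df["n"].to_numpy()
)
r, p = corr["volumes"]
print(f"site accuracy vs scan length (50-300 volumes): r = {r:+.2f}, p = {p:.2f} "
      "(longer scans -> less Fisher-z noise -> better classification)")
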