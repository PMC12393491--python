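"""Extract co-activation brain states with PAM k-medoids.

Normalizes and concatenates the cohort, scans k with the selection
battery (explained variance, variance gain, medoid silhouette, state
absence, centroid overlap), picks K, and checks the recovered states
against the planted ones.
"""

import numpy as np

from capdyn.clustering import match_states, scan_k, select_k
from capdyn.io import concatenate_cohort, normalize_subject
from capdyn.synthetic import SyntheticConfig, generate_cohort

bundle, truth = generate_cohort(
    SyntheticConfig(n_subjects_per_group=10, frames_per_subject=150,
                    n_rois=40, seed=0)
)
dataset = concatenate_cohort([normalize_subject(ts) for ts in bundle.subjects])
print(f"point cloud: {dataset.n_rois} ROIs x {dataset.n_frames} frames")

report = scan_k(dataset, k_min=2, k_max=6, n_restarts=5, seed=0)
print("\nK-selection criteria:")
print(report.table.round(3).to_string(index=False))
selection = select_k(report)
print(f"\nselected K = {selection.k} (conclusive: {selection.conclusive})")
print("criteria: gain in explained variance tapers below 0.01 after K,")
print("silhouette peaks, every subject still visits every state, and")
print("centroids stay spatially distinct.")

solution = report.solutions[selection.k]
match = match_states(solution.mean_centroids, truth.centroids)
print(f"\nmatched correlation with planted states: "
      f"{np.round(match.matched_correlations, 3)}")
print("(values near 1: the extracted cluster means reproduce the planted "
      "co-activation patterns)")
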