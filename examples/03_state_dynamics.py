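"""Temporal dynamics of the extracted states and group differences.

Computes dwell time, fractional occupancy and joint transition
probabilities per subject, then compares groups with pooled-variance
t-tests (BH-adjusted over states).
"""

import numpy as np

from capdyn.clustering import kmedoids
from capdyn.dynamics import cohort_table, sequences_from_solution, summarize
from capdyn.inference import group_metric_tests
from capdyn.io import concatenate_cohort, normalize_subject
from capdyn.synthetic import SyntheticConfig, generate_cohort

bundle, truth = generate_cohort(
    SyntheticConfig(n_subjects_per_group=10, frames_per_subject=150,
                    n_rois=40, seed=0)
)
dataset = concatenate_cohort([normalize_subject(ts) for ts in bundle.subjects])
solution = kmedoids(dataset, 4, n_restarts=5, seed=0)

sequences = sequences_from_solution(dataset, solution.labels, 4)
summaries = [summarize(seq) for seq in sequences]
table = cohort_table(summaries)

print("per-state cohort means:")
print(table.groupby("state")[
    ["dwell_time_s", "fractional_occupancy_pct",
     "exit_probability", "enter_probability"]
].mean().round(3).to_string())
print("\n(dwell time in seconds; occupancies sum to 100% per subject;")
print(" transition probabilities are joint switch probabilities, so the")
print(" off-diagonal matrix sums to 1 per subject)")

tests = group_metric_tests(table, bundle.clinical, "dwell_time_s", adjust="bh")
print("\nHC vs MDD dwell-time t-tests (df = n_HC + n_MDD - 2):")
print(tests.round(4).to_string(index=False))
print("\nthe planted effect destabilizes state 3 in the MDD group, so its")
print("dwell time should show the largest (positive HC-MDD) difference.")
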