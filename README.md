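# capdyn

Brain-state analysis of resting-state fMRI: extraction of recurring
whole-brain **co-activation patterns (CAPs)** from regional BOLD time
series, quantification of their **temporal dynamics** (dwell time,
fractional occupancy, transition/exit/enter probabilities) with group
comparisons, and a **network-control-theoretic energy landscape** of
the transitions on structural connectomes. The package is aimed at
computational-psychiatry and network-neuroscience work where brain
dynamics are compared between clinical groups (e.g. healthy controls
vs. major depressive disorder) and related to symptom scores, and it
ships a synthetic-cohort generator with full planted ground truth so
every stage of the analysis is testable without patient data.

## The method

**States.** Each fMRI volume is a point in R^N (N ROIs). Per-subject
series are z-scored per ROI and concatenated into an N x T point cloud;
PAM k-medoids under the correlation distance d = 1 − Pearson r
partitions the T frames into K recurring co-activation patterns. K is
chosen with a battery of criteria: explained variance and its gain
(taper below 0.01 per unit K), mean medoid silhouette
s = (d₂ − d₁)/max(d₁, d₂), the fraction of subjects with an absent
state, and pairwise centroid overlap — plus split-half stability and a
phase-randomized null (surrogates preserve each ROI's amplitude
spectrum, hence autocorrelation, while destroying co-activation).

**Dynamics.** Per subject, dwell time (mean run length x TR, seconds),
fractional occupancy (%), and joint transition probabilities
P(i→j) = N(i→j)/N(switches) with self-transitions removed and no
counting across subject boundaries; exit/enter probabilities are
off-diagonal row/column means. Group contrasts use pooled-variance
t-tests; symptom relationships use OLS
`Q = β0 + β_cx·cx + β_s·sex + β_a·age + β_m·medication + ε`, with
BH-FDR or Bonferroni adjustment.

**Energies.** Activity is modelled as LTI dynamics
`dx/dt = A x + B u` on the stabilized connectome
`A = W/(λ_max(W)+c) − I`. The optimal control steering state i to
state j over horizon T = 1 minimizes
`∫ (x−xf)ᵀS(x−xf) + ρ·uᵀu dt` (ρ = 1, S = I, B = I), solved exactly
through the Hamiltonian two-point boundary-value system and matrix
exponentials. Transition energy is `∫ u² dt` (per node and total);
exit/enter energy asymmetries classify states as sink-like (local
minima) or source-like (local maxima) of the energy landscape.

## Worked example

`examples/` contains one short script per capability. Extracting states
from a synthetic cohort (`python examples/02_extract_brain_states.py`):

```
point cloud: 40 ROIs x 3000 frames

K-selection criteria:
 k  explained_variance  variance_gain  mean_medoid_silhouette  state_absence_fraction  max_centroid_correlation
 2               0.514            NaN                   0.483                     0.0                    -1.000
 3               0.662          0.149                   0.472                     0.0                    -0.271
 4               0.784          0.122                   0.530                     0.0                    -0.131
 5               0.793          0.009                   0.439                     0.0                     0.940
 6               0.802          0.008                   0.346                     0.0                     0.940

selected K = 4 (conclusive: True)

matched correlation with planted states: [0.983 0.994 0.984 0.988]
```

Variance gain drops below 0.01 after K = 4 while the medoid silhouette
peaks there and centroids stay distinct — the selector returns the
planted K, and the recovered cluster means correlate > 0.98 with the
planted patterns. The other examples generate cohorts (`01`), compute
dynamics and group tests (`03`), run the phase-randomized null (`04`),
compute transition-energy landscapes (`05`), and execute the whole
seeded pipeline with a digest manifest (`06`).

A thin CLI mirrors the stages:

```bash
capdyn synth --out cohort --seed 1
capdyn cluster --bold-dir cohort/bold --out run --select --k-min 2 --k-max 8
capdyn run --config config.json --seed 1 --out run
```

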