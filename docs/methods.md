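# Methods

## Study conditions and scope

The pipeline analyzes a block-design motor task measured under three
conditions: right-ankle dorsiflexion alone (`Task`), dorsiflexion with
simultaneous tactile-pressure stimulation of the tibialis anterior
(`Task+AgonistStim`), and dorsiflexion with stimulation of a control area
(`Task+ControlStim`).  A session is nine 30 s rest / 30 s task cycles plus
one closing 30 s rest — 570 s, 190 volumes at TR 3 s.  The nine task
periods carry the three conditions interleaved (A, B, C repeated three
times by default; the within-session condition order is configurable
because it is not uniquely determined by the paradigm description).  The
network nodes are 23 motor-system regions (3 mm spheres at their
activation-peak MNI coordinates) packaged in
`src/weaklink/data/motor_roster.csv`.

Voxelwise activation mapping, image realignment/normalization and the
stimulation apparatus are out of scope; the pipeline starts from ROI time
series (or from already-aligned 4D volumes via sphere extraction).

## Synthetic cohort generator

No raw cohort is publicly available, so `weaklink.synthetic` generates one
with a known answer.  Per subject,

x_t = drive_t · a  +  AR(1)[ L_{c(t)} ε_t ]  +  drift_t  +  confound leakage,

where ε_t is i.i.d. standard normal, L_{c(t)} is the Cholesky factor of the
correlation matrix of the condition active at volume *t* (rest volumes use
identity plus a weak global factor, r = 0.05, so rest carries none of the
planted structure), the AR(1) coefficient is 0.3, drift is linear plus
quadratic (amplitudes 1.5 and 1.0 SD), eight confounds (six random-walk
motion traces, two AR tissue signals) leak into the data at 0.1 SD, and
the task drive is the condition boxcar convolved with a canonical
double-gamma HRF.

Parameter notes (all configurable through `NoiseConfig` /
`GroundTruthConfig`):

- **Planted structure.** Three modules — cortical motor (10 nodes),
  somatosensory association (8), subcortical (5) — with within-module
  correlation 0.5 (0.25 subcortical) and between-module 0.15.  The three
  somatosensory relays (L thalamus, both cerebella) are special-cased to a
  weak 0.05 background so they carry few links, plus planted
  condition-specific links in the weak 0.12–0.28 range: one
  relay↔cortical-motor link at baseline (R cerebellum–M1, 0.25), eight
  under agonist stimulation (including thalamus–M1 at 0.12, the weakest
  planted edge, and thalamus–SMA at 0.21), five under control stimulation
  (thalamus–SMA 0.22).  Matrices are floored to positive definiteness and
  renormalized; a request whose minimum eigenvalue is far below zero is
  rejected instead of silently repaired.
- **Task-drive amplitude 0.25 SD.**  The planted covariance is defined as
  the correlation structure of the task volumes, so the shared evoked
  drive must stay a small perturbation: at 0.25 SD it biases measured
  task-segment correlations by < 0.01, while a BOLD-realistic 1 SD drive
  would add ~0.04 of spurious correlation to *every* edge and contaminate
  the planted answer.  Generator correctness is asserted by a convergence
  test: with nuisances off, empirical task-volume correlations match the
  planted matrix to < 0.03 (max-abs over all 253 edges) at 20 000 volumes.
- **Between-subject variability.**  One effect-size factor per subject,
  f ~ max(0, 1 + N(0, 0.2)), scales all off-diagonal correlations.
- **What the generator does not emulate:** physiological hemodynamic
  nonlinearity (balloon-type models), head motion in image space,
  slice-timing/multiband effects, spatially correlated noise.  Passing
  recovery tests therefore demonstrates the correctness and calibration of
  the analysis chain under the stated statistical model, not robustness to
  every artifact of real fMRI.

## Preprocessing

Fixed, logged order: sphere extraction (voxel centers within radius,
inclusive boundary — at 3 mm voxels a 3 mm sphere holds the center plus
its six face neighbors) → zero-phase 2nd-order Butterworth bandpass
0.008–0.09 Hz (forward–backward, 30-volume reflective padding) → OLS
residualization on intercept, six motion parameters, two tissue signals
and the tissue signals' first differences → per-condition concatenation of
task volumes after dropping the first 2 volumes (6 s) of each block for
the hemodynamic rise.  Whether filtering precedes regression is not
determined by the source description; filtering-first is the default and
the order is switchable and recorded in the provenance list.

## Network estimation

Pearson correlation over a condition's 24 segmented volumes, Fisher
transform, then per edge a two-sided one-sample *t* across subjects
against zero.  BH-FDR at q = 0.05 is applied within each condition's 253
edges (networks are constructed separately per condition, so the family is
not pooled).  Surviving positive-mean edges keep the group-mean *z* as
weight; surviving negative edges are dropped and counted, matching the
positive-weight network definition.  The group mean under an
intercept-only model equals the "beta" a group-level GLM would report.

## Graph measures

Distances D = 1 − W (absent links infinite; weights ≥ 1 rejected).
Shortest paths by Dijkstra with path counting on the shortest-path DAG;
path-length ties within 1e-10 count as equal.  Betweenness is the raw sum
over unordered pairs of pass-through fractions (a normalized column is
also emitted); on 23-node networks raw values land in the tens, zeros are
common.  Modularity is weighted Newman Q; `louvain_partition` runs seeded
Louvain `n_restarts` times (default 100), each followed by deterministic
single-node-move hill climbing (ascending node index, ties to the lowest
module id), and returns the best Q with a canonical relabeling — repeated
calls with one seed are bit-identical, and on ≤ 8-node graphs the result
matches the exhaustive maximum over all set partitions in the test suite.
Resolution is fixed at 1.

## Null models

Topology: Maslov–Sneppen double-edge swaps (10 attempted swaps per link;
on very dense graphs the attempt budget can exhaust early, which is warned
and acceptable because the achieved swaps already randomize the topology).
Weights: the original multiset is re-placed greedily, largest weight onto
the free edge whose endpoints have the largest residual strength budget —
degree sequence and weight multiset are preserved exactly (asserted per
ensemble member), node strengths approximately (Spearman ≥ 0.9).
Partition similarity between two partitions is the Pearson correlation of
their 253-entry pairwise co-assignment vectors (1 = same module), with the
adjusted Rand index emitted alongside; a single-module or all-singleton
partition makes the correlation undefined and is flagged (NaN) unless the
two vectors are equal.

## Condition contrasts

- **Strength percent change**: per node, 100 · s_c / s_Task; zero-baseline
  nodes are flagged NaN.
- **Per-subject strengths** for the Friedman test are row sums of each
  subject's Fisher-z matrix restricted to the group network's link set,
  keeping link topology fixed across subjects (the source description does
  not specify this construction; fixing the topology is this package's
  choice and is recorded here).
- **Friedman test** per node across the three conditions with average-rank
  tie correction; exact permutation p (DP over per-subject rank
  permutations) when the arrangement count is ≤ 3·10^5, chi-square with
  k − 1 df otherwise; Bonferroni × 23.
- **Profile analysis**: nodes split into strictly-increased vs
  decreased-or-unchanged betweenness (ties to the second group), then a
  mixed-design ANOVA group × condition interaction on case-centered
  values tests profile parallelism.  Mauchly's W (orthonormal-contrast
  covariance determinant/trace ratio, chi-square approximation on the
  pooled within-group covariance) is reported with a Greenhouse–Geisser
  corrected p alongside the uncorrected one.

## Layout and exports

Kamada–Kawai springs between all pairs with ideal length d_ij = weighted
shortest-path distance and stiffness 1/d², minimized by L-BFGS from a
seeded circular start (gradient tolerance 1e-4, ≤ 10^4 iterations);
disconnected components are laid out separately and offset.  Exports:
Pajek .net (1-based ids, quoted labels, 6-decimal weights, lossless
round-trip with the packaged reader), GraphML, edge-list TSV, coordinate
CSV, and a JSON run report validated against a packaged skeleton.

## Problem sizes and known limitations

The packaged defaults are the study conditions: 21 subjects, 190 volumes,
23 nodes, q = 0.05, 100 nulls, 100 Louvain restarts.  Recovery and
calibration suites use these sizes directly (25 cohort draws for the
end-to-end check; 2000 replicates for FDR and type-I calibration; exact
enumeration oracles up to 6–8 nodes).

Two power limitations are inherent to the conditions, not implementation
defects.  A condition contributes only 3 × 8 = 24 usable volumes, so a
subject's Fisher z for a true r = 0.12 edge has sampling SD ≈ 0.3 (the
bandpass halves the effective bandwidth of 1/√T ≈ 0.22), the group
non-centrality is ≤ 2.5, and FDR-level detection power is ~35–60%: the
weakest planted link replicates in roughly half of independent cohorts
(its absence at baseline, and module recovery, are stable).  The same
noise floor makes per-node Friedman tests on the relays significant only
sporadically after Bonferroni.  Single observed cohorts can nevertheless
show such effects prominently — which is how a weak link can be reported
from one measured dataset while not replicating in the majority of
re-draws under identical conditions.
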