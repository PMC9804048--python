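# Methods

`dfnc-states` implements a dynamic functional network connectivity (dFNC)
state analysis for paired-session, two-group resting-state fMRI designs,
together with a synthetic cohort generator that provides full ground truth
for every stage. This note records the models, the defaults and why they
are what they are, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## The analysis model

**Windowed connectivity.** A session's component time courses
(T time points × C components) are segmented into overlapping windows of
width 30 TR sliding in steps of 1 TR, giving `floor((T − width)/step) + 1`
windows (201 for T = 230). Each window is weighted by a taper built by
convolving a rectangle of the window width with a unit-area Gaussian of
σ = 3 TR. The taper's support extends ⌈4σ⌉ samples beyond each rectangle
edge so its total mass equals the window width; at the series boundary the
overhang is clipped. The tapered, weighted covariance of each window is
optionally regularized by the graphical LASSO (L1-penalized sparse inverse
covariance), converted to correlation, and Fisher z-transformed with |r|
clamped at 1 − 1e−7 (z ≈ 8.4). Windows live in component-pair space — the
C(C−1)/2 strict-upper-triangle entries.

**Penalty selection.** The per-session LASSO penalty is chosen from a grid
(default log-spaced 0.01–1) by held-out Gaussian log-likelihood over 100
random window splits (hold-out fraction 0.2). Because the penalty is
applied to single windows downstream, each repetition fits the candidate
precision to one randomly drawn training window's covariance and scores
it as `logdet Θ − tr(S_test Θ)` against the held-out windows' average
covariance — fitting to a pooled (many-window) covariance instead would
wash out the very noise the penalty exists to control and always select
the smallest candidate. A one-element grid skips the cross-validation;
penalty 0 is the exact unregularized path (the sample correlation), used
as the default in the pipeline driver and in the large recovery
experiments, where per-window graphical-LASSO fits would dominate run time
without changing what those experiments measure (state geometry is
preserved by the shrinkage-free path). The regularized path is exercised
at session scale in the test suite, including the penalty → 0 equivalence
and a sparsistency check on independent components.

**States.** Windows of all subjects and both phases are pooled and
clustered by k-means under the city-block (L1) distance: assignment to the
nearest centroid (ties to the lowest state index), centroid update by the
element-wise median — the exact minimizer of the within-cluster L1 cost.
The default of 500 random restarts mirrors standard practice for this
analysis; the recovery experiments use far fewer (3–8) because the
synthetic states are well separated and k-means++-style seeding (D-sampling
under L1) converges to the same solution — the restart count is a runtime
knob, not part of the model. Convergence is declared when the total cost
changes by ≤ 1e−6 (relative); each restart is capped at 200 Lloyd
iterations. States are renumbered by descending total occurrence, so
"state 1" is always the most frequent pattern of a fit.

**Model order (elbow).** For each candidate k, the cluster validity index
I(k) = (mean within-cluster L1 distance) / (mean pairwise between-centroid
L1 distance) is computed, and the selected k maximizes the discrete
curvature I(k−1) − 2I(k) + I(k+1) over interior k; an exactly linear curve
(no positive curvature) raises an error. Successive k fits are warm-started
from the previous solution plus the farthest point, which keeps the
validity curve monotone where the data supports it and removes spurious
end-of-range curvature from under-optimized high-k fits.

**Temporal properties.** From each session's window-state sequence:
fractional windows (percentage of windows per state), mean dwell time
(average run length in windows, terminal runs included — excluding them
biases short sessions), and the number of transitions (runs − 1).
Unvisited states report occupancy 0 and dwell 0, with a `visited` mask,
so group-level tables are complete.

**Statistics.** Between-group comparisons use a two-sample t-test when
both arms pass a Lilliefors-corrected Kolmogorov–Smirnov normality check
(estimated mean/SD), otherwise the Mann–Whitney U; within-group OFF→ON
comparisons use the Wilcoxon signed-rank with zero differences dropped.
Small-sample paths are enumerated exactly — all C(n_a+n_b, n_a) group
assignments for Mann–Whitney (combined n ≤ 20), all 2^n sign patterns for
Wilcoxon (n ≤ 15) — with midranks, so ties are handled without
approximation; larger samples use the scipy normal approximations with
tie correction. The 2×2 categorical test is Pearson chi-squared without
continuity correction (the uncorrected statistic reproduces the reference
gender-table p ≈ 0.49; the corrected convention differs in the second
decimal and is deliberately not used). Severity correlations are partial
Spearman: all variables rank-transformed, covariate ranks (plus
intercept) regressed out of both sides by least squares, and the Pearson
correlation of rank residuals tested against t with df = n − 2 − #covariates.
With no covariates this reduces exactly to ordinary Spearman; if the
covariates fully explain a variable the result is flagged degenerate.
FDR is Benjamini–Hochberg, applied per metric per contrast family across
the k states.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with a levodopa-induced-dyskinesia study design as the template: a LID
group (41 subjects) and a NoLID group (34), each scanned OFF and ON
medication, 230 time points per session at TR = 2 s, 22 components in 7
networks (BG 2, AUD 1, SMN 5, VIS 4, CEN 5, DMN 4, CB 1).

**Hidden process.** Each session follows a semi-Markov chain over k
states (default 5): run lengths are geometric with configurable mean
(default 60 time points), and the next state is drawn from the cell's
occupancy-preference softmax with the current state excluded. Stationary
occupancy has a closed form (embedded-chain stationary distribution
weighted by mean dwell) used in the convergence tests. The defaults plant
one effect: in the LID group's ON phase, state 1 receives an occupancy
logit of +1 and a 1.4× dwell mean — the "dyskinetic ON phase occupies and
dwells in the strongly connected state more" structure. Each subject
carries a per-state logit random effect (SD 0.35) shared by both phases,
giving realistic between-subject occupancy variance and within-subject
phase correlation.

**State covariances.** Each patterned state assigns a ±1 sign to every
network (rows of a Hadamard matrix), and its correlation matrix is
`between·σσᵀ + (within − between)·blockdiag + (1 − within)·I`
(defaults within 0.45, between 0.35) — positive-definite by construction,
with every between-network pair at ±0.35 and any two patterned states
flipping roughly half of those pairs. The last state is weakly connected
throughout (within 0.15), the familiar most-frequent baseline state. This
sign-flip geometry makes the planted states near-equidistant, which is
what gives the validity curve a well-defined elbow; an earlier design with
hand-drawn per-state blocks required an eigenvalue-clipping repair that
silently shrank the planted separations and produced an unreliable elbow.
Component signals are zero-mean multivariate normal draws with the
covariance of the current hidden state — they emulate *post-processed*
component time courses (white in time apart from state switching), which
is why the pipeline's post-processing stage defaults off in time-course
mode.

**Severity.** AIMS (the dyskinesia severity score, LID group only) is
`max(0, 9.12 + 50·(occupancy − E[occupancy]) + N(0, 4))` where occupancy
is the subject's realized ON-phase fraction in the severity-linked state
(default state 2) — a linear, floored link matching a monotone
association without inventing a mechanism. Demographic covariates
(age at onset, LEDD, disease duration, MMSE) are drawn per group from the
reference cohort's means and SDs and are independent of the severity
link, so covariate adjustment must not destroy it.

**Motion.** Realignment parameters are random walks (step 0.02 mm /
4e−4 rad per frame, mean FD ≈ 0.1 mm). A configurable fraction of
subjects is planted as QC violators by inflating the step 12× (mean FD
≈ 1.2 mm). The default fraction is 0: the default cohort represents the
*analyzed* (post-exclusion) sample, matching the 41/34 design; violator
planting is exercised explicitly in the QC tests.

**What the generator does not model.** Hemodynamics, physiological noise,
scanner drift, spatial structure (in time-course mode), dyskinesia
duration. Passing recovery tests therefore show that the chain of
estimators is correct and calibrated under the assumed state-switching
model — not that the pipeline is robust to every nuisance structure of
real fMRI.

## Quality control

Framewise displacement is the Power convention: sum of absolute
frame-to-frame differences of the six parameters, rotations converted via
a 50 mm radius; the reference analysis names only "framewise
displacement", and this is the dominant convention at a 0.5 mm threshold.
Exclusion applies strict inequalities (mean FD > 0.5 mm, any |translation|
> 3 mm, any |rotation| > 3°, per axis, rotations compared in degrees);
boundary values are retained. The per-axis reading of the caps is a
convention choice, not a claim about the original study's rule.

## Group ICA (voxel mode)

Two-level reduction (per-session PCA to ~1.5× the model order, temporal
concatenation, group PCA to the model order) followed by spatial FastICA;
the run with the largest total source kurtosis over a small number of
restarts is kept, replacing run-stability clustering, and the model order
is a configuration constant rather than an estimated quantity — order
estimation and stability analysis are orthogonal to the state analysis
this package exists for. Back-reconstruction projects the group mixing
through each session's retained reduction operators to get session time
courses, then least-squares fits session maps. Component selection uses
the spectral criteria (low-frequency power ratio over 0–0.1 Hz vs
0.15–0.25 Hz bands ≥ 2; spectral dynamic range ≥ 0.01 on the unit-power
Welch spectrum) and network labels by template correlation; the dynamic
range definition (peak power minus minimum power above the peak) and both
thresholds are conventions calibrated so low-frequency sources separate
from white-noise sources on generator data. Post-processing is linear
detrend, MAD-based despiking (|z| > 4 replaced by cubic interpolation
through clean samples), least-squares removal of the six motion
parameters, and a zero-phase order-5 Butterworth low-pass at 0.1 Hz
(≈ 60 dB at 0.2 Hz after forward-backward application).

## Numerical and design choices

- Fisher-z clamp 1 − 1e−7 everywhere a correlation reaches ±1.
- Assignment ties in k-means go to the lowest state index; empty clusters
  are re-seeded at the worst-fit window.
- "Top connections" keep ⌈fraction × n_pairs⌉ pairs by |value| (12 edges
  at 5% of 231 pairs), tagged positive/negative/zero.
- All randomness flows from one seed through process-independent child
  seeds (CRC-keyed `SeedSequence`), so cohorts, penalties, and clusterings
  are bit-reproducible across interpreter runs; outputs are written with
  fixed float formats and hashed into the run manifest.
- Problem sizes in the shipped experiments: state recovery uses the full
  default cohort (75 subjects × 2 sessions × 230 time points, ≈ 30k
  windows) over 5 seeds; model-order recovery uses 20-subject cohorts
  over 10 seeds per planted k; test calibration uses 1000 null
  replications at the design's arm sizes; severity recovery uses 20
  cohorts at n = 41. These sizes make the full suite run on a single CPU
  in well under half an hour while leaving the Monte-Carlo margins far
  from the pass thresholds.

## Known limitations

- Dwell-time estimates from window sequences carry end-censoring and
  window-smearing biases (runs shorter than half a window vanish; terminal
  runs are truncated). No correction is applied, matching common practice;
  the recovery tolerance (15%) reflects the residual bias at the default
  dwell of 60 time points. Substantially longer dwells at a fixed session
  length would push the censoring bias past that tolerance.
- The elbow criterion needs states that are actually separated in
  connectivity space; on weakly separated mixtures the validity curve is
  smooth and the selected k is unstable — a property of the criterion, not
  of this implementation.
- Exact Mann–Whitney enumeration is exponential; it is capped at combined
  n = 20 (≈ 184k assignments) and Wilcoxon at n = 15 (32k patterns).
- The voxel-mode ICA is a compact two-level implementation adequate for
  the linear-mixing generator; it does not attempt to replicate any
  specific toolbox's output on real data.
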