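# Methods

This note records the models implemented in `nmpgrn`, the conventions and
defaults chosen where a design was genuinely open, and what the synthetic
data do and do not establish.

## Pre-processing

Pipeline order is fixed: QC-filter cells → filter genes → CPM → log10.
A cell passes QC with ≥ 10⁶ total reads and ≥ 1000 expressed genes
("expressed" = count > 0). A gene is kept when detected in ≥ 10 cells —
detection counted on the QC-passing cells only — and not flagged as a
pseudogene. CPM rescales each cell to 10⁶ total counts; the log layer is
log10(CPM + 1), the pseudocount chosen so zeros map to zero. Layer tags
(`counts` / `cpm` / `log_cpm`) are enforced at operation boundaries, so
normalising twice or logging raw counts is an error rather than a silent
corruption. Manual image-based debris/doublet curation of microfluidic
captures is not reproducible in software and is deliberately replaced by
the two numeric thresholds alone.

## Feature selection

Each gene's 1-D expression distribution is discretised by the Bayesian
Blocks change-point dynamic program (events fitness `N(log N − log T)` per
block, geometric prior with false-alarm probability p0 = 0.05 via
`ncp = 4 − log(73.53 · p0 · n^−0.478)`). The DP is exact; tests verify it
against exhaustive enumeration of all 2^(n−1) partitions at small n. One
behaviour worth knowing: for two tight, well-separated value clusters the
optimum is dense–gap–dense (the wide, nearly empty middle block absorbs the
one or two most extreme stragglers), not a single cut.

Mutual information between discretised genes is the plug-in estimator in
natural log (nats), with no small-sample bias correction. A gene is
selected when it exceeds MI > 0.25 (strict) with at least two distinct
partners. The log base is the main knob for reproducing any particular
selected-gene count on real data: a cutoff of 0.25 nats ≈ 0.36 bits, so a
bits-based reading of the same threshold selects more genes. Whether MI is
computed on CPM or log-CPM matters little because the discretisation adapts
its edges to any monotone transform; CPM is the default.

Dispersion (variance/mean) is z-scored within 20 equal-frequency bins of
mean expression (ties broken by gene order); zero-mean genes get dispersion
0 with a warning.

## Gene modules, cell populations, differential expression

Gene modules: hierarchical clustering of 1 − Spearman ρ with the Ward
criterion; the linkage for genes is chosen to match the cell-clustering
linkage for internal consistency. Two cut modes: a fixed module count
(default 5), or a fine cut (~300 clusters) retaining modules of ≥ 4 genes.
Cells cluster on 1 − Spearman ρ of z-scored levels of the selected genes.
Module activity is the per-cell module mean, z-scored within module and
then within cell; with a single module the per-cell z is defined as 0.

Differential expression uses a left-censored Gaussian (Tobit) likelihood on
log-CPM with censoring at the detection limit (default 0 = log10(0 + 1)).
The null model has a common mean, the alternative group-specific means with
a shared scale; 2Δℓ is referred to χ²(df = 1). Fits use L-BFGS-B with the
analytic gradient and a Nelder-Mead fallback; a non-convergent gene is
flagged and assigned p = 1. The shared-scale, df = 1 convention is an
approximation of the common Tobit-LRT implementations; the null-calibration
test (empirical type-I error within [0.04, 0.06] at α = 0.05 under a
censored null) is the operative check. Significance thresholds (5e-5,
5e-7) are exposed parameters, with no further multiplicity correction.

## Consensus state graph and pseudotime

The cell-cell distance is Euclidean over the selected genes in log-CPM
space. Each pMST replicate sets a uniformly random 20 % of the off-diagonal
*pairs* (both orientations, keeping the matrix symmetric) to a forbidding
constant (10⁶ × max distance) and extracts the MST. To make the MST unique
and runs reproducible, a deterministic rank epsilon (≈ 10⁻¹² of the scale,
ordered by node pair) is added to every weight — a tie-break by (weight,
node-pair order) implemented through weight perturbation rather than an
explicit sorted Kruskal, because the consensus draws hundreds of MSTs and
uses the C implementation in scipy.

Per round, 100 replicates (configurable) are summed into edge-occurrence
counts; the non-zero occurrence distribution is split into 2 classes by the
exact Fisher/Jenks dynamic program, and the lowest-mean class is dropped.
Replicate batches are independent between rounds and pMSTs are always drawn
from the full distance matrix; convergence is declared when the retained
edge *count* repeats between consecutive rounds (matching a convergence
criterion on the number of included edges), with `max_rounds` = 20 as a
guard. Because occurrence filtering can in principle disconnect the graph,
a connectivity guard restores the highest-occurrence dropped edges until
the graph is connected again; this keeps shortest-path queries well-posed
and is on by default.

Pseudotime: Yen's K-shortest loopless paths (default K = 100) between each
(early, late) cell pair, terminal populations of 12 cells each by default.
Cells map to 50 bins by rank along their path with no interpolation; bin
averages over all paths are smoothed by local quadratic regression with
tricube weights over a span of 0.5 (no robustness iterations). Bins never
visited by any path (possible for very short paths) are filled by linear
interpolation before smoothing. Fractional identity min-max normalises each
marker gene to [0, 1], sums increasing markers with weight +1 and
decreasing markers with −1, and affinely rescales the result across cells
to [0, 1]; constant genes are dropped with a warning.

## Thermodynamic circuit model

States of a gene's regulatory region are weighted by products of
`K_TX · c_TX · x_T` over bound inputs; with activators at c = 10,
repressors at c = 0 and n = 2 independent sites per input, the bound and
unbound sums factor as

    Z_bound   = K_Pol · x_Pol · Π_activators (1 + K c x)²
    Z_unbound = Π_all regulators (1 + K x)²

and `p_bound = Z_bound / (Z_bound + Z_unbound)`. The polymerase
concentration never appears separately from `K_Pol · x_Pol`; it is fixed at
1. RA→Sox2 and Wnt→Bra are permanent activating inputs with K = 10.

Dynamics: `dx/dt = 2·p_bound − 2·x` per species, initial state
(Sox2, Bra, M) = (0.8, 0.001, 0.001) — the epiblast-like state — and
effective signal levels 0.001 + scheduled external value (the additive
reading of the schedule). Days D2–D5 map to t ∈ [0, 3], one unit per day,
giving sub-day relaxation at α = δ = 2. Four named schedules: mesodermal
(Wnt 1.0 / RA 0.1 throughout), neural I (switch to RA 1.0 / Wnt 0 at D3),
neural II (RA 0.1 / Wnt 0 at D3), anterior (both 0.1 throughout). Mutants
zero the production rate of the named species.

Two integrators are provided: an adaptive LSODA path (rtol 1e-8,
segment-wise so schedule discontinuities never straddle a step) for
analysis, and a fixed-step RK4 path (dt = 0.005, numba-compiled, n = 2
hard-wired) used by the optimiser; they agree to < 1e-4 on the reference
model and the RK4 error at the optimiser's dt = 0.02 is ~0.02 on the
objective scale, well below between-topology score gaps.

The Chemical Langevin version integrates by Euler–Maruyama (default
dt = 1e-3) with per-species noise `sqrt(max(production + degradation, 0)/Ω)`;
states are clipped at 0 after each step, and |x| > 10 aborts with advice to
reduce dt. Default Ω = 100 produces mixed fates at intermediate signals.

Endpoint classes use a 0.5 threshold convention on clipped D5
concentrations: neural (Sox2 ≥ 0.5, M < 0.5), mesoderm (M ≥ 0.5,
Sox2 < 0.5), NMP (Bra ≥ 0.5, neither of the above), else unassigned. The
attractors are known only graphically, so thresholds are a convention, with
one visible consequence under the reference fit: the deterministic
mesodermal endpoint at D5 (M ≈ 0.30, still relaxing towards its M ≈ 0.6
fixed point) sits below threshold, so a sizeable share of stochastic
mesodermal-condition runs is labelled unassigned and "mesoderm wins" holds
among assigned fates rather than as an absolute majority. The I/O map
applies a common D2–D3 Wnt-high/RA-low phase before the grid signals and
tabulates endpoint-class proportions per (RA, Wnt) pair.

An optional mesoderm→RA feedback term (`dx_R/dt = α_R x_M − δ_R x_R`) is
available but off by default; the core model treats RA and Wnt as static
inputs.

## Topology search

The six TF→TF affinities are optimised in log10 space within [−2, 3] by
scipy's differential evolution (best1bin, population 15×dim, up to 300
generations, tol 1e-8, polished), restarted 30 times by default; every
restart RNG derives from (master seed, topology id, restart index) so
results are independent of execution order. The distance function scales
each gene's trajectories by that gene's maximum over all six experiments,
averages |simulated − target| at each experiment's target points and sums
the six experiment scores.

The target table encodes the qualitative outcomes (all values on the scaled
[0, 1] axis, package conventions): a Bra-high/Sox2-mid NMP-like state at
D3 in the mesodermal and neural-I conditions; mesoderm (M 0.8, others low)
at D5 under sustained Wnt; neural (Sox2 0.8) at D5 under RA; anterior
Sox2-high at both D3 and D5; no mesoderm without Bra; persistent
Bra/Sox2 co-expression at D5 without Msgn1/Tbx6 under Wnt and delayed Bra
decay without it after Wnt withdrawal.

Restart-best solutions are clustered on their log10 parameter vectors by a
Gaussian mixture with the component count chosen by BIC over 1..5. The
covariance is diagonal: with ~30 points in 6 dimensions a full covariance
(27 parameters per component) overfits and BIC degenerates to the maximum
component count, failing planted-mixture recovery; the diagonal model
recovers planted structure correctly. Clusters with ≥ 4 members are
retained and the topology score is the mean score of the best retained
cluster; topologies without one are flagged unresolved and scored by the
mean over all restarts. When the ranking runs at a reduced restart budget,
the 4-of-30 retention rule is scaled proportionally
(`min_cluster_size="auto"`): with 5 restarts this reduces the topology
score to its best coherent solution group, which is robust to the
occasional restart that gets captured by a local optimum — a mean over all
restarts would penalise the optimiser's failures rather than the topology.

At the scoreboard level, the "clearly separated top group" is defined as
the topologies preceding the first consecutive score gap exceeding 3× the
median adjacent gap among the eight best scores. At a scaled-down budget
(5 restarts, 60 generations, population 8×dim, search dt 0.02) the ranking
reproducibly yields a top group of two: the all-repressive wiring and its
sibling with Bra→Msgn1/Tbx6 activating, i.e. the cross-repressive core
with one degenerate edge sign. The reference parameter set shipped with the
package is the dominant solution cluster of a higher-budget fit of the
activating variant (9 of 10 restarts in one tight cluster, score 0.650).

## Cytometry

Gating order: rectangular minimum thresholds on FSC-A and SSC-A (debris),
then a relative band (default ±35 %) around the median FSC-A/FSC-H ratio
(doublets; defaults are tuned to the synthetic generator, real-instrument
values are deployment-specific). The logicle transform follows the
standard biexponential construction: shape p solves w = 2p·ln(p)/(p+1),
the upper branch is `T·e^−(m−w) (e^(y−w) − p² e^−((y−w)/p) + p² − 1)` with
odd symmetry below w, and the forward map inverts it by vectorised
bisection (64 iterations). Scale positions are reported on [0, 1], so the
high-signal asymptote has slope 1/M per decade. Parameter training per
channel: T = max, M = 4.5, A = 0, and W from the 5th percentile r of
negative events as (M − log10(T/|r|))/2, falling back to W = 0.5 for
channels with no negative events (the synthetic generator produces none).

k-means (k = 4) runs on the pooled marker intensities of two samples after
the larger is randomly downsampled to the smaller's size; centres are named
mesoderm (highest Tbx6), neural (highest Sox2 among the rest), NMP
(highest Bra among the rest), unassigned (remainder) — a decision rule
that resolves the ambiguity of purely verbal signatures. All events of
each full sample are then assigned to the nearest centre.

## Synthetic data: what it emulates, what it does not

The branching generator draws three cell groups (NMP trunk with latent
pseudotime in [0, 0.5), mesodermal and neural branches in [0.5, 1]) and
four gene programs whose means follow logistic ramps (midpoint 0.5,
steepness 10): the NMP program decays along both branches, each branch
program rises only on its own branch, housekeeping genes stay flat.
Per-gene maxima are log-uniform over a decade; per-cell library sizes are
gamma with mean 10⁶ and CV 10 %; counts are negative-binomial
(gamma-Poisson, dispersion 0.1 by default, Poisson in the limit 0) and
independently zeroed with the dropout probability (0.2 by default). Truth
(branch, latent pseudotime, gene program, expected counts) lives in sidecar
tables only.

The cytometry generator draws four log-normal populations in (Bra, Sox2,
Tbx6) — around 10^3.8 for each population's high marker and 10^2.1–10^2.4
otherwise, σ = 0.12 decades — plus log-normal scatter, low-scatter debris
and doublets following an FSC-A ≈ 2× singlet trend.

Neither generator attempts realistic gene identities, depth distributions,
batch effects, spectral spillover or instrument-specific scatter; passing
recovery tests therefore demonstrates the correctness of the algorithms
under their stated assumptions, not performance on any particular real
dataset. Counts on real data (how many genes pass an MI cutoff, how many
genes a signature contains) are sensitive to the MI log base and to Tobit
conventions and are not reproduced by synthetic fixtures.

## Problem sizes used in tests

The shipped test suite exercises the pipeline at deliberately modest sizes
chosen as the smallest that make each statistical check stable: 60–150
genes × 300–600 cells for trajectory recovery, 4000 null genes for Tobit
calibration, 100-run CLE ensembles, 5 restarts per topology for the
64-topology ranking, and 10³–10⁴ cytometry events.
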