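# Methods

## Model and assumptions

Two cell types share an environment: producers *C* pay a constant rate
cost κ (per day) to supply a public good consumed within a neighborhood of
*n* cells; free-riders *D* consume without producing. The model is
mean-field in composition: the neighborhood producer fractions N_C and
N_D are the large-population expectations of sampling n−1 neighbors at the
current global cooperator frequency y, with the focal cell's own
contribution included for a producer (hence the exact identity
N_C − N_D = 1/n, the "benefit-to-self" that lets cooperation survive in
small neighborhoods). The benefit is sigmoidal in the producer fraction,
`(1+e^σ)/(1+e^(σ−βN))`: normalized to 1 at N = 0, inflection at σ/β,
saturation at 1+e^σ. β < σ keeps the growth-rate difference r_C − r_D
monotone in y (at most transcritical behavior, alternative stable
monomorphic states); β > σ permits a non-monotone difference and therefore
a stable/unstable interior pair and saddle-node folds. The benefit
evaluation is a single dispatch point (`sigmoid_benefit`), so an
alternative Hill-type form could be slotted in; it is deliberately not
implemented.

Density dependence is global and acts multiplicatively on births only
(E_K = 1 − Y/K); death rates are constant. Negative intrinsic growth rates
are meaningful at the deterministic layer (flow toward extinction) and are
clamped to zero only where rates become jump propensities.

Boundary conventions: y = 1 when only producers remain, y = 0 when only
free-riders remain; at total extinction all rates are zero and the
cooperator fraction is undefined.

## Deterministic layer

`integrate_ode` solves the planar system with LSODA at rtol 1e-8 /
atol 1e-10; the right-hand side floors its inputs at zero so trajectories
cannot cross the axes. The reduced cooperator-fraction equation

    dy/dt = y(1−y)[E_K (r_C(y) − r_D(y)) − (δ_C − δ_D)]

is the exact quotient-rule reduction of the planar system. For fitting,
the default `exponential_regime` freezes E_K = 1: four-day competition
assays run far from confluence, and the reduced equation then needs no
knowledge of absolute densities. `full_logistic` co-integrates Y from a
supplied Y0 for sensitivity analysis; near carrying capacity it slows
selection (smaller |Δy|), which is the expected direction of the bias.

Invasion experiments initialize the resident at its logistic level
K(1−δ/r) plus a small inoculum of the invader. Verdicts use
y_final > 0.99 (invader fixes), < 0.01 (repelled), otherwise coexistence
once |dy/dt| < 1e-6; the default horizon is 500/α, extended up to 4× three
times if the composition is still drifting — slow eigenvalues near
coexistence states are O(1e-3)/day at the reference parameters, so a fixed
short horizon would misreport "undecided".

## Equilibria, stability, classification

Interior equilibria solve δ_D r_C(y) = δ_C r_D(y) (the ratio-of-rates
balance; for δ_C = δ_D = 0 the condition degenerates to r_C = r_D). The
function is smooth and cheap, so roots are bracketed on a 4096-point
uniform grid and bisected to 1e-10, with duplicates merged below 1e-6; a
local minimum of |f| below 1e-8 without a sign change is reported as a
degenerate (tangency) root — the saddle-node point itself. Each regular
root gets Y* = K(1 − δ_C/r_C(y*)) (roots with r_C(y*) ≤ δ_C have no
positive-density counterpart and are discarded) and a stability label from
the eigenvalues of a finite-difference Jacobian of the planar system
(relative step 1e-6, one-sided at the axes); |Re λ| < 1e-8 is reported as
`marginal` rather than forced into a class. A composition-unstable
interior state is a planar saddle (attracting in total density), which is
what "unstable polymorphic equilibrium" means here; `Equilibrium.is_stable`
encodes that reading.

Dynamical classes come from boundary invasibility — C invades all-D iff
r_C(0)·δ_D/α_D > δ_C, D invades all-C iff r_D(1)·δ_C/r_C(1) > δ_D — with
the interior-equilibrium structure used as a consistency check that raises
a diagnostic on disagreement instead of silently preferring either
criterion. The four labels describe rare-mutant invasion; in the fold
regime (β > σ) a stable interior state can legitimately coexist with a
stable all-D, and the label is then `D_dominance` even though established
mixtures persist — this is a property of invasibility classification, not
an inconsistency, so it does not trip the diagnostic. Bifurcation sweeps label an event `saddle_node` when the
regular interior root count changes between 2 and 0 with both monomorphic
stabilities unchanged, and `transcritical` when a boundary state's
stability flips between adjacent control values. Hysteresis sweeps carry
the final state of each control step into the next, reseeding 1
individual-equivalent of any missing type (mirroring stochastic
reintroduction); zero perturbation leaves monomorphic states absorbing.

## Stochastic individual-based model

The Gillespie direct method samples the jump process with per-capita birth
propensities max(0, r_i(y) E_K) and death propensities δ_i, recomputed
after every event. The loop is plain Python with batched uniforms; at the
reference density (K = 1000) it advances ~10^5 events/s, which covers all
ensemble sizes used here without approximation (no tau-leaping). States
are recorded zero-order-hold on a user grid; ensembles spawn independent
child streams from one root `SeedSequence`, so runs are reproducible and
independent. Outcome labels at t_max: `all_C`/`all_D` when one type is
extinct, `extinct` when both are, otherwise `coexistence` (floor 1
individual). The default classification horizon is 200/α.

The optional `sampled_neighborhood` mode draws the n−1 neighbors
hypergeometrically from the current population per event instead of using
the mean-field expectation; with fewer than n−1 other cells the
neighborhood truncates to the available population. Because the benefit is
convex below its inflection, sampling shifts effective rates slightly
(Jensen), but ensemble outcomes at K = 1000 agree with the mean-field mode
within combined sampling error, which is the regime the mean-field layer
assumes.

## Compartment model

`N` compartments share one carrying capacity. Each cycle: every individual
is independently assigned a uniform random compartment (jointly
multinomial, totals conserved exactly), then each compartment evolves for
T_s = 10/α days under the planar dynamics with its local fraction y_i and
neighborhood size n_i fixed at its start-of-cycle occupancy (minimum 1 for
rate evaluation: a lone producer keeps its full self-benefit, a lone
free-rider gets none), coupled through the global density factor
(capacity_mode `per_compartment`, with per-patch capacity K/N, is provided
as a sensitivity switch). End-of-cycle masses are stochastically rounded
(expectation-preserving) so the next mix redistributes discrete
individuals. The long-run cooperator fraction is averaged over the last
20% of cycles; default 200 cycles (100 in the scaled acceptance runs).
With n_i frozen per cycle the mixing step, not the flow, defines the
neighborhood — the modeling intent of the compartment construction.

`ncrit_meanfield` replaces the occupancy distribution by its mean Y/N.
Two criteria are exposed because they answer different questions:
`all_D_unstable` (rare producer invades the free-rider state at
n = Y*_D/N) is monotone in β; the default `all_C_stable` (rare free-rider
fails to invade the producer state, with the producer-state occupancy
solved self-consistently) reproduces the characteristic non-monotone β
dependence — weak benefits need small patches to cover the cost, while
near-saturating benefits equalize the two types everywhere except in
nearly private patches, pushing N_crit toward the total population size.
`ncrit_numeric` bisects over N on majority-vote replicate outcomes of the
full mixing loop.

## Fitting

Observed frequency changes are modeled as the reduced-equation prediction
plus iid Gaussian noise of unknown scale; profiling the variance reduces
maximum likelihood to least squares in (β, σ). The objective is evaluated
on an 8×8 grid over the bounds (β ∈ [0,20], σ ∈ [0,10]) and the best three
grid points seed Nelder–Mead refinements (fatol 1e-8); estimates within
1e-6 of a bound are flagged `at_bound` rather than silently returned.
Fixed nuisance parameters default to α = 1/day, κ = 0.25α, equal deaths —
the convention of the competition-assay reanalysis — and are overridable.
Because the interaction range of a secreted factor is unobserved, the fit
is repeated over n = 4…40 (mean 22) and summarized by per-condition
medians with interquartile ranges; per-n failures are recorded and
excluded.

## Synthetic data

The generator emulates the competition-assay design: seeding fractions
0.1…0.9 in steps of 0.1, three replicates, a 4-day assay, additive
Gaussian noise with sd 0.02 on the fraction change, and per-condition true
(β, σ) (neighborhood size fixed or drawn uniformly on an integer range).
These defaults are the study conditions for the estimator tests; noisy
changes are clipped to keep the final fraction in [0,1], a rare boundary
effect at this noise scale. What the generator does **not** emulate:
plate-to-plate batch effects, counting error correlated across wells,
density dependence during the assay, or drift in the cost parameter —
so passing recovery tests demonstrate estimator correctness on the model's
own terms, not robustness to real-world assay artifacts.

## Problem sizes and numerical choices

Ensemble sizes follow the reference protocols (200 runs for outcome
statistics and mean-field comparisons). Compartment sweeps use a
geometric N grid 4…128 with 10 replicates × 100 cycles — the grid spans
the transition located by the mean-field estimate (N_crit ≈ 61 at the
weak-benefit setting) and is a sweep window, not a model parameter.
Estimator calibration uses 100 seeded repeats. Property draws (interior
root counts) use 10^4 random parameter sets over β, σ ∈ [0,10],
n ∈ [2,50], κ ∈ [0, α].

## Known limitations

- The mean-field composition assumption degrades for small populations;
  the sampled-neighborhood mode quantifies the gap but no finite-population
  correction of the expectations themselves is applied.
- Outcome labels at a finite horizon are transient-sensitive in regimes
  where one type decays very slowly (see the weak-benefit ensemble: the
  coexistence share keeps falling from ~85% at t=200/α to a few percent by
  t≈1200/α because free-riders at the producer-dominated state die at only
  ~5×10⁻³/day). Quantities quoted at a horizon should always carry it.
- No spatial structure beyond uniform remixing (no migration kernels,
  gradients, or anisotropic diffusion), and no coevolution of the carrying
  capacity.
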