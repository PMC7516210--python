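# Methods

`segn` reconstructs time-varying, signed, weighted gene regulatory networks
from two-treatment time-course expression data, and links them to
phenotypic traits through a causal ODE layer. This note records the model,
the estimation choices, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Plasticity model

For gene *i* measured under a control treatment (1) and a stress treatment
(2) over a shared, possibly uneven time schedule, the dynamic
transcriptional plasticity (DTP) is the treatment difference of
expression, y_i(t) = Y_i2(t) − Y_i1(t); traits define the dynamic
phenotypic plasticity (DPP) z_j(t) the same way. Replicates within a
(treatment, time) cell are averaged before differencing — clonal
replicates are exchangeable, so there is no natural pairing. Each
plasticity series is decomposed into a smooth expectation g_i(t) plus
residual error, with g_i(t) fitted by least squares in a Legendre
orthogonal polynomial (LOP) basis on the affinely mapped interval
[t_0, t_T] → [−1, 1]. The default order is 4 for short designs and can be
selected per entity by AIC over orders 2–6; the inference pipeline for
dense designs (30 time points) uses order 12, high enough to track the
oscillatory plasticity responses the regulatory model produces.

## Functional clustering

Genes are grouped into modules by a finite mixture over whole DTP time
courses. The default emission treats the rounded plasticity value at each
time as Skellam-distributed — the difference of two Poisson counts with
time-varying intensities μ₁(t), μ₂(t), matching the count-difference
origin of DTP — so the module mean curve is μ₁(t) − μ₂(t). Intensity
curves are LOPs in mapped time passed through a softplus link so they stay
positive with unconstrained coefficients. Time points are treated as
independent within the emission (no within-gene temporal covariance).
The Skellam log-pmf is evaluated through the exponentially scaled modified
Bessel function (`scipy.special.ive`), which is both stable and fast
enough for the EM inner loop; it agrees with a direct Poisson-convolution
sum to 10⁻¹⁰ over the tested grid.

EM starts from k-means on per-gene LOP coefficients, uses L-BFGS for the
intensity M-step (warm-started between iterations), restarts on empty
modules, and stops at a relative log-likelihood change of 10⁻⁶. The
number of modules is chosen by AIC = −2·loglik + 2·[(L−1) + 2L(r+1)].
A Gaussian emission (`emission="gaussian"`) is available for plasticity
values that are not count-like.

## Regulatory ODE and decomposition

Each gene's plasticity dynamics follow a game-theoretic decomposition into
an independent component and per-regulator dependent components:

    dg_i/dt = Q_i(g_i(t)) + Σ_{i'} Q_ii'(g_i'(t)).

Every Q is a Legendre polynomial in its argument gene's *expression
value*, rescaled affinely to [−1, 1] by that curve's observed range, and
saturated (evaluated at the clipped boundary, 20% margin) outside it —
polynomial extrapolation is unbounded and would destabilize the
integrated system. Two identifiability conventions are imposed, because
the split of a fitted derivative into components is gauge-free without
them:

* dependent components carry no free constant: each Q_ii' is normalized
  to vanish at zero plasticity (a regulator at its pre-treatment baseline
  exerts no influence), with the shed constant absorbed by Q_i;
* the independent component holds the initial condition: P_i(t_0) =
  g_i(t_0) and every P_ii'(t_0) = 0, attributing all baseline expression
  to the gene's own kinetics.

The node and edge quantities of the network are the component integrals
P_i(t) = g_i(t_0) + ∫ Q_i(ĝ_i) ds and P_ii'(t) = ∫ Q_ii'(ĝ_i') ds.
`decompose` integrates the state and all components jointly with one
classical RK4 pass, so the additivity identity
P_i(t) + Σ P_ii'(t) = ĝ_i(t) holds to round-off at every grid time.

### Estimation

Estimation is two-stage. Stage one fits each entity's smooth curve and
analytic derivative as above. Stage two selects each target's regulators
and estimates coefficients:

1. **Support proposals.** The target's derivative curve is regressed on
   Legendre expansions of every candidate curve under a group-lasso
   penalty (block proximal coordinate descent, penalty weight √group
   size, 30-point logarithmic path with warm starts). The target's own
   expansion enters unpenalized. The distinct active sets along the path
   are the candidate supports.
2. **Trajectory-based model choice.** Each support is scored by an
   extended BIC on the *integrated trajectory*: with the independent
   component restricted to first-order kinetics Q_i(g) = α + βg during
   selection, the fitted system for a fixed support is a scalar linear
   ODE with known forcing, so the trajectory is linear in all
   coefficients given β. β is profiled on a decay grid (−1.0 … 0.03,
   augmented by data-driven anchors from the target's own
   derivative-vs-value slope) and the remaining coefficients solved by
   linear least
   squares against basis responses propagated once per β (each RK4 step
   is then a linear recurrence, evaluated with `lfilter`; a light ridge,
   λ = 10⁻⁴ of the mean squared column norm, suppresses mutually
   cancelling component blocks along flat directions of the SSE
   surface). The criterion is
   n·log(SSE/n + v) + df·(log n + 2γ·log K), with n the number of design
   observations, v the observation-noise variance estimated from the
   curve-fit residuals (plus a 0.1%-of-signal smoothing-bias floor),
   K the number of candidates, and γ = 0.8.
3. **Greedy refinement.** Starting from the best path support and from
   the empty set, greedy add/drop/swap moves descend the same criterion;
   the better endpoint wins, truncated to the d_max = 5 strongest groups.

Derivative-residual matching alone — the textbook two-stage scheme — is
retained as the code path when no observed series is supplied, but it is
markedly less reliable: along a near-monotone trajectory the map from
expression value to derivative is single-valued, so a flexible
self-term can absorb regulator contributions, and candidate curves that
share dynamical modes substitute for one another freely. Scoring on the
integrated trajectory with a rigid (first-order) self-term restores most
of the usable signal; this is the package's main methodological choice
where the estimation algorithm was genuinely open.

`fit_ode` provides the general fit (component order 3 by default,
optional trajectory-matching refinement from 8 seeded multi-starts);
`fit_ode_linear_self` is the selection-consistent fit used by the
benchmark, with trajectory-optimal coefficients and first-order
independent kinetics. The benchmark fits components of order 2: dependent
couplings in realistic systems are well described by linear-plus-quadratic
terms, and the extra cubic freedom only helps spurious supports imitate
the data.

## Interaction taxonomy and networks

At any time t the pair (P_ii'(t), P_i'i(t)) classifies the interaction of
genes i and i′ into eleven types: symmetric/asymmetric synergism (both
positive, magnitudes equal/unequal), directional synergism toward i or
i′ (one positive, one zero), altruism toward i or i′ (opposite signs),
symmetric/asymmetric antagonism (both negative), directional antagonism
toward i or i′ (one negative, one zero), and coexistence (both zero).
Values within ε of zero count as zero; ε defaults to 5% of the largest
|P| at the snapshot time (the model gives no natural absolute scale), and
magnitude equality uses a 10% relative tolerance. Classification uses the
cumulative P values, not instantaneous derivatives, so edge classes evolve
smoothly along the time axis. Hubs are nodes whose total (in + out)
degree strictly exceeds the network mean. Centrality reports cover
degree, normalized closeness, raw shortest-path betweenness, eccentricity,
principal-eigenvector centrality (all on the undirected skeleton) and
PageRank with damping 0.85 on the directed graph; disconnected graphs are
handled per component and flagged.

## Trait causal layer

Trait dynamics follow the same decomposition with three component groups —
independent kinetics, trait-dependent terms, and gene- (or module-)
dependent terms — fitted with the identical two-stage machinery over the
pooled candidate set of all other traits plus all gene or module curves
(joint selection; the data decide which kind of predictor survives).
Genes with direct edges into a trait form the causal set; remaining genes
are layered by their shortest directed-path distance to that set, with
unreachable genes flagged. Module mean curves are the default gene-side
predictors (coarse-grained mode); individual gene curves within one module
are the fine-grained mode.

## Synthetic data generator

The generator emulates the study conditions of the edge-recovery
benchmark: a sparse directed regulatory system observed as two-treatment
expression with additive Gaussian noise. Its design (all defaults chosen
once; the benchmark scenario is 33 genes, 45 true edges, noise variance
0.01, 30 equally spaced time points):

* **Scale.** Plasticity runs on the expression-count-difference scale
  (amplitudes of order ten), so δ² = 0.01 plays the role of small
  measurement noise, as in real count-derived plasticity series.
* **Graph.** 70% of edges form mutually regulated pairs — the dominant
  motif between co-expression modules in stress-response networks — with
  opposite-sign linear couplings whose pair-specific strength sets a
  rotational frequency (≈0.35–1.95 rad per unit time). Pairs sit early
  in a random topological order; the remaining one-directional edges run
  from core (pair) genes strictly downstream with in-degree capped at 2
  and low per-source fan-out. The cascade-of-oscillators layout keeps
  the system provably stable while giving every gene a non-monotone,
  spectrally identifiable curve.
* **Component functions.** Intrinsic terms are mean-reverting affine
  kinetics (drive |a| ∈ [2, 10], decay ∈ [0.15, 0.5]); one-directional
  couplings are c·(g + κg²/10) with |c| log-uniform on [0.2, 1.0] and
  |κ| ∈ [0.3, 0.7], mixed signs everywhere. Initial plasticity
  magnitudes are drawn from [3, 8] with random sign so the stress onset
  excites all modes. Unstable draws (trajectory beyond ±80) are
  resampled, up to a capped number of retries.
* **Observation model.** Treatment 1 observes a constant pre-treatment
  baseline, treatment 2 baseline + trajectory; each observation carries
  Gaussian noise of variance δ²/2, so the DTP difference has variance δ².

What the generator does *not* emulate: library-size and normalization
artifacts, replicate-level overdispersion, missing cells, time-warping
between replicates, and regulation that changes sign over time within one
edge. Passing the benchmark therefore demonstrates that the estimation
machinery recovers sparse regulatory structure from clean plasticity
dynamics of realistic shape and noise level — not that it is robust to
upstream preprocessing pathologies, which are outside this package's
scope.

## Benchmark protocol

Per replicate: simulate, compute DTP, fit curves (order 12), select
regulators and fit the ODE per target, decompose, and call the ordered
pair (i′, i) an edge iff i′ survived selection and |P_ii'(t_T)| exceeds
5% of the largest |P| at t_T. Confusion counts are over all ordered gene
pairs; TPR = TP/(TP+FN), FPR = FP/(FP+TN); the ROC sweeps a threshold over
|P_ii'(t_T)| scores (unselected pairs score 0) and AUC is the trapezoid
area, which equals the normalized Mann–Whitney U statistic. Replicate
seeds derive from one master seed via `SeedSequence.spawn`. Ten
replicates of the 33-gene scenario run in roughly ten minutes on one CPU;
examples and tests use smaller systems (8–15 genes) where the point is the
contract, not the operating characteristics.

## Numerical choices

* RK4 with fixed substeps everywhere (default internal step: span/300 for
  component fitting, one quarter of the output grid spacing for
  decomposition); a halving check confirms the expected 16× error decay.
* Curve fitting is plain least squares; under-determined orders raise.
* Group lasso: convergence when the largest coefficient update falls
  below 10⁻⁷, at most 200 sweeps per λ.
* EM: iteration cap 500, relative tolerance 10⁻⁶, 5 restarts by default,
  empty-module restarts, intensity floor 10⁻⁸ inside the softplus link.
* Degenerate inputs: constant target curves select no regulators (with a
  warning); constant candidate curves map to zeroed basis columns and are
  never selected; degenerate value ranges fall back to a unit-width map.
* All randomness (k-means seeding, EM restarts, multi-start jitter,
  simulation) hangs off explicit integer seeds.

## Limitations

* Regulator identity is only as identifiable as the data's dynamical
  richness allows: genes whose curves share their entire spectral content
  with other genes can be confused, and near-monotone designs (few time
  points, overdamped responses) will under-recover true edges while
  staying sparse. This is a property of the inference problem, not of
  the implementation.
* The selection-stage restriction to first-order independent kinetics
  trades flexibility for identifiability; strongly nonlinear intrinsic
  kinetics are absorbed into the dependent components or the residual.
* No confidence intervals on coefficients or edge presence (bootstrap
  hooks are future work), and no within-gene temporal covariance in
  either the clustering emission or the fitting criterion.
* The trait layer assumes gene-level equations contain no trait terms, so
  stacking the gene and trait systems leaves gene fits unchanged by
  construction.
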