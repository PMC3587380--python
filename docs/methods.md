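# Methods

## Model

`diffvar` estimates gene regulatory networks for two experimental
conditions jointly from short time-series expression data. Each condition
`c ∈ {1, 2}` follows a first-order vector autoregressive model in state
space form:

    x_t^(c) = (A ∘ E^(c)) x_{t-1}^(c) + η_t,   η_t ~ N(0, H),   t = 2, …, T^(c)
    y_t^(c) = x_t^(c) + ρ_t,                   ρ_t ~ N(0, R),   t observed

with hidden expression levels `x_t`, diagonal system and observation
covariances `H = diag(h)` and `R = diag(r)`, a coefficient matrix `A`
**shared** across conditions, and binary edge indicators `E^(c)` that
switch individual regulations on or off per condition. A regulation
j → i is *common* when `E_ij^(1) = E_ij^(2) = 1` and a *change* when the
indicators differ. Unequally spaced sampling is handled by dropping the
observation equation at grid points without a measurement; the system
grid itself is always equally spaced (e.g., one step per 3 hours for the
lung-cell schedule).

Priors: `A_ij | h_i` is centred Gaussian with variance `h_i·α1` when the
edge is active in at least one condition (`F_ij = 1 − (1−E_ij^(1))(1−E_ij^(2))`)
and `h_i·α0` otherwise, with `α0 ≪ α1` — a spike-and-slab gate that
shrinks inactive coefficients hard. `h_i ~ IG(u0, k0)` and
`r_i ~ IG(v0, l0)` (shape / inverse scale). Each indicator pair carries
the coupling prior `P(E^(1)_ij, E^(2)_ij | z_ij) = z_ij/2` for a
disagreeing pair and `(1−z_ij)/2` for an agreeing pair — the unique
normalization proportional to the disagreement potential — with
`z_ij ~ Beta(ζ_i0, ζ_i1)`. Small `z_ij` expresses the biological prior
that most regulations survive a treatment. The initial state `x_1`
carries no prior of its own; the first system factor is the 1→2
transition (the information-form smoother needs no explicit
initialisation because grid point 1 always carries either an observation
term or the transition quadratic).

## Inference: variational annealing

The target is the configuration of `E` maximizing the marginal
likelihood with `X` and `Θ = (A, h, r, z)` integrated out. Exhaustive
search is exponential in `p²`, so the posterior is approximated by a
factorized `Q(X) Q(Θ) Q(E)` and optimized by tempered coordinate ascent
on the lower bound

    L_τ = ⟨log P(Y, X, Θ, E)⟩ + H[Q(X)] + H[Q(Θ)] + τ·H[Q(E)].

One inner cycle runs, in this order:

1. **M-step** — conjugate updates: `Q(A_i | h_i) Q(h_i)` is
   normal-inverse-gamma per target gene, pooling regression statistics
   from both conditions, masked by the edge probabilities
   (`⟨E_ij E_ik⟩ = e_ij e_ik` off-diagonal, `e_ij` on it) and augmented
   with the expected prior precision `f_ij/α1 + (1−f_ij)/α0`; `Q(r_i)`
   is inverse gamma on pooled observation residuals; `Q(z_ij)` is Beta
   with the expected disagreement added to `ζ_i0` and the expected
   agreement to `ζ_i1`.
2. **Hyperparameter update** — `(u0, k0)`, `(v0, l0)` and per-gene
   `(ζ_i0, ζ_i1)` are re-estimated by maximizing the expected log prior
   (empirical Bayes): the inverse-gamma problem profiles the inverse
   scale and solves a 1-d concave problem in the shape by Newton on the
   log scale; the Beta problem is a damped 2-d Newton on mean-log
   sufficient statistics. When all posteriors coincide the maximizers
   run away (the prior collapses toward a point mass); shapes are capped
   at 1e5 and a failed solve keeps the previous value. By default the
   update runs every inner cycle (`update_hyper=False` disables it, e.g.
   when a fixed model is needed for oracle comparisons).
3. **E-step** — the Gaussian chain `Q(X) ∝ exp⟨log P⟩` is smoothed
   exactly in information form: its block-tridiagonal precision uses
   `⟨H⁻¹(A∘E)⟩` on the off-diagonal and the full quadratic expectation
   `⟨(A∘E)' H⁻¹ (A∘E)⟩` (not the outer product of means) on the
   diagonal, so parameter uncertainty inflates the state noise. A
   forward block elimination plus backward covariance recursion yields
   means, marginal second moments and lag-one cross moments — the
   variational Kalman filter/smoother in precision form; unobserved grid
   points simply contribute no measurement term. Near-singular blocks
   get logged jitter (starting at 1e-9 of the mean diagonal).
4. **A-step** — each `e_ij^(c)` is set to `σ(Δ_ij^(c)/τ)`, the logistic
   of the tempered expected complete-log-joint gain of switching the
   indicator on: the system-likelihood term (linear in `⟨A_ij/h_i⟩`,
   quadratic through `⟨A_ij A_ik/h_i⟩` — in which the `h_i` factor of
   the conditional coefficient covariance cancels — and the co-active
   probabilities `e_ik`), the prior term through `F_ij` (coupling to the
   other condition's `e`), and the potential term through
   `⟨log z_ij⟩ − ⟨log(1−z_ij)⟩`. Entries of one column are conditionally
   independent across target genes and are updated simultaneously;
   columns and conditions sweep sequentially (exact Gauss–Seidel), five
   sweeps per call. Probabilities are clipped to [1e-12, 1−1e-12].

The inner loop repeats until the relative change of `L_τ` falls below
1e-6 (or 100 cycles); then τ is divided by 1.05, from τ = 2.5 down to
0.01. As τ → 0 the Bernoulli posteriors harden and the final networks
are read off by thresholding `e_ij^(c) > 0.5` (a tie counts as absent).
Every step is exact coordinate ascent on `L_τ`, so the bound is
non-decreasing within a temperature — this is asserted in the tests. The
trace also records the un-tempered variant of the bound (ordinary
`H[Q(E)]`) for diagnostics.

With empirical-Bayes updates enabled and all edge posteriors still near
0.5 (high τ), the Beta update adds ~0.5 pseudo-counts per cycle to
`ζ_i0, ζ_i1` — the bound then improves by a slowly decaying amount each
cycle and early temperatures typically run to the `inner_max` cap. This
is expected behaviour of per-cycle empirical Bayes, not a convergence
failure; `inner_max` bounds its cost.

**EM-style baseline** (`em_fit`): the same loop at a single temperature,
but the edge indicators are treated as parameters to be *maximized*:
each cycle assigns every `e_ij^(c)` to whichever endpoint of (0, 1) has
the larger expected complete log joint (the mean-field objective is
linear in each indicator, so coordinate maximization is an endpoint
assignment), and the result is thresholded at 0.5. Without the
tempered path this greedy scheme commits to borderline edges
immediately and cannot revise early mistakes, which is why it retains
substantially more false positives than the annealed fit — the
behaviour the benchmark comparison quantifies. The soft
unit-temperature update (the plain variational method) remains
available via `a_step(..., tau=1, maximize=False)`.

**Choosing α0** (`select_alpha0`): leave-one-time-point-out cross
validation. For every candidate α0 and every observed time point, the
model is refitted with that observation held out and the squared
distance between the held-out vector and the smoothed prediction is
accumulated; the α0 with the smallest total wins (ties break small). The
final observed point anchors the grid and is never held out. Strict LOO
refits the model `2·T_obs` times per candidate; the `stride` option
holds out every k-th point instead, which is how the desk-scale runs
keep CV affordable. α1 stays fixed at 1000 (any sufficiently flat slab
behaves identically; CV over it would be ill-determined).

## Annealing optimality on tiny instances

For 3-gene, 6-time-point systems with tightly pinned trajectories the
marginal likelihood of every one of the 2^18 edge configurations can be
computed: `Θ` integrates in closed form given `X` (row-wise
normal-inverse-gamma, inverse-gamma for `r`, Beta-potential for `z`) and
`X` is integrated by importance sampling with common random numbers, so
configuration rankings are stable. The annealed configuration matches
the exhaustive argmax on most instances and always lands within the top
handful of configurations; on a minority of weak-data realisations it
terminates in a genuinely different basin of the mean-field functional
(verified by refitting with clamped configurations: the bound and the
exact marginal rank the competing configurations identically). This
matches the known caveat that deterministic annealing is a hill climb —
optimality is guaranteed only if the globally optimal Q functions are
found and the premise factorization holds, which this model family
satisfies only approximately.

## Synthetic benchmark

`simdata` reproduces the evaluation design the method is meant for:

* **Base network** — an undirected preferential-attachment graph with
  exactly `n_edges` edges (one attachment per arriving node, then
  preferential top-up; no particular scale-free generator is canonical
  for this design, so any heavy-tailed generator with an exact edge
  count is admissible — the degree tail is property-tested). Edges are oriented
  by fair coins, root nodes (in-degree 0) get autoloops, and every edge
  draws its AR coefficient uniformly from {±0.5, ±0.6, ±0.7, ±0.8, ±0.9}.
* **Condition split** — autoloops and 70% of the remaining edges are
  common; each other edge goes to exactly one condition by a fair coin,
  keeping its coefficient. Default scale: 100 genes, 150 non-autoloop
  edges → 105 common + 45 condition-specific.
* **Stability** — the coefficient set permits unstable systems;
  coefficients are redrawn (topology and split fixed) until both
  effective matrices have spectral radius < 1, up to 100 attempts.
* **Dynamics** — `x_t = (A∘E) x_{t-1} + η_t` from `x_0 = 0` with a
  100-step burn-in; observations add independent `N(0, obs_sd²)` noise
  at scheduled points only. System sd is 1; observation sd 0.1 (low
  noise) or 1 (high noise).
* **Schedules** — `equal` observes every grid point. `three_block`
  emulates irregular sampling: the grid has 8n/5 points in blocks of
  3n/5, 2n/5, 3n/5; the first block keeps every point, the second one of
  every two, the third one of every three. The kept point of each group
  is its **last**, so the final grid point is observed and defines the
  grid length (25 observed points on a 40-point grid, 50 on 80).
* **Replication** — one network pair per benchmark seed; replicate
  datasets redraw only the noise.

What the generator does *not* emulate: non-Gaussian measurement error,
gene-specific noise scales, missing individual genes at a time point,
nonlinear or higher-order dynamics, and replicate arrays per time point.
Passing the benchmark therefore demonstrates correct inference under the
model's own assumptions, not robustness to the full messiness of
microarray data.

## Scoring

Edge recovery pools both conditions: a predicted regulation (i, j, c) is
a true positive iff the true network of condition c contains it;
autoloops count. Change detection scores the edges present in exactly
one *estimated* network: a true positive requires the true networks to
contain that edge in exactly that condition, so an edge common in truth
but estimated once is a false positive here despite being a true
positive for edge recovery. Autoloops are excluded from change detection
(they are common by construction). Precision is TP/(TP+FP), NaN when
nothing is predicted. Reported fractional TP/FP are means over
replicates; per-replicate counts are integers.

## Problem sizes and defaults

The shipped experiments run at desk scale: the benchmark grid uses 20
genes / 30 edges / 3 replicates with `inner_max=40` (verified to give
identical desk-scale results to the default cap) and a two-point α0 grid
{1e-3, 1e-1} with stride-30 holdout; structure recovery uses 10 genes /
15 edges / 100 time points / 5 seeds. The full-scale design (100 genes,
150 edges, 10 replicates, strict LOO-CV) runs through the same code
path — `BenchmarkSpec()` defaults — and takes hours of CPU.

Other defaults: α1 = 1000, α0 = 0.01 unless CV-selected, τ from 2.5 by
/1.05 to 0.01, `u0 = k0 = v0 = l0 = 1`, `ζ_i0 = ζ_i1 = 10`, `x`
initialised from observations with linear interpolation at unobserved
grid points, edge probabilities initialised at 0.5. The fit is
deterministic given data and configuration; seeds only drive simulation.

## Gene screening for two-condition analyses

`cv_screen_genes` reduces an array to the analysis set in two stages:
rank genes by coefficient of variation of the pooled series and keep the
top `n_first` (default 500); then rank the survivors by a
between-condition divergence and keep `n_final` (default 100). The
divergence statistic is not canonical; the default is the mean absolute
difference of time-matched profiles, with maximal absolute log fold
change as an alternative (`stage2="max_fold"`). Identical conditions
give all-zero stage-2 scores and fall back to stage-1 order.

## Known limitations

* Two conditions only; the indicator construction extends to more
  conditions but the potential coupling would need a redesign.
* VAR(1) dynamics only — regulatory lags beyond one grid step are
  absorbed into spurious or missed edges.
* The annealed optimum is a local optimum of the bound; weak data (very
  short series) can leave it one basin away from the marginal-likelihood
  argmax (see above).
* Strict LOO-CV for α0 is quadratic in series length times the cost of a
  fit; use `stride` for long series.
* Empirical-Bayes hyperparameter updates at every cycle inflate
  `ζ`/shape parameters while the edge posteriors are undecided; harmless
  but the reason early temperatures run to the iteration cap.
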