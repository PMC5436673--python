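# Methods

## Model and assumptions

`hierord` assumes the network processes information in stages: nodes
occupy hierarchy levels `0 … K`, information flows along directed edges,
and **direct links between nodes far apart in the hierarchy are rare**.
Under that locality assumption the topology alone carries ordinal
information about levels, and the few anchored nodes pin the scale and
orientation that topology cannot supply (the objective depends only on
absolute level differences, so without anchors any solution could be
reflected or translated).

The pipeline has three stages.

### 1. Directed spectral embedding

The random-walk matrix is `P = D⁻¹W` with `D` the diagonal of
out-degrees; rows with zero out-degree are replaced by the uniform row.
When the graph is not strongly connected the walk has no unique positive
stationary distribution, so a teleportation mix
`P' = ηP + (1−η)·(1/n)·11ᵀ` is applied with `η = 0.99` by default
(`η = 1`, i.e. no teleportation, when the graph is strongly connected —
checked first). The Perron vector `ψ` is taken from a dense left
eigendecomposition of `P'`, normalized to sum 1, with entries clamped at
a positivity floor of 1e−10; entries below −1e−10 raise an error telling
the caller to lower `η`.

The normalized directed Laplacian

    L_d = I − (Ψ^{1/2} P' Ψ^{−1/2} + Ψ^{−1/2} P'ᵀ Ψ^{1/2}) / 2

is symmetrized against roundoff and decomposed densely (`scipy.linalg.eigh`,
ascending eigenvalues). Its spectrum lies in `[0, 2]` with `λ₁ = 0` and
eigenvector `ψ^{1/2}`; for symmetric `W` and `η = 1` it reduces exactly
to the classic `I − D^{−1/2} W D^{−1/2}`, which the tests use as an
oracle. Eigenvector signs are fixed by making each vector's first
component of magnitude > 1e−12 positive, so the embedding is bitwise
deterministic. Problem sizes here are tens to a few hundreds of nodes;
dense decompositions are both simpler and faster than iterative solvers
at that scale, so no sparse path is provided.

The embedding `Y` takes the **first k eigenvectors including the
trivial first one**; a `drop_first` flag exposes the common alternative
of starting at the second eigenvector (default off). Rows of `Y` are
scaled to unit Euclidean norm to give `Z`; a row norm below 1e−12 raises
an error (it signals a degenerate graph or too small `k`). Row-wise
unit-norm scaling is used because the representative vectors are defined
to lie on the unit k-sphere; a per-column scaling would not achieve
that.

### 2. Pseudo hierarchical distances

With `δ = K/2` and `ε = 1/δ`, the regularized Tanimoto similarity of two
unit rows is `s = fᵢᵀfⱼ / (‖fᵢ−fⱼ‖² + fᵢᵀfⱼ + ε)`; since
`‖fᵢ−fⱼ‖² = 2 − 2fᵢᵀfⱼ` on the sphere, the denominator is
`2 − fᵢᵀfⱼ + ε ≥ 1 + ε > 0`. The attainable range is
`[−1/(3+ε), 1/(1+ε)]`, so every pseudo distance `μ = δ − s` is strictly
inside `(0, K)`. Note this attainable range is a strict subset of
`[−δ, δ]`; the implementation computes the formula as defined and does
not enforce the looser interval. The diagonal is computed by the same
formula (`s_ii = 1/(1+ε)`) and never enters the objective.

`μ` has a deliberately narrow dynamic range around `δ` — it is an
*estimated mean* of the level gap, not a calibrated regressor — and the
optimization below extracts the ordering from its small variations.

### 3. Anchored level minimization

The objective `F(h) = Σ_{i<j} (|hᵢ − hⱼ| − μᵢⱼ)²` is summed over
unordered pairs with the diagonal excluded (ordered summation would
double `F` without moving the argmin; diagonal terms are constants).
Anchors are hard equality constraints: their coordinates are removed
from the optimization entirely.

`F` is nonconvex and nonsmooth. Each of `restarts` (default 50) restarts
draws the free coordinates uniformly from `[0, K]` (restart `r` uses seed
`seed + r`, so one global seed reproduces everything) and minimizes the
smoothed objective, `|x| ≈ √(x² + τ²)`, with L-BFGS-B under the box
`[0, K]`. A single solve at the target `τ = 1e−6` stalls on the kinks of
`|x|`: measured on planted 40-node instances, its best restart objective
(≈ 4400) stayed above the objective of the planted truth (≈ 4170) and
recovery correlation collapsed to ≈ 0.36. Each restart therefore follows
a **continuation schedule**: solve at `τ = K/4`, shrink `τ` tenfold,
re-solve warm-started, down to the final `τ`. The coarse early solves
see a heavily smoothed landscape and place coordinates globally; the
fine solves sharpen the kinks. With the schedule, best objectives land
*below* the planted-truth objective and mean recovery PCC is ≈ 0.91 at
the study conditions. The analytic gradient
`∂F/∂hᵢ = 2 Σⱼ (z̃ᵢⱼ − μᵢⱼ)(hᵢ − hⱼ)/z̃ᵢⱼ`, `z̃ = √(Δh² + τ²)`, is
supplied to the solver.

Because many near-tied local minima exist (discrete hierarchies are
themselves ambiguous — many level assignments explain the same
connectivity), the returned `h` is the coordinate-wise **mean of the
restarts whose exact objective is within `keep_frac` (default 5 %) of
the best restart**, clipped to `[0, K]` with anchors re-imposed.
Averaging all restarts regardless of quality would mix in poor minima;
averaging only ties makes the estimator well-defined and smooths the
arbitrary choices within the tied set. The reported objective is the
exact (unsmoothed) objective re-evaluated at the averaged point — it is
typically above the best single restart, since the average of distinct
minima is not itself a minimum. Discretization rounds half-up
(`⌊h + 0.5⌋`) and clips to `{0 … K}`; half-up is chosen to make tests
deterministic where a tie rule is otherwise unspecified.

## Choosing k and K

Spectral gaps `γᵢ = λᵢ₊₁ − λᵢ` (reported as magnitudes, which are
nonnegative for ascending eigenvalues) indicate how many eigenvectors
carry structure. `suggest_parameters` counts a leading gap as *large*
while it exceeds `c` (default 2) times the median of the gaps after it;
`k` = number of leading large gaps, falling back to 4 with a logged
warning when none stands out. The run of "relatively similar" gaps that
follows (each within a factor 3 of the run's first gap) extends the
level count: total levels = large + run, `K` = total − 1. On a profile
with three dominant gaps, five similar ones and a tiny tail this reads
as 8 levels (`K = 7`). Both numbers are suggestions for a human in the
loop — the heuristic is intentionally simple, the CLI always prints the
full gap vector, and every caller can override `k` and `K`.

## Synthetic planted hierarchies

The generator draws the study benchmark: node `i` gets level
`i mod (K+1)` (deterministic round-robin, so only edges are random) and
each ordered pair receives a directed edge independently with
probability `p0·exp(−β·|Δlevel|)` — the simplest monotone embodiment of
the locality assumption. Weak connectivity is enforced by resampling (up
to 100 attempts, then an error); a `require_connected=False` escape
hatch exists for regimes where connectivity is unattainable by
construction (e.g. extreme `β`, where all edges are same-level).

Study conditions used throughout tests and the acceptance script:
`n = 40`, `K = 9`, `p0 = 0.6`, `β = 1.5` (about 130 directed edges per
graph), anchors on one true bottom and one true top node, `k = 4`,
50 restarts, 10 graph seeds. Five-node instances for the
exhaustive-search comparison use `K_planted = 2`, `p0 = 0.8`, `β = 0.8`
and a `{0..9}` level grid on the three free coordinates (10³
combinations). These sizes keep the full suite under a minute while the
40-node study matches the scale of real cortical networks (32 and 47
areas).

What the generator does **not** emulate: reciprocity statistics of real
cortico-cortical connections, hub/degree heterogeneity, distance-
dependent wiring in physical space, and the feedforward/feedback laminar
asymmetry that defines empirical hierarchies. Passing the recovery tests
therefore shows the method recovers a hierarchy whose signature in the
topology matches the model's own locality assumption; it does not by
itself certify performance on tract-tracing data.

## Evaluation

PCC, MAE and RMSE all use population (1/n) denominators, matching the
printed definitions rather than the n−1 sample convention; on identical
vectors they attain their optima (1, 0, 0). Alignment is by node label,
not file position, restricted to the label intersection (logged when the
sets differ). When either vector is constant the correlation is
undefined and the report carries `None` rather than a number — MAE and
RMSE are still computed. `anchored_pair_fraction` quantifies how much
pairwise hierarchical information a set of anchors supplies: the
fraction of connected (unordered) node pairs incident to an anchored
node, e.g. a single anchor touching 16 of 315 connected pairs supplies
5.08 %.

## Degenerate inputs and numerical tolerances

- Zero out-degree rows → uniform transition row (stated fallback, no error).
- Reducible graphs at `η = 1` → error instructing a lower `η`; the
  default `η` resolves this automatically.
- Perron positivity floor 1e−10; embedding row-norm floor 1e−12;
  similarity denominator guard 1e−12 (unreachable for unit rows);
  eigenvalue identities asserted at 1e−8, symmetry at 1e−10.
- Anchors outside `[0, K]`, unknown anchor labels, and empty anchor sets
  are rejected before any computation.

## Known limitations

- The optimizer offers no global-optimality guarantee; the exhaustive
  integer-grid comparison holds at n = 5 and the random-point sanity
  bound at moderate n, but large instances rely on restart coverage.
- `μ`'s compressed range makes absolute level calibration weak: levels
  near the anchors are more reliable than mid-range levels, and MAE on
  planted data is ≈ 1.2–1.4 levels even at PCC > 0.9.
- Suggested `(k, K)` are heuristics; on small or gap-flat spectra the
  fallback values are arbitrary and should be overridden.
- Binary 0/1 connectivity is the intended regime; non-binary weights are
  accepted (and row-normalized away in `P`) but untested against any
  empirical reference.
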