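# Methods

This note documents the models, conventions and numerical choices behind
`netcog`, in the order data flows through the package.

## Synthetic cohort generator

**Model.** Real resting-state fMRI for the target population is not
publicly available, so cohorts are simulated from a latent community model.
The 90 ROIs are partitioned into consecutive modules of ~10; each module
shares a standard-normal latent signal added with loading *a* to every
member ROI, on top of independent unit-variance noise. The expected
within-module correlation is a²/(1+a²). Controls use
`connectivity_strength_control` (default 0.6 → correlation ≈ 0.26);
patients use *a* − `patient_effect` (default 0.6 − 0.3 = 0.3 → ≈ 0.08).
This is the simplest generative model that yields a tunable group
difference in local-efficiency AUC with the clinically observed direction
(patients lower).

**Score link.** Each subject's cognition score is
clip(intercept + slope · E<sub>local</sub>AUC + N(0, σ), 0, 30). The
predictor's entire exploitable signal is E<sub>local</sub> AUC by
construction, mirroring the feature the clinical analysis selected.
Defaults (intercept −5.1, slope 150, noise SD 2.0) were calibrated once so
the default 90-ROI cohort reproduces the reported clinical group means
(patients ≈ 21.5, controls ≈ 27.4 points) given the generator's own
E<sub>local</sub>-AUC scale (patient mean ≈ 0.177, control ≈ 0.217), and so
cross-validated errors land on the reported scale (RMSE ≈ 2 points). The
default run length (230 timepoints = a typical 240-volume acquisition minus
10 discarded start-up volumes) is an assumption; the true acquisition
length is unreported.

**Determinism.** One seed-sequence per cohort, spawned per subject by
counter, makes generation order-independent and byte-reproducible.

**What the generator does not emulate.** No haemodynamics, no spatial
structure, no motion or physiological confounds, no heavy-tailed or
negatively correlated connectivity, and between-subject topology variance
is narrower than in clinical data. Passing tests therefore demonstrate that
the pipeline recovers signal it is pointed at — not clinical effect sizes.

## Connectome construction

Pearson correlation between ROI rows (zero-variance rows are an error
naming the ROI); Fisher-Z transform of off-diagonal entries, with |p| = 1
clipped to ±(1 − 1e−7) under a warning (exact duplicates can occur in
synthetic data). The Z matrix's diagonal is stored as 1 purely as a
notational placeholder — no downstream computation reads it. Binarization
keeps the `round(s·n(n−1)/2)` strongest edges; edges are ranked by signed z
(most positive first), the dominant convention for binarized functional
connectomes, with absolute-value ranking available. Ties break
lexicographically by (i, j), which makes edge sets nested across
sparsities. The grid 0.10–0.40 (step 0.01) is realized by integer stepping
to avoid floating-point drift.

## Graph metrics

Distances are unweighted shortest paths computed by level-wise BFS with
boolean matrix products (O(diameter·n³) bitwise work — faster than
per-source Dijkstra at these sizes, and verified against a Floyd–Warshall
oracle in the tests). Conventions, stated so tests can be exact:

- nodes with degree < 2 contribute 0 to C<sub>p</sub> and E<sub>local</sub>;
- efficiencies treat unreachable pairs as 1/∞ = 0;
- L<sub>p</sub> averages over reachable pairs only, warns on disconnection,
  and is NaN when no pair is reachable;
- AUC is the trapezoid rule on the exact grid (exact for linear curves).

The small-world normalizers use Maslov–Sneppen degree-preserving
double-edge swaps (10 attempts per edge, 100 nulls per graph by default,
fully seeded, one independent ensemble per sparsity). The randomization
scheme and ensemble placement are field-standard choices; both are
configurable. Tests and examples use smaller ensembles (2–20 nulls), sized
to what the assertions need.

## PCA feature weighting

Features are standardized with the (n−1) sample SD; the covariance of
standardized columns equals the correlation matrix (trace 7). Weights are
eigenvalue shares w<sub>i</sub> = λ<sub>i</sub>/Σλ<sub>j</sub>. Attributing
eigenvalues to *original* features is mathematically ill-posed (eigenvalues
belong to components), so the default rule makes the attribution a
bijection: each eigenvalue, largest first, claims the unclaimed feature on
which its eigenvector loads most strongly (ties by feature index); weights
then sum to exactly 1. A positional `by_rank` attribution (j-th eigenvalue
→ j-th feature column) is provided as the literal alternative reading.
Selection keeps weights > 0.6 — with weights summing to 1 this admits at
most one feature; an empty selection falls back to the argmax with a
warning. Eigenvector signs are fixed (largest-magnitude component positive)
so projections are deterministic. PCA is fitted on the patient group; the
selected *raw* AUC feature is the default predictor input, with the
eigenvector projection c = B·v available but off by default.

## LSSVR

Only the kernelized dual is materialized (the primal weight vector lives in
an unspecified feature space). The fit solves the (n+1)×(n+1) KKT saddle
system [[0, 1ᵀ],[1, K + I/J]]·[b; a] = [0; y] with a dense symmetric solve;
the residual is checked below 1e−8 and Σa<sub>i</sub> = 0 holds by the
constraint row. The RBF width convention exp(−‖x−x′‖²/σ²) has no factor 2
in the denominator — equivalent to the conventional kernel up to
reparameterizing σ², but kept literal so tuned values are interpretable in
this package's convention. Inputs are standardized with training-fold
mean/SD before kernel evaluation, making σ² scale-free. The GPSV baseline
delegates to scikit-learn's ε-SVR (C = 1, ε = 0.1) behind the same
interface.

## Whale optimization and the Lévy-flight variant

Standard WOA: H = 2h·r₁ − h, C = 2r₂ with h = 2 − 2t/T linearly decaying;
encircling (|H| < 1, p < 0.5), random search around a random whale
(|H| ≥ 1, p < 0.5), or logarithmic spiral X* + M₃e^{bl}cos(2πl) with
l = (h₂ − 1)r₃ + 1, h₂ = −1 − t/T (p ≥ 0.5). Once h ≤ 1 — the midpoint of
the linear schedule — the exploration branch can never fire; this loss of
late-run exploration is the motivation for the Lévy variant, which replaces
r₁ in H by a Mantegna-sampled Lévy draw s = μ/|ν|^{1/β} (β = 1.5,
σ<sub>μ</sub> = 0.6966 from the closed form, σ<sub>ν</sub> = 1), restoring
occasional long jumps at any iteration. C stays 2r₂ in both variants.

The Lévy variant's convergence schedule is
h(t) = 2·exp(0.15 − ln(10)·(t/T)⁴): h(1) ≈ 2e^{0.15} = 2.32, nearly flat
through the first half (quartic exponent), exponential decay late. The
published formula for this schedule is typographically ambiguous; this
parse is the default because it satisfies the schedule's stated behavioral
contract (slow early decrease, fast late decrease, h(1) ≈ 2e^{0.15}), and
alternative parses are registered in `lwoa.H_SCHEDULES`. Tests assert only
the contract, never one parse.

Other choices: positions clip to the bounding box (deterministic, vs
reflection); the best-so-far updates immediately whenever a better feasible
candidate is evaluated; non-finite objective values trigger in-bounds
resampling. Defaults: population 20, 100 iterations. The hyperparameter
search runs in log₁₀ space over J ∈ [10⁻², 10⁴], σ² ∈ [10⁻³, 10³] — wide,
scale-free bounds chosen because no published bounds exist.

## Cross-validation pipeline

Prediction uses the patient group only (the clinical data set D);
controls enter only the group statistics and PCA-direction analyses.
Stratification for regression CV orders subjects by score (random
tie-break) and deals consecutive blocks of k across folds — fold sizes
differ by ≤ 1 (50 subjects / 10 folds → exactly 5) and every fold spans the
score range. The same partition (per seed) serves all variants, so
comparisons are paired. Feature extraction runs once per subject before the
folds (it uses no labels); PCA selection and hyperparameter tuning are
fitted inside each training fold. The tuner's objective is the mean RMSE of
an inner 5-fold split of the training fold — the standard nested-CV choice;
degenerate (J, σ²) that make the KKT system unsolvable receive a large
finite penalty. MAPE is reported as a fraction.

Group statistics: pooled-variance two-sample t (Welch optional) per metric
AUC; regional analysis correlates each region's node-efficiency AUC over
the sparsity grid with the score (per-region Pearson r, p, flagged at
uncorrected p < 0.05 to mirror the original analysis; Benjamini–Hochberg
available behind a flag). The published per-region r values are univariate,
so the per-region association is the default; a joint regression is not.

## Problem sizes in the test suite

The suite runs the full default cohort (90 subjects × 90 ROIs × 31
thresholds) for the parameter-recovery checks, with the tuner at population
10 × 25 iterations × 5 inner folds — budgets sized to what the medians
being asserted need. Module-level tests use 30-ROI cohorts, a coarse
7-point grid, and 2–20-graph null ensembles. Monte-Carlo calibration of the
generator uses 100 replicate null cohorts (50 subjects/group) and 20 seeded
effect-direction replicates at reduced dimension.

## Known limitations

- The synthetic cohort's topology variance is narrow; between-subject
  E<sub>local</sub>-AUC spread comes mostly from sampling noise, so the
  score link's slope dominates the recoverable signal.
- Weighted-graph metrics, partial correlation, modularity/hub analyses and
  multimodal extensions are out of scope.
- The eigenvalue-to-feature attribution is a documented convention for an
  ill-posed published rule; published weight tables should not be expected
  to reproduce under any fixed convention.
- With weights summing to 1, the 0.6 selection threshold can select at most
  one feature; whether that was the published intent is unknowable, so the
  threshold is configurable.
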