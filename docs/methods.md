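# Methods

## Model

A methylation sample is modeled probe-pair-wise. Probe location classes are
I (inside a CpG island), S (shore, within 2000 bp of an island, boundary
inclusive) and O (outside). Hidden methylation states are L, M, H in that
canonical order, which is used for indexing, tie-breaking and serialization
throughout. Emissions are beta distributions per (class, state); the medium
state is symmetric (a single shared shape, enforced structurally in the
optimizer, never by averaging after the fact), and H is structurally absent
from class I — the state is omitted from the model rather than carried with
zero weight, which keeps both the free-parameter count and the M-step well
defined.

A gene's first two probes (by genomic coordinate) form a length-2 hidden
Markov chain whose pair class (I,I), (S,S), (O,O) or (S,I) selects an
initial state distribution ω and a transition matrix T. (I,S) pairs are
swapped into (S,I), with the beta-values swapped accordingly; pair classes
mixing O with I or S are excluded from pair modeling (they are rare on
two-probe array designs) though their probes still inform the marginal
mixtures. The free-parameter budget is fixed by the structure: emissions
3 + 5 + 5 = 13, initial distributions 1 + 2 + 2 + 2 = 7, transitions
2 + 6 + 6 + 3 = 17, total 37 per sample.

All densities are evaluated in natural-log space and joint sums use
log-sum-exp; beta shapes above ~100 overflow the linear-domain density well
inside the unit interval. Beta-values are clamped to [1e-6, 1 − 1e-6]
before density evaluation: real arrays produce exact 1.0 (infinite density
when β_shape < 1), and although β-value 0 entries are filtered as bad
quality at load, clamping also covers them defensively.

## Estimation

Fitting is two-stage maximum likelihood per sample, with no pooling across
samples.

**Stage 1 (per location class).** EM on the pooled beta-values of the class
— all probes, including those of single-probe genes, since the marginal
mixture applies to any probe. The E-step computes state responsibilities;
the M-step updates mixture proportions in closed form and maximizes the
weighted beta log-likelihood per state numerically. Because that objective
depends on the data only through Σw, Σw·log x and Σw·log(1−x), each shape
update costs O(1) after the E-step: L-BFGS-B on log-shapes with analytic
gradients (digamma), box-bounded to shapes in [0.01, 500] to prevent
boundary spikes. The update is guarded to never accept a step that lowers
the expected complete-data log-likelihood, so the procedure is a
generalized EM and the observed log-likelihood trace is non-decreasing (the
tests allow 1e-8 relative numerical slack).

Initialization is deterministic: values are split at 0.25 and 0.75 into
provisional L/M(/H) groups, shapes start at the per-group method-of-moments
solution (symmetric variance-matched shape for M) and ω at the group
frequencies (+0.5 smoothing so no state starts dead). Optional seeded
random restarts (`n_restarts`) perturb shapes multiplicatively and ω by a
Dirichlet draw and keep the best final likelihood; the default is 0
restarts because the deterministic start tracks the states' biological
meaning and proved sufficient on the generator's regimes. Convergence:
relative log-likelihood change below 1e-8 or 500 iterations.

**Stage 2 (per pair class).** Baum-Welch on the length-2 chains with
emissions held fixed from stage 1 (the two-step scheme is deliberate; a
joint refit is out of scope). The E-step enumerates the exact joint
posterior over at most nine states; the M-step updates ω and T in closed
form, so monotonicity is exact. ω is initialized at the stage-1 marginal
proportions of the first probe's class and estimated freely — it is not
pinned to the marginals. Empty transition rows (a first-probe state with no
posterior mass) fall back to a uniform row.

Classes with no probes or no pairs are omitted with a warning and the
free-parameter count shrinks accordingly (e.g. a sample without (O,O)
pairs fits 29 parameters).

## Decoding and the false annotation rate

Joint posteriors are computed by exact enumeration — for a 2-step chain
this equals forward-backward, and its argmax equals the Viterbi path — so
decoding is exactly testable against brute force. Ties in the argmax break
toward the lexicographically smallest joint state under L < M < H.
Per-probe marginal posteriors are sums of the joint posterior.

FAR = mean over pairs of (1 − max posterior): the model's expected error
rate of the MAP state assignment. Under correct model specification it is
calibrated — decoding data simulated from the same model, the observed
wrong-assignment frequency matches FAR (tested at ±0.01 on 10,000 pairs).
Note the numeric value depends entirely on how separated the emission
distributions are: the bundled fixtures give FAR ≈ 0.03, while noisier
real-tissue mixtures give considerably larger values.

## Classification

Each fitted sample is reduced to the joint prior proportions ν = ω ⊗ T per
pair class (28 features for a full model; an ω-only variant is available
via `joint=False`). A sample is assigned to the group minimizing the
diagonal standardized squared distance with group mean and variance
computed leave-one-out for the sample's own group. Diagonal covariance is a
deliberate choice: with ~6 samples per group a full covariance is singular.
Variances are floored at 1e-8 (with a warning) for near-constant features;
argmin ties break toward the first group in sorted label order.

## Group comparison

The overall state of a probe pair in a group is the modal Viterbi state
across the group's samples, ties toward the componentwise-smaller state.
Candidate differential pairs are those whose overall states differ between
the two groups; each is then tested by Fisher's linear discriminant
criterion on the per-sample joint posterior proportion vectors, with
significance calibrated by permuting group labels (defaults: 10,000
permutations, 1% level, matching standard practice for this analysis; the
package-level simulations use 999 permutations to keep runtimes short,
which leaves the add-one p-value estimator exact at the 1% level). The
statistic is d′(S_w + λI)⁻¹d — the maximized between/within scatter ratio
along the optimal discriminant — with ridge λ = 1e-6·trace(S_w)/dim because
small groups make S_w singular; the criterion value (not a classification
error rate) is used as the test statistic. The add-one estimator
p = (1 + #{perm ≥ obs})/(1 + n_perm) is super-uniform under the null. No
multiple-testing correction is applied by default, matching the two-filter
procedure (state difference AND significance); the returned p-value table
can be passed through statsmodels' `multipletests` for a
Benjamini-Hochberg variant. Per-probe change records (L→M, M→L, M→H, H→M,
L→H, H→L) count each changed probe of a selected pair and are tabulated by
type and by genomic region.

## Synthetic data

The generator draws (k₁, k₂, x₁, x₂) exactly from the model and lays genes
out in 20 kb blocks on one synthetic chromosome, each block carrying one
1 kb CpG island, with probe offsets chosen so interval-based classification
(2000 bp shores) reproduces the intended classes exactly; for (S,I) genes
the island probe precedes the shore probe on the chromosome, so pair
assembly exercises the swap rule. Default gene counts (2,000 pairs, ~50%
(I,I), 20% (S,S), 15% (O,O), 15% (S,I), plus ~20% single-probe genes)
loosely follow two-probe array designs where island probes dominate.
Emission fixtures L = Beta(1.5, 18), M = Beta(8, 8), H = Beta(15, 1.8) are
invented, well-separated shapes — the states' means sit near 0.08, 0.5 and
0.89 — and the "normal-like"/"tumor-like" profiles differ in mixture and
transition probabilities, most strongly outside islands where the
tumor-like profile makes medium methylation dominant. These are fixtures,
not estimates from any cohort. All randomness flows from a single seed via
spawned substreams per pair class, so output is bit-reproducible.

What the simulator does *not* emulate: array technical artifacts (batch
effects, detection p-values, background normalization), probe-level biases
such as CpG density within a probe, between-gene spatial correlation, and
cell-composition gradients. Passing recovery/calibration tests therefore
demonstrates correctness of the estimation and decoding machinery under
the model's own assumptions, not robustness to real-tissue
model misspecification.

## Numerical choices and problem sizes

- Convergence: relative log-likelihood tolerance 1e-8, max 500 iterations
  per stage; EM monotonicity asserted with 1e-8 relative slack.
- Shape bounds [0.01, 500], optimized on the log scale.
- Degenerate inputs: all-identical values raise; fewer than 50
  values/pairs warn; empty classes are omitted with a warning.
- Model files round-trip at 17 significant digits (`%.17g`), lossless for
  doubles.
- The test suite and the acceptance script use simulation sizes chosen as
  the smallest at which the checked statistical properties are stable:
  recovery at 5,000 pairs per class, FAR calibration at 10,000 pairs,
  type-I error over 500 repetitions of a 6-vs-6 comparison with 999
  permutations, classification over 4 groups of 6-10 samples.

## Known limitations

- Chains are exactly length 2; genes with more probes contribute only
  their first two, and no chromosome-scale HMM is attempted.
- Stage-2 estimates condition on stage-1 emissions; standard errors of
  (ω, T) ignore emission uncertainty.
- The leave-one-out classifier assumes feature independence (diagonal
  covariance) and is transductive; `MahalanobisClassifier.predict` on new
  samples uses full training-group moments instead.
- The permutation test treats samples as exchangeable under the null; it
  does not model paired designs or covariates.
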