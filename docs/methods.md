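# Methods

## Study design and data model

The package analyses a two-arm temperature-shift time course. All eggs
incubate at the female-producing temperature (FPT) until Day 0; a
subset shifts to the male-producing temperature (MPT). Day 0 therefore
exists only in the FPT arm and serves as the common pre-shift baseline
for both arms. Days 0, 3, 6 and 12 carry three biological replicates
per (condition, day) cell and are statistically testable; Days 18, 24,
30 and 36 (Day 36 FPT only) are single samples and are used only
descriptively — the testing layer refuses singleton groups outright
rather than producing untrustworthy p-values.

Expression values are FPKM-like continuous positives. All testing and
trajectory work happens on log₂(value+1); displayed fold changes use no
pseudocount, so a transcript undetected in the baseline group reports
an infinite log₂ fold change, which is carried as a tagged infinite
value (never capped) and excluded from z-scoring and clustering —
capping would invent a magnitude.

## Differential expression

Each comparison is a per-gene two-sample test on log₂(value+1),
Benjamini–Hochberg corrected across genes, with the two-stage threshold
convention (α = 0.05 and FDR 0.05 for the initial test, FDR 0.01 for
the screen that gates every downstream gene set). The BH step-up is
implemented directly — q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j clipped to 1 — and is
oracle-tested against a brute-force evaluation of the definition and
against statsmodels.

The default test statistic is a **moderated t**: gene-wise pooled
variances are shrunk toward an empirical-Bayes prior (s₀², d₀)
estimated across all genes by the scaled inverse-chi-square moment
method on log variances, and the statistic uses the shrunk variance
with df + d₀ degrees of freedom. With three replicates per group a
plain Welch test has ≈4 degrees of freedom; its heavy-tailed null means
BH-corrected significance at q < 0.01 over ~1000 genes requires
|t| > 10, which typical 4-fold effects at realistic replicate noise do
not reach — the moderated statistic is the standard remedy in exactly
this regime and is cross-validated against R limma's lmFit/eBayes
(p-values, prior df and prior variance all agree) in the test suite. A
plain Welch test remains available (`method="welch"`). Genes with
numerically zero variance in both groups are untestable and
conservatively receive p = 1 and direction "none".

Calibration: on 200 global-null simulations (1000 genes, 3 vs 3) the
suite verifies that the fraction of simulations producing any
discovery at q < 0.01 stays within 0.01 plus three binomial standard
errors. Under a global null "empirical FDR" is not directly estimable
(the ratio V/R is undefined when R = 0 in most runs), so the bound is
stated on the discovery probability, which BH controls in this regime.

## Screens

All screens are pure set algebra over DEG tables and are oracle-tested
against naive re-derivations. Conventions that the underlying analysis
leaves open, decided here once:

* **Candidate screen intersection day** — a change over the interval
  (tᵢ, tᵢ₊₁) is crossed with the sex-dependent set at the interval's
  right endpoint tᵢ₊₁, where the change has manifested.
* **Dimorphism on no-replicate days** — Days 18–36 cannot be tested, so
  dimorphism there is the descriptive rule |M−F log₂FC| ≥ 1
  (configurable, recorded in output metadata).
* **Timespan labels** — from the gene's first dimorphic day: a
  contiguous dimorphic run through the final observed day is *Long*, a
  contiguous run that ends earlier is *Short*, any gap is *Ambiguous*;
  never-dimorphic genes are unlabeled.
* **Clustering** — average linkage on Euclidean distance between
  row-z-scored (mean 0, sample sd 1) M−F log₂FC profiles; rows are
  pre-sorted lexicographically by gene id so ties break
  deterministically; the dendrogram is also emitted as newick.

## Network inference

The model class is a linear ODE system dx/dt = A·x + b·u(t) with x the
log₂ fold-change trajectories relative to Day 0 (so x(0) = 0) and u a
unit step at the shift. Observed fold changes are interpolated with
monotone piecewise-cubic (PCHIP) splines — exact at observations, no
overshoot — onto a 0.1-day grid; derivatives are central differences on
that grid.

Structure search is greedy forward selection per target gene. The
self-decay term is always present. At each step every remaining
candidate (other genes, up to the in-degree cap, plus the step input,
which is not counted against the cap) is fitted by least squares of the
derivative; the winner is the candidate whose *simulated target
trajectory* (single ODE integrated with its selected regulators'
interpolated trajectories as exogenous inputs) has the lowest mean
squared error against the interpolated data. Prior-listed candidates
have their error discounted by (1 + confidence) and win ties, so the
prior biases but never forces selection. Selection stops when the
trajectory MSE reaches `allowed_error` (default 0.01), no candidate
improves the fit, or the cap (default 3) is reached. Collinear
candidates are dropped with a warning. The reported `fit_error` is the
mean squared deviation of the fully coupled model simulation (matrix
exponential closed form) from the interpolated trajectories.

Driving selection by trajectory error rather than derivative residual
makes the greedy search optimize the same objective as its stopping
rule, and the suite verifies it against exhaustive enumeration of all
structures within the cap (smallest structure reaching the tolerance;
ties by error then lexicographic order) on 50 random stable 3-gene
systems.

**Identifiability.** A single step response often under-determines the
wiring: a decay-plus-input model can track many smooth monotone
trajectories to MSE ~10⁻⁴, and 3-day sampling leaves a PCHIP
interpolation floor of ~2·10⁻⁴ against the true trajectories. Exact
ground-truth recovery is therefore tested where it is actually
possible: noise-free cascade systems observed daily with
`allowed_error` = 10⁻⁴, where recovery is exact (weights within a few
percent). On random stable 5-gene systems with observation noise
sd 0.05 the edge-support F1 against ground truth plateaus near 0.6
(precision ≈ 0.75) — weakly contributing edges are genuinely
unrecoverable there, and the suite freezes a mean-F1 floor of 0.5
rather than pretending otherwise. The synthetic GRN generator
guarantees every gene is excited by the input (directly or through the
network), since a silent gene's edges are unobservable in principle.

## Robustness

Two resampling tests re-run the full inference: Gaussian noise
(mean 0, sd 0.05 by default) added to the *observed* fold changes,
which are then re-interpolated — perturbing observations rather than
the dense grid, since the grid is an artifact of interpolation — and
random omission of ⌈10 %⌉ of the prior pairs (without replacement,
independent across replicates). Edge frequency is inclusion count over
replicates; failed replicates are discarded, logged and redrawn so the
denominator stays fixed. An edge strictly above 0.5 in *both* tests is
robust (strictness is configurable; the boundary case is excluded), and
a robust edge at or above 0.8 in both is highly robust. Reference
protocol scale is 1000 replicates per test; the desk-scale default in
the pipeline and tests is 200, which bounds the frequency standard
error at ≈0.035 and leaves the >0.5 / ≥0.8 labels stable in practice.

## Synthetic data generator

The generator emulates the temperature-shift design exactly (sample layout above)
and plants four gene classes on top of a log-uniform FPKM baseline
(1–256 by default) with additive Gaussian noise on the log₂ scale
(sd 0.25 by default — multiplicative on the linear scale):

* *development-dependent* — a ±effect step from a random tested day
  onward, applied to **both** arms (never dimorphic);
* *sex-dependent* — a whole-arm ±effect offset on one arm from Day 3;
* *temperature-responsive* — a ±effect step in the MPT arm from Day 3
  onward, mirroring the shift-at-Day-0 design;
* *candidate (both)* — a later-onset (Day 6 or 12) single-arm step,
  development-dependent and dimorphic at once.

Default planted effect is 2.0 log₂ units (4-fold), a magnitude typical
of the strongly responding genes such screens target. The generator
does **not** emulate count-level sampling noise, library-size effects,
within-clutch correlation, or cell-type composition shifts as gonads
differentiate; passing tests demonstrate that the pipeline's logic is
correct under its stated noise model, not that full-dataset gene
lists would be reproduced from raw data. Replicate noise for real FPKM
data is unknown here; sd 0.25 is a choice, not an estimate.

Where exact replicate counts matter the suite uses the design's own
numbers (3 vs 3); simulation-based tests use 200–1000 genes and 20–200
replicates per check, sizes at which every measured margin (recall,
false positives, F1, frequency gaps) is stable across reruns.

## Known limitations

* The DEG engine is a moderated t on log FPKM, not a count-model test;
  absolute study-scale DEG counts are out of reach by design.
* Linear dynamics with a single step input cannot represent
  saturation, delays, or hidden regulators; inferred edges are
  hypotheses ranked by robustness, not mechanisms.
* Prior handling treats pairs as (optionally undirected) selection
  biases only; confidence values other than 0.25 are accepted but all
  pairs are treated symmetrically in kind.
* Timespan labels on Days 18–36 rest on single samples and a
  descriptive threshold; they are annotations, not inferences.
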