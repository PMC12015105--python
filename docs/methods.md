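# Methods

`shumpanel` implements the statistical workflow used to turn a handful of
candidate serum / extracellular-vesicle (EV) protein assays into a single
diagnostic score for platinum resistance in high-grade serous ovarian cancer:
simulate realistic ELISA panel tables, size the discovery cohort, evaluate
single markers by ROC analysis, combine markers into one unit-norm linear
score by smoothed-HUM maximization, and quantify the resulting rule's
out-of-sample behaviour and coefficient uncertainty.

## Generative model for panel tables

Marker concentrations are lognormal within each class.  For marker $k$ with
coefficient of variation $c_k$ the log-scale SD is
$\sigma_k = \sqrt{\ln(1+c_k^2)}$ (the exact lognormal relation, not the
small-CV approximation $\sigma \approx c$; they differ by <5% at $c = 0.6$).
Log-concentrations are multivariate normal with a user-supplied correlation
matrix $R$; the platinum-resistant (PR) class mean is shifted by
$a_k \ln f_k$ where $f_k$ is the natural-scale fold-change and
$a_k \in [0,1]$ is an attenuation factor equal to 1 for EV material and, by
default, 0.2 for the candidate EV markers when the assay matrix is whole
serum — emulating the empirical pattern that the candidate proteins separate
the classes in EVs but not in serum.  A healthy-control class, when
requested, shares the platinum-sensitive (PS) baseline distribution.

Fold-changes are calibrated to a target single-marker AUC through the
equal-variance binormal identity
$\mathrm{AUC} = \Phi\!\big(\ln f / (\sigma\sqrt{2})\big)$, inverted as
$f = \exp(\Phi^{-1}(\mathrm{AUC})\,\sigma\sqrt 2)$.  The default study-like
design uses 44 PS + 44 PR samples, CV 60%, exchangeable inter-marker
correlation $\rho = 0.1$ (the observed correlations are weak but unprinted),
and marker AUC targets CFH 0.95, TMEM205 0.84, CD1B 0.60, FAS 0.55,
CA125 0.53, HE4 0.55, mesothelin 0.58.  The CD1B/FAS/mesothelin values are
the package's own choice of "modest, not significant at this n" levels; only
the four markers with published AUCs enter the calibrated analyses.

What the generator does *not* emulate: assay floor/ceiling effects and
left-censoring at the limit of detection, batch effects between cohorts,
heavier-than-lognormal tails, and any dependence of the EV and serum noise
beyond sharing one latent vector per patient in the paired generator.
Passing tests on this synthetic family therefore demonstrate correctness of
the statistical machinery under its stated model, not robustness of the
biomarker panel on real sera.

## Power design

The discovery design is a two-sided two-sample pooled-variance t-test on
log-transformed concentrations (the fold-change/CV parameterization implies a
log-scale analysis; no other test is meaningful here).  With noncentrality
$\delta = \ln f / (\sigma\sqrt{2/n})$ and $2n-2$ degrees of freedom, power is
$P(|T'| > t_{1-\alpha/2})$ for noncentral $T'$.  Significance is
Bonferroni-adjusted as $\alpha_0/(m\cdot c)$ over $m$ candidate markers and
$c$ contrasts; the default design (0.05 over 10 markers and 2 contrasts)
gives 0.0025, at which fold 3, CV 60% and $n = 10$ per group yield power
0.799.  `solve_n_for_power` inverts the formula by bisection over integer
$n$.  A deep-tail underflow in scipy's noncentral-t CDF is clamped to zero
where the wrong-sided rejection probability is negligible.

## ROC machinery

The AUC is the Mann–Whitney estimator computed from midranks, with ties
worth one half.  Curves use thresholds at $+\infty$, the midpoints between
adjacent distinct pooled scores in descending order, and $-\infty$, so every
achievable confusion table appears exactly once and the trapezoidal area
equals the Mann–Whitney value to machine precision.  Classification at
threshold $\tau$ is `score > τ`.  Youden's $J = \mathrm{TPR} - \mathrm{FPR}$
is maximized over curve thresholds with ties broken toward the lowest
threshold (highest sensitivity).  MCC follows the usual four-factor formula
with the zero-denominator convention MCC = 0.  AUC differences are tested
with DeLong's structural-components method (paired covariance when the same
subjects underlie both scores; summed variances otherwise); a
class-stratified bootstrap variance is available as an alternative.
Single-marker reports auto-orient a marker whose raw AUC falls below 0.5 and
record the flip.

## SHUM combination

For a linear score $\beta^\top x$ the empirical HUM (hypervolume under the
ROC manifold; the AUC for two classes, the correctly-ordered-triplet
proportion for three ordered classes) is a step function of $\beta$, so the
fit maximizes the smoothed surrogate in which each order indicator is
replaced by the logistic kernel $s(t) = 1/(1+e^{-t})$ at bandwidth $h$:

$$\mathrm{SHUM}_h(\beta) = \frac{1}{n_1 n_0} \sum_{i,j}
  s\!\big((\beta^\top x_i - \beta^\top y_j)/h\big),$$

with the analogous triple product for three ordered classes.  $s$ is chosen
for its bounded smooth gradient and the symmetry $s(-t) = 1 - s(t)$, which
makes the objective of $-\beta$ the complement of that of $\beta$.  As
$h \to 0^+$ the surrogate converges to the empirical HUM; at $h = 0$ a tie
contributes $s(0) = 1/2$, exactly the AUC's half-credit convention.

$\beta$ is constrained to the unit Euclidean sphere (the score is invariant
to positive scaling, so the norm is not identifiable) and markers are
z-standardized on the fitting data first — unit-norm coefficients over
markers with wildly different units (CA125 in U/mL against ELISA
absorbances) are only comparable on a standardized scale.  The fitted
(center, scale) pairs travel with the coefficients and are reused verbatim
when the score is applied to new samples.

Optimization is projected gradient ascent on the sphere (ascend, project the
gradient onto the tangent space, renormalize; backtracking line search with
step growth) under a coarse-to-fine bandwidth annealing schedule, geometric
from $1$ to $0.05$ over 8 stages, expressed in units of the pooled
within-class SD of the current combined score.  Multi-start uses 20 random
unit vectors plus the pooled-covariance Fisher/LDA direction as a warm
start.  Because the target of interest is the *unsmoothed* HUM, the
optimizer (a) remembers the best iterate by empirical HUM along each
trajectory, and (b) finishes with a discrete pair-flip polish: the empirical
HUM changes only when $\beta$ crosses a hyperplane
$(x_i - y_j)^\top\beta = 0$, so the polish tries the minimal rotation that
flips each of the nearest mis-ranked pairs and accepts improvements until a
local combinatorial optimum is reached.  The winner across starts is chosen
by empirical HUM with the smoothed objective as tie-break, and the sign is
fixed so mean PR score exceeds mean PS score.  Everything is deterministic
given the config seed.

Two-class fitting is the default; the ordered three-class HUM
(control < PS < PR) is implemented with an analytic gradient but off by
default, since the published combination was evaluated on the two patient
classes.

## Evaluation

*Leave-one-out*: each fold refits the standardization, the combination and
the Youden cut-off on the remaining $n-1$ samples and classifies the
held-out sample — refitting the cut-off inside the fold is the only choice
that keeps the held-out label out of the model.  A single-marker mode fixes
a one-hot $\beta$ and refits only the cut-off (a fixed clinical threshold,
e.g. CA125 = 35 U/mL, is available instead).  Pooled confusion counts yield
LOO TPR/FPR/MCC.

*Bootstrap*: coefficient SEs come from class-stratified resampling with
replacement (preserving the cohort sizes), 500 draws by default, each draw
refit and sign-aligned to the full-data $\beta$ (unit-norm vectors are
identified only up to sign) before per-coefficient SDs are taken; degenerate
resamples in which a class collapses to one unique row are redrawn.

*Diagnostic rule*: the deployable object is the pair (combination vector,
Youden cut-off); a new sample is called PR when its combined score exceeds
the cut-off.  All report numbers are rounded only at serialization
(4 decimals), and one global seed drives the generator, optimizer restarts
and bootstrap through independently spawned child streams.

## Numerical and design notes

* The adjusted level 0.0025 corresponds to 10 markers × 2 contrasts
  ($0.05/20$); the power report surfaces this arithmetic explicitly because
  divisor typos (e.g. writing 10×3 for the same 0.0025) are easy to make and
  costly to inherit silently.
* SHUM-vs-AUC agreement at very small bandwidth is only meaningful when no
  cross-class score gap is comparable to $h$: a pair gap $d$ contributes an
  error $\approx e^{-d/h}/(n_1 n_0)$.  Verification at $h = 10^{-3}$ uses
  scores on a 0.05 grid, where this truncation error is below $10^{-6}$ and
  exact ties match the half-credit convention identically.
* Problem sizes in the test-suite and acceptance computations — e.g. 10
  replicate panels of 44+44 for AUC summaries, 2000/class for
  optimal-direction recovery, 500 bootstrap draws — were chosen as the
  smallest sizes at which the quantities of interest are stable to well
  within their assertion tolerances.
* Degenerate inputs: non-positive-definite correlation matrices are rejected
  with the offending eigenvalue; zero-variance markers cannot be
  standardized (fit) and yield missing entries (correlation); a
  single-valued score set returns the $J = 0$ diagonal point with a warning.

## Limitations

The combination is linear and unregularized by design; with ~5 markers and
44+44 samples the training AUC is optimistically biased (the LOO numbers are
the honest ones), and bootstrap SEs on unit-norm coefficients are SDs on a
sphere, not confidence intervals.  The pair-flip polish guarantees a local
combinatorial optimum, not the global empirical-HUM maximizer; the
acceptance checks bound its gap against exhaustive search in two dimensions.
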