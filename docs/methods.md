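# Methods

This note documents the models, numerical choices, and design decisions
behind `fdacbr`, and what the synthetic experiments do and do not show.

## Data model and quantization

An examination record is a map from attribute names to raw values
(categories or measurements).  The shipped `EncodingScheme` covers sixteen
hypertension risk factors: six static demographic/lifestyle attributes
(gender, age band, dietary habit, smoking, drinking, heart rhythm) and ten
clinical or lifestyle attributes that change between exams (exercise
frequency, central obesity, BMI, diabetes, heart rate, blood urea, total
cholesterol, triglyceride, LDL, HDL).  Numeric attributes are quantized by
half-open bins, lower bound inclusive (a BMI of exactly 24 codes as
overweight, code 2); where the clinical convention prints an explicit
`≥`, the bin edges follow it (triglyceride ≥ 5.65 → code 3).  The
hypertension status itself is the binary label, coded NO→0 / YES→1, and is
never part of the feature vector.  The scheme is config-driven
(YAML/JSON), so cohorts with more attributes plug in without code changes.

Two quirks of the quantization are worth knowing.  First, several codings
are *inverted* with respect to risk (age > 65 has the lowest code, high
total cholesterol codes 1 versus 2 for normal), so the linear risk score
is not globally monotone in clinical severity; this mirrors the coding
conventions of community screening tables and is handled, not "fixed".
Second, the codes are ordinal integers consumed directly by the dot
product — a one-hot expansion would decouple the risk score from the code
magnitudes and is deliberately not used.

## Attribute weights

`fit_forest_weights` trains a bagged forest of depth-limited CART trees
(scikit-learn) with one row per examination and the concurrent label.
Defaults: depth 5, 500 trees, bootstrap resampling, and *all* features
considered at each split (pure bagging).  The per-attribute importance
`D_i` is the unnormalized mean decrease in Gini impurity across trees
(each split weighted by the fraction of samples reaching it), and the
weight vector is `w_i = D_i / Σ D_j`, which sums to one by construction.

Considering all features per split was chosen because the method's role
here is *weighting*, not prediction: it removes the extra variance of
feature subsampling and makes the weights nearly equivariant under
permutation of the attribute columns.  Exact equivariance is not attainable
— the library's split search traverses features in a seed-dependent order,
so impurity ties can break differently — and the tests assert equivariance
at a 0.03 tolerance with matching top attribute.

A reference weight table from a real community study ships as a fixture
(`load_published_weights`).  Its sixteen printed rows sum to 1.083 and the
source elides further rows, so the fixture is marked unnormalized, records
the printed sum, and offers a renormalized view; it is used for worked
examples and oracle arithmetic, never as a substitute for fitting.

## Risk curves

The per-exam risk is the dot product of the code vector with the weights;
a resident's time-ordered risks form a `RiskSeries` on the half-yearly
grid (March of the first study year is index 1, September index 2, …,
index 20 after ten years).

Series are smoothed by least squares in a B-spline basis evaluated with
the Cox–de Boor recursion (order-1 basis functions are right-continuous
interval indicators with the final span closed, so the partition of unity
holds on the whole support; 0/0 terms are 0).  The spline order is 4
(cubic) by default — standard for aperiodic smooth functional data — and
knot vectors are clamped at the series endpoints.

Basis size ("auto" mode): `K = min(max_basis, ceil(N/2))` with
`max_basis = 6`, the order reduced to `K` when necessary.  Roughly two
observations per basis function means noisy exam data is *never*
interpolated — an interpolating fit chases single-exam noise and produces
useless derivatives — and short histories get deliberately stiff fits (a
straight line for two to three exams, a quadratic for four to five).
Interior knots sit at equally spaced quantiles of the observed times.  An
interpolating fit (`knots="interpolating"`, K = N, de Boor's
knot-averaging rule) remains available for exact-representation checks.
One-point series degenerate to a constant with point support.

Derivatives are computed analytically from the spline coefficients
(order k−1 spline on the interior knots), never by finite differences.

## Registration

`register_curves` aligns a set of curves by pure time translation:
alternating minimization of `REGSSE = Σ_i ∫ [R_i(t+δ_i) − μ̂(t)]² dt` over
the common support window, re-estimating the mean curve `μ̂` between
sweeps.  Numerical choices: shifts bounded to ±2 grid slots (one year);
bounded scalar minimization per curve on a dense presample of each curve
(linear interpolation, constant extrapolation beyond the support so the
integration window stays fixed); a δ update is accepted only when it
strictly lowers that curve's integral, which makes REGSSE provably
non-increasing across sweeps; convergence when the mean curve changes by
less than 1e-6 (sup-norm) or after 50 sweeps.  δ is not re-centred:
identical curves stay at δ = 0 and only relative shifts are meaningful.
Registration is a config flag (on by default in the retrieval pipeline);
the evaluation harness compares curves in the raw exam-time frame because
truncated target histories admit no consistent registration.

## Interval similarity

The overlap of two curves' (effective) supports is cut into the unit grid
intervals clipped to the overlap.  Per interval both L2 distances (curve
values; first derivatives) are computed by composite 16-node
Gauss–Legendre quadrature, subdividing at the splines' breakpoints so the
rule is exact for the piecewise-polynomial integrand.  Distances are
length-normalized (root mean square over the interval) so partial edge
intervals are not under-penalized; on full unit intervals this equals the
plain integral form.  The influence factor blends the two distances,
`c_i = θ·d_act,i + (1−θ)·d_der,i`; θ = 0.6 by default (θ = 1 ignores
trend, θ = 0 ignores level — both permitted for sensitivity sweeps).

The blended quantities are distances, while the tiered reuse strategy
needs a bounded similarity percentage.  The declared mapping is
`s_i = exp(−c_i / s0)` per interval, then decay-mass-normalized
aggregation `Sim = Σ s_i μ^(n−i) / Σ μ^(n−i)` over the time-ordered
intervals (0⁰ := 1, so μ = 0 keeps only the newest interval; μ = 0.8 by
default).  Zero distance maps to exactly 100%, the ranking implied by the
raw decayed distance aggregate is preserved per interval, and the
similarity is monotonically decreasing in every interval distance.  The
raw (unnormalized) decayed aggregate of the blended distances is exposed
alongside for formula-level checks.  The scale `s0` defaults to the
median positive blended distance over the candidate set of the current
retrieval, making percentages comparable within one case base; it can be
fixed explicitly for cross-base comparability.  This distance→percentage
mapping is a convention of this package; only the tier bands (90/70/60)
are an external given.

Retrieval ranks all comparable cases (cases with no overlapping window
are excluded and counted), breaking ties by more recent last exam, then by
id.  The engine path precomputes curve and derivative values on the global
19-interval quadrature grid and uses unit intervals fully inside both
supports — exact for unregistered curves (integer supports); with
fractional registration shifts, partial edge intervals are dropped.  The
exact clipped-interval path (`pairwise_similarity`) is the reference
implementation and the two agree to ~1e-7 in tests.

## Synthetic cohorts

The generator emulates a community screening programme at the scale of
thousands of examinations: 500 residents by default, a 20-slot grid, 80%
attendance per exam (at least two exams guaranteed), three trajectory
archetypes.  Per resident, the latent severity trajectory (in [0,1]) is
the archetype shape (piecewise linear: steadily worsening 0.20→0.80,
stable ≈0.5, improving 0.80→0.22) plus a constant level offset
(sd 0.03) and a smooth piecewise-linear perturbation (six knots,
amplitude sd 0.10).

At each attended exam the ten time-varying attributes are quantized from
`severity + setpoint + noise`: per-exam noise sd 0.08, and a *per-resident
per-attribute setpoint* (sd 0.10) capturing that individuals' biomarkers
run persistently high or low independent of their current trajectory —
between-person baseline variance is a dominant feature of real biomarker
panels, and it is precisely the corruption of absolute levels that
motivates comparing trends as well as levels.  Cut points are spread over
severities 0.35–0.90 so the weighted code sum tracks the latent
trajectory across the whole range; the inverse-coded attributes (total
cholesterol; the "never exercises" category) sit at extreme severities so
the sum stays monotone overall.  Demographics are drawn once per resident
from population frequencies, independent of the trajectory.  The
hypertension label is Bernoulli with log-odds increasing in the latent
severity (steepness 8, centre 0.55) plus a modest demographic shift for
age, smoking and drinking — age is the dominant real-world hypertension
factor, and the shift lets the forest learn nonzero demographic weights,
which in turn inject realistic constant offsets into the risk curves.

Ground truth is defined on the *noise-free* latent curves: the correct
neighbours of a target are the same-archetype residents nearest in latent
L2 distance over the target's observed window.  A latent-curve oracle
retriever is therefore an upper bound for any method that sees only the
coded exams; on the default cohorts it scores ≈0.98 (archetype overlap is
rare but possible), and exactly 1.0 on well-separated configurations.

What passing the synthetic experiments does **not** show: the generator
samples category codes directly rather than raw physiology, keeps
demographics constant over ten years (nobody ages across a band
boundary), uses a single label model shared by all residents, and plants
an archetype structure that real cohorts need not have.  Absolute
accuracy numbers on this test bed do not transfer to real screening data;
only the relative, qualitative patterns are meaningful.

## Evaluation protocol

A retrieval for a target is *correct* when the top-ranked case is among
the target's k = 10 ground-truth neighbours (the generator's oracle
standing in for a physician panel; the protocol's printed k is
parameterized because sources disagree between ten and five).  Reported
experiments use 200 targets per cohort with at least ten exams each, and
the seed-averaged results over five cohorts (seeds 1–5).  The exam-count
response truncates each target to its last m ∈ {2,4,6,8,10} exams while
the case base keeps full histories.  Baselines see only the target's
latest encoded exam: cosine similarity, and a mean grey-relational
coefficient with resolution 0.5 — simplified stand-ins for the
cross-sectional comparators in the CBR literature, not reimplementations.

Observed patterns on the default conditions: accuracy grows with history
length (≈6% at two exams to ≈12% at ten, against a k/n chance level of
2%) and overtakes the flat latest-exam baselines from four exams on;
μ = 0.8 roughly doubles the accuracy of μ = 0; the θ = 0.6 blend is
clearly better than trend-only (θ = 0) and statistically indistinguishable
from, on average marginally better than, level-only (θ = 1).  The last
point is a structural property of slow half-yearly trajectories: interval
derivative distances are several times smaller than level distances, so
the Eq-10-style blend at θ = 0.6 ranks nearly identically to θ = 1; the
derivative term's value appears exactly when persistent level offsets
(setpoints, demographic effects) corrupt level matching.

## Known limitations

* The similarity percentage depends on the case-base-derived scale `s0`;
  tier assignments are therefore relative to the base unless `s0` is
  pinned.
* Registration assumes pure translation; amplitude or nonlinear phase
  variation is out of scope.
* The forest is a weighting device; no probability calibration of the
  risk score is attempted, and the score's scale is arbitrary (weights
  sum to one, codes are small integers).
* Exam-time ties across residents are broken by recency and id, which is
  deterministic but arbitrary.
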