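# Methods

## Model and assumptions

The package implements the multimethod latent state–trait model for random
and fixed situations (MM-LST-RF) and its reduced forms (LST-RF with a
single method, MM-LST with a single situation). The measurement model is
linear-Gaussian: manifest variables load on a situation-specific trait
factor, an occasion factor, and — for non-reference indicators — a
trait-method factor (loading fixed at 1) and optionally an occasion-method
factor. Identification follows the reference-indicator convention: the
first indicator of the first method has unit loadings and zero intercept in
every situation; one occasion-method loading per method-situation cell is
fixed at 1 (the lowest-index non-reference indicator of that method, a
deterministic choice mirroring the reference-indicator convention); all
loadings and intercepts are time-invariant. Occasion, trait-method,
occasion-method and change-score residual factors have zero means.

Internally the model is a symbolic parameter graph over LISREL-style
matrices (Λ, B, Ψ, Θ, ν, α) whose entries are fixed numbers or labeled free
parameters; equality constraints are shared labels. Implied moments follow
the reduced form Σ = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + Θ, μ = ν + Λ(I−B)⁻¹α. Composite
latent variables (e.g. `T_S2 = T_S1 + TDIFF_S2`) are rows of B with fixed
unit paths and zero residual variance, which makes the correlated-trait and
latent change-score parametrizations exactly covariance-equivalent under
the mapping Cov(T₁,T₂) = (1+β)Var(T₁), Var(T₂) = (1+β)²Var(T₁) + Var(ω).

## Estimation

Listwise ML minimizes the normal-theory −2 log-likelihood of the
complete-case sample moments; FIML sums pattern-wise Gaussian
log-likelihoods over observed coordinates (unbiased under MAR) and, when
the user model has no mean structure, internally adds one free mean per
manifest so the mean model is saturated and the degrees of freedom are
unchanged. The FIML saturated reference point is obtained by EM for the
unstructured mean and covariance; the listwise one in closed form. The
independence baseline uses per-variable ML. Gradients of the objective are
analytic (matrix path rules) and are verified against finite differences in
the test suite.

Optimization is unconstrained L-BFGS-B (gradient tolerance 1e-7 on the
summed objective, function tolerance 1e-12, followed by a short polishing
pass). Variances are deliberately unbounded: inadmissible solutions must
surface as negative variance estimates ("Heywood cases"), which are flagged
in the fit result and used diagnostically (e.g. to drop occasion-method
factors), never silently clipped. If the first solution fails to converge
*or* converges with a negative variance, up to three jittered restarts
(seed-controlled) probe other basins and the best converged solution by
likelihood is kept — a Heywood solution that is the genuine optimum
therefore remains visible.

Start values are moment-informed: unit loadings; the trait variance starts
at the cross-occasion covariance of the situation's reference indicator
(the natural method-of-moments estimate of stable variance, clipped to
[0.1, 2] times the reference variance); occasion and occasion-method
variances start at 15%, trait-method at 25%, and error variances at 40% of
the reference-indicator variance; slopes and covariances at zero. When
latent means are modeled, intercepts start at the item mean minus the
situation's reference-indicator mean (the metric the trait mean occupies);
otherwise at the item mean. A simpler "half the reference variance for all
variances" rule proved prone to a spurious basin in mean-structured models
on discretized data (negative trait variance with slope near −1), which
motivated this choice.

Standard errors come from the observed information (central finite
differences of the analytic gradient); singular information yields
per-parameter non-identification flags instead of numbers. χ² is
2(llₛₐₜ − ll); RMSEA uses N in its denominator with a 90% CI from
noncentral-χ² inversion; SRMR uses covariance residuals only
(standardized by sample standard deviations, means excluded) so the index
is comparable across mean-structure settings — this can differ from
software that folds mean residuals in. AIC/BIC use −2ll with the subject
count. No multiplicity correction is applied to parameter z tests;
invariance decisions use the change-in-fit rule below, not p-values.

## Equivalence, invariance and decision rule

Within-factor equivalence levels (congeneric → essential equivalence →
equivalence → essential parallelity → parallelity) progressively fix
loadings to 1, intercepts to 0 (trait family only; the residual families
have zero means, so intercept-bearing levels reduce to their loading/error
implications with a logged note), and equate error variances. Error
variance equating is scoped within situation × occasion across the
factor's indicators, because factors are situation-specific and equivalence
is defined over the indicators of one factor. Default restrictions are
conservative: parallel trait factors, essentially equivalent occasion
and occasion-method factors, all latent variables uncorrelated, no mean
structure, listwise estimation.

Measurement invariance across methods or situations adds equality labels:
metric (loadings), scalar (plus intercepts), residual (plus error
variances); trait means stay free across situations so latent comparisons
remain possible. Groups containing a fixed member (reference indicators,
identification loadings) are skipped and logged. The sequence runs the
time-invariant default model as its least restrictive member, forces a mean
structure so all four models stay nested, and decides each step with the
large-sample change-in-fit rule: non-invariant iff ΔCFI ≤ −.010 AND
(ΔRMSEA ≥ .015 OR ΔSRMR ≥ .030 for metric, ≥ .010 for scalar/residual),
thresholds inclusive. A CFI-only exceedance is flagged separately without
flipping the conjunctive decision, so a stricter CFI-only reading remains
recoverable from the report.

## Identification caveats

Two structural facts matter for small designs. With congeneric
occasion-method loadings, a method contributing only two non-reference
indicators provides two within-occasion covariance moments per situation
against three parameters (one free loading, T occasion-method variances) —
under-identified; unit occasion-method loadings (essential equivalence, the
default) restore identification. With two indicators per method, the
reference method's occasion-method factor has a single indicator and is
never identified; such designs should exclude occasion-method factors.
Populations with a zero occasion variance leave the occasion loadings
unidentified (their product with the variance is what the likelihood sees).

## Coefficients

All coefficients are computed from the implied latent covariance matrix
(I−B)⁻¹Ψ(I−B)⁻ᵀ, which makes them identical under both trait
parametrizations. Consistency and specificity exclude method variance by
definition; the method share (trait-method plus occasion-method variance
over implied manifest variance) is reported separately so that
Con + Spe + method share = Rel holds as an identity, with
Rel = 1 − Var(ε)/Var(Y). Denominators are model-implied, not sample,
variances, keeping all shares in [0,1] for admissible solutions.
Commonalities are squared cross-situation correlations of corresponding
factors; pairs with no modeled association (no covariance set, structural
regression, or custom line linking them — detected by evaluating the
implied latent covariance at a generic interior parameter point) are
reported as *unavailable* rather than zero; zero or negative factor
variances raise an undefined-correlation error.

## Synthetic data

The generator draws exogenous latent residuals from N(0, Ψ) (eigenvalue
factorization, so positive-semidefinite populations with exactly singular
directions are allowed), propagates them through the latent regressions,
and adds Gaussian errors; MCAR masking is optional. Default populations are
deterministic functions of the parameter indices: loadings 1 ± 0.15
varying by item, trait variance 1.0, occasion variance 0.25, trait-method
0.5 (substantial method effects), occasion-method 0.15, errors 0.4–0.6
(reliabilities around .6–.9), trait correlation .55 when modeled,
interaction slope −0.4. Measurement parameters depend only on the item
(i, m), so default populations are measurement-invariant across occasions
and situations — the correct null for invariance calibration.

Two ready-made generators emulate the published example designs. The
`real_like` dataset (425 × 24) mirrors a two-context, two-occasion,
true-/false-keyed five-point-Likert study: trait mean 3.64 in the
reference context, latent mean difference −0.43, interaction slope −0.4,
difference-residual variance 0.09 (population commonality ≈ .7), small
occasion variances, no occasion-method factors, intercepts placed so item
means sit mid-scale, values rounded and clipped to 1..5 with 2% MCAR. The
`simulated_like` dataset (500 × 36) is continuous and complete with
correlated traits. Both are emulations of the published designs — the
discretization attenuates covariances slightly, so estimates on `real_like`
recover the population values only approximately — and neither reproduces
the published data values; conclusions from tests on them concern the
engine, not any empirical claim. Real questionnaire data differ in ways the
generator does not emulate: MNAR missingness, item-level skew and floor
effects, and non-invariance across occasions.

## Simulation sizes in the test suite

Deterministic checks run at the sizes that make them sharp: the
million-subject moment oracle (tolerance 0.01 entrywise), 20,000-subject
parameter recovery (tolerance 0.05). Calibration checks use compact
designs so many replicates stay cheap: standard-error calibration with 150
replicates of a 12-variable LST design at n = 500 (empirical SD within 15%
of the mean reported SE), type-I error of the likelihood-ratio test with
100 replicates (binomial envelope 0–0.11 around .05), χ² mean ≈ df with 60
replicates at n = 2000, invariance null and power checks with 10–15
replicates of a 16-variable design at n = 800. These sizes are the
package's own simulation-design choices balancing Monte-Carlo error
against suite runtime.

## Known limitations

Continuous-ML estimation only (no ordinal/WLSMV, robust corrections,
bootstrap, or auxiliary-variable FIML); single-group, single-trait models;
residual covariances between manifest variables are not representable
(error structure is diagonal; ω-residual covariances can be added as
latent covariances via custom lines); no reference-method variant; the
custom-syntax grammar is a restricted subset (`=~`, `~~`, `~`, `~ 1` with
numeric or label premultipliers) and rejects anything else rather than
ignoring it.
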