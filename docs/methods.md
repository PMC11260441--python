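# Methods

`pedvar` estimates the genetic and environmental components of variance in
a quantitative trait measured on a small laboratory pedigree.  The package
was built around a concrete use case — relative bar width (RBW) in a
maternally mouthbrooding cichlid, measured as the width of a colored flank
bar divided by standard body length — but every piece is generic: any
Gaussian trait on a two-or-more-generation pedigree fits.

## The animal model

The core model is the Gaussian animal model

    y = X beta + Z_a u_a + Z_d u_d + Z_b u_b + e

with `u_a ~ N(0, A sigma2_a)` (A the additive relationship matrix from the
pedigree), `u_d ~ N(0, I sigma2_d)` a maternal (dam) intercept,
`u_b ~ N(0, I sigma2_b)` a brood intercept, and `e ~ N(0, I sigma2_e)`.
Narrow-sense heritability is the posterior of
`sigma2_a / (sigma2_a + sigma2_d + sigma2_b + sigma2_e)`.  "Brood nested in
dam" needs no explicit nesting term because brood identifiers are unique
across dams.  Fixed effects are an intercept plus optional sex and
rearing-condition factors (treatment-coded, first level absorbed).

**Priors.**  Each variance carries a scaled-inverse-chi-square prior with
scale `V` and degree-of-belief `nu` — equivalently inverse-Gamma(shape =
nu/2, rate = nu·V/2).  The default is the weakly-informative convention
(V = 1, nu = 0.002).  One consequence deserves emphasis: the prior density
contains a factor `exp(-nu·V / (2 sigma2))`, which acts as a *soft floor*
on every variance at roughly `nu·V / (2n)`.  With V = 1 and nu = 0.002 the
floor is ~1e-5–1e-4; for a proportion-scale trait with phenotypic variance
~9e-4 this is *not* negligible — it prevents any component ratio from
approaching 0 or 1, and caps the additive ratio near ~0.7 even on
noise-free data (we verified this against the exact two-dimensional
marginal posterior computed by numerical integration).  Analyses that need
the boundary reachable should set `V` at the trait's variance scale; the
package exposes this per component via `ModelSpec.priors`.  Fixed effects
carry an improper flat prior.

**Sampler.**  A Gibbs sampler alternates (i) one joint draw of *all*
location effects (beta and every u) from the mixed-model-equations
conditional Gaussian, via a dense Cholesky factorization of the coefficient
matrix, and (ii) conjugate scaled-inverse-chi-square draws for each
variance, `(nu·V + u' K^{-1} u) / chi2(nu + q)` with K = A for the animal
term and I otherwise, and the analogue with the residual sum of squares for
`sigma2_e`.  The joint location draw is the reason the sampler mixes well:
at the pedigree sizes this package targets (~10^2 individuals, coefficient
matrices of order ~150–500) one Cholesky per iteration costs ~0.3 ms, and
the thinned chains have lag-1 autocorrelations of a few percent.  A⁻¹ is
obtained once by dense factorization (Henderson's sparse rules would be
over-engineering at this scale).  Starting values are variances split
equally from the sample phenotypic variance; the conjugate sampler forgets
them within the burn-in.

**Chain lengths.**  The default `ChainSettings` (500,000 iterations,
burn-in 10,000, thinning 50, ~9,800 retained draws) reproduce much longer
runs within Monte-Carlo tolerance at this problem size.  The test suite and
the acceptance script use shorter chains (8,000–60,000 iterations), sized
so every posterior summary they assert has Monte-Carlo error well inside
the asserted tolerance; effective sample sizes are reported alongside.

**Summaries.**  Variance ratios are computed per draw (so the components
plus residual sum to exactly 1 per draw), then summarized by the maximizer
of a Gaussian-KDE (posterior mode) and the shortest interval containing
95% of sorted draws (HPD).  The KDE bandwidth is Scott's rule times 2: the
mode of a raw-Scott KDE is noisy (sd ~0.06 at 10^5 draws for a unit
normal), and mild oversmoothing trades a little peak-location bias for a
~3x smaller variance.  "Total variance explained" is the posterior mode of
the per-draw `1 − residual ratio`.  Effective sample size uses the
initial-positive-sequence truncation of the autocorrelation sum (capped at
n; a constant chain reports ESS = n and autocorrelation 0 by convention).

**DIC.**  Conditional deviance `D = −2 Σ log N(y_i; fitted_i, sigma2_e)`
averaged over retained draws, with `p_D = D̄ − D̂` from the plug-in at the
posterior-mean fitted values and posterior-mean residual variance;
DIC = D̄ + p_D.  Absolute DIC values depend on these conventions, so only
*comparisons between models fitted to the same data* are meaningful, and
all tests assert orderings, never levels.

## Pedigree algebra

`A` is built by the tabular method over a computed topological order
(never trusting file order).  An independent recursive coancestry
implementation (`kinship`) exists solely as a cross-check; a property test
asserts `A = 2f` elementwise over hundreds of random pedigrees including
inbred matings.  Unknown parents are a single internal sentinel; "", "NA",
"NaN", "None", "0" and "." are accepted in files.  Records with exactly one
known parent are allowed — the unknown side behaves as an unrelated,
non-inbred founder.  `A` is dense; entries are guaranteed in [0, 2] with
diagonal `1 + F`.

## The synthetic study design

The generator emulates a two-generation breeding study: unrelated
wild-caught founders (13 dams, 12 sires by default) mated into 20 full-sib
broods totalling 113 offspring (brood sizes 4–15), with 13 broods
paternally half-sib connected, 10 maternally, 3 unconnected, and no dam ×
sire pair repeated.  Connectivity is constructed, not rejection-sampled:
the overlap between the paternal and maternal half-sib sets follows from
the three target counts, shared parents are partitioned into groups of ≥2
broods, and a short retry loop removes the (rare) repeated-pair
collisions.  Offspring are split across three rearing conditions — within
each split brood half "IF" (intermittent feeding) and half control; whole
broods otherwise "standard" — and sexes are assigned 50:50 at birth.

Phenotypes are gene-dropped: founder breeding values `a ~ N(0, V_a)`,
offspring `a = (a_s + a_d)/2 + N(0, V_a/2)` (no inbreeding is possible in
a two-generation design with unrelated founders; with one unknown parent
the Mendelian-sampling variance rises to 3/4 V_a).  Offspring get
`y = mu + a + dam_effect + brood_effect + e`; founders get
`y = mu + a + e*` with `Var(e*) = V_e + V_dam + V_brood`, holding the
*phenotypic* variance constant across generations — wild parents
experienced unobserved maternal and brood environments of their own.  This
choice also makes the expected offspring-on-mid-parent slope exactly h²
(and, at the default components, puts the mid-parent R² of the noise
simulation at `0.00045 / (0.00045 + 0.03²) = 0.33`).

Defaults: `mu = 0.33`, `V_p = 0.0009` (so simulated RBW spans roughly the
wild range of ~27–40% of standard length), split as `V_a = 0.00045` (h² =
0.5), `V_dam = V_brood = 0.00009`, `V_e = 0.00027`.  Repeated measurements
add iid noise with sd 0.012 (~1 RBW percentage point, the scale of
photographic measurement error), giving an expected repeatability of
`V_p / (V_p + 0.012²) ≈ 0.86`.

What the generator does *not* emulate: multi-generation breeding,
selection, unbalanced sex ratios, dominance or sex-linked variance,
age/size covariates, and measurement drift over time.  Tests passing on
this generator therefore show the *estimators* behave correctly under the
stated model, not that real bar-width data satisfy that model.

## Classical statistics

*Mid-parent regression*: OLS of brood-mean offspring trait on the parents'
average, slope = h² in expectation under additive inheritance.
*Dam + sire mixed model*: offspring trait on dam and sire values with a
brood random intercept, each parent's expected coefficient h²/2.  The
random-intercept LMM is estimated by REML with the variance ratio profiled
out; the profiled score equation is solved analytically (per-group
Sherman–Morrison identities) and driven to machine precision with Brent's
method — derivative-free search stalls at ~sqrt(eps), which is visible
when checking against the balanced-ANOVA closed form.  Boundary estimates
return `var_group = 0` exactly, with fixed effects equal to OLS.
Fixed-effect t-tests use residual-style degrees of freedom `n − p − (g −
1)` (recorded in the result); the package's reproduction targets are
estimates, not p-values, so the df approximation is deliberately simple.
*Paired t-test*: df = n − 1; all-zero differences give t = 0, p = 1;
constant nonzero differences give t = ±inf, p = 0 (documented
conventions).  *Repeatability*: R = intraclass correlation from the
intercept-only REML fit, parametric-bootstrap CI, and a boundary-corrected
(0.5 · chi²₁) restricted likelihood-ratio test.

## The identifiability simulation

To ask whether a dataset of this size and shape can separate additive
genetics from maternal/brood environment, offspring are re-simulated as
`mid-parent value + N(0, 0.03²)` on the fixed pedigree with fixed parental
phenotypes (only offspring values are redrawn — the parental draw anchors
the design), and the three random-effect structures are refit to every
replicate with independently derived seeds.  Summaries are medians of
per-replicate posterior modes (never modes of pooled draws) plus the
fraction of replicates each structure wins on DIC.  The characteristic
outcome — reproduced by the acceptance script and asserted by tests — is
that DIC correctly prefers the animal-only structure, while the full model
still assigns sizeable variance to the never-simulated dam and brood terms
and roughly halves the additive ratio.  Model *selection* is reliable at
this design size; variance *partitioning under the wrong structure* is not.

The default replicate count in tests and the acceptance script is 20 (the
full-length experiment runs 100 via configuration); chains are sized as
described above.  All randomness descends from one master seed through
SHA-256-derived, process-stable spawn keys, so every table is bit
reproducible.

## Known limitations

- Gaussian traits only; no multivariate or non-Gaussian responses.
- Dense linear algebra limits pedigrees to a few thousand individuals.
- DIC is the only model-comparison criterion (matching the analysis this
  package reproduces); WAIC/LOO are not implemented.
- The Satterthwaite df approximation for LMM t-tests is not implemented;
  reported p-values use residual df and are approximate.
- With the (V = 1, nu = 0.002) default prior on small-variance traits,
  component ratios cannot reach the 0/1 boundaries (see Priors above);
  this mirrors the convention of the software family this package follows
  rather than a recommendation.
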