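# Methods

## Mixed models and REML

All phenotypic analyses are linear mixed models fitted by restricted
maximum likelihood. Writing `V = Z G Z' + R` for the marginal covariance,
the restricted log-likelihood with fixed effects profiled out is

    lR = -1/2 [ (n - p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ],

with `P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1` and `p` the rank of `X`.
BLUPs are `u_hat = G Z' V^-1 (y - X beta_hat)` and their prediction-error
variance (PEV) is `G - G Z' P Z G`.

Fixed effects are the intercept, environment, and block nested within
environment (treatment-coded). Environments and blocks are treated as
fixed throughout — the standard choice for MET analyses with few
environments, where an environmental variance has no usable estimand; an
optional numeric covariate slot is available for, e.g., days to harvest.

Three layouts cover the analyses:

* **single** — one environment, `g ~ N(0, sigma_g^2 I_m)`;
* **nested** — genotype-within-environment effects with
  `cov(u_i.) = Sigma_env`, any of eight structures (below), and residual
  variance homogeneous (ID) or per-environment (DIAG);
* **interaction** — `g + ge` with two scalar variances. Marginally this
  equals the nested layout under homogeneous compound symmetry via
  `sigma_g^2 = c`, `sigma_ge^2 = v - c`; the two layouts are implemented
  through different evaluators (a structure-exploiting per-genotype block
  solver vs a dense Woodbury solver), so their numerical agreement
  (observed ~1e-12 in log-likelihood) is a genuine cross-check, which the
  test suite asserts at 1e-5.

The genetic-effect-vector ordering is genotype-major, i.e. the covariance
is `I_m ⊗ Sigma_env`; this is the dimensionally consistent reading of a
"genotype nested within environment" effect with an environment-indexed
covariance.

### Covariance structures

| name | form | params |
|------|------|--------|
| ID | v I | 1 |
| DIAG | diag(v_k) | q |
| CShom | v diag + c off-diag | 2 |
| CSHet | sqrt(v_k v_l) rho | q+1 |
| AR1 | v rho^\|k-l\| | 2 |
| AR1H | sqrt(v_k v_l) rho^\|k-l\| | q+1 |
| UNST | any SPD | q(q+1)/2 |
| FA1 | lambda lambda' + diag(psi) | 2q |

Optimisation is on an unconstrained scale: log variances, logistic-mapped
correlations (compound-symmetry correlations bounded in
(-1/(q-1), 1) so the matrix stays positive definite), log-Cholesky for
UNST, and free loadings with log specific variances for FA1 (sign
indeterminacy resolved by forcing the first loading non-negative). AR1
orderings follow the canonical environment order of the dataset, which is
arbitrary and documented as such. The response is standardised internally
to unit variance (parameters are rescaled on output; correlations are
scale-free), which keeps one set of optimizer bounds meaningful for all
traits; variances are bounded below at 1e-10 of the phenotypic variance,
so boundary solutions appear as tiny-but-positive estimates rather than
exceptions.

The optimiser is L-BFGS-B with numerical gradients from three starting
points — a moment-based start (covariance of genotype-by-environment cell
means, shrunk 20% toward sphericity, plus pooled within-cell residual
variances) and two jittered copies — followed by a Nelder–Mead polish
(ftol 1e-12 / fatol 1e-10). Three starts rather than a larger multi-start
were adopted after profiling showed the moment start reaches the same
optimum on this problem class; non-convergence is flagged on the result
and such fits are excluded from model selection rather than raised.

### Model selection and tests

AIC = -2 lR + 2k and BIC = -2 lR + k log(n - p), with `k` the number of
variance parameters only (the fixed part is common to all candidates) and
the BIC sample size taken as the residual degrees of freedom, the
convention of the MET software this workflow mirrors (an `n`-based variant
is available by flag). Ties break on fewer parameters, then on the
canonical structure-name order. Likelihood-ratio tests use
`2 (lR_full - lR_reduced)` against a plain chi-square by default; the
50:50 boundary mixture for a single variance component is available behind
a flag.

## Genetic parameters

Generalised heritability follows the PEV-of-differences form

    Hc2 = 1 - vbar_Delta / (2 sigma_g^2),
    vbar_Delta = 2/(m(m-1)) sum_{i<j} (pev_ii + pev_jj - 2 pev_ij).

The factor 2 in the denominator is required for the balanced-case identity
`Hc2 -> sigma_g^2 / (sigma_g^2 + sigma^2 / r)` (verified numerically to
1e-12 on balanced trials); a variant without it, which appears in some
published write-ups of the formula, is available as `printed_form=True`.
For MET summaries the genotype main effect of the interaction model
supplies `sigma_g^2` and the PEV block; values may leave [0, 1] in
degenerate numerical cases and are reported raw.

Both CVg and CVe (`100 sqrt(variance)/mean`) are reported; published
summary tables of this trial type label the residual CV simply "CV".
Between-environment genetic correlations are read off the fitted
`Sigma_env` (structures with a shared correlation parameter yield equal
off-diagonals by construction); trait correlations are Pearson
correlations of genotype BLUPs with complete-pairs handling. Magnitude
classes are weak (|r| <= 0.45), moderate (0.45 < |r| < 0.76) and strong
(|r| >= 0.76) — the published class bounds leave (0.45, 0.46) unassigned
and it is closed into "moderate".

## GGE biplot

The genotype × condition table (adjusted means or BLUPs) is
column-centered, removing the condition main effect, and decomposed by
SVD. Scores use a singular-value-partitioning exponent `f` (genotype
scores `u d^f`, condition scores `v d^(1-f)`); `f = 0.5` by default, and
on rank-2 tables sector memberships and AEC rankings are invariant to `f`
(asserted by tests). Which-won-where sectors come from the convex hull of
the genotype (PC1, PC2) scores with boundary rays perpendicular to hull
edges; a condition's winner is computed as the hull vertex maximising the
inner product with the condition score — the normal-fan characterisation
of the same sectorisation, which on a rank-2 table equals the per-column
argmax of the data exactly. Trailing singular values below 1e-12 of the
largest are zeroed so that genuinely low-rank tables behave exactly
(collinear score sets raise a geometry error instead of fabricating
sectors). Column standardisation is off by default (center-only); a flag
enables it for multi-trait tables on different units.

## Selection

Truncation selection takes the best `round(intensity * n)` genotypes
(round-half-up; ties broken by label). The multiplicative index uses
`(yhat - lambda)` factors for increase-traits and `(lambda - yhat)` for
decrease-traits so the index is monotone in merit for every trait;
genotypes with any non-positive factor are non-admissible and excluded
before truncation (a literal rank-by-product mode exists). Acceptance
limits `lambda_t` are agronomic choices; the default places them 5% of the
observed range beyond the worst adjusted value, keeping all genotypes
admissible, because population-mean limits would disqualify nearly every
genotype when the index traits are positively correlated (pulp weight and
skin weight share the fruit-size factor). RS is the mean BLUP of the
selected set, RS% divides by the base-population mean of adjusted
phenotypes (full-sibs only by default; the base is an explicit parameter
since reported gain percentages are sensitive to it).

## Diallel compatibility

Crosses are classified by fruit-set rate: compatible (> 50%),
incompatible (exactly 0), otherwise partially compatible — 50% exactly is
partial, since the rule is strict. Selfs are excluded from the
30-reciprocal-cell summary. The packaged 6×6 fixture encodes the published
compatibility grid; compatible cells carry synthetic 10/10 counts and
partial cells synthetic denominators reproducing the printed percentages
exactly (only the classes are meaningful, as the source grid prints no raw
counts).

## Synthetic data

The generator emulates the study design: 30 full-sibs + 2 parents, three
environments with 6/3/3 randomized complete blocks, plot-mean records for
WF, DF, LF, TS, WS, SS and fruit count, with means, variance components
and residual heterogeneity at the magnitudes published for this crop
(heritabilities land in the 0.7–0.9 band), parents offset toward their
published means, fixed block shifts (variance 10% of the residual), and 5%
of plots deleted completely at random. Genetic cell effects follow the
interaction decomposition (main + GEI); across-trait correlation comes
from a two-factor loading model (fruit-size factor; sweetness factor)
giving the strong WF–WS block (~0.96) and negative solubles relations.
The same correlation matrix is applied to the GEI deviations and the plot
residuals — not only to the main effects — because jointly measured traits
must remain physically consistent at plot level: with independent
deviations, WF − WS would go negative in ~7% of plots, violating the data
model. Pulp traits (WP, YP) and yield are *derived*, not drawn, so the
identity WP = WF − WS holds exactly. Rare residual WS > WF draws
(~1 plot per dataset) are clipped to 98% of WF and counted in the truth
record.

What the generator does not emulate: spatial field trend, within-plot
plant variation, covariate effects (ripening time), non-normal traits, and
informative missingness. Passing tests therefore demonstrate correctness
of the estimation machinery under the assumed model, not robustness to
real-data pathologies.

A trait can instead carry an explicit across-environment genetic
covariance (any structure); such traits are drawn independently and are
the basis of the covariance-recovery studies. The diallel simulator gives
selfs probability zero and otherwise binomial fruit set at
`base_rate × (fraction of compatible pollen)` under gametophytic control
(shared-allele veto under sporophytic control); defaults are 10
pollinations per cross and base rate 0.9.

## Validation experiment sizes

The replicated studies in `metqg.experiments` (used by the acceptance
script and test suite) use: 5 balanced replicates for the REML/ANOVA
comparison; 100 replicates of the study design for unstructured-covariance
recovery, scored as the relative error of the *mean* estimate across
replicates (a single replicate with m = 32 genotypes has ~25% sampling SD
per entry, so per-replicate error cannot measure bias); 50 replicates for
BIC selection consistency under a diagonal truth with variances (4, 1,
0.25) against the candidate set {ID, DIAG, CShom, CSHet, UNST}; 200 random
rank-2 6×3 tables for which-won-where exactness; and one balanced
50-genotype trial for the heritability closed form.

## Known limitations

* No spatial or autoregressive-in-field residual models; no pedigree or
  marker kinship; traits are analysed one at a time.
* FA with more than one factor is not implemented (FA1 only, matching the
  candidate menu).
* Heritability standard errors are not computed.
* The multiplicative index is sensitive to the acceptance limits; the
  amplitude-based defaults are a neutral convention, not a recommendation.
* S-allele genotypes are simulated, never inferred from observed diallels.
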