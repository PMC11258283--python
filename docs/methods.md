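# Methods

## Problem and model

A cis-Mendelian-randomization (cis-MR) analysis asks whether a molecular
exposure X (a protein level, transcript abundance, or a downstream
biomarker) causally affects an outcome Y, using SNPs from the gene's local
region as instrumental variables. Unlike polygenic MR, the instruments are
few and in strong linkage disequilibrium (LD), and some may act on the
outcome directly (horizontal pleiotropy), which invalidates them.

With standardized genotypes and traits, the structural model is

    X = Σ_i bX_i G_i + ε_X,
    Y = θ X + Σ_i r_i G_i + ε_Y,

so the conditional (joint) SNP–outcome effects satisfy bY_i = θ bX_i + r_i.
A valid instrument has bX_i ≠ 0 and r_i = 0. The parameter θ is identified
when the valid instruments form the largest ("plurality") group of
instruments implying a common ratio bY_i / bX_i.

GWAS summary statistics report *marginal* effects β\*, related to the
conditional ones through the LD correlation matrix R by β\* = R β. The
package works on the conditional scale:

    β̂  = R⁻¹ β̂*,      Σ = R⁻¹ (R ∘ s s′) R⁻¹,

with s the vector of marginal standard errors and ∘ the element-wise
product. Two points drive the whole design and are easy to get wrong:

1. **Conditional, not marginal, effects.** A single true direct effect r_k
   spreads through R into the marginal effects of *every* correlated SNP
   (r\* = R r), so the plurality condition that holds conditionally is
   generically violated marginally. `fit_marginal_model` implements the
   marginal variant purely so the failure is reproducible; the benchmark
   harness shows its rejection rate under the null several-fold above
   nominal.
2. **Union instrument set.** Omitting an outcome-associated SNP while
   keeping SNPs correlated with it re-routes its direct effect through the
   retained instruments, again invalidating all of them. Selection therefore
   runs on the exposure *and* the outcome, and the model takes the union;
   outcome-only SNPs are expected to be flagged invalid by the fit itself.

## Constrained maximum likelihood

Treating the conditional estimates as multivariate normal with known
covariances, the log-likelihood (constants dropped) is the sum of two
Mahalanobis terms in (θ, b_X, r). For a candidate number K of invalid
instruments, the likelihood is maximized subject to ‖r‖₀ = K:

* the support is initialized from the K largest |β̂_Y − θ⁽⁰⁾b_X⁽⁰⁾| and
  iteratively re-ranked on the scaled squared residuals
  (β̂_Y − θ̂ b̂_X)² / diag(Σ_Y), re-maximizing after each re-ranking and
  accepting only likelihood increases; ties keep the lower index so runs are
  deterministic;
* K is selected by BIC(K) = −2 l + log(min(N_X, N_Y)) · K over the full
  candidate set {0, …, m−2} (cis-regions are small, so the scan is cheap);
  BIC ties resolve to the smaller K;
* multiple starts guard the non-convex support search: the deterministic
  start (θ=0, b_X=0) plus `n_starts = 5` random starts with
  θ⁽⁰⁾ ~ U(−0.5, 0.5) and b_X⁽⁰⁾ drawn from the sampling distribution of
  the conditional exposure estimates.

### Numerical choices

*Inner maximizer.* For a fixed support, the likelihood is maximized by
ascent on the one-dimensional θ-profile: at any trial θ the inner block
(b_X, r_A) has a closed-form joint GLS solution, and θ moves by a
safeguarded Newton step (finite-difference derivatives, backtracking that
only accepts increases). Alternating the three single-block updates —
θ ratio, ridge-type b_X solve, GLS r_A solve — has the same fixed points but
zigzags through the strongly coupled (θ, b_X) valley, needing 100+ cycles
where the profiled ascent needs fewer than ten; both were implemented and
agree with a generic numerical optimizer and with exhaustive support
enumeration to 1e-6. Tolerance 1e-7 on the log-likelihood change, 200
iteration cap, 100 outer (re-ranking) rounds; kernels are numba-compiled.

*Support refinement.* The re-ranking heuristic can settle one element away
from the best K-subset. After it converges, a single-swap local search runs
on the best-of-starts fit for each K: every in/out exchange is screened by
the exact profile value at the current θ̂ (one linear solve each), the top
screened candidates are re-maximized fully, and only likelihood
improvements are accepted, iterating until no swap helps. With this step
the per-K maximized likelihood matches exhaustive support enumeration to
1e-6 on every tested instance (m ≤ 6, all K).

*Bounded effect size.* When the selected "valid" set happens to carry no
exposure signal (possible in perturbed or deliberately mis-specified fits),
the profile rises monotonically toward a flat plateau as |θ| → ∞ and the
MLE diverges. The ascent is restricted to |θ| ≤ 10 — on the standardized
scale this is far beyond any plausible effect — and a fit reported at the
boundary is flagged non-converged. Without the bound, a handful of
perturbations with divergent θ̂ can dominate the data-perturbation mean and
standard deviation.

*Standard error.* The observed Fisher information of the profile
log-likelihood at θ̂ (b_X and r on the selected support profiled out in
closed form), second derivative by central finite difference with step
1e-4 · max(1, |θ̂|). Non-negative curvature raises a degenerate-information
error rather than returning a fake SE.

*Data perturbation (DP).* BIC selection is consistent but not exact at
finite N; to propagate selection uncertainty, B = 100 perturbed copies
β̂⁽ᵇ⁾ ~ MVN(β̂, Σ) are drawn for both traits, the entire scan re-run on
each, and the causal estimate and SE taken as the mean and standard
deviation of the perturbed θ̂⁽ᵇ⁾. The p-value uses a two-sided normal
reference (a t reference is a defensible alternative; the normal is used
throughout and is, if anything, slightly anti-conservative at B = 100).
Perturbation b draws from the dedicated substream (seed, b), so enlarging B
extends rather than reshuffles the sequence. DP inference is visibly
conservative under the null — rejection rates well below nominal — matching
the behavior of selection-averaged estimators generally.

## Comparator estimators

Generalized IVW/Egger regress marginal outcome on marginal exposure effects
with weight Ω_Y⁻¹, Ω_Y = R ∘ s_Y s_Y′; the LD-aware pair applies the same
formulas to conditional estimates with weight Σ_Y⁻¹. The IVW point
estimates of the two families are algebraically identical (asserted to
1e-8 in tests); the Egger ones differ. Egger fits first orient every SNP so
the exposure effect is non-negative (flipping outcome effects and the sign
structure of the weight matrix consistently), since Egger regression is not
invariant to allele coding. Standard errors default to multiplicative
random-effects dispersion φ = max(1, Pearson residual variance), with a
fixed-effects flag; p-values are normal by default with a t option. The
published descriptions do not pin down either choice numerically, so both
are exposed and the default recorded here.

## Instrument selection

`stepwise_joint_selection` approximates conditional-and-joint stepwise
selection from summary statistics: forward steps add the best conditionally
significant SNP (joint GLS on the selected-plus-candidate submatrix of R),
a collinearity cap (default max |r| = 0.9) blocks near-duplicates, and
backward steps drop SNPs whose joint p-value rises above the threshold.
Default p-threshold 5e-6; 5e-8 is exposed. The genotype-level original
additionally tracks allele frequencies and effective sample sizes;
assuming the reference-panel R equals the GWAS-sample R, the summary-level
approximation matches it on well-behaved regions but is not byte-for-byte
identical, and is documented as an approximation. `ld_clump` provides
greedy r² clumping (default 0.001) for independent-instrument baselines.

## Synthetic data

### Summary-statistic designs

`simulate_summary` draws effects on chosen instrument sets
(b_X ~ N(0,1) on I_X, r ~ N(0,1) on I_Y, or r_i = κ/√N_Y in the
weakly-invalid regime), scales them to variance-explained targets
(h²_X = h²_Y = 0.05 by default), and samples marginal estimates
β̂\* ~ MVN(R b, σ\*² R) with σ\*_X² = (1−h²_X)/N_X and
σ\*_Y² = (1−θ²h²_X−h²_Y)/N_Y; LD is AR(ρ) (default ρ = 0.6, m = 10,
N_X = 10000, N_Y = 50000) or two AR blocks with constant cross-correlation.

The variance-explained normalization deserves a note. Scaling the
conditional effects so that b′Rb = h² is the textbook definition, but the
benchmark mean-F-statistic values this generator is validated against
(3.6 / 6.3 / 27.3 at N_X = 500/1000/5000 and 6.0 / 11.1 at reduced h²)
all equal 1 + N h²/(m(1−h²)) to printed precision, which is the value
obtained when the *marginal* effect vector Rb is scaled to squared norm h²;
under the conditional normalization with AR(0.6) LD the mean F is ~1.7×
larger. The generator therefore defaults to `h2_scale="marginal"` — the
convention the benchmark numbers identify — and offers
`h2_scale="conditional"` for the textbook definition. Type-I error and
power conclusions are insensitive to the choice; instrument-strength
summaries are not.

### Individual-level design

`simulate_individual` emulates the individual-level benchmark without any
real genotype panel: genotypes are Binomial(2, MAF) with AR-patterned LD
produced by double-thresholding latent Gaussians whose pairwise correlation
is chosen by inverting the tetrachoric (Hermite-series) attenuation, so the
*realized genotype* correlations match the AR target (within ~0.02 at
n = 5000). Phenotypes follow the structural model with a shared standard
-normal confounder U and unit noises; effects default to the stated
scenario-2 rules (7 exposure SNPs with |b| ~ U(0.1, 0.2) of random sign,
2 nearby pleiotropic SNPs with r ~ U(0.1, 0.2)). Cohorts (exposure GWAS
10000, outcome GWAS 100000, reference panel 5000; region width 50 SNPs —
a free parameter, not derivable from any stated design) are disjoint
independent draws. `gwas_scan` regresses the centered phenotype on
standardized genotypes per SNP; monomorphic SNPs are excluded and reported.

What the generator does *not* emulate: realistic block-structured LD with
recombination hotspots, allele-frequency/LD coupling, population structure
or relatedness, case-control outcomes, and sample overlap between the two
GWAS. A green test therefore establishes correctness of the estimators
under the stated generative models, not robustness to those real-data
features.

## Evaluation metrics

Type-I error and power are rejection rates at α = 0.05 under θ = 0 and
θ ≠ 0; RMSE and bias are computed under the null configuration. Instrument
strength is the mean per-SNP marginal Wald chi-square (β̂\*/σ\*)². The
genomic inflation factor is the median implied χ²₁ statistic over 0.4549.
BH-FDR uses the standard step-up procedure (statsmodels backend, checked
against an independently coded oracle). Failed fits are excluded from rate
denominators and counted.

## Known limitations

* The support search is a heuristic; with multi-start it matches exhaustive
  enumeration on every tested instance (m ≤ 6), but no global-optimality
  guarantee exists for larger m.
* Exposure and outcome GWAS are assumed independent (no sample overlap).
* The reference-panel LD matrix is treated as the GWAS LD matrix; panel
  noise is not propagated (eigenvalue flooring at 1e-6 plus unit-diagonal
  rescaling guards invertibility only).
* DP inference is conservative under the null; its B = 100 default trades
  p-value resolution for runtime.
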