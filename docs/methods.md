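# Methods

## Model and estimation

pGENMi scores one TF against one phenotype by a two-group mixture over
per-gene TWAS p-values. Writing π_g = σ(w0 + Σ_m w_m r_gm) for the
logistic mediation prior and b(p; α) = α p^(α−1) for the Beta(α, 1)
density, the per-gene likelihood is

    f(p_g) = (1 − π_g) · 1 + π_g · b(p_g; α),

and the observed-data log-likelihood is Σ_g ln f(p_g). The shape α is
restricted to (0, 1] so the mediator arm is always enriched toward small
p-values; α = 1 reduces both arms to the uniform density and makes the
model exactly uninformative (log-likelihood 0 regardless of the weights —
a degeneracy with consequences for testing, below).

Estimation is by EM. The E-step gives responsibilities
γ_g = π_g b / ((1−π_g) + π_g b). The M-step splits: α has the closed form
−Σγ / Σγ ln p (clamped to [1e−6, 1]); the weights solve a logistic
regression with fractional labels γ, fitted by damped Newton–Raphson with
a ridge penalty λ = 1e−6 on w1..wM (never the intercept). The ridge keeps
the optimum finite under complete separation of the binary evidence —
without it the weights diverge whenever, e.g., every gene with evidence
has a small p-value. Convergence is declared when the relative
log-likelihood change drops below 1e−8, with a cap of 1000 iterations.

Two numerical devices deserve mention:

* **Ridge/monotonicity interaction.** Because the weight M-step maximises
  the *penalised* expected complete-data log-likelihood, an iteration that
  shrinks a large weight norm can lower the *unpenalised* observed
  log-likelihood by up to λ·Δ‖w‖²/2 (order 1e−9 in practice). The EM loop
  therefore falls back to the α-only update — a plain EM step, provably
  monotone — whenever the full update would decrease the observed
  log-likelihood. EM traces are monotone to machine-level slack as a
  result, and the test suite asserts this on randomized inputs.

* **Polish steps on flat ridges.** EM converges sublinearly along the
  α → 1 ridge (where the likelihood is nearly flat in all parameters) and
  along weight-separation directions; fits that would otherwise crawl for
  the full 1000 iterations are finished by an L-BFGS-B refinement of the
  penalised observed log-likelihood with analytic gradients, interleaved
  at stall points. The refined point is only adopted when it does not
  decrease the log-likelihood, preserving the monotone trace. This is a
  pure acceleration: it targets the same stationary points the EM fixed
  points are.

### Multistart policy

The likelihood surface is multimodal: besides the global structure, there
are "sparse-mediator" modes with small α, a strongly negative intercept
and large-magnitude evidence weights, which a cold start (α = 0.5, w = 0)
systematically misses — most visibly on *null* data, where missing them
biases the likelihood-ratio statistic toward zero and makes the test
appear anticonservative-proof by accident. The alternative fit therefore
uses four starts and keeps the best optimum: cold; warm (the null
solution with w1..wM = 0, which guarantees LLR ≥ 0 by EM monotonicity);
and two sparse-regime starts (α = 0.1, w0 = −4, w_m = ±1). The null fit
uses cold plus one sparse start. Cross-checks against a nine-start
Nelder–Mead direct maximiser and a 50-random-start EM sweep found no
systematic shortfall of this policy.

## Hypothesis testing

The TF score is LLR = (ℓ_alt − ℓ_null)/ln 2, reported in log2 units. An
approximate p-value refers the deviance 2·ln2·LLR to χ² with df = M, the
number of evidence weights removed under the null. Two caveats are
deliberate and documented rather than hidden:

* Published LLR thresholds for this model family (4.5 and 1.74, both
  described as roughly p ≈ 0.05) are not mutually consistent under any
  single (df, base) convention — χ²-derived thresholds are 4.32 bits at
  df = 2 and 2.77 at df = 1. This package exposes df and the log base
  explicitly instead of reproducing either printed correspondence.

* The χ²_M reference is conservative. Under the null, roughly half of
  fitted replicates land on the α = 1 boundary, where the evidence
  weights are entirely unidentifiable (the likelihood is flat in w), so
  the freed dimensionality is effectively smaller than M. Simulation at
  G = 2000, M = 2 puts the 95th percentile of the deviance near 4.1
  against a χ²₂ critical value of 5.99, and the realised type-I rate at
  nominal 0.05 near 0.02. The test suite checks this calibration over 500
  null replicates.

Genes with missing p-values or missing evidence rows are dropped (logged),
not imputed. p-values are clamped to [1e−12, 1] before density
evaluation because b(p; α) diverges at 0 for α < 1.

## Evidence construction

Coordinates are BED-style 0-based half-open throughout. The cis window of
a gene is the 50-kb region upstream of its TSS, strand-relative, with the
TSS base itself included: [tss−span, tss+1) on '+', [tss, tss+span+1) on
'−', clipped at the chromosome start. Both the span and the
TSS-inclusion flag are configurable.

All association scans are covariate-adjusted partial regressions: the
two-sided t-test of the predictor coefficient in OLS on
[1, predictor, covariates], with n − (k+2) degrees of freedom. TWAS
regresses phenotype on each gene's expression; eQTL scans regress a
gene's expression on each SNP dosage in its window; eQTM scans substitute
CpG beta values for dosages. The genome-wide drivers use Frisch–Waugh
residualisation against the shared covariate block, which is numerically
identical to per-unit OLS (asserted to 1e−8 against both a hand-rolled
residualisation oracle and statsmodels OLS) and orders of magnitude
faster. Monomorphic features and zero-residual-variance fits are skipped
and logged; collinear designs raise errors naming the offending column.

Per (TF, gene, evidence kind), the evidence bit is set from the *most
significant* feature of that kind lying inside one of the TF's
(HOT-filtered) peaks within the gene's window: r = 1 iff that minimum
p ≤ 0.05 (threshold configurable). Taking the per-(gene, TF) best
in-peak feature is the default; an alternative mode first picks the
single best feature per gene across the whole window and then requires
it to fall in a peak — both readings of the best-variant rule are
implemented because the published description is ambiguous between them.
HOT-region filtering removes any peak overlapping a user-supplied
exclusion BED by ≥ 1 bp; the derivation of HOT regions themselves is out
of scope. TFs whose evidence is all-zero in every kind are untestable
(their weights are unidentifiable) and are dropped before fitting, as are
general TFs (POLR2A, POLR3A, POLR3G, TBP) by default.

Population-structure covariates can be approximated by top principal
components of the column-standardised dosage matrix (plain SVD, sign
fixed by making the largest-magnitude loading positive). This is a
deliberate simple stand-in for dedicated stratification tools; covariates
are otherwise accepted as a precomputed numeric matrix and their encoding
is the caller's responsibility.

## Baselines and comparison statistics

Two deliberately simple baselines are provided for contrast. The
TF-expression baseline associates a TF with a drug when the TF's own
expression partially correlates with the phenotype, with
Benjamini–Hochberg FDR across all (TF, drug) pairs (flag to correct per
drug instead). The ChIP-enrichment baseline tests, per (TF, drug), the
hypergeometric overlap of the top-k genes by maximum in-window ChIP peak
score with the top-k genes by TWAS significance (k = 500 by default; BH
per drug). All top-k selections break score ties by gene id so runs are
bit-reproducible.

`compare_sets` reports overlap, Jaccard coefficient and the upper-tail
hypergeometric probability P(X ≥ overlap) for two association sets in an
explicit universe; the universe defaults to (#testable TFs × #drugs) in
pipeline outputs and is always recorded in the metadata.

## Synthetic data

Two generators back the test suite and the acceptance script.

**Model draws** sample the generative model directly: evidence bits
iid Bernoulli(prevalence_m), z_g from the logistic prior, p_g uniform or
Beta(α, 1) via the inverse CDF p = u^(1/α). These support estimator-level
checks: parameter recovery (G = 20000, M = 2, w = [−2, 1.5, 1], α = 0.2
recovers α within ±0.02 and weights within ±0.15), stratum distributions,
and null calibration.

**Population simulation** emits a full cell-panel-style dataset in
exactly the TSV/BED dialects the pipeline reads. Genotypes are
Binomial(2, maf) dosages with maf ~ U(0.1, 0.5); methylation beta values
are logistic transforms of Gaussians (so a planted *linear* association
with expression lives on the logit scale while values respect [0, 1]);
expression carries planted cis effects at one causal SNP and one causal
CpG per gene plus covariate confounding (a binary batch-like factor and a
continuous axis, per-gene coefficients N(0, 0.5)) and N(0, 1) noise; the
phenotype sums the expression of a random set of mediator genes plus
covariate effects and noise. The causal TF receives 400-bp peaks centred
on the causal features of every mediator gene (plus a 15% background of
random features of non-mediator genes); decoy TFs receive peaks over
random features of 25% of genes. A single root seed expands into
independent child streams (geometry / genotype / methylation / expression
noise / phenotype / peaks) so any subset of the data is reproducible on
its own, and identical seeds give byte-identical files.

Default scale and effect sizes were fixed once from power calculations,
not tuned to outcomes: 200 individuals, 2000 genes, 5 SNPs + 3 CpGs per
window, cis effect sizes 0.6 (per-feature t ≈ 5, so planted in-peak
evidence is recovered with sensitivity ≳ 0.99 while null in-peak features
fire at the 0.05 threshold rate), and 40 mediator genes against phenotype
noise sd 3 (per-mediator TWAS t ≈ 2 — a realistic *enrichment* of small
p-values rather than a wall of hits; the implied fitted α is far from
the boundary). At this scale the full pipeline (scans, intersection,
five TF fits) runs in a few seconds per seed on one CPU; the test suite
and acceptance script size their replicate counts (20 end-to-end seeds,
500 null replicates, 10–20 recovery seeds) to stay within minutes.

What the simulation does *not* emulate — and what passing tests therefore
do not demonstrate about real panels: linkage disequilibrium among
variants (each window's features are independent), probe-level expression
noise structure, genotype imputation error, trans effects, coregulated
gene modules (the model's independence assumption over genes is satisfied
by construction here), and real population admixture (only a two-subpopulation
option exists, for exercising the genotype-PCA helper).

## Known limitations

* Evidence is binary per channel; continuous evidence strengths are out
  of scope by design.
* The χ² p-value is approximate and conservative (see above); rankings by
  LLR are the primary output, as in the original analysis.
* The per-(gene, TF) vs global best-variant ambiguity is resolved by a
  flag, default per-(gene, TF).
* `AssociationTable` universes, thresholds and seeds are recorded in
  manifests; reproducibility is bit-level only under identical library
  versions.
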