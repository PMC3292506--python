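# Methods

`gpcombine` is a desk-scale pipeline for studying how much the
reliability of genomic prediction improves when several related dairy
cattle reference populations are pooled into one. It simulates
multi-country bull populations with a controlled genetic architecture,
fits the prediction models used by different evaluation systems on
national and combined references, measures validation reliability the
way progeny-test validations do, and compares the realized improvement
with a deterministic expectation.

## Population and trait model

Each country contributes a cohort of progeny-tested bulls. A bull's
record for a trait is a deregressed proof (DRP): a pseudo-observation of
his true breeding value `u` with reliability

    r² = EDC / (EDC + λ),    λ = (4 − h²) / h²,

where EDC is the effective daughter contribution (simulated log-normal
with a country-specific mean of 85–153 daughters and log-SD 1.0, so a
few bulls have over a thousand daughters). The DRP equals `u` plus
progeny-test noise with variance `σ_g²(1 − r²)/r²`.

The "same" trait in two countries is not genetically identical:
genotype-by-environment interaction and trait-definition differences are
encoded by a between-country genetic correlation matrix `rg`, imposed at
the QTL-effect level (each QTL's per-country effect vector is
multivariate normal with correlation `rg`). Consequently a foreign
bull's proof, viewed on the target country's scale, carries effective
reliability `rg² · r²` — the package's one-parameter emulation of
across-country conversion, and the mechanism that makes combined
reference data less informative per record whenever `rg < 1`. Noise is
drawn independently per evaluating scale.

Genomes are 0/1/2 SNP dosages: founder haplotypes drawn from
population allele frequencies that diverge from a shared ancestral
frequency by a Balding–Nichols model (Fst-like parameter, default 0.02
for closely related populations), descendants formed from a recombined
paternal gamete (Haldane crossovers on a uniform map, default 10
chromosomes × 1 Morgan) and a maternal gamete drawn from the population
frequencies (dams are unobserved throughout). QTL are a random subset of
the markers, so marker data can in principle capture all genetic
variance; true values are rescaled so every country scale has exactly
`σ_g` genetic SD.

What the generator does **not** emulate: realistic cattle LD decay,
maternal pedigree (maternal gametes are linkage-equilibrium draws, which
halves long-range LD relative to a closed pedigree), genotyping error,
imputation, and the across-country evaluation machinery itself (proofs
are simulated directly on each country scale). Passing tests therefore
demonstrate internal consistency of the methods at a realistic
information structure, not predictions about any particular real cattle
population.

## Prediction models

All models work on centered dosages `x = dosage − 2p` with per-record
residual weights `w = r²/(1 − r²)` (a reliability of 1 is rejected;
zero-reliability records are dropped as uninformative) and residual base
variance `σ_e² = σ_g²`, so a record's residual variance is `σ_g²/w`.

* **Weighted SNP-BLUP** — random regression on all markers with equal
  prior variance `σ_a² = f·σ_g²/Σ 2p_j(1−p_j)` (`f` = marker variance
  fraction, default 1). The mixed-model equations are solved by direct
  factorization; at desk scale (≤ a few thousand markers) iterative
  solvers buy nothing and exact solves are easier to test.
* **GBLUP** — the equivalent animal model with
  `G = MM'/Σ 2p_j(1−p_j)`; used as the independent oracle for the
  SNP-BLUP solution (the two DGV vectors must agree to 1e−6 relative)
  and for relationship projection of non-reference bulls.
* **Bayesian mixture** — each marker effect from a two-component normal
  mixture (prior proportion π = 0.95 small-variance, large:small
  variance ratio 100:1, total marker variance a configured fraction of
  `σ_g²`), plus a polygenic term with covariance proportional to the
  sire-only pedigree relationship matrix. Variance components are
  inputs, not sampled; this keeps the polygenic full-conditional
  precision matrix constant so the polygenic vector can be drawn jointly
  each iteration from one precomputed Cholesky factorization. The marker
  sweep is a numba-compiled single-site Gibbs update. Defaults: 500
  iterations, 125 burn-in, thin 1 in the experiment configuration —
  enough for stable posterior-mean DGV at these sizes, verified by the
  chain-doubling test. A preset assigns 40% of genetic variance to
  polygenes and 60% to markers, mirroring evaluation systems built that
  way.

Multi-population (combined) references get one fixed mean per
population. Drift gives each population a nonzero mean true breeding
value; with a single intercept those means leak into the marker effects
and systematically depress combined-reference accuracy. Real
multi-country evaluations absorb such level differences in the scale
conversion; the per-population fixed effect is the desk equivalent. DGV
contain the marker (plus polygenic) part only, never the fixed means.

GEBV blending combines a DGV with a pedigree index by a two-source
selection index; the default source covariance `min(rel_DGV, rel_PI)`
treats the weaker source as fully contained in the stronger one, which
reduces the blend to the better single source in the nested case and is
documented as an approximation isolated in one operation.

## Validation

Bulls born before a per-population cut-off year (latest year that still
leaves ≥ the target fraction, default 25%, in validation; boundary ties
go to validation) with EDC ≥ 20 form the reference. Validation bulls are
post-cut-off domestic bulls whose sire is in the reference (sire scope
national by default; a combined scope reproduces the
enlarged-validation rule used where the national rule leaves too few
bulls). The pedigree index is half the sire's shrunken proof
(`PI = r²·DRP/2`, `rel_PI = r²/4`; dams carry no information).

Reliability of a prediction is the squared weighted correlation with
the validation DRP divided by the weighted mean DRP reliability;
weights are the prediction weights standardized to mean 1. The ratio is
noisy and may exceed 1; it is logged, not clipped. Unbiasedness is the
weighted regression of DRP on the prediction (slope 1, intercept 0 when
unbiased; the intercept is also reported in genetic-SD units). The gain
attributed to genomic information is `REL_GBV − REL_PI`.

Because validation candidates are in practice pre-selected on parent
average, the simulator can select candidates as the top half by PI
among the youngest bulls; directional selection reduces the
GBV–DRP correlation, so selected validation sets underestimate
reliability — the package demonstrates the effect but implements no
correction for it.

## Expected gains

The deterministic engine is `r² = T/(T + M_e)` with
`T = Σ_k N_k · rg_k² · rel_k` summed over source populations and `M_e`
the effective number of independent chromosome segments. It reduces to
the standard single-population accuracy formula at `rg = 1`, is additive
in sources, and exposes exactly the factors that drive the benefit of
combining: reference sizes, proof reliabilities, relatedness. `M_e` is
never hard-coded — it is calibrated per country × trait by inverting the
formula at the realized national reliability, then applied to the
combined source structure (sources enter with their target-scale mean
reliabilities, so the rg discount is already inside `rel_k`).

## The desk-scale experiment

Default configuration: four populations ("DFS", "DEU", "NLD", "FRA") of
500 reference + 125 validation bulls each, 2000 markers, 200 QTL, four
traits spanning the interesting corners of the (h², rg) space — 0.39/0.88
(protein-like), 0.37/0.98 (udder-depth-like), 0.15/0.88 (SCS-like),
0.02/0.70 (fertility-like); two countries fit SNP-BLUP, one the mixture
with 10% polygenic share, one the 40%-polygenic preset. Three replicates
run in roughly six minutes on one CPU; the 16 000-bull scale of a real
consortium is reachable through the same configuration objects but is
not the default. The same validation bulls and PI serve the national and
combined blocks, so the realized gain equals the difference in REL_GBV.

Sampling limits worth knowing: each cell's reliability comes from
~90–125 validation bulls, giving the per-cell realized−expected
difference a sampling SD of ≈0.08 per replicate (≈0.045 over three).
Per-cell agreement tighter than ~0.1 is therefore not resolvable at this
scale; the acceptance checks compare realized and expected gains per
trait (±0.07) and overall (±0.05), where averaging over populations and
replicates brings the noise down accordingly. Two systematic effects
remain visible and are expected: variable-selection models gain slightly
more from added data than the equal-variance accumulation formula
predicts, and polygenic terms add pedigree information the formula does
not model.

## Numerical choices and edge cases

* All randomness flows from one `SeedSequence` per entry point; same
  config + seed ⇒ bit-identical output (MCMC included).
* Monomorphic markers are dropped with a logged count; missing
  genotypes are an error (imputation is out of scope); multiallelic VCF
  records are skipped with a warning.
* A singular reference GRM gets a configurable 1e−6 ridge, logged; the
  SNP-BLUP system cannot be singular (λ_s > 0).
* Report tables round half-even at 2 decimals by default (configurable:
  half-up/half-down), using decimal — not binary-float — semantics.
* Ties at the validation cut-off year all go to validation; ties in PI
  selection are broken by stable sort order.
* Bulls with EDC = 0 have undefined DRP and are excluded with a warning.

## Known limitations

* The across-country conversion is a single-parameter reliability
  discount; it reproduces the information structure, not the full
  machinery, of international evaluations.
* PI uses sire information only; dam and maternal-grandsire paths are
  absent, so PI reliabilities top out at `rel_sire/4`.
* The selection-index blend approximates the published blending
  approach; the QTL-detection/haplotype model used by one partner is out
  of scope (its variance split is available as a mixture preset, clearly
  an approximation).
* Estimated reliabilities are ratios of noisy moments: at n ≈ 100
  validation bulls individual table cells move by ±0.1 between seeds.
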