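# Methods

## Model

`fedglmm` tests single-variant association with a binary trait under a
logistic mixed model. For subject *i*,

    logit P(y_i = 1 | b) = x_i' α + G_i β + b_i,        b ~ N(0, τ V),

with fixed covariate effects α (p-vector, intercept first), a per-variant
genotype effect β, and a polygenic random intercept b whose covariance is the
genetic relationship matrix V scaled by the variance component τ. V is taken
as a *relationship* matrix (self-relatedness ≈ 1 on the diagonal, i.e. twice
the kinship coefficient); any symmetric near-PSD matrix in cohort order is
accepted as-is.

The test is two-stage. The **null model** (β = 0) is fitted once; every
variant is then scored against it, which makes genome-wide testing a cheap
linear pass and keeps genotype data out of the model-fitting stage entirely.

### Null fit: PQL with AI-REML

The Bernoulli likelihood with a correlated random effect has no closed form;
the fit uses penalized quasi-likelihood. At current (α, b), with η = Xα + b
and π = expit(η):

    ν(π) = π(1 − π),  w = ν,  Ỹ = η + (y − π)/ν,  Ψ = Xα,
    Σ = W⁻¹ + τV,  Ω = Σ⁻¹X,  Ξ = X'Ω,  P = Σ⁻¹ − ΩΞ⁻¹Ω'.

Each iteration performs, in order: working update → Σ factorization →
GLS update α̂ = Ξ⁻¹Ω'Ỹ → BLUP update b̂ = τVΣ⁻¹(Ỹ − Ψ) → projection P →
one AI-REML step for τ,

    s = ½(Ỹ'PVPỸ − tr(PV)),   a = ½ Ỹ'PVPVPỸ,   τ ← max(τ + s/a, τ_floor),

ignoring the dependence of W on τ (the standard PQL simplification). The
AI-REML fixed point was verified to coincide with direct numerical
maximization of the restricted likelihood on Gaussian data to ~1e-7.

α is initialized by a plain logistic Newton fit (b = 0, τ = 0), τ by the
sample variance of y, b at zero. Convergence is declared when the
max-absolute change over all monitored parameters (α for the Newton stage;
α, b, τ for the PQL stage) falls below 1e-6 — the stricter of the two
plausible rules (parameter change vs. log-likelihood change); the Bernoulli
log-likelihood trace is recorded for diagnostics. Iteration caps default to
50 (Newton) and 100 (PQL).

### Score test

For a dosage vector g (columns in cohort order, missing values already
imputed to twice the allele frequency):

    T = g'PỸ,   var(T) = g'Pg,   p = SF_χ²₁(T²/var).

Because PX = 0, any component of g in the span of X drops out of both T and
var — monomorphic variants give var = 0 and a missing p-value (reason code
`degenerate variance`, var_floor 1e-10). Variants are filtered at pooled
MAF < 0.01 before scoring.

### The τ = 0, V = I limit

With the variance component pinned at zero and identity relatedness the
entire machinery collapses to ordinary logistic regression: α̂ equals the
IRLS MLE and (T, var) equal the textbook efficient-score test. This limit is
asserted against statsmodels in the test suite and is the main guard against
algebra errors in the projection.

## Federated protocol

Federation is simulated in-process: sites and the central server are objects
exchanging serialized matrices through the secure-aggregation primitives,
with every transfer logged in a JSON-lines transcript. This reproduces the
message flow, the protection structure and the numerics of a networked
deployment; sockets, TLS and deployment infrastructure are out of scope.
Rounds are synchronous; a missing site share aborts the protocol.

**Stage 1 (Newton):** sites compute local gradients X_j'(y_j − π_j) and
Hessians X_j'W_jX_j, which are encrypted and round-robin aggregated; the
server applies the Newton step and broadcasts α.

**Stage 2 (PQL):** per iteration, sites send weight vectors w_j (plaintext,
as the protocol specifies); the server forms Σ⁻¹ and VΣ⁻¹ and returns
vertical partitions (optionally quantized to float32); sites compute
Ω_j = Σ⁻¹_(j)X_j (EADP-aggregated), Ξ_j = X_j'Ω_(j) and Ω_(j)'Ỹ_j
(secure-summed), and BLUP shares b̂_j = τ(VΣ⁻¹)_(j)(Ỹ_j − Ψ_j). The
projection matrix is assembled at the server from rotation-masked products
Ω_jQ and Q⁻¹Ξ⁻¹Ω_j' — the shared invertible Q (entries N(0, variance n),
regenerated if cond > 1e6) cancels in the sum, so the server obtains
ΩΞ⁻¹Ω' without seeing Ω. τ is updated at the server by AI-REML.

**Stage 3 (score):** the server distributes row partitions P_(j) and
(PỸ)_(j) once; per chunk of k variants (default k = 200) sites secure-sum
G_j(PỸ)_(j) into T, EADP-aggregate the G'P column partitions, and
secure-sum (G'P)_(j)G_j' into G'PG, whose diagonal is the score variance.
The mask (OTP-like) backend is the default for this stage.

A config flag `assume_block_diagonal_kinship` enables the shortcut where Σ⁻¹
is assembled from within-site blocks only; it is exact whenever cross-site
relatedness is zero and is tested against the full protocol in that case.

### Secure-aggregation primitives

* **OTP-like masking** (`mask` backend): encryption adds a seeded Gaussian
  pad with sd = 1e6 × the magnitude of the protected matrix class; the pad
  holder regenerates and subtracts it after aggregation. Cancellation is
  exact up to float64 addition error (~1e-10 relative), which is why
  federated results match pooled results to well under 1e-6.
* **Partitioned noise**: each site draws noise supported only on its own
  rows; the summed noise is dense and no single party — including the
  server — can remove another site's share. In EADP the server therefore
  only ever sees the aggregate plus total partitioned noise, and each site
  recovers only its own clean row slice.
* **Mock-HE backend** (`mock-he`): a plaintext stand-in honoring the same
  additive-backend contract (keygen/encrypt/add/decrypt, session tags),
  used to exercise protocol flow exactly; a real lattice-based backend can
  be registered under its own name via `register_backend`.
* **Quantization**: float32 round-trip of large transfers (Σ⁻¹, VΣ⁻¹, G'P),
  relative error ≤ 2⁻²³ per entry. In scoring, quantization is applied to
  the aggregated G'P partitions before the variance step; quantizing the
  mask-protected shares instead would couple the float32 error to the pad
  scale, which is not quantified by the protocol description.

### Privacy surface

The server legitimately receives: aggregated gradients/Hessians, w vectors,
Ỹ, Ξ, noise-protected Ω aggregates, rotation-masked P components, T and
G'PG aggregates, and the full kinship matrix. It never receives raw X_j,
y_j or G_j; `audit_transcript` enforces this structurally on every run, and
the test suite asserts both the audit and the exact noise accounting of the
EADP aggregate. Sending w and Ỹ in plaintext is a documented exposure of
the protocol (mitigable by re-submission and discard after use); collusion
resistance and malicious-adversary protections are out of scope.

## Cohort simulator

Each family is a 4-level, 16-member pedigree (8 founders, 8 descendants: 4
children of founder couples, 2 grandchildren, 2 great-grandchild full
siblings). Founder haplotypes are drawn i.i.d. from per-variant allele
frequencies (default Uniform(0.05, 0.5)) — a frequency model replacing
reference-panel sampling so that fixtures need no downloads. Descendants
inherit one uniformly chosen haplotype allele per parent per locus,
independently across loci (no linkage). The expected relationship matrix
uses the standard numerator-relationship (tabular) recursion and is block
diagonal across families.

Phenotypes follow

    η_i = Σ_c g_ic β_c + gender_i·0.1 + b_i + ε_i,     y_i ~ Bernoulli(expit(η_i)),

with 20 causal variants, β_c ~ N(0, sd 0.5), ε_i ~ N(0, sd 0.5), and an
explicit polygenic term b ~ N(0, τA) with τ = 0.5 by default (drawn through
a jittered Cholesky factor of the block-diagonal A). The explicit b makes
"true τ" well defined for recovery experiments; the gender effect default is
0.1 (an alternative stated level of 0.01 is configurable). Default study
size is 400 families (6,400 subjects) subsampled to 6,000 and split randomly
into 3 sites, so family members may span sites and induce cross-site
kinship.

What the simulator does **not** emulate: linkage disequilibrium, admixture
and population stratification beyond an optional covariate hook, genotyping
error, and realistic allele-frequency spectra. Passing tests therefore
demonstrate correctness of the algorithm and protocol under the modeled
data-generating process, not robustness to real-data artifacts.

## Numerical choices

* π is clipped to [1e-10, 1 − 1e-10] before forming ν, w, Ỹ.
* Σ is inverted by Cholesky; failure raises with the condition number.
* τ is floored at 1e-8; a nonpositive average-information scalar triggers a
  halved previous step with a warning instead of a division.
* The projection is computed with Ξ⁻¹ (solve, not explicit inverse in the
  pooled path): only the inverse satisfies PX = 0 and the GLS normal
  equations.
* The pooled fit computes b̂ via matrix-vector products τ·V(Σ⁻¹r) rather
  than materializing VΣ⁻¹ each iteration; the federated path materializes
  the partitions because they are protocol messages.
* All randomness (simulator, masks, rotation, session tags) flows from
  explicit seeds, so a (config, seed) pair reproduces results bit-for-bit.

## Cost estimator

Transfer sizes are rows × cols × bytes / 2²⁰ MiB with 8-byte elements (4
when quantized), per-site dimensions using the fractional n_j = n/J, and a
configurable homomorphic ciphertext-expansion factor (default 13.5, midpoint
of an observed 12–15× range). p counts the intercept plus covariates. The
two Newton-stage vector/matrix rows are reported at 8 bytes like everything
else, even though some published summaries of those two cells are consistent
with 4-byte elements.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run desk-scale versions of the
study conditions, chosen as the smallest sizes at which each property is
meaningful: protocol equivalence and transcript audits on 400-subject,
100-variant, 3-site cohorts; quantization fidelity and calibration on
~2,000-subject cohorts (≥5,000 null variants for uniformity; 10 seeds for
τ recovery at simulator defaults); cost arithmetic at the full n = 32,000
deployment parameters, which is pure arithmetic. The τ-recovery band
[0.35, 0.65] reflects PQL's known attenuation for binary traits: on a pure
polygenic design (no causal variants, no environmental noise) the same
engine recovers only ~0.17 of a true τ = 0.5 because the diagonal-dominant
part of a pedigree relationship matrix is weakly identifiable from Bernoulli
observations — a property of the estimator verified against lme4's Laplace
fit on an exchangeable design, not a defect of the implementation.

## Known limitations

Single variance component and random intercepts only (no random slopes); β
is never estimated (score test only); no meta-analysis mode; no real
network transport or malicious-adversary protections; PQL's variance
component is attenuated for binary traits, though p-value calibration is
unaffected (asserted by the uniformity test).
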