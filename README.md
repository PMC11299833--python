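# fedglmm

Federated logistic mixed-model association testing for binary GWAS traits.

Multi-site genetic association studies face two coupled problems: related
individuals (families, cryptic kinship) confound naive per-variant tests, and
privacy regulation prevents pooling genotypes across institutions. `fedglmm`
addresses both at once. It implements the GMMAT-style two-stage score test for
binary traits under a logistic mixed model,

```
logit P(y_i = 1 | b) = x_i' α + b_i,        b ~ N(0, τ V),
```

where `V` is the n × n genetic relationship (kinship) matrix, and runs it
either **pooled** (all data in one place — the reference engine) or
**federated**: J sites hold their own phenotypes, covariates and genotypes,
and only protected intermediate matrices are exchanged through a simulated
central server.

Stage one fits the null model (α, τ, b) by penalized quasi-likelihood with an
average-information REML update for the variance component τ. Stage two scores
every variant g against the fitted null:

```
T = g' P Ỹ,     var(T) = g' P g,     T² / var ~ χ²₁,
```

with `P = Σ⁻¹ − Ω Ξ⁻¹ Ω'`, `Σ = W⁻¹ + τV`, `Ω = Σ⁻¹X`, `Ξ = X'Ω`, and
`Ỹ` the PQL working response. The federated protocol reproduces exactly these
quantities through secure aggregation — OTP-like additive masking, per-site
partitioned noise, round-robin summation, an encrypt–aggregate–decrypt–
partition (EADP) primitive, and rotation masking for `P` — so federated and
pooled analyses agree to floating-point cancellation error, not approximately.

The package also ships a pedigree-based cohort simulator (founder haplotypes,
Mendelian gene dropping, expected relationship matrices, logit-link binary
phenotypes) and an estimator of the protocol's per-message network traffic.

## Worked example

```sh
fedglmm simulate --out study --families 25 --snps 100 --sites 3 \
    --subsample-to 400 --seed 11
fedglmm score --study study --out pooled.tsv
fedglmm score --study study --federated --backend mask --seed 1 \
    --out federated.tsv --transcript transcript.jsonl
```

The two results tables carry one row per variant (`SNP, ..., AF, SCORE, VAR,
PVAL`) and agree to six decimals; `transcript.jsonl` logs every inter-party
transfer with its protection flag. The same analysis from Python:

```python
import numpy as np
from fedglmm import SimConfig, assemble_study, fit_null_pooled, score_test_chunk
from fedglmm import make_server, fit_null_federated, algorithm3_fed_score

study = assemble_study(SimConfig(n_families=25, n_snps=100, subsample_to=None, seed=11))
pooled = fit_null_pooled(study.pooled)
server = make_server(study.pooled.V, backend="mask", seed=1)
fed = fit_null_federated(study.sites, server)
print(np.max(np.abs(fed.alpha - pooled.alpha)), abs(fed.tau - pooled.tau))
```

prints differences on the order of `1e-9` / `1e-10` — the mask-cancellation
residue of float64 arithmetic, far below any statistical tolerance.

Per-client network traffic for a large deployment (n = 32,000, 12 covariates,
3 sites, 1M variants, 200-variant chunks):

```sh
fedglmm costs --n 32000 --p 12 --sites 3
```

lists, e.g., 2604.1667 MiB per iteration for each site's `Σ⁻¹` partition and
48.8281 MiB per chunk for the masked `G'P` matrix, with a column scaling each
row by the ciphertext-expansion factor of a homomorphic backend.

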