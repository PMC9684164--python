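# zknock

Knockoff-based conditional inference for GWAS summary statistics, with
meta-analysis of studies that may share samples.

## The problem

Conventional GWAS tests each variant marginally and controls the
family-wise error rate with a Bonferroni threshold. That is conservative
and, because of linkage disequilibrium (LD), it flags proxy variants
that merely travel with the causal ones. Knockoff inference replaces the
marginal test with a conditional one — is variant *j* associated with
the trait *given all other variants in the region?* — and controls the
false discovery rate (FDR) instead, which buys power for the many
small-effect loci that sit below genome-wide significance.

Classical model-X knockoffs need individual-level genotypes to build the
synthetic negative-control copies. This package instead generates
**knockoff copies of the Z-scores directly**: for the score-test
statistic `Z = GᵀY/√n`, a knockoff copy that is exchangeable with the
original in second moments can be sampled as

    Z̃ = P Z + E,   E ~ N(0, V)

where `P = I − DΣ⁻¹` (stacked M times for M copies),
`C = 2D − DΣ⁻¹D`, V has C on its diagonal blocks and C − D off it, and
Σ is the LD matrix estimated from a reference panel. The diagonal
decoupling matrix `D = diag(s)` solves

    minimize Σⱼ |1 − sⱼ|   s.t.   ((M+1)/M)·Σ − D ⪰ 0,   s ≥ 0.

Only summary statistics and a reference panel are needed; the sampled
knockoff Z-scores are equivalent in distribution to computing score
statistics on individual-level second-order knockoff genotypes.

Selection uses the multiple-knockoff filter: per variant, the importance
score is the squared Z; κ indexes which of the M+1 scores wins (0 = the
original), τ is the winner's margin over the median of the rest, and
`W = τ·1{κ=0}`. Variants are selected when τ clears the data-dependent
threshold

    min{ t>0 : (1/M + #{κ≥1, τ≥t}/M) / #{κ=0, τ≥t} ≤ q }

which provably controls the FDR at q. A per-variant q-value reports the
smallest target at which each variant would be selected.

For meta-analysis of K studies with arbitrary sample overlap, the
package estimates a K×K study-correlation matrix from decorrelated null
Z-scores (`DΣ⁻¹Z`, using variants with |Z| ≤ 1.96), derives either
sample-size weights `wₖ = √(nₖ/N)` or power-optimal nonnegative weights
(a quadratic program in cor.S), and inflates the knockoff noise by the
dependency factor

    γ = √(1 + N/N_eff − N_eff/N)  ≥ 1,

so the meta-analysis mimics knockoff generation on the pooled unique
samples. Independent studies give γ = 1; two identical studies give
N_eff = N/2 and γ ≈ 1.58.

## Worked example

`examples/filter_basics.py` runs the filter on five variants with one
knockoff copy each:

```
kappa (0 = original wins): [0 0 0 1 0]
tau   (winning margin)   : [5. 4. 3. 2. 1.]
W     (selection evidence): [5. 4. 3. 0. 1.]

threshold at target FDR 0.35: 3.0
q-values: [0.333 0.333 0.333 1.    0.5  ]
selected variant indices: [0 1 2]
```

The three variants whose original score beats the knockoff by the
largest margins are selected (their estimated FDR, 1/3, is below the
0.35 target); the variant whose knockoff won gets q = 1 and can never
be selected.

`examples/meta_overlap.py` meta-analyzes two simulated studies of 1500
samples each that share half of their members:

```
estimated study correlation : 0.332  (true overlap 0.50)
effective sample size       : 2253 of N = 3000
dependency factor gamma     : 1.257  (1 = independent)

selected 8 variants at FDR 0.1; 8 of 8 causal found
```

γ > 1 inflates the knockoff noise to compensate for the duplicated
samples; without it the knockoffs would be too quiet and the FDR would
be inflated. `examples/single_study.py` and
`examples/power_fdr_simulation.py` show the cached-model pipeline and
the replicate-level power/FDR harness.

## Command line

A thin CLI wraps the same library calls:

```
zknock model    --panel ref.vcf.gz --out cache.npz --seed 1
zknock run      --sumstats study.tsv --model cache.npz --fdr 0.1 --out out/ --seed 1
zknock meta     --sumstats s1.tsv --n 40000 --sumstats s2.tsv --n 65000 \
                --model cache.npz --weights optimal --fdr 0.1 --out out/ --seed 1
zknock corr     --sumstats s1.tsv --n 40000 --sumstats s2.tsv --n 65000 \
                --model cache.npz --out corr.json --seed 1
zknock simulate --out sim.tsv --seed 1
```

`run`/`meta` write a per-variant results table (CHR, POS, REF, ALT, Z,
W, KAPPA, TAU, QVALUE, SELECTED), a JSON manifest recording seeds,
weights, cor.S and γ, and a map from pruned variants to their LD-cluster
representatives. Reruns with the same inputs and seed are
bitwise-identical.

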