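# Methods

This note documents the statistical model implemented by `zknock`, the
defaults and numerical choices, what the synthetic-data generator does
and does not emulate, and known limitations.

## Knockoff Z-scores from summary statistics

For a standardized phenotype Y and standardized genotype matrix G over
n independent samples, the score-test vector is `Z = GᵀY/√n`. Under the
null its distribution is N(0, Σ) with Σ the variant correlation (LD)
matrix. A second-order knockoff copy of Z — exchangeable with Z in
first and second moments, conditionally independent of Y — can be drawn
without individual data:

    Z̃ = P Z + E,   E ~ N(0, V),
    P = stack_M(I − DΣ⁻¹),   V = blocks(C on diag, C − D off),
    C = 2D − DΣ⁻¹D,   D = diag(s).

`s` solves the convex program `min Σ|1 − sⱼ|` subject to
`((M+1)/M)Σ − D ⪰ 0`, `s ≥ 0`. Larger s decouples knockoffs more
strongly from the originals and raises power; the semidefinite
constraint caps how much decoupling the LD permits.

Two solvers are provided:

- **equi** (default): the equicorrelated closed form
  `sⱼ = min(1, ((M+1)/M)·λ_min(Σ))`. O(p³) for one eigendecomposition,
  scalable, and exact for equicorrelated blocks.
- **sdp**: maximizes Σsⱼ under the same constraint via sequential
  quadratic programming on the smallest-eigenvalue constraint (gradient
  −vⱼ² from the bottom eigenvector). Sharper per-variant s on
  heterogeneous blocks, slower; intended for small-to-moderate p.

Both enforce feasibility to 1e−8. Each is validated against the other
on equicorrelated inputs where they provably coincide.

## Filter

Importance scores are squared Z-scores, `T = Z²` and `T̃ᵐ = (Z̃ᵐ)²`.
Per variant, κ is the argmax over the M+1 scores (0 = original), τ is
the winner minus the median of the remaining M ordered scores, and
`W = τ·1{κ=0}`. The selection threshold at target q is

    τ̂ = min{ t>0 : (1/M + #{κ≥1, τ≥t}/M) / #{κ=0, τ≥t} ≤ q },

scanned over the observed positive τ values only (the estimate is
piecewise constant between them, so this scan is exact). Selection is
the inclusive set {κ=0, τ ≥ τ̂}, which coincides with {q-value ≤ q}; the
q-value is the running minimum of the estimated FDP over thresholds up
to the variant's own τ, capped at 1, and fixed to 1 whenever κ ≠ 0.
Both quantities are tested for exact agreement with a brute-force scan
over every candidate threshold.

Numerical choices:

- **Ties in κ** (possible on quantized scores) are broken uniformly at
  random with an explicit seed. A deterministic tie-to-original rule
  would bias the FDP upward under the null.
- **Median of an even count** uses the midpoint convention.
- The **threshold is global**: statistics from all genomic blocks are
  pooled before the filter runs. Per-block thresholding would break the
  FDR guarantee.

## Meta-analysis with sample overlap

The meta Z-score is `Z_meta = Σₖ wₖ Cₖ Zₖ` with Cₖ a 0/1 diagonal
observation mask (an unobserved variant contributes 0 to both the meta
Z and its knockoff; no rescaling is applied because the filter is
scale-free). Knockoff copies are
`Z̃_meta = Σₖ wₖ Cₖ (P Zₖ + γ Eₖ)` with Eₖ ~ N(0, V) fresh per study.

The study correlation cor.S is the pairwise correlation of the
decorrelated vectors `DΣ⁻¹Zₖ` over variants observed in both studies
of a pair with |Z| ≤ 1.96 in **both** (the conservative reading; the
cap removes polygenic signal so the residual correlation reflects
shared samples). The estimate is PSD-repaired before use. It is mildly
attenuated by the truncation at ±1.96, which makes γ slightly
conservative in the opposite direction of the raw overlap; empirically
the FDR remains controlled at all tested overlaps.

Weights are either `wₖ = √(nₖ/N)` (size scheme, default) or the
solution of `min wᵀ·cor.S·w` s.t. `Σ wₖ√nₖ = 1, w ≥ 0` (optimal
scheme, solved by SLSQP with a KKT residual check; a 1e−8 ridge is
added when cor.S is singular so duplicated studies deterministically
get the minimum-norm symmetric optimum). For case-control studies nₖ
may be replaced by the effective count `4/(1/n_case + 1/n_control)`.

The dependency factor is `γ = √(1 + N/N_eff − N_eff/N)` with
`N_eff/N = N/Σᵢⱼ√(nᵢnⱼ)cor.Sᵢⱼ` under size weights and
`Σwₖ²/(wᵀ·cor.S·w)` under optimal weights (the latter is the printed
approximation; the exact form for non-size weights is not closed-form).
N_eff estimates above N — possible through noise in cor.S — are clipped
to N, so γ ≥ 1 always. Heterogeneous-LD groups (e.g. ancestries) get
per-group P, V and γ, combined with √(n_l/N) weights; optimal weighting
*across* groups is deliberately not invented.

## Preprocessing

- **p-to-Z**: `Z = direction·|Φ⁻¹(p/2)|`. (The naive signed quantile
  `sign·Φ⁻¹(p/2)` negates the statistic since Φ⁻¹(p/2) < 0 for p < 1;
  the magnitude-times-sign form is the evident intent of that
  transformation.) p = 0 is rejected with a pointer to the 1e−300
  floor; p = 1 maps to 0.
- **LD estimation**: per-block sample correlation of standardized
  dosages, shrunk toward the identity with default intensity 0.1
  (external panels are small; shrinkage keeps the blocks invertible),
  then eigenvalue-clipped to the PSD cone at 1e−10 and rescaled to unit
  diagonal. Missing panel genotypes are mean-imputed before
  correlation.
- **Pruning**: complete-linkage hierarchical clustering on 1 − |r| cut
  at 1 − 0.75. Complete linkage is the one standard linkage whose cut
  guarantees the within-cluster pairwise |r| ≥ 0.75 property. One
  representative per cluster is drawn uniformly at random (seeded) so
  the analyzed set is positionally unbiased; members map to their
  representative in a companion table.
- **Blocks**: contiguous, ≤ 1000 variants and ≤ 1 Mb by default, never
  splitting a cluster; inter-block LD is not modelled, so long-range
  confounding is outside the model (see Limitations).
- **Allele harmonization**: match on (CHR, POS, REF, ALT); swapped
  alleles flip the Z sign; strand-ambiguous A/T and C/G variants are
  dropped with a warning.

## Synthetic cohorts

The generator emulates the structure of a sequencing-cohort region
without any restricted data:

- **Genotypes**: two independent latent-Gaussian haplotypes per sample
  with block-AR(1) correlation (ρ = 0.5 within 20-variant blocks),
  dichotomised at the per-variant MAF quantile (MAF ~ U(0.05, 0.45))
  and summed to 0/1/2 dosages. Dichotomisation attenuates the latent
  correlation; the attenuation is *realized, not assumed* — the
  knockoff model is always built from the realized genotype
  correlations, exactly as a real analysis builds it from a panel.
- **Phenotypes**: 10 causal variants with effects
  `βⱼ = a/√(2mⱼ(1−mⱼ))`, a set so the causal variance equals 1.
  Quantitative: `Y = X₁ + Σβⱼ·Gⱼ + ε`, `X₁ ~ N(0,1)` observed,
  `ε ~ N(0,3)` unobserved. Dichotomous: logistic with linear predictor
  `β₀ + X₁ + X₂ + Σβⱼ·Gⱼ`, X₂ unobserved, β₀ calibrated by bisection to
  a 10% marginal prevalence (Monte-Carlo tolerance 0.002 on the
  realized predictor). Only X₁ is adjusted in the analysis, so the
  generator deliberately includes model misspecification.
- **Two-study design**: a pool of 2·n_study samples; each study draws
  n_study members with round(overlap·n_study) shared. One phenotype per
  unique individual, so overlap induces genuine Z correlation.
- **Desk-scale profile**: n_study = 1000, p = 300 variants before the
  MAC > 25 filter and |r| ≥ 0.75 pruning, 100 replicates. These sizes
  keep a full multi-scenario validation on one CPU in minutes while
  preserving the per-replicate signal-to-noise of the full-scale design
  (2500 samples/study, 2000 variants, 1000 replicates), which remains
  one config change away.

What passing these experiments shows: FDR control and nonzero power of
the end-to-end pipeline under block LD, realistic MAFs, unobserved
covariates and sample overlap of 0–50%. What it does not show: behavior
under long-range LD (inter-block correlation is absent by
construction), fine ancestry structure, genotyping error, or LD
mismatch between panel and cohort — the last being the method's main
practical failure mode, mitigated in practice by matched panels and the
MAF > 1% restriction.

## Determinism

Every stochastic call takes a seed. Pipelines derive per-block seeds
from the run seed through a seed sequence keyed by block index, so
block order cannot change results, and a rerun with identical inputs
and seed is bitwise-identical. The model cache round-trips bit-exactly.

## Known limitations

- Inter-block LD is not modelled; the filter cannot attenuate
  long-range confounding.
- The SDP solver targets block sizes of a few hundred variants; very
  large blocks should use the equi solver.
- cor.S from few variants is noisy; the estimator refuses pairs with
  fewer than 100 shared null variants by default.
- Power is lost when the causal variant is a pruned cluster member
  rather than the representative; group-level exchangeability (group
  knockoffs) would address this and is out of scope here.
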