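# spatialsfs

Site frequency spectra of rare deleterious variants under
geographically concentrated sampling.

When a genetic study samples individuals from a limited geographic
region ("narrow" sampling) rather than uniformly across a population's
range ("broad" sampling), the number and frequencies of the rare,
negatively selected variants it discovers change systematically.
`spatialsfs` implements an analytic model of this effect, an in-model
spatial simulator that validates it, and a weighted cohort-resampling
pipeline for in-silico sampling-design experiments — aimed at
population and statistical geneticists thinking about biobank-scale
study design, rare-variant association power, and SFS-based inference
of fitness effects.

## The model

Carriers of a deleterious allele live on an `L x L` torus: new mutations
arise by a Poisson process with rate `ρ·μ` per unit area per generation
(`ρ` population density, `μ` per-site mutation rate), disperse by
isotropic diffusion with RMS displacement `σ` per generation, reproduce
at rate `1 − s` and die at rate `1` (`s` > 0 the heterozygous fitness
cost). A sample of `n` haploid genomes is drawn through a Gaussian
spatial kernel of width `w` (per-axis SD), or uniformly.

Carriers of one allele spread over a characteristic length
`ℓ_c = σ / (2·√s)` before the allele's extinction. At stationarity the
kernel-weighted population frequency of an allele is approximately
Gamma-distributed with shape `θ_E` (effective mutation supply) and rate
`γ_E` (effective selection intensity); Poisson sampling then makes the
sample allele count Negative Binomial,

    K ~ NegBin(θ_E, γ_E / (γ_E + n)),

whose entries are the expected sample SFS. For concentrated sampling
(`w ≪ L`):

    θ_E = μ · ρ · ℓ_c² · λ,      γ_E = s · ρ · ℓ_c² · λ,
    λ(x) = 4π / (eˣ · E1(x)),    x = (w / ℓ_c)²,

with `E1` the exponential integral; under uniform sampling they reduce
to the panmictic `N·μ` and `N·s` (`N = ρ·L²`). `ρ·ℓ_c²·λ` acts as the
population size effectively being sampled. Because `θ_E/γ_E = μ/s`
identically, broader sampling **discovers** more variants (`θ_E` grows)
while **diluting** each one to lower sample frequency (`γ_E` grows), and
the expected allele frequency across all sites stays exactly `μ/s`
regardless of design.

## Worked example

```python
from spatialsfs import PopulationParams, SamplingKernel
from spatialsfs.theory import effective_params, expected_summary_stats

pop = PopulationParams(sigma=10.0, rho=20.0, mu=1e-9, s=0.01, L=1000.0)
for kern, name in [(SamplingKernel.gaussian(width=30.0, center=(500, 500)), "gaussian w=30"),
                   (SamplingKernel.uniform(), "uniform")]:
    eff = effective_params(pop, kern)
    st = expected_summary_stats(eff, pop, n=10_000, M=50_000)
    print(f"{name}: ell_c={eff.ell_c:.1f}  lambda={eff.lam:.2f}  "
          f"theta_E={eff.theta_E:.3e}  gamma_E={eff.gamma_E:.3e}")
    print(f"   p_variant={st.p_variant:.3e}  p_singleton={st.p_singleton:.3e}  "
          f"mean_freq_variant={st.mean_freq_variant:.3e}  mean_freq_all={st.mean_freq_all:.1e}")
```

prints

```
gaussian w=30: ell_c=50.0  lambda=11.32  theta_E=5.660e-04  gamma_E=5.660e+03
   p_variant=5.759e-04  p_singleton=3.612e-04  mean_freq_variant=1.737e-04  mean_freq_all=1.0e-07
uniform: ell_c=50.0  lambda=400.00  theta_E=2.000e-02  gamma_E=2.000e+05
   p_variant=9.753e-04  p_singleton=9.515e-04  mean_freq_variant=1.025e-04  mean_freq_all=1.0e-07
```

Reading this: at dispersal `σ=10` and cost `s=0.01` an allele's carriers
spread over `ℓ_c=50` length units. A `w=30` kernel effectively samples
`ρ·ℓ_c²·λ ≈ 5.7×10⁵` of the `N = 2×10⁷` individuals, so it finds ~40%
fewer variant sites per locus than the uniform design
(`p_variant` 5.8×10⁻⁴ vs 9.8×10⁻⁴, discovery) but sees each variant at
~70% higher mean frequency (1.7×10⁻⁴ vs 1.0×10⁻⁴, dilution reversed:
narrow samples concentrate variants). The all-sites mean frequency is
`μ/s = 10⁻⁷` in both designs — the two effects cancel exactly.

## What's in the package

| module | contents |
| --- | --- |
| `spatialsfs.theory` | `ℓ_c`, `λ`, effective parameters, NegBin SFS, expected summary statistics, Gamma allele-frequency density |
| `spatialsfs.kernels` | torus geometry, wrapped-Gaussian sampling densities, exact Brownian dispersal steps |
| `spatialsfs.simulate` | Gillespie branching-process simulator (coupled habitat and per-family ensemble modes), kernel-weighted frequencies, method-of-moments estimators of `(θ_E, γ_E)` with bootstrap SEs, simulated sample spectra |
| `spatialsfs.sfs` | `SampleSFS` histograms, observed summary statistics, per-`k` spectrum ratios with crossover detection |
| `spatialsfs.cohort` | synthetic cohorts (clustered carriers from the branching model + uniform non-carriers, severity classes by `s`), sampling-density estimation, SIR resampling at chosen breadths, multi-design reports |
| `spatialsfs.experiments` | the canned validation studies used by the tests and the reproduction script |

A `spatialsfs` command-line tool wraps the library
(`theory sfs/stats`, `simulate run/sfs`, `stats`,
`cohort generate/resample`); every output TSV carries a `#` provenance
header with the full parameter set that produced it. Cohort genotype
matrices can be written/read as haploid VCF or 0/1 TSV.

See `docs/methods.md` for the model's assumptions, the estimators'
finite-size corrections, and the design of the synthetic-cohort study.

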