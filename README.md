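# imtracer

Time-dependent isolation–migration inference from pairwise coalescence
rates.

Genome pairs sampled within and across two populations carry, in their
local density of heterozygous sites, the distribution of their pairwise
coalescence times.  PSMC/MSMC-family methods estimate that distribution
as a piecewise-constant coalescence rate λ(t); the *relative
cross-coalescence rate* 2λ₁₂/(λ₁₁+λ₂₂) is then a popular but heuristic
0→1 profile of population separation.  `imtracer` goes one step further
and re-expresses the three rate functions {λ₁₁, λ₁₂, λ₂₂} as an explicit
two-island isolation–migration (IM) model with time-dependent population
sizes N₁(t), N₂(t) and a time-dependent symmetric migration rate m(t),
so that separations, post-split gene flow and archaic admixture appear
as interpretable pulses of migration.

For a pair of lineages the IM model is a four-state Markov chain over
(S₁₁, S₁₂, S₂₂, C) — both lineages in island 1, one in each, both in
island 2, coalesced — with rates 2m, m, 1/(2N₁), 1/(2N₂) as laid out in
`imtracer.im_model`.  The fit minimizes a regularized chi-square between
the per-time-segment coalescence probabilities of this chain and those
implied by the measured rates, for all three start states:

    χ² = Σᵢ [ Σ_s₀ (P_IM(i|s₀) − P_rates(i|s₀))² / P_rates(i|s₀)
              + β₁ m_i Δt_i + β₂ ((N₁ᵢ−N₂ᵢ)/(N₁ᵢ+N₂ᵢ))² ]

The headline summary is the cumulative migration probability

    M(t) = 1 − exp(−2 ∫₀ᵗ m dt′)

the probability that a cross-population pair has mixed by time t;
1 − M(t*) estimates the fraction of ancestry from lineages diverged
deeper than t*.

The package is self-contained for simulation studies: it ships an exact
structured-coalescent rate engine (noise-free λ's for arbitrary
multi-deme demographies), an msprime-based sequence simulator writing
multihetsep files, and a pairwise SMC' hidden-Markov rate estimator with
EM, so the whole pipeline — simulate → estimate rates → combine → fit →
summarize — runs end to end without external data.

## Worked example

Fit the IM model to noise-free rates of a clean population split at
75 kya (two demes of diploid size 20,000; generation time 29 y):

```python
import numpy as np
from imtracer import make_time_grid, fit_im, FitConfig
from imtracer.scenarios import clean_split, exact_coal_rates
from imtracer.summaries import m_percentiles, detect_pulses

grid = make_time_grid(n_ref=10_000)           # 28 segments, ~18 kya–2 Myr
rates = exact_coal_rates(clean_split(75.0), grid)
result = fit_im(rates, FitConfig(), grid=grid)

median = m_percentiles(result, [0.5])[0] * 29 / 1000
print(f"M(t)=0.5 crossing: {median:.1f} kya")
for p in detect_pulses(result):
    print(f"pulse {p.t_start*29/1000:.0f}-{p.t_end*29/1000:.0f} kya, "
          f"delta-M {p.delta_M:.3f}")
```

prints

```
M(t)=0.5 crossing: 77.7 kya
pulse 37-99 kya, delta-M 0.997
```

— a single migration pulse around the simulated split, with the M(t)
midpoint one grid segment from the true 75 kya.  The same machinery run
on the split-with-migration scenario (per-direction migration total 0.5
at 10–15 kya) places the inter-pulse plateau of M(t) at 0.63–0.66,
matching the analytic mixed-pair probability 1 − e⁻¹ ≈ 0.63.

The command-line interface mirrors the library:

```
imtracer simulate split_with_migration --seed 1 -o sims/
imtracer estimate-rates -I 0,1,2,3 --pattern 1*2+25*1+1*2+1*3 \
    sims/*.multihetsep.txt -o pop1.final.txt
imtracer combine pop1.final.txt cross.final.txt pop2.final.txt -o comb.txt
imtracer fit comb.txt --mu 1.25e-8 --beta1 1e-8 --beta2 1e-6 -o fit.tsv
imtracer summarize fit.tsv --deep-at 300000,600000,1000000
```

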