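# plastimod

Forward-time population-genetic simulation of **phenotypic-plasticity
evolution in patchy habitats**: a haploid, two-locus, two-allele, two-deme
Wright–Fisher model in which a plasticity-modifier locus (alleles *m*/*M*)
buffers selection on a target (structural) locus (alleles *a*/*d*) that is
under opposing directional selection in an ancestral (favorable) and a
derived (adverse) deme.

The package is for population geneticists and theoreticians who want to
study how **population structure with limited migration turns a costly
plasticity modifier into a balanced polymorphism**, and how that standing
variation fuels rapid evolution when the environment flips. It provides:

- a vectorized stochastic engine (migration → selection → recombination →
  multinomial reproduction each generation; single-mutant introductions;
  absorption or a 100 *N*-generation cap),
- a deterministic infinite-population companion with the closed-form
  equilibria `x1* = (1 − tan(θ/2))/2`, `x2* = 1 − x1*`,
  `θ = tan⁻¹(sp / μ)` and numerical stability analysis,
- the cumulative-heterozygosity statistic
  `H_L = 2 Σ_t Σ_i x_{Mi,t}(1 − x_{Mi,t}) N_i/N` (neutral expectation ≈ 2)
  with exact Markov-chain and closed-form neutral oracles,
- ensemble/sweep drivers and the environmental-switch protocol, and
- a CLI (`plastimod`) with TSV output and fully reproducible seeding.

Fitness scheme per deme *i* (haplotype order `am, aM, dm, dM`):

    w_am = 1 + s_i        w_aM = 1 + s_i(1 − p_ai)
    w_dm = 1 − s_i        w_dM = 1 − s_i(1 − p_di)

With the symmetric parameterization (`s1 = s = −s2`, all `p_hi = p`) the
modifier's implied environment-specific benefit is exactly twice its
environment-independent cost (`b/c = 2`), so neither force alone fixes or
purges it — migration–selection balance does the rest.

## Worked example

Balanced polymorphism versus drift, at desk scale:

```python
import numpy as np
from plastimod import ModelParams, run_ensemble, equilibrium_for_params

# symmetric opposing selection, limited continuous migration
params = ModelParams.symmetric(N=200, s=0.03, p=1.0, e=4, r=0.5,
                               intro_prob=0.001)
bal = run_ensemble(params, 5000, np.random.default_rng(43))
print(f"balanced:  mean H_L = {bal.mean_HL:.1f} ± {bal.se_HL:.1f}")

neutral = ModelParams.symmetric(N=100, s=0.0, p=0.0, e=1, intro_prob=0.0)
drift = run_ensemble(neutral, 20000, np.random.default_rng(1),
                     first_mutant_locus="modifier")
print(f"neutral:   mean H_L = {drift.mean_HL:.2f} ± {drift.se_HL:.2f}")

eq = equilibrium_for_params(params)
print(f"deterministic equilibrium: x1* = {eq.x1_star:.3f}, x2* = {eq.x2_star:.3f}")
```

prints

```
balanced:  mean H_L = 25.4 ± 3.1
neutral:   mean H_L = 2.12 ± 0.13
deterministic equilibrium: x1* = 0.333, x2* = 0.667
```

The neutral ensemble recovers the drift expectation
`2(1 − 1/N) = 1.99` within its bootstrap error; the balanced regime sits an
order of magnitude above it because the modifier is held at the interior
equilibrium (≈ 0.33 in the adapted deme, ≈ 0.67 in the maladapted one) for
thousands of generations before drift finally breaks the balance.

The same experiments from the shell:

```bash
plastimod ensemble --n 200 --s 0.03 --p 1 --e 4 --intro-prob 0.001 \
    --replicates 5000 --seed 43 --out balanced.tsv
plastimod equilibrium --s 0.03 --p 1 --e 4 --n 200
plastimod switch --n 500 --s 0.02 --p 1 --e 5 --intro-prob 0 \
    --replicates 3000 --seed 7 --first-mutant-locus modifier --out switch.tsv
```

The `switch` command runs the rapid-evolution protocol: 40 *N* generations
of burn-in, conditioning on a still-segregating modifier, 200 observed
generations, a sign flip of selection in both demes, and 800 more observed
generations — the conditioned deme means swap to the opposite deme's
former equilibrium within a few hundred generations.

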