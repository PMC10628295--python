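# Methods

## The model

`plastimod` simulates a haploid, two-locus, two-allele, two-deme
Wright–Fisher metapopulation. A **target (structural) locus** carries
alleles *a* (ancestral) and *d* (derived) and is under directional
selection of opposite sign in the two demes: deme 1 is the ancestral,
favorable habitat (coefficient `s1`), deme 2 the derived, adverse habitat
(`s2`; the symmetric preset sets `s1 = s = -s2`). A **plasticity-modifier
locus** carries alleles *m* (non-plastic) and *M* (plastic); the *M* allele
discounts the selective effect of whichever target allele it is paired with
by the factor `(1 - p_hi)`, where `p_hi` is the net benefit-minus-cost of
plasticity for target allele *h* in deme *i*. The fitnesses of the four
haplotypes in deme *i* are

    w_am = 1 + s_i            w_aM = 1 + s_i (1 - p_ai)
    w_dm = 1 - s_i            w_dM = 1 - s_i (1 - p_di)

so with `p = 1` plasticity fully buffers selection on the target. In the
symmetric case the implied environment-specific benefit *b* of plasticity
on maladapted backgrounds is exactly twice the environment-independent cost
*c*: `c = w_am1 - w_aM1 = sp`, `b = (w_dM1 - w_dm1) + c = 2sp`, so
`b/c = 2` for any `s, p > 0`. This makes the modifier deleterious where the
resident background is adapted and beneficial where it is maladapted —
the engine of spatial balancing selection.

Each generation applies, in order:

1. **Migration** (every `I`-th generation): `e1` individuals drawn without
   replacement (multivariate hypergeometric over haplotype counts) from
   deme 1 move to deme 2, and simultaneously `e2` the other way, both
   drawn from the pre-migration snapshot. `I = 1` is continuous migration;
   `e2 = 0` gives source–sink dynamics (deme 2 transiently holds `N2 + e1`
   individuals until reproduction restores `N2`).
2. **Selection**: `x' = x w / w_bar` per deme on the frequency vector.
   Optional environmental perturbation replaces `s_i` by `(1 + eps_t) s_i`
   with one `eps_t ~ N(0, sigma)` per generation shared by both demes; a
   draw that would make a fitness negative is clamped to zero (never
   triggered at the surveyed parameter ranges `s <= 0.03`, `sigma <= 0.5`).
3. **Recombination**: with `D = x'_am x'_dM - x'_aM x'_dm`, the coupling
   haplotypes lose `D r` and the repulsion haplotypes gain it. Marginal
   allele frequencies are untouched, and the map is exactly the identity
   whenever either locus is monomorphic.
4. **Reproduction**: multinomial sampling of `N_i` individuals per deme
   from the expected frequencies (Wright–Fisher drift).

Replicates start from a pristine state (all *am*), receive a single mutant
at generation 0 at a uniformly chosen locus in a size-weighted deme, and
introduce the remaining locus's mutant with probability `intro_prob`
(= N·mu) per generation, once per replicate (or recurrently at the
modifier locus when `recurrent` is set, in which case a draw landing on an
individual already carrying *M* is a no-op). A replicate ends when both
loci are monomorphic and no introduction is pending, or at the cap of
`100 (N1 + N2)` generations.

## The H_L statistic

Diversity at the modifier locus is measured as cumulative heterozygosity
within demes, averaged over the metapopulation:

    H_L = 2 * sum_t sum_i x_{Mi,t} (1 - x_{Mi,t}) N_i / N

accumulated over post-reproduction (and post-introduction) frequencies from
the introduction generation onward. Because binomial resampling contracts
heterozygosity by exactly `(1 - 1/N)` per generation, a neutral new mutant
yields `E[H_L] = 2(1 - 1/N)`, essentially 2 regardless of population size,
so ensemble means far above 2 diagnose long-lived balanced polymorphism.
Two independent oracles pin this down in the tests: the closed form
`2 N x0 (1 - x0)` and an exact copy-number Markov chain solved by a
fundamental-matrix linear system (`exact_markov_HL`, feasible to N = 1000).
The statistic is accumulated in a streaming fashion; trajectories are
stored only on request (single-replicate runs, thinned every k-th
generation).

## Deterministic companion and the equilibrium convention

Holding the target locus fixed at *a* in both demes reduces the
deterministic dynamics to a 2-D map on the per-deme *M* frequencies:
migration `x_i <- (1 - m) x_i + m x_j` with per-deme replacement fraction
`m = e/(I N_i)` (continuous approximation; `periodic` mode applies `e/N_i`
on schedule), then selection with the a-background fitnesses. The
closed-form interior equilibrium in half-angle form is

    x1* = (1 - tan(theta/2)) / 2,   x2* = 1 - x1*

`equilibrium_frequencies` exposes the printed parameterization
`theta = atan(sp / (e/(I N)))`; `equilibrium_for_params` uses the
convention that actually matches the iterated map, `theta = atan(sp / 2m)`.
The factor 2 is not arbitrary: under symmetric exchange the *difference*
`x2 - x1` decays at rate `2m` (both demes move toward each other), and it
is this difference that selection `sp` balances. The reconciliation was
established numerically by fixed-point iteration against both readings of
the composite parameter; the closed form is a weak-selection /
weak-migration approximation of the discrete map, accurate to
`O(sp + m)` (and the discrete fixed point's coordinate sum deviates from 1
only at `O(s^2)`, because `w_aM1/w_am1` and `w_aM2/w_am2` are not exact
mirrors). Local stability is assessed by a central-difference Jacobian
(step `1e-6`) at a fixed point located to `1e-12`; the spectral radius is
below 1 whenever `sp` and `m` are both positive, reaches 1 on the neutral
line, and the deme equilibria collapse toward each other as migration
grows (homogenization, the high-migration loss of structure). An
8-dimensional full-haplotype deterministic mode reusing the stochastic
stage functions cross-checks the reduction.

## The environmental-switch protocol

To demonstrate rapid evolution from standing variation, replicates are
burned in for `40 N` generations, conditioned on the *M* allele still
segregating in the metapopulation, observed for 200 generations at
quasi-equilibrium, subjected to a sign flip of both selection coefficients
(the environmental switch), and observed for 800 more generations. The
reported trajectories are conditioned means per deme. At the package's
reduced default scale (demes of 500, `s = 0.02`, `p = 1`, `e = 5`,
single-locus modifier dynamics) the conditioned means sit near the
deterministic equilibria (~0.29/0.71), cross within tens of generations of
the switch, and settle on the mirror values well inside the 800-generation
window.

## What the generator emulates — and what it does not

All inputs are parameter configurations; every fixture is generated by the
engine itself. The default study conditions are the desk-scale analogues
of the published survey: deme sizes 100–1000 (not 10,000), replicate
counts 5×10³–2×10⁵ (not 2×10⁷), the `100 N` generation cap retained
exactly, migration from 1 migrant per generation to panmixia (half of each
deme exchanged), `p` in [0.25, 1], `r` in [0, 0.5], `intro_prob` default
0.001. Full-scale parameters remain expressible in any config. Two
consequences of the reduced scale matter for interpretation: (i) modifier
polymorphism at deme size 200 persists for thousands — not tens of
thousands — of generations, so mean H_L lands near 20 rather than in the
hundreds, and the replicates still polymorphic at the cap are typically
polymorphic at the *target* locus, whose selection differential (2s) is
twice the modifier's (sp); (ii) conditioned switch ensembles are tens of
replicates, so trajectory means carry visible Monte-Carlo noise. The model
itself omits diploidy, more than two alleles/loci/demes, overlapping
generations, and any explicit phenotype: fitness is specified directly.

## Numerical and design choices

- Haplotype order is `(am, aM, dm, dM)` everywhere; state is stored as
  integer counts (migration moves whole individuals; reproduction samples
  individuals), frequencies are derived views.
- The batch engine advances all replicates of an ensemble in lockstep on a
  single seeded `numpy` Generator and retires finished replicates, which
  is what makes 2×10⁵-replicate ensembles run in seconds-to-minutes on one
  core. Runs are exactly reproducible given `(params, n_replicates,
  seed)`; per-cell substreams are spawned for sweep grids. Per-replicate
  substreams are not used because numpy's binomial/multinomial samplers
  consume a stream-position-dependent number of variates.
- The 4-category hypergeometric migration draw uses the sequential
  conditional method (three univariate hypergeometric draws), which
  broadcasts across replicates.
- Frequencies are clipped at 0 and renormalized before multinomial
  sampling to absorb last-bit floating-point drift; selection raises an
  explicit error if the mean fitness is zero on the support.
- Fixed-point iteration: absolute-change tolerance `1e-12` (tests use
  `1e-13`), cap 10⁷ iterations.
- H_L standard errors are replicate-level bootstrap (10³ resamples,
  chunked), because the H_L distribution is extremely heavy-tailed — a
  handful of long-lived replicates carries most of the mean.
- Second-introduction timing (end of generation, after reproduction,
  counted in that generation's H_L term) is what makes the neutral
  expectation come out exactly `2(1 - 1/N)`.
- Figure-axis conventions elsewhere sometimes plot H_L normalized so that
  1 marks neutrality; this package reports raw H_L (neutral ≈ 2) and
  exposes a `mean_HL_normalized = mean_HL / 2` column in sweep output.

## Known limitations

- The closed-form equilibrium is first-order; at strong selection or
  migration (`sp + m` approaching 0.1) the discrete map's fixed point
  visibly departs from it.
- `exact_markov_HL` scales as O(N²) memory / O(N³) solve; guarded at
  N ≤ 1000.
- Trajectory recording is limited to single-replicate runs; ensembles
  store only streaming summaries.
- In recurrent-mutation mode replicates always run to the generation cap
  (an introduction is always pending), which is the intended semantics but
  makes that mode expensive at large N.
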