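"""Tests for the finite-population Wright-Fisher engine: migration,
generation stepping, mutant introduction, and replicate runs."""

import numpy as np
import pytest

from plastimod import (
    MetapopState,
    ModelParams,
    introduce_first_mutant,
    maybe_introduce_second_mutant,
    migrate,
    run_replicate,
    simulate_batch,
    step_generation,
)
from plastimod.core import I_aM, I_am, I_dM, I_dm
from plastimod.stochastic import BatchRunner, _mv_hypergeometric


def _state(c1, c2, **flags):
    return MetapopState(counts=np.array([c1, c2]), **flags)


class TestMultivariateHypergeometric:
    def test_marginal_means(self, rng):
        colors = np.tile([40, 30, 20, 10], (20000, 1))
        draws = _mv_hypergeometric(rng, colors, 25)
        assert (draws.sum(axis=1) == 25).all()
        assert draws.mean(axis=0) == pytest.approx(25 * np.array([0.4, 0.3, 0.2, 0.1]), rel=0.05)

    def test_full_draw_returns_everything(self, rng):
        colors = np.array([[3, 1, 4, 2]])
        assert (_mv_hypergeometric(rng, colors, 10) == colors).all()


class TestMigrate:
    def test_no_migration_is_identity(self, rng):
        p = ModelParams.symmetric(N=100, s=0.0, p=0.0, e=0)
        s0 = _state([100, 0, 0, 0], [0, 0, 100, 0])
        out = migrate(s0, p, rng)
        assert (out.counts == s0.counts).all()

    def test_full_exchange_swaps_demes(self, rng):
        p = ModelParams(N1=100, N2=80, e1=100, e2=80)
        s0 = _state([70, 10, 15, 5], [0, 0, 0, 80])
        out = migrate(s0, p, rng)
        assert (out.counts[0] == s0.counts[1]).all()
        assert (out.counts[1] == s0.counts[0]).all()

    def test_monomorphic_sources_are_deterministic(self, rng):
        p = ModelParams(N1=100, N2=100, e1=10, e2=10)
        s0 = _state([100, 0, 0, 0], [0, 100, 0, 0])
        out = migrate(s0, p, rng)
        assert (out.counts[0] == [90, 10, 0, 0]).all()
        assert (out.counts[1] == [10, 90, 0, 0]).all()

    def test_counts_conserved_and_nonnegative(self, rng):
        p = ModelParams(N1=60, N2=40, e1=25, e2=10)
        s0 = _state([20, 10, 15, 15], [5, 5, 10, 20])
        for _ in range(50):
            out = migrate(s0, p, rng)
            assert (out.counts >= 0).all()
            # metapopulation haplotype totals conserved
            assert (out.counts.sum(axis=0) == s0.counts.sum(axis=0)).all()
            # post-migration deme sizes reflect the exchange
            assert out.counts[0].sum() == 60 - 25 + 10
            assert out.counts[1].sum() == 40 - 10 + 25


class TestStepGeneration:
    def test_absorbing_monomorphic_state(self, rng):
        p = ModelParams.symmetric(N=50, s=0.0, p=0.0, e=0)
        s0 = _state([50, 0, 0, 0], [50, 0, 0, 0])
        out = s0
        for _ in range(5):
            out = step_generation(out, p, rng)
        assert (out.counts == s0.counts).all()
        assert out.t == 5

    def test_deme_sizes_restored_each_generation(self, rng):
        p = ModelParams(N1=80, N2=40, s1=0.02, s2=-0.02, e1=20, e2=0)  # source-sink
        s0 = _state([40, 20, 10, 10], [10, 10, 10, 10])
        out = s0
        for _ in range(10):
            out = step_generation(out, p, rng)
            assert out.counts[0].sum() == 80
            assert out.counts[1].sum() == 40

    def test_multinomial_mean_matches_expected_frequencies(self, rng):
        """One generation from a fixed composition: the Monte-Carlo mean of
        the post-reproduction frequencies equals the deterministic
        selection expectation within 3 standard errors."""
        n_rep = 100_000
        p = ModelParams.symmetric(N=100, s=0.03, p=1.0, e=0, r=0.0)
        counts = np.tile([[50, 0, 50, 0], [50, 0, 50, 0]], (n_rep, 1, 1))
        from plastimod.stochastic import _generation_kernel

        new = _generation_kernel(counts, 0, p, rng)
        freqs = new / 100
        # deme 1: w = (1.03, 1, 0.97, 1) on (0.5, 0, 0.5, 0) -> (0.515, 0, 0.485, 0)
        expected = 0.515
        se = np.sqrt(expected * (1 - expected) / 100 / n_rep)
        assert freqs[:, 0, I_am].mean() == pytest.approx(expected, abs=3 * se)
        # deme 2 mirror: a disfavored
        assert freqs[:, 1, I_am].mean() == pytest.approx(0.485, abs=3 * se)

    def test_deme1_dynamics_independent_of_deme2_selection_when_isolated(self):
        """With e = 0 the demes evolve independently: the distribution of
        deme 1's M frequency is unchanged when deme 2's selection
        coefficient changes (checked on ensemble means within Monte-Carlo
        error)."""
        from plastimod.stochastic import _generation_kernel

        base = dict(N1=60, N2=60, p_a1=1, p_d1=1, p_a2=1, p_d2=1, e1=0, e2=0, r=0.5)
        pA = ModelParams(s1=0.02, s2=-0.02, **base)
        pB = ModelParams(s1=0.02, s2=0.9, **base)
        n_rep, T = 40_000, 30
        means = []
        for params, seed in ((pA, 5), (pB, 6)):
            rng_ = np.random.default_rng(seed)
            counts = np.tile([[30, 30, 0, 0], [30, 0, 30, 0]], (n_rep, 1, 1))
            for t in range(T):
                counts = _generation_kernel(counts, t, params, rng_)
            x1 = counts[:, 0, I_aM] / 60
            means.append((x1.mean(), x1.std(ddof=1) / np.sqrt(n_rep)))
        (mA, seA), (mB, seB) = means
        assert mA == pytest.approx(mB, abs=3 * np.hypot(seA, seB))


class TestIntroductions:
    def test_first_mutant_single_copy(self, rng):
        p = ModelParams.symmetric(N=100, s=0.0, p=0.0, e=0)
        out = introduce_first_mutant(MetapopState.pristine(p), p, rng)
        assert out.counts[:, I_am].sum() == p.N - 1
        assert out.counts[:, [I_aM, I_dm]].sum() == 1
        assert out.target_introduced != out.modifier_introduced

    def test_first_mutant_requires_pristine_state(self, rng):
        p = ModelParams.symmetric(N=100, s=0.0, p=0.0, e=0)
        s1 = introduce_first_mutant(MetapopState.pristine(p), p, rng)
        with pytest.raises(ValueError, match="pristine"):
            introduce_first_mutant(s1, p, rng)

    def test_locus_choice_is_uniform(self, rng):
        """Over many draws each locus receives the first mutation about half
        the time (binomial 99.7% interval)."""
        n = 100_000
        p = ModelParams.symmetric(N=50, s=0.0, p=0.0, e=0)
        runner = BatchRunner(p, n, rng)
        frac_target = runner.introduced[:, 0].mean()
        se = np.sqrt(0.25 / n)
        assert frac_target == pytest.approx(0.5, abs=3 * se)

    def test_deme_choice_weighted_by_size(self, rng):
        n = 100_000
        p = ModelParams(N1=9000, N2=1000)
        runner = BatchRunner(p, n, rng)
        in_deme1 = runner.counts[:, 0].sum(axis=-1) != runner.counts[:, 0, I_am]
        # mutant is the only non-am individual, so deme 1 holds it iff its
        # composition deviates from monomorphic am
        frac = in_deme1.mean()
        se = np.sqrt(0.9 * 0.1 / n)
        assert frac == pytest.approx(0.9, abs=3 * se)

    def test_second_mutant_never_fires_with_zero_probability(self, rng):
        p = ModelParams.symmetric(N=50, s=0.0, p=0.0, e=0, intro_prob=0.0)
        s1 = _state([49, 1, 0, 0], [50, 0, 0, 0], modifier_introduced=True)
        out = maybe_introduce_second_mutant(s1, p, rng)
        assert (out.counts == s1.counts).all() and not out.target_introduced

    def test_second_mutant_fires_immediately_with_probability_one(self, rng):
        p = ModelParams.symmetric(N=50, s=0.0, p=0.0, e=0, intro_prob=1.0)
        s1 = _state([49, 1, 0, 0], [50, 0, 0, 0], modifier_introduced=True)
        out = maybe_introduce_second_mutant(s1, p, rng)
        assert out.target_introduced
        assert out.counts[:, [I_dm, I_dM]].sum() == 1

    def test_second_mutant_requires_first(self, rng):
        p = ModelParams.symmetric(N=50, s=0.0, p=0.0, e=0, intro_prob=1.0)
        with pytest.raises(ValueError, match="first mutant"):
            maybe_introduce_second_mutant(MetapopState.pristine(p), p, rng)

    def test_waiting_time_is_geometric(self, rng):
        """With intro_prob = 0.1 the waiting time to the second mutation is
        geometric with mean 10 generations."""
        n = 10_000
        p = ModelParams.symmetric(N=30, s=0.0, p=0.0, e=1, intro_prob=0.1)
        runner = BatchRunner(p, n, rng, first_mutant_locus="modifier")
        first_seen = np.full(n, -1)
        for _ in range(300):
            if runner.n_active == 0:
                break
            newly = runner.introduced[:, 0] & (first_seen < 0)
            first_seen[newly] = runner.t
            runner._one_generation(drop=True)
        newly = runner.introduced[:, 0] & (first_seen < 0)
        first_seen[newly] = 300
        waits = first_seen[first_seen > 0]
        # mean of Geometric(0.1) is 10; 3 sigma band with sd ~ sqrt(0.9)/0.1
        se = np.sqrt(0.9) / 0.1 / np.sqrt(waits.size)
        assert waits.mean() == pytest.approx(10.0, abs=3 * se)


class TestRunReplicate:
    def test_neutral_fixation_probability_is_one_over_N(self, rng):
        """A neutral new mutant fixes with probability 1/N."""
        p = ModelParams.symmetric(N=50, s=0.0, p=0.0, e=1, intro_prob=0.0)
        n = 100_000
        res = simulate_batch(p, n, rng, first_mutant_locus="modifier")
        from plastimod import Fate

        frac_fixed = np.mean(res.fate_modifier == Fate.FIXED)
        se = np.sqrt((1 / 100) * (1 - 1 / 100) / n)
        assert frac_fixed == pytest.approx(1 / 100, abs=3 * se)

    def test_beneficial_mutant_establishes_at_branching_rate(self, rng):
        """An M mutant in the adverse deme with full plasticity has selective
        advantage ~ s; isolated (e = 0), it escapes early loss at roughly the
        branching-process rate 2s, far above the neutral 1/N2."""
        s, N = 0.05, 500
        # short cap: establishment (escape from early stochastic loss) is
        # resolved within a few hundred generations
        p = ModelParams.symmetric(N=N, s=s, p=1.0, e=0, intro_prob=0.0,
                                  max_gens_factor=5)
        n = 20_000
        res = simulate_batch(p, n, rng, first_mutant_locus="modifier", first_mutant_deme=1)
        from plastimod import Fate

        frac_escaped = np.mean(res.fate_modifier != Fate.LOST)
        s_adv = 1.0 / (1.0 - s) - 1.0
        expect = (1 - np.exp(-2 * s_adv)) / (1 - np.exp(-2 * N * s_adv))
        assert frac_escaped > 3 / N
        assert frac_escaped == pytest.approx(expect, rel=0.25)

    def test_cap_rule(self):
        """Parameters forcing stable polymorphism at modest scale: survivors
        end exactly at 100N generations."""
        p = ModelParams.symmetric(N=30, s=0.0, p=0.0, e=1, intro_prob=0.0,
                                  max_gens_factor=2)
        res = simulate_batch(p, 2000, np.random.default_rng(0), first_mutant_locus="modifier")
        assert res.end_generation.max() <= p.max_generations
        # with a tiny cap some neutral replicates must still be segregating
        assert (res.end_generation == p.max_generations).any()

    def test_replicate_result_fields(self):
        p = ModelParams.symmetric(N=40, s=0.0, p=0.0, e=1, intro_prob=0.0, seed=7)
        res = run_replicate(p, record_every=1, first_mutant_locus="modifier")
        assert res.fate_modifier in ("lost", "fixed", "persistent_poly")
        assert res.fate_target == "never_introduced"
        assert res.HL >= 0
        assert res.end_generation <= p.max_generations
        assert res.trajectory is not None
        # trajectory covers introduction generation onwards
        assert res.trajectory[0, 0] == 0

    def test_batch_is_deterministic_given_seed(self, balanced_params):
        a = simulate_batch(balanced_params, 200, np.random.default_rng(123))
        b = simulate_batch(balanced_params, 200, np.random.default_rng(123))
        assert (a.hl == b.hl).all()
        assert (a.end_generation == b.end_generation).all()
        assert (a.fate_modifier == b.fate_modifier).all()
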