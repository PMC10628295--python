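"""Ensemble statistics, parameter sweeps, and the environmental-switch
protocol, plus exact neutral oracles for validation.

The central statistic is the cumulative heterozygosity at the plasticity
modifier locus,

    H_L = 2 * sum_t sum_i x_{Mi,t} (1 - x_{Mi,t}) N_i / N,

accumulated over post-reproduction frequencies from the introduction
generation onward.  Under pure drift a single new mutant yields
E[H_L] = 2 (1 - 1/N), essentially 2 for any population size, so ensemble
means far above 2 diagnose long-lived balanced polymorphism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ModelParams
from .stochastic import (
    BatchResult,
    BatchRunner,
    NoConditionedReplicatesError,
    simulate_batch,
)


def cumulative_heterozygosity(traj: np.ndarray, N1: int, N2: int) -> float:
    """H_L from a per-generation, per-deme M-frequency trajectory.

    ``traj`` has shape (T, 2); the statistic is additive over time, so it
    can equally be accumulated in a streaming fashion (as the stochastic
    engine does) without storing the trajectory.
    """
    x = np.asarray(traj, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("trajectory must have shape (T, 2)")
    w = np.array([N1, N2]) / (N1 + N2)
    return float(2.0 * ((x * (1.0 - x)) @ w).sum())


def expected_neutral_HL_closed_form(N: int, x0: float) -> float:
    """Expected cumulative heterozygosity for a neutral allele at initial
    frequency ``x0`` in a single panmictic Wright-Fisher deme of size ``N``.

    Binomial resampling contracts heterozygosity by exactly (1 - 1/N) per
    generation, so summing the geometric series from the introduction
    generation gives ``2 N x0 (1 - x0)``; a single new mutant (x0 = 1/N)
    yields 2 (1 - 1/N).
    """
    return 2.0 * N * x0 * (1.0 - x0)


def exact_markov_HL(N: int) -> float:
    """Exact E[H_L] for a single new neutral mutant in one deme of size
    ``N``, from the binomial-transition Markov chain on copy number.

    Solves for expected visit counts to each transient copy-number state
    starting from one copy (fundamental-matrix linear solve), then sums
    2 x (1 - x) over visits.  Exact to numerical precision; a brute-force
    cross-check of the closed form, kept deliberately independent of the
    simulation engine.
    """
    if N > 1000:
        raise ValueError(f"exact_markov_HL is limited to N <= 1000 (got {N})")
    j = np.arange(N + 1)
    # transition matrix on copy number: row i -> Binomial(N, i/N)
    P = stats.binom.pmf(j[None, :], N, (j / N)[:, None])
    Q = P[1:N, 1:N]
    e1 = np.zeros(N - 1)
    e1[0] = 1.0  # start from a single copy
    visits = np.linalg.solve(np.eye(N - 1) - Q.T, e1)
    x = j[1:N] / N
    h = 2.0 * x * (1.0 - x)
    return float(visits @ h)


@dataclass
class EnsembleSummary:
    """Aggregate outcome of a replicate ensemble."""

    params: ModelParams
    n_replicates: int
    mean_HL: float
    se_HL: float
    fate_proportions_target: dict[str, float]
    fate_proportions_modifier: dict[str, float]
    mean_end_generation: float
    frac_at_cap: float
    result: BatchResult = field(repr=False)

    def to_row(self) -> dict:
        """Flat dict for tabular output (one sweep cell)."""
        row: dict = {
            k: getattr(self.params, k)
            for k in (
                "N1", "N2", "s1", "s2", "p_a1", "p_d1", "p_a2", "p_d2",
                "e1", "e2", "I", "r", "sigma", "intro_prob", "recurrent",
                "max_gens_factor",
            )
        }
        row.update(
            n_replicates=self.n_replicates,
            mean_HL=self.mean_HL,
            HL_se=self.se_HL,
            mean_HL_normalized=self.mean_HL / 2.0,
            mean_end_generation=self.mean_end_generation,
            frac_at_cap=self.frac_at_cap,
        )
        for locus, props in (
            ("target", self.fate_proportions_target),
            ("modifier", self.fate_proportions_modifier),
        ):
            for name, v in props.items():
                row[f"{locus}_{name}"] = v
        return row


def bootstrap_se(values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000) -> float:
    """Replicate-level bootstrap standard error of the mean.

    Used instead of the plug-in SE because the H_L distribution is extremely
    heavy-tailed (a few long-persisting replicates dominate the mean).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    means = np.empty(n_boot)
    chunk = max(1, int(2e7) // max(n, 1))
    b = 0
    while b < n_boot:
        k = min(chunk, n_boot - b)
        idx = rng.integers(0, n, size=(k, n))
        means[b:b + k] = values[idx].mean(axis=1)
        b += k
    return float(means.std(ddof=1))


def run_ensemble(
    params: ModelParams,
    n_replicates: int,
    rng: np.random.Generator | int | None = None,
    *,
    first_mutant_locus: str = "random",
    first_mutant_deme: int | None = None,
    n_boot: int = 1000,
    log_every: int = 0,
) -> EnsembleSummary:
    """Run an ensemble of independent replicates and aggregate H_L, fates,
    and run lengths.  Deterministic for a fixed seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    res = simulate_batch(
        params, n_replicates, rng,
        first_mutant_locus=first_mutant_locus,
        first_mutant_deme=first_mutant_deme,
        log_every=log_every,
    )
    cap = params.max_generations
    return EnsembleSummary(
        params=params,
        n_replicates=n_replicates,
        mean_HL=float(res.hl.mean()),
        se_HL=bootstrap_se(res.hl, rng, n_boot),
        fate_proportions_target=res.fate_proportions("target"),
        fate_proportions_modifier=res.fate_proportions("modifier"),
        mean_end_generation=float(res.end_generation.mean()),
        frac_at_cap=float(np.mean(res.end_generation >= cap)),
        result=res,
    )


def sweep(
    base: ModelParams,
    grid: dict[str, list],
    n_replicates: int,
    seed: int = 0,
    *,
    out_path=None,
    first_mutant_locus: str = "random",
) -> pd.DataFrame:
    """Cartesian parameter sweep: one ensemble per grid cell.

    ``grid`` maps ModelParams field names to lists of values; every
    combination is run with its own seed spawned from ``seed``.  If
    ``out_path`` names an existing TSV from an earlier (partial) sweep,
    cells already present there are skipped and the table is extended,
    making long sweeps resumable.
    """
    from dataclasses import replace

    if not grid:
        raise ValueError("sweep requires a non-empty grid")
    unknown = set(grid) - set(ModelParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown grid parameter(s): {sorted(unknown)}")
    keys = sorted(grid)
    existing = None
    if out_path is not None:
        import os

        if os.path.exists(out_path):
            existing = pd.read_csv(out_path, sep="\t", comment="#")
    cells = list(itertools.product(*(grid[k] for k in keys)))
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for cell, ss in zip(cells, seeds):
        overrides = dict(zip(keys, cell))
        if "s1" in overrides and "s2" not in overrides and "s2" not in grid:
            overrides["s2"] = -overrides["s1"]  # keep the symmetric preset symmetric
        params = replace(base, **overrides)
        if existing is not None and len(existing):
            match = np.ones(len(existing), dtype=bool)
            for k, v in overrides.items():
                match &= np.isclose(existing[k], v) if isinstance(v, float) else (existing[k] == v)
            if match.any():
                rows.append(existing[match].iloc[0].to_dict())
                continue
        summary = run_ensemble(
            params, n_replicates, np.random.default_rng(ss),
            first_mutant_locus=first_mutant_locus,
        )
        rows.append(summary.to_row())
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


@dataclass
class SwitchTrajectory:
    """Conditioned mean M-frequency trajectories around an environmental
    switch: ``pre_window`` generations at quasi-equilibrium followed by
    ``post_window`` generations after the sign flip of selection."""

    mean_freq: np.ndarray  # (pre_window + post_window, 2)
    pre_window: int
    post_window: int
    n_conditioned: int
    n_replicates: int

    @property
    def pre(self) -> np.ndarray:
        return self.mean_freq[: self.pre_window]

    @property
    def post(self) -> np.ndarray:
        return self.mean_freq[self.pre_window:]

    def to_frame(self) -> pd.DataFrame:
        T = self.mean_freq.shape[0]
        gen = np.arange(T) - self.pre_window  # 0 = switch generation
        return pd.DataFrame(
            {
                "generation": np.repeat(gen, 2),
                "deme": np.tile([1, 2], T),
                "mean_frequency": self.mean_freq.ravel(),
                "n_conditioned": self.n_conditioned,
            }
        )


def environmental_switch_experiment(
    params: ModelParams,
    n_replicates: int,
    rng: np.random.Generator | int | None = None,
    *,
    burn_in: int | None = None,
    pre_window: int = 200,
    post_window: int = 800,
    first_mutant_locus: str = "modifier",
) -> SwitchTrajectory:
    """Rapid-evolution-from-standing-variation protocol.

    Each replicate starts from a single mutant, runs a long burn-in
    (default 40N generations), and is kept only if the M allele still
    segregates in the metapopulation at burn-in end.  The conditioned
    ensemble is then observed for ``pre_window`` generations at
    quasi-equilibrium, the sign of both selection coefficients is flipped
    (the environmental switch), and observation continues for
    ``post_window`` generations.  Returns conditioned mean per-deme
    trajectories.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    if burn_in is None:
        burn_in = 40 * params.N
    runner = BatchRunner(
        params, n_replicates, rng, first_mutant_locus=first_mutant_locus
    )
    runner.advance(until=burn_in, drop=True)
    if runner.n_active:
        x = runner._modifier_freqs()
        w = params.deme_sizes / params.N
        meta = x @ w
        runner.keep_active((meta > 0) & (meta < 1))
    n_cond = runner.n_active
    if n_cond == 0:
        raise NoConditionedReplicatesError(
            "no replicate was polymorphic at the modifier locus at the end of "
            f"burn-in ({burn_in} generations); increase n_replicates"
        )
    pre = runner.advance_recording(pre_window)
    runner.s_scale *= -1.0
    post = runner.advance_recording(post_window)
    return SwitchTrajectory(
        mean_freq=np.vstack([pre, post]),
        pre_window=pre_window,
        post_window=post_window,
        n_conditioned=n_cond,
        n_replicates=n_replicates,
    )
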