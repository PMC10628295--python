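"""Finite-population Wright-Fisher dynamics for the two-deme model.

A generation consists of, in order: migration of whole individuals (only on
scheduled generations), selection and recombination applied at frequency
level within each deme, and multinomial reproduction restoring each deme to
its census size.  Mutant introductions happen at the end of a generation,
immediately after reproduction, so the cumulative-heterozygosity accumulator
includes the introduction generation.

The workhorse is :class:`BatchRunner`, which advances many replicates in
lockstep on (replicates, demes, haplotypes) count arrays; the scalar
operations (:func:`migrate`, :func:`step_generation`, ...) are thin wrappers
over the same kernels, so there is a single code path for the dynamics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import (
    I_am, I_aM, I_dm, I_dM,
    MetapopState, ModelParams,
    apply_recombination, fitness_values,
)

TARGET, MODIFIER = 0, 1  # locus indices used by introduction bookkeeping


class Fate(enum.IntEnum):
    """Per-locus outcome of a replicate."""

    LOST = 0
    FIXED = 1
    PERSISTENT_POLY = 2
    NEVER_INTRODUCED = 3


class NoConditionedReplicatesError(RuntimeError):
    """Raised when an experiment conditions on a property no replicate has."""


def _mv_hypergeometric(rng: np.random.Generator, colors: np.ndarray, nsample) -> np.ndarray:
    """Batched multivariate hypergeometric draw.

    Draws ``nsample`` individuals without replacement from each row of
    ``colors`` (category counts along the last axis), via the sequential
    conditional method: each category in turn is a univariate hypergeometric
    draw against the remaining pool.
    """
    colors = np.asarray(colors, dtype=np.int64)
    out = np.zeros_like(colors)
    rem_total = colors.sum(axis=-1)
    rem_sample = np.broadcast_to(np.asarray(nsample, dtype=np.int64), rem_total.shape).copy()
    for k in range(colors.shape[-1] - 1):
        rem_total = rem_total - colors[..., k]
        out[..., k] = rng.hypergeometric(colors[..., k], rem_total, rem_sample)
        rem_sample = rem_sample - out[..., k]
    out[..., -1] = rem_sample
    return out


def _migrate_counts(counts: np.ndarray, e1: int, e2: int, rng: np.random.Generator) -> None:
    """One migration event, in place, on a (R, 2, 4) count array.

    Both directions are drawn from the same pre-migration snapshot, so a
    migrant cannot be re-migrated within the event and ``e1 = N1, e2 = N2``
    swaps the demes exactly.
    """
    if e1 == 0 and e2 == 0:
        return
    snap1 = counts[:, 0].copy()
    snap2 = counts[:, 1].copy()
    out1 = _mv_hypergeometric(rng, snap1, e1) if e1 > 0 else 0
    out2 = _mv_hypergeometric(rng, snap2, e2) if e2 > 0 else 0
    counts[:, 0] = snap1 - out1 + out2
    counts[:, 1] = snap2 - out2 + out1


def _selection_recombination(
    counts: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    s_scale: float,
) -> np.ndarray:
    """Expected post-selection, post-recombination frequencies, shape (R, 2, 4)."""
    sizes = counts.sum(axis=-1, keepdims=True)
    freqs = counts / sizes
    eps = rng.normal(0.0, params.sigma, size=counts.shape[0]) if params.sigma > 0 else 0.0
    post = np.empty_like(freqs)
    for d, (s_i, (p_a, p_d)) in enumerate(
        [
            (s_scale * params.s1, (params.p_a1, params.p_d1)),
            (s_scale * params.s2, (params.p_a2, params.p_d2)),
        ]
    ):
        w = fitness_values(s_i, p_a, p_d, eps)  # (R, 4) or (4,)
        weighted = freqs[:, d] * w
        wbar = weighted.sum(axis=-1, keepdims=True)
        if np.any(wbar <= 0):
            raise ValueError("mean fitness is zero: selection update undefined")
        post[:, d] = weighted / wbar
    if params.r > 0:
        post = apply_recombination(post, params.r)
    # guard against floating-point drift before multinomial sampling
    np.clip(post, 0.0, None, out=post)
    post /= post.sum(axis=-1, keepdims=True)
    return post


def _generation_kernel(
    counts: np.ndarray,
    t: int,
    params: ModelParams,
    rng: np.random.Generator,
    s_scale: float = 1.0,
) -> np.ndarray:
    """Advance a (R, 2, 4) count array by one full generation.

    Migration fires when ``t % I == 0`` with ``t`` the generation counter of
    the incoming state (so the very first generation includes a migration
    event).  Returns the new count array; the input is not modified.
    """
    counts = counts.copy()
    if t % params.I == 0:
        _migrate_counts(counts, params.e1, params.e2, rng)
    expected = _selection_recombination(counts, params, rng, s_scale)
    new = np.empty_like(counts)
    new[:, 0] = rng.multinomial(params.N1, expected[:, 0])
    new[:, 1] = rng.multinomial(params.N2, expected[:, 1])
    return new


# ---------------------------------------------------------------------------
# scalar (single-state) operations


def migrate(state: MetapopState, params: ModelParams, rng: np.random.Generator) -> MetapopState:
    """One migration event: ``e1`` individuals drawn without replacement from
    deme 1 move to deme 2 and simultaneously ``e2`` from deme 2 to deme 1."""
    out = state.copy()
    counts = out.counts[None, ...]
    _migrate_counts(counts, params.e1, params.e2, rng)
    out.counts = counts[0]
    return out


def step_generation(state: MetapopState, params: ModelParams, rng: np.random.Generator) -> MetapopState:
    """One full generation: migration (if scheduled), selection,
    recombination, and multinomial reproduction; increments ``t``."""
    out = state.copy()
    out.counts = _generation_kernel(state.counts[None, ...], state.t, params, rng)[0]
    out.t = state.t + 1
    return out


def introduce_first_mutant(
    state: MetapopState,
    params: ModelParams,
    rng: np.random.Generator,
    locus: str = "random",
) -> MetapopState:
    """Place the initial single mutant.

    One locus is chosen uniformly at random (or forced via ``locus`` in
    ``{"target", "modifier"}``), and one individual uniformly from the
    metapopulation (deme weighted by its size); that individual's ``am``
    haplotype becomes ``dm`` (target) or ``aM`` (modifier).
    """
    if state.target_introduced or state.modifier_introduced:
        raise ValueError("introduce_first_mutant requires a pristine state")
    if (state.counts[:, I_am] != params.deme_sizes).any():
        raise ValueError("introduce_first_mutant requires both demes monomorphic am")
    out = state.copy()
    if locus == "random":
        which = TARGET if rng.integers(2) == 0 else MODIFIER
    elif locus in ("target", "modifier"):
        which = TARGET if locus == "target" else MODIFIER
    else:
        raise ValueError(f"unknown locus {locus!r}")
    deme = 0 if rng.integers(params.N) < params.N1 else 1
    dest = I_dm if which == TARGET else I_aM
    out.counts[deme, I_am] -= 1
    out.counts[deme, dest] += 1
    if which == TARGET:
        out.target_introduced = True
    else:
        out.modifier_introduced = True
    return out


def maybe_introduce_second_mutant(
    state: MetapopState,
    params: ModelParams,
    rng: np.random.Generator,
) -> MetapopState:
    """With probability ``intro_prob``, mutate one uniformly chosen
    individual's allele at the locus that has not yet mutated (a -> d at the
    target, m -> M at the modifier), at most once per replicate outside
    recurrent mode."""
    if not (state.target_introduced or state.modifier_introduced):
        raise ValueError("first mutant must be introduced before the second")
    target_pending = not state.target_introduced
    modifier_pending = (not state.modifier_introduced) or params.recurrent
    if not (target_pending or modifier_pending):
        return state
    if params.intro_prob <= 0 or rng.random() >= params.intro_prob:
        return state
    which = TARGET if target_pending else MODIFIER
    out = state.copy()
    u = int(rng.integers(params.N))
    deme, within = (0, u) if u < params.N1 else (1, u - params.N1)
    h = int(np.searchsorted(out.counts[deme].cumsum(), within, side="right"))
    if which == TARGET:
        dest = h + 2 if h < 2 else h  # a -> d, preserving the modifier allele
        out.target_introduced = True
    else:
        dest = h + 1 if h % 2 == 0 else h  # m -> M, preserving the target allele
        out.modifier_introduced = True
    if dest != h:
        out.counts[deme, h] -= 1
        out.counts[deme, dest] += 1
    return out


# ---------------------------------------------------------------------------
# batched replicate engine


@dataclass
class ReplicateResult:
    """Outcome of one replicate run."""

    fate_target: str
    fate_modifier: str
    end_generation: int
    HL: float
    HL_deme: np.ndarray  # unweighted per-deme cumulative heterozygosity
    trajectory: np.ndarray | None = None  # columns: t, x_M1, x_M2


@dataclass
class BatchResult:
    """Vectorized outcomes of an ensemble of replicates."""

    hl: np.ndarray
    hl_deme: np.ndarray
    end_generation: np.ndarray
    fate_target: np.ndarray  # Fate codes
    fate_modifier: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.hl.shape[0]

    def fate_proportions(self, locus: str) -> dict[str, float]:
        codes = self.fate_target if locus == "target" else self.fate_modifier
        return {f.name.lower(): float(np.mean(codes == f)) for f in Fate}


class BatchRunner:
    """Advances an ensemble of replicates in lockstep.

    All replicates share the generation counter; finished replicates
    (both loci monomorphic with no introduction still pending) are recorded
    and removed from the active set, so the per-generation cost shrinks as
    replicates absorb.  Determinism: for a fixed ``(params, n_replicates,
    seed)`` the full set of outcomes is reproducible.
    """

    def __init__(
        self,
        params: ModelParams,
        n_replicates: int,
        rng: np.random.Generator,
        *,
        first_mutant_locus: str = "random",
        first_mutant_deme: int | None = None,
        record_every: int = 0,
        s_scale: float = 1.0,
        log_every: int = 0,
    ) -> None:
        if n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if record_every and n_replicates != 1:
            raise ValueError("trajectory recording is supported for single replicates only")
        self.params = params
        self.rng = rng
        self.s_scale = s_scale
        self.record_every = record_every
        self.log_every = log_every
        self.t = 0
        R = n_replicates
        self.counts = np.zeros((R, 2, 4), dtype=np.int64)
        self.counts[:, 0, I_am] = params.N1
        self.counts[:, 1, I_am] = params.N2
        self.idx = np.arange(R)
        self.introduced = np.zeros((R, 2), dtype=bool)
        self.hl = np.zeros(R)
        self.hl_deme = np.zeros((R, 2))
        self.end_generation = np.full(R, -1, dtype=np.int64)
        self.fate_target = np.full(R, -1, dtype=np.int8)
        self.fate_modifier = np.full(R, -1, dtype=np.int8)
        self._trajectory: list[tuple[int, float, float]] = []
        self._weights = params.deme_sizes / params.N
        self._first_introduction(first_mutant_locus, first_mutant_deme)
        self._accumulate_hl()
        self._maybe_record()

    # -- initialization -----------------------------------------------------

    def _first_introduction(self, locus: str, deme: int | None) -> None:
        R = self.idx.size
        rng = self.rng
        if locus == "random":
            which = rng.integers(0, 2, size=R)
        elif locus in ("target", "modifier"):
            which = np.full(R, TARGET if locus == "target" else MODIFIER)
        else:
            raise ValueError(f"unknown locus {locus!r}")
        if deme is None:
            d = (rng.integers(0, self.params.N, size=R) >= self.params.N1).astype(np.int64)
        else:
            d = np.full(R, deme, dtype=np.int64)
        rows = np.arange(R)
        dest = np.where(which == TARGET, I_dm, I_aM)
        self.counts[rows, d, I_am] -= 1
        self.counts[rows, d, dest] += 1
        self.introduced[rows, which] = True

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_active(self) -> int:
        return self.idx.size

    def _modifier_freqs(self) -> np.ndarray:
        """Post-reproduction M-allele frequency per deme, shape (R_active, 2)."""
        sizes = self.counts.sum(axis=-1)
        return (self.counts[:, :, I_aM] + self.counts[:, :, I_dM]) / sizes

    def _accumulate_hl(self) -> None:
        x = self._modifier_freqs()
        het = x * (1.0 - x)
        self.hl[self.idx] += 2.0 * het @ self._weights
        self.hl_deme[self.idx] += 2.0 * het

    def _maybe_record(self) -> None:
        if self.record_every and self.n_active and self.t % self.record_every == 0:
            x = self._modifier_freqs()[0]
            self._trajectory.append((self.t, float(x[0]), float(x[1])))

    def _pending(self) -> np.ndarray:
        """(R_active, 2) mask: locus may still receive an introduction."""
        p = self.params
        if p.intro_prob <= 0:
            return np.zeros((self.n_active, 2), dtype=bool)
        intro = self.introduced[self.idx]
        pending = ~intro
        if p.recurrent:
            pending[:, MODIFIER] = True
        return pending

    def _second_introductions(self) -> None:
        p = self.params
        if p.intro_prob <= 0 or self.n_active == 0:
            return
        pending = self._pending()
        eligible = pending.any(axis=1)
        fire = eligible & (self.rng.random(self.n_active) < p.intro_prob)
        rows = np.flatnonzero(fire)
        if rows.size == 0:
            return
        # exactly one locus can be pending outside recurrent mode; prefer the
        # never-introduced locus when both are (recurrent mode, early gens)
        which = np.where(pending[rows, TARGET], TARGET, MODIFIER)
        u = self.rng.integers(0, p.N, size=rows.size)
        deme = (u >= p.N1).astype(np.int64)
        within = np.where(deme == 0, u, u - p.N1)
        cum = self.counts[rows, deme].cumsum(axis=-1)
        h = (within[:, None] >= cum).sum(axis=-1)
        dest = np.where(
            which == TARGET,
            np.where(h < 2, h + 2, h),      # a -> d
            np.where(h % 2 == 0, h + 1, h),  # m -> M
        )
        moved = dest != h
        self.counts[rows[moved], deme[moved], h[moved]] -= 1
        self.counts[rows[moved], deme[moved], dest[moved]] += 1
        self.introduced[self.idx[rows], which] = True

    def _finished_mask(self) -> np.ndarray:
        N = self.params.N
        m_count = self.counts[:, :, [I_aM, I_dM]].sum(axis=(1, 2))
        d_count = self.counts[:, :, [I_dm, I_dM]].sum(axis=(1, 2))
        mono = ((m_count == 0) | (m_count == N)) & ((d_count == 0) | (d_count == N))
        return mono & ~self._pending().any(axis=1)

    def _fates(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        N = self.params.N
        out = []
        for locus, cols in ((TARGET, [I_dm, I_dM]), (MODIFIER, [I_aM, I_dM])):
            cnt = self.counts[rows][:, :, cols].sum(axis=(1, 2))
            fate = np.where(
                cnt == 0, Fate.LOST, np.where(cnt == N, Fate.FIXED, Fate.PERSISTENT_POLY)
            ).astype(np.int8)
            fate[~self.introduced[self.idx[rows], locus]] = Fate.NEVER_INTRODUCED
            out.append(fate)
        return out[0], out[1]

    def _retire(self, rows: np.ndarray) -> None:
        """Record outcomes for the given active rows and drop them."""
        if rows.size == 0:
            return
        orig = self.idx[rows]
        ft, fm = self._fates(rows)
        self.fate_target[orig] = ft
        self.fate_modifier[orig] = fm
        self.end_generation[orig] = self.t
        keep = np.ones(self.n_active, dtype=bool)
        keep[rows] = False
        self.counts = self.counts[keep]
        self.idx = self.idx[keep]

    def keep_active(self, mask: np.ndarray) -> None:
        """Restrict the active set (used for conditioning in experiments);
        dropped replicates are retired with their current state."""
        self._retire(np.flatnonzero(~np.asarray(mask)))

    # -- advancing ----------------------------------------------------------

    def _one_generation(self, drop: bool) -> None:
        self.counts = _generation_kernel(self.counts, self.t, self.params, self.rng, self.s_scale)
        self.t += 1
        self._second_introductions()
        self._accumulate_hl()
        self._maybe_record()
        if drop:
            self._retire(np.flatnonzero(self._finished_mask()))
        if self.log_every and self.t % self.log_every == 0:
            import sys

            print(f"generation {self.t}: {self.n_active} replicates active", file=sys.stderr)

    def advance(self, until: int, drop: bool = True) -> None:
        """Step all active replicates forward until generation ``until`` or
        until every replicate has finished."""
        while self.n_active and self.t < until:
            self._one_generation(drop)

    def advance_recording(self, n_gens: int) -> np.ndarray:
        """Step forward ``n_gens`` generations without retiring anyone,
        returning the per-generation mean M frequency per deme over the
        current active set, shape (n_gens, 2)."""
        out = np.empty((n_gens, 2))
        for g in range(n_gens):
            self._one_generation(drop=False)
            out[g] = self._modifier_freqs().mean(axis=0)
        return out

    def run_to_completion(self) -> BatchResult:
        """Run to absorption or the 100N-style cap and collect outcomes."""
        cap = self.params.max_generations
        self.advance(until=cap, drop=True)
        self._retire(np.arange(self.n_active))  # survivors hit the cap
        return BatchResult(
            hl=self.hl,
            hl_deme=self.hl_deme,
            end_generation=self.end_generation,
            fate_target=self.fate_target,
            fate_modifier=self.fate_modifier,
        )

    @property
    def trajectory(self) -> np.ndarray | None:
        if not self.record_every:
            return None
        return np.array(self._trajectory)


def simulate_batch(
    params: ModelParams,
    n_replicates: int,
    rng: np.random.Generator,
    *,
    first_mutant_locus: str = "random",
    first_mutant_deme: int | None = None,
    log_every: int = 0,
) -> BatchResult:
    """Run ``n_replicates`` independent replicates to absorption or cap."""
    runner = BatchRunner(
        params, n_replicates, rng,
        first_mutant_locus=first_mutant_locus,
        first_mutant_deme=first_mutant_deme,
        log_every=log_every,
    )
    return runner.run_to_completion()


def run_replicate(
    params: ModelParams,
    rng: np.random.Generator | None = None,
    *,
    first_mutant_locus: str = "random",
    first_mutant_deme: int | None = None,
    record_every: int = 0,
) -> ReplicateResult:
    """Run a single replicate from a pristine state to absorption or cap.

    The first mutant is inserted at ``t = 0``; the second locus mutates with
    per-generation probability ``intro_prob`` until it has fired once.  The
    run halts when both loci are monomorphic and no introduction is pending,
    or at ``max_gens_factor * N`` generations.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    runner = BatchRunner(
        params, 1, rng,
        first_mutant_locus=first_mutant_locus,
        first_mutant_deme=first_mutant_deme,
        record_every=record_every,
    )
    res = runner.run_to_completion()
    return ReplicateResult(
        fate_target=Fate(res.fate_target[0]).name.lower(),
        fate_modifier=Fate(res.fate_modifier[0]).name.lower(),
        end_generation=int(res.end_generation[0]),
        HL=float(res.hl[0]),
        HL_deme=res.hl_deme[0],
        trajectory=runner.trajectory,
    )
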