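"""Parameter and state containers and the pure per-generation transforms.

The model tracks a haploid metapopulation split into two demes under
spatially opposing selection.  Each individual carries a two-locus
haplotype: a target (structural) locus with alleles ``a`` (ancestral) and
``d`` (derived), and a plasticity-modifier locus with alleles ``m``
(non-plastic) and ``M`` (plastic).  Everything downstream — the stochastic
Wright-Fisher engine and the deterministic recursion — is built from three
pure stage functions defined here: fitness assignment, selection, and
recombination.

Haplotype ordering is fixed everywhere as ``(am, aM, dm, dM)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical haplotype ordering used by every engine and writer.
HAPLOTYPES = ("am", "aM", "dm", "dM")

#: Indices into the canonical ordering.
I_am, I_aM, I_dm, I_dM = 0, 1, 2, 3

#: Sign pattern of the linkage-disequilibrium correction, one entry per
#: haplotype: coupling haplotypes (am, dM) lose D*r, repulsion haplotypes
#: (aM, dm) gain it.
_RECOMB_SIGNS = np.array([-1.0, 1.0, 1.0, -1.0])


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set for one model configuration.

    Parameters
    ----------
    N1, N2
        Deme sizes (individuals).  Deme 1 is the ancestral, favorable
        habitat; deme 2 the derived, adverse one.
    s1, s2
        Directional selection coefficients on the target locus in each
        deme (``|s_i| < 1``).  The symmetric case has ``s1 = s = -s2``.
    p_a1, p_d1, p_a2, p_d2
        Plasticity effects: the net benefit/cost of the ``M`` allele for
        target allele ``h`` in deme ``i``, each in ``[0, 1]``.  ``p = 1``
        fully neutralizes selection on the target allele it is paired with.
    e1, e2
        Migrants per migration event leaving deme 1 and deme 2
        (non-negative integers, ``e_i <= N_i``).  ``e2 = 0`` gives
        source-sink dynamics.
    I
        Generations between migration events; ``1`` means continuous
        migration.
    r
        Recombination rate between the two loci, in ``[0, 0.5]``.
    sigma
        Standard deviation of the per-generation selection perturbation
        ``eps_t ~ N(0, sigma)``; the realized coefficient is
        ``(1 + eps_t) * s_i``.
    intro_prob
        Per-generation probability (``N*mu``) of introducing the mutant at
        the locus that has not yet mutated.
    recurrent
        If true, introductions at the plasticity locus repeat every
        generation with probability ``intro_prob`` instead of firing at
        most once.
    max_gens_factor
        Cap multiplier: a replicate runs at most
        ``max_gens_factor * (N1 + N2)`` generations (default 100).
    seed
        Optional master seed recorded with the configuration.
    """

    N1: int
    N2: int
    s1: float = 0.0
    s2: float = 0.0
    p_a1: float = 0.0
    p_d1: float = 0.0
    p_a2: float = 0.0
    p_d2: float = 0.0
    e1: int = 0
    e2: int = 0
    I: int = 1
    r: float = 0.5
    sigma: float = 0.0
    intro_prob: float = 0.0
    recurrent: bool = False
    max_gens_factor: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("N1", "N2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("s1", "s2"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1, got {getattr(self, name)}")
        for name in ("p_a1", "p_d1", "p_a2", "p_d2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name, cap in (("e1", self.N1), ("e2", self.N2)):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            if v > cap:
                raise ValueError(
                    f"{name}={v} exceeds deme size {cap}: cannot emigrate more "
                    "individuals than a deme holds"
                )
        if not (isinstance(self.I, (int, np.integer)) and self.I >= 1):
            raise ValueError(f"I must be a positive integer, got {self.I!r}")
        if not 0 <= self.r <= 0.5:
            raise ValueError(f"r must lie in [0, 0.5], got {self.r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if not 0 <= self.intro_prob <= 1:
            raise ValueError(f"intro_prob must lie in [0, 1], got {self.intro_prob}")
        if not (isinstance(self.max_gens_factor, (int, np.integer)) and self.max_gens_factor >= 1):
            raise ValueError(f"max_gens_factor must be a positive integer, got {self.max_gens_factor!r}")

    @classmethod
    def symmetric(
        cls,
        N: int,
        s: float,
        p: float,
        e: int,
        *,
        I: int = 1,
        r: float = 0.5,
        sigma: float = 0.0,
        intro_prob: float = 0.0,
        recurrent: bool = False,
        max_gens_factor: int = 100,
        seed: int | None = None,
    ) -> "ModelParams":
        """Symmetric preset: equal demes, ``s1 = s = -s2``, all plasticity
        effects equal to ``p``, reciprocal migration ``e1 = e2 = e``."""
        return cls(
            N1=N, N2=N, s1=s, s2=-s,
            p_a1=p, p_d1=p, p_a2=p, p_d2=p,
            e1=e, e2=e, I=I, r=r, sigma=sigma,
            intro_prob=intro_prob, recurrent=recurrent,
            max_gens_factor=max_gens_factor, seed=seed,
        )

    @property
    def N(self) -> int:
        """Metapopulation size ``N1 + N2`` (constant across generations)."""
        return self.N1 + self.N2

    @property
    def max_generations(self) -> int:
        """Generation cap: ``max_gens_factor * (N1 + N2)``."""
        return self.max_gens_factor * self.N

    @property
    def deme_sizes(self) -> np.ndarray:
        return np.array([self.N1, self.N2], dtype=np.int64)

    def selection_coefficient(self, deme_index: int) -> float:
        if deme_index not in (1, 2):
            raise ValueError(f"deme_index must be 1 or 2, got {deme_index}")
        return self.s1 if deme_index == 1 else self.s2

    def plasticity_effects(self, deme_index: int) -> tuple[float, float]:
        """(p_a, p_d) for the given deme."""
        if deme_index not in (1, 2):
            raise ValueError(f"deme_index must be 1 or 2, got {deme_index}")
        return (self.p_a1, self.p_d1) if deme_index == 1 else (self.p_a2, self.p_d2)

    def with_flipped_selection(self) -> "ModelParams":
        """Environmental switch: sign-flip of both selection coefficients."""
        return replace(self, s1=-self.s1, s2=-self.s2)


@dataclass
class DemeState:
    """Haplotype counts for one deme, in the canonical (am, aM, dm, dM) order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4,):
            raise ValueError("DemeState requires exactly four haplotype counts")
        if (self.counts < 0).any():
            raise ValueError("haplotype counts must be non-negative")

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        """Frequency view ``x_h = n_h / N``; sums to 1."""
        return self.counts / self.counts.sum()

    @property
    def modifier_frequency(self) -> float:
        """Frequency of the plastic allele M (aM + dM)."""
        return float((self.counts[I_aM] + self.counts[I_dM]) / self.counts.sum())

    @property
    def derived_frequency(self) -> float:
        """Frequency of the derived target allele d (dm + dM)."""
        return float((self.counts[I_dm] + self.counts[I_dM]) / self.counts.sum())


@dataclass
class MetapopState:
    """The full simulator state: two demes, a generation counter, and flags
    recording whether each locus's mutant has been introduced."""

    counts: np.ndarray  # shape (2, 4) haplotype counts, demes x haplotypes
    t: int = 0
    target_introduced: bool = False
    modifier_introduced: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 4):
            raise ValueError("MetapopState requires a (2, 4) count array")
        if (self.counts < 0).any():
            raise ValueError("haplotype counts must be non-negative")

    @classmethod
    def pristine(cls, params: ModelParams) -> "MetapopState":
        """Both demes monomorphic for the am haplotype at t = 0."""
        counts = np.zeros((2, 4), dtype=np.int64)
        counts[0, I_am] = params.N1
        counts[1, I_am] = params.N2
        return cls(counts=counts)

    @property
    def deme1(self) -> DemeState:
        return DemeState(self.counts[0].copy())

    @property
    def deme2(self) -> DemeState:
        return DemeState(self.counts[1].copy())

    @property
    def total_size(self) -> int:
        return int(self.counts.sum())

    def modifier_count(self) -> int:
        """Metapopulation copy number of the M allele."""
        return int(self.counts[:, [I_aM, I_dM]].sum())

    def target_count(self) -> int:
        """Metapopulation copy number of the derived allele d."""
        return int(self.counts[:, [I_dm, I_dM]].sum())

    def copy(self) -> "MetapopState":
        return MetapopState(
            counts=self.counts.copy(),
            t=self.t,
            target_introduced=self.target_introduced,
            modifier_introduced=self.modifier_introduced,
        )


@dataclass(frozen=True)
class FitnessTable:
    """Relative fitnesses of the four haplotypes in one deme.

    With ``p = 0`` the modifier is neutral (``w_aM = w_am`` and
    ``w_dM = w_dm``); with ``s = 0`` all four entries equal 1.
    """

    w_am: float
    w_aM: float
    w_dm: float
    w_dM: float

    @property
    def values(self) -> np.ndarray:
        return np.array([self.w_am, self.w_aM, self.w_dm, self.w_dM])

    def mean_fitness(self, freqs: np.ndarray) -> float:
        """Frequency-weighted mean fitness ``w_bar``."""
        return float(np.dot(np.asarray(freqs), self.values))


def fitness_values(
    s: float | np.ndarray,
    p_a: float,
    p_d: float,
    eps: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Broadcastable fitness builder.

    Returns ``(1+s~, 1+s~(1-p_a), 1-s~, 1-s~(1-p_d))`` along the last axis
    with ``s~ = (1+eps)*s``, clamped at zero so that an extreme perturbation
    draw can never produce a negative fitness.
    """
    s_eff = np.asarray((1.0 + np.asarray(eps)) * s)
    w = np.stack(
        [
            1.0 + s_eff,
            1.0 + s_eff * (1.0 - p_a),
            1.0 - s_eff,
            1.0 - s_eff * (1.0 - p_d),
        ],
        axis=-1,
    )
    return np.maximum(w, 0.0)


def fitness_table(params: ModelParams, deme_index: int, eps: float = 0.0) -> FitnessTable:
    """Fitness table for one deme, optionally perturbed.

    The haplotype carrying the locally adapted target allele (``a`` in the
    ancestral deme where ``s_i > 0``) has fitness ``1 + s_i``; the plastic
    ``M`` allele discounts the selective effect of its target-locus partner
    by the factor ``(1 - p)``.  A perturbation draw ``eps`` rescales the
    selection coefficient to ``(1 + eps) * s_i``.
    """
    s_i = params.selection_coefficient(deme_index)
    p_a, p_d = params.plasticity_effects(deme_index)
    w = fitness_values(s_i, p_a, p_d, eps)
    return FitnessTable(*(float(v) for v in w))


def apply_selection(freqs: np.ndarray, w: FitnessTable | np.ndarray) -> np.ndarray:
    """Deterministic selection update ``x' = x * w / w_bar``.

    Broadcasts over leading axes; the last axis is the haplotype axis.

    Raises
    ------
    ValueError
        If the mean fitness is zero on the support of ``freqs`` (all mass on
        zero-fitness haplotypes), which would make the update undefined.
    """
    x = np.asarray(freqs, dtype=float)
    wv = w.values if isinstance(w, FitnessTable) else np.asarray(w, dtype=float)
    wbar = np.sum(x * wv, axis=-1, keepdims=True)
    if np.any(wbar <= 0):
        raise ValueError("mean fitness is zero: selection update undefined")
    return x * wv / wbar


def apply_recombination(freqs: np.ndarray, r: float) -> np.ndarray:
    """Deterministic recombination update.

    With linkage disequilibrium ``D = x_am * x_dM - x_aM * x_dm``, returns
    ``(x_am - D r, x_aM + D r, x_dm + D r, x_dM - D r)``.  Single-locus
    marginal frequencies are unchanged; when either locus is monomorphic
    ``D = 0`` and the map is exactly the identity.
    """
    x = np.asarray(freqs, dtype=float)
    D = x[..., I_am] * x[..., I_dM] - x[..., I_aM] * x[..., I_dm]
    out = x + (D * r)[..., None] * _RECOMB_SIGNS
    if np.any(out < -1e-9):
        raise RuntimeError("recombination produced a negative frequency; invalid input")
    return out
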