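"""Infinite-population dynamics for the symmetric model.

With the target locus fixed for the ancestral allele ``a`` in both demes —
the configuration in which balancing selection on the modifier operates —
the deterministic dynamics reduce to a 2-D map on the per-deme M-allele
frequencies ``(x1, x2)``: migration mixes the demes, then selection pushes
``M`` down in the adapted deme and up in the maladapted one.  The map has a
closed-form interior fixed point parameterized by the angle

    theta = atan( sp / mu_eff ),   mu_eff = 2 e / (I * N_i),

with ``x1* = (1 - tan(theta/2)) / 2`` and ``x2* = 1 - x1*``.  ``theta``
runs from 0 (no selection: both demes at 1/2) to pi/2 (no migration: local
fixation at 0 and 1).  The composite migration strength ``mu_eff`` is twice
the fraction of a deme replaced by immigrants per generation, because
migration contracts the *difference* between the two demes at twice the
per-deme replacement rate; this convention is verified against the iterated
map in the test suite (agreement to first order in ``sp`` and the migration
fraction; the closed form is a weak-selection/weak-migration limit, not an
exact fixed point of the discrete map).

An 8-dimensional full-haplotype deterministic mode (:func:`det_step_full`)
reuses the stochastic engine's stage functions with expectation updates and
serves as a cross-check of the reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParams, apply_recombination, apply_selection, fitness_values


@dataclass(frozen=True)
class EquilibriumSolution:
    """Interior equilibrium of the symmetric two-deme modifier dynamics.

    ``theta`` in [0, pi/2] encodes the relative strength of selection and
    migration; ``x1_star`` (ancestral deme) lies in [0, 1/2] and ``x2_star``
    (derived deme) in [1/2, 1], with ``x1_star + x2_star = 1``.
    """

    theta: float
    x1_star: float
    x2_star: float

    @property
    def pair(self) -> tuple[float, float]:
        return (self.x1_star, self.x2_star)


def _equilibrium_from_theta(theta: float) -> EquilibriumSolution:
    # half-angle form: algebraically identical to
    # x1* = (1 + (cos t - 1)/sin t)/2,  x2* = x1* (sin t + 1)/cos t,
    # but finite at both endpoints.
    u = math.tan(theta / 2.0)
    return EquilibriumSolution(theta=theta, x1_star=(1.0 - u) / 2.0, x2_star=(1.0 + u) / 2.0)


def equilibrium_frequencies(s: float, p: float, e: float, I: float, N: float) -> EquilibriumSolution:
    """Closed-form equilibrium in the printed parameterization
    ``theta = atan(sp / (e/IN))``.

    Raises
    ------
    ValueError
        If both the selection product ``s*p`` and the migration rate
        ``e/(I*N)`` are zero (theta undefined).
    """
    sp = s * p
    mig = e / (I * N)
    if sp < 0 or mig < 0:
        raise ValueError("equilibrium_frequencies requires s*p >= 0 and e/(I*N) >= 0")
    if sp == 0 and mig == 0:
        raise ValueError("theta undefined: s*p and e/(I*N) are both zero")
    return _equilibrium_from_theta(math.atan2(sp, mig))


def equilibrium_for_params(params: ModelParams) -> EquilibriumSolution:
    """Equilibrium matching the discrete recursion for a symmetric
    parameter set: the migration argument is the reconciled effective rate
    ``2 e / (I * N_i)`` (see module docstring)."""
    _require_symmetric(params)
    sp = params.s1 * params.p_a1
    mig = 2.0 * params.e1 / (params.I * params.N1)
    if sp == 0 and mig == 0:
        raise ValueError("theta undefined: s*p and migration are both zero")
    return _equilibrium_from_theta(math.atan2(sp, mig))


def _require_symmetric(params: ModelParams) -> None:
    ps = (params.p_a1, params.p_d1, params.p_a2, params.p_d2)
    if not (
        params.N1 == params.N2
        and params.e1 == params.e2
        and math.isclose(params.s1, -params.s2)
        and all(math.isclose(p, ps[0]) for p in ps)
    ):
        raise ValueError("this operation requires the symmetric parameterization")


def det_step(
    freq_pair: tuple[float, float],
    params: ModelParams,
    mode: str = "continuous_approx",
    t: int = 0,
) -> tuple[float, float]:
    """One deterministic generation of the 2-D reduction.

    Migration first — in ``continuous_approx`` mode a fraction
    ``e/(I*N_i)`` of each deme is replaced by the other deme every step; in
    ``periodic`` mode the full per-event fraction ``e/N_i`` applies only
    when ``t % I == 0`` — then selection within each deme using the
    a-background fitnesses ``w_am,i = 1 + s_i`` and
    ``w_aM,i = 1 + s_i (1 - p_ai)``.  The map preserves [0, 1]^2 and fixes
    the corners (0, 0) and (1, 1).
    """
    x1, x2 = freq_pair
    if mode == "continuous_approx":
        m1 = params.e2 / (params.I * params.N1)
        m2 = params.e1 / (params.I * params.N2)
    elif mode == "periodic":
        if t % params.I == 0:
            m1 = params.e2 / params.N1
            m2 = params.e1 / params.N2
        else:
            m1 = m2 = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    y1 = (1.0 - m1) * x1 + m1 * x2
    y2 = (1.0 - m2) * x2 + m2 * x1
    out = []
    for y, s_i, p_a in ((y1, params.s1, params.p_a1), (y2, params.s2, params.p_a2)):
        w_am = 1.0 + s_i
        w_aM = 1.0 + s_i * (1.0 - p_a)
        out.append(y * w_aM / (y * w_aM + (1.0 - y) * w_am))
    return (out[0], out[1])


def det_step_full(
    freqs: np.ndarray,
    params: ModelParams,
    mode: str = "continuous_approx",
    t: int = 0,
) -> np.ndarray:
    """One deterministic generation of the full (2, 4) haplotype-frequency
    system: migration mixing, then the same selection and recombination
    stage functions used by the stochastic engine, with reproduction being
    the identity in the infinite-population limit."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (2, 4):
        raise ValueError("det_step_full expects a (2, 4) frequency array")
    if mode == "continuous_approx":
        scale = 1.0 / params.I
    elif mode == "periodic":
        scale = 1.0 if t % params.I == 0 else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    e1, e2 = params.e1 * scale, params.e2 * scale
    N1, N2 = params.N1, params.N2
    mixed = np.empty_like(f)
    mixed[0] = ((N1 - e1) * f[0] + e2 * f[1]) / (N1 - e1 + e2)
    mixed[1] = ((N2 - e2) * f[1] + e1 * f[0]) / (N2 - e2 + e1)
    out = np.empty_like(f)
    for d in range(2):
        s_i = params.selection_coefficient(d + 1)
        p_a, p_d = params.plasticity_effects(d + 1)
        w = fitness_values(s_i, p_a, p_d)
        out[d] = apply_selection(mixed[d], w)
    return apply_recombination(out, params.r)


def iterate_to_fixed_point(
    x0: tuple[float, float],
    params: ModelParams,
    mode: str = "continuous_approx",
    tol: float = 1e-12,
    max_iter: int = 10**7,
) -> tuple[tuple[float, float], int]:
    """Iterate :func:`det_step` until the update falls below ``tol``
    (absolute, summed over coordinates).  Returns the fixed point and the
    number of iterations; raises if the cap is reached first."""
    x = tuple(float(v) for v in x0)
    for n in range(1, max_iter + 1):
        nxt = det_step(x, params, mode, t=n - 1)
        if abs(nxt[0] - x[0]) + abs(nxt[1] - x[1]) < tol:
            return nxt, n
        x = nxt
    raise RuntimeError(f"fixed-point iteration did not converge within {max_iter} steps")


def stability_eigenvalues(
    eq: EquilibriumSolution | tuple[float, float],
    params: ModelParams,
    mode: str = "continuous_approx",
    residual_tol: float = 1e-8,
    step: float = 1e-6,
) -> float:
    """Spectral radius of the Jacobian of :func:`det_step` at a fixed point.

    The Jacobian is estimated by central differences (step ``1e-6``); a
    spectral radius below 1 indicates local stability.  The point must be a
    fixed point of the map: if the residual exceeds ``residual_tol`` a
    ``ValueError`` reporting the residual is raised.
    """
    x = eq.pair if isinstance(eq, EquilibriumSolution) else tuple(eq)
    fx = det_step(x, params, mode)
    residual = abs(fx[0] - x[0]) + abs(fx[1] - x[1])
    if residual > residual_tol:
        raise ValueError(
            f"point {x} is not a fixed point of det_step (residual {residual:.3e} "
            f"> {residual_tol:.1e}); iterate to convergence first"
        )
    J = np.empty((2, 2))
    for j in range(2):
        hi = list(x)
        lo = list(x)
        hi[j] += step
        lo[j] -= step
        f_hi = det_step(tuple(hi), params, mode)
        f_lo = det_step(tuple(lo), params, mode)
        J[:, j] = (np.array(f_hi) - np.array(f_lo)) / (2 * step)
    return float(np.max(np.abs(np.linalg.eigvals(J))))
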