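"""Adsorption kinetics of a tethered ideal chain zipping onto a line of receptors.

A Gaussian chain of ``N`` segments of length ``b`` is grafted to a flat
reflecting surface and carries ``M`` binding ligands spaced ``delta_N = N/M``
monomers apart; their matching receptors sit ``delta_a`` apart in a straight
line on the surface.  The model in this module is built in four stages, in
the order the physics unfolds:

1. *Tethered-end binding* -- the mean first-passage time (MFPT) for a chain
   end to reach a hemispherical capture zone of radius ``eps`` at distance
   ``a``, dominated by the entropic barrier ``3 a^2 / (2 N b^2)`` (in units
   of k_B T) of stretching the chain.
2. *Accelerated zipper* -- full adsorption modelled as an absorbing
   continuous-time Markov chain over the number of receptors left to bind:
   single-step zipping at rate ``k_1`` plus occasional loop-forming jumps
   across ``q >= 2`` receptors at rates ``k_q``.
3. *Kinetic Monte-Carlo* -- a Gillespie simulator of the same chain, used as
   an independent stochastic check of the analytic MFPTs.
4. *Centre-of-mass drift* -- the non-equilibrium "stem and flower" effect:
   early binding events are limited by the slow relaxation of the long free
   chain rather than by reaching, which produces an optimal receptor number
   for fastest complete adhesion.

Unit convention: lengths in units of ``b`` and times in units of ``b^2/D``
(``b`` and ``D`` are kept as explicit parameters defaulting to 1 so
dimensional inputs also work).  The capture radius defaults to ``eps = b``.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

__all__ = [
    "DomainError",
    "NumericalError",
    "RangeOverflowError",
    "NoRootError",
    "ChainSpec",
    "radial_density",
    "radial_density_normalization",
    "mfpt_numeric",
    "mfpt_closed_form",
    "log_mfpt_closed_form",
    "tau_q",
    "log_tau_q",
    "loop_bind_time_nonspecific",
    "zipper_dominance_coefficient",
    "RateVector",
    "build_rate_vector",
    "build_rate_matrix",
    "MfptSolution",
    "mfpt_linear_solve",
    "mfpt_two_step_recurrence",
    "mfpt_two_step_closed",
    "mfpt_zipper_approx",
    "SimResult",
    "DoubleStepFraction",
    "simulate_absorption",
    "estimate_double_step_fraction",
    "tau_com",
    "com_ratio",
    "m_star_com",
    "m_star_drift",
    "operative_m_star",
    "RegimeSplit",
    "regime_split",
    "tau_drift",
    "AdhesionBreakdown",
    "total_adhesion_time",
    "adhesion_time_scan",
    "OptimumSearchResult",
    "optimal_receptor_number",
    "optimal_m_asymptotic",
    "ExperimentConfig",
    "run_experiment",
    "loop_cutoff_table",
    "receptor_count_table",
    "fixed_density_table",
    "adhesion_distance_table",
    "adhesion_density_table",
    "fit_loglog_slope",
    "write_table",
    "read_table",
]

logger = logging.getLogger("zipbind")

#: largest exponent representable as a double; beyond it results are reported
#: in log-space only.
_LOG_MAX = math.log(sys.float_info.max)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class NumericalError(RuntimeError):
    """A quadrature or root solve failed to reach its requested accuracy.

    Attributes
    ----------
    achieved : float
        The relative accuracy actually achieved (or ``nan`` if unknown).
    """

    def __init__(self, message: str, achieved: float = math.nan):
        super().__init__(message)
        self.achieved = achieved


class RangeOverflowError(OverflowError):
    """A time is too large to materialise in linear space.

    ``log_value`` carries the natural log of the result so callers can keep
    working in log-space.
    """

    def __init__(self, message: str, log_value: float):
        super().__init__(message)
        self.log_value = log_value


class NoRootError(RuntimeError):
    """A bracketed root solve found no sign change over the scanned interval."""

    def __init__(self, message: str, interval: tuple[float, float]):
        super().__init__(message)
        self.interval = interval


# ---------------------------------------------------------------------------
# Chain / receptor geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpec:
    """Physical parameters of the chain and the receptor line.

    Parameters
    ----------
    N : int
        Chain length in segments.
    b : float
        Segment (Kuhn) length.
    D : float
        Diffusion coefficient of a single monomer, ``k_B T / gamma``.
    eps : float, optional
        Capture radius of the hemispherical reaction zone around a receptor.
        Defaults to ``b``.
    M : int
        Number of binding ligands / receptors (1 allowed).
    delta_a : float
        Spacing between consecutive receptors along the surface.

    Notes
    -----
    For multi-receptor work the ligands are evenly spaced, so ``N`` must be
    divisible by ``M``; the constructor rejects specs violating this.
    """

    N: int
    b: float = 1.0
    D: float = 1.0
    eps: float | None = None
    M: int = 1
    delta_a: float = 0.0

    def __post_init__(self):
        if self.eps is None:
            object.__setattr__(self, "eps", self.b)
        if self.N < 1 or int(self.N) != self.N:
            raise DomainError(f"N must be a positive integer, got {self.N}")
        if self.M < 1 or int(self.M) != self.M:
            raise DomainError(f"M must be a positive integer, got {self.M}")
        if self.b <= 0 or self.D <= 0 or self.eps <= 0:
            raise DomainError("b, D and eps must all be positive")
        if self.delta_a < 0:
            raise DomainError(f"delta_a must be >= 0, got {self.delta_a}")
        if self.N % self.M != 0:
            raise DomainError(
                f"N={self.N} is not divisible by M={self.M}: ligands cannot "
                "be spaced evenly along the chain"
            )

    @property
    def a(self) -> float:
        """Distance from the grafting point to the last receptor, ``M * delta_a``."""
        return self.M * self.delta_a

    @property
    def delta_N(self) -> int:
        """Number of chain segments between consecutive ligands, ``N // M``."""
        return self.N // self.M


# ---------------------------------------------------------------------------
# Stage 1: single tethered-ligand binding
# ---------------------------------------------------------------------------

def radial_density(rho: float, spec: ChainSpec, a: float) -> float:
    """Effective radial density of the chain end about a receptor at distance ``a``.

    The end of a chain grafted at the origin next to a reflecting wall has an
    effective radial distribution, as a function of the distance ``rho`` from
    the receptor::

        P_eq(rho) = (2 b / a) sqrt(N pi / 6) (3 / (2 pi N b^2))^{3/2}
                    exp(-3 (a^2 + rho^2) / (2 N b^2)) I_1(3 a rho / N b^2)

    with ``I_1`` the modified Bessel function of the first kind.  The product
    ``exp(-x) I_1(y)`` is evaluated through the exponentially scaled Bessel
    function, so the expression is overflow-safe for arbitrarily stretched
    configurations (the net exponent is ``-3 (rho - a)^2 / (2 N b^2) <= 0``).

    Under the hemispherical measure ``2 pi rho^2 d rho`` this density
    integrates to 1 (see :func:`radial_density_normalization`).
    """
    if a <= 0:
        raise DomainError(f"receptor distance a must be > 0, got {a}")
    if rho < 0:
        raise DomainError(f"rho must be >= 0, got {rho}")
    Nb2 = spec.N * spec.b**2
    y = 3.0 * a * rho / Nb2
    pref = (2.0 * spec.b / a) * math.sqrt(spec.N * math.pi / 6.0) \
        * (3.0 / (2.0 * math.pi * Nb2)) ** 1.5
    # i1e(y) = exp(-y) I_1(y);  exp(y - 3(a^2+rho^2)/(2Nb^2)) = exp(-3(rho-a)^2/(2Nb^2))
    return pref * special.i1e(y) * math.exp(-3.0 * (rho - a) ** 2 / (2.0 * Nb2))


def _rho_max(spec: ChainSpec, a: float) -> float:
    # truncation 12 standard deviations of the free-end distribution past the
    # target: residual mass < 1e-30
    return a + 12.0 * math.sqrt(spec.N * spec.b**2 / 3.0)


def radial_density_normalization(spec: ChainSpec, a: float,
                                 rel_tol: float = 1e-10) -> float:
    """Integral of :func:`radial_density` under the measure ``2 pi rho^2 d rho``."""
    val, err = integrate.quad(
        lambda r: 2.0 * math.pi * r * r * radial_density(r, spec, a),
        0.0, _rho_max(spec, a), epsrel=rel_tol, limit=400,
    )
    return val


def mfpt_numeric(spec: ChainSpec, a: float, rel_tol: float = 1e-8) -> float:
    """Mean first-passage time for the chain end to reach the capture zone.

    Evaluates the first-passage integral over the equilibrium radial density::

        tau_on = 2 pi int_eps^inf d rho [D rho^2 P_eq(rho)]^{-1}
                 [int_rho^inf d rho' rho'^2 P_eq(rho')]^2

    by nested adaptive quadrature (both integrals truncated twelve standard
    deviations of the free-end distribution past ``a``).  This is the slow,
    assumption-free route; :func:`mfpt_closed_form` is the closed-form limit
    used to build all multi-receptor rates.

    Raises
    ------
    NumericalError
        If the quadrature cannot reach ``rel_tol``; the achieved relative
        accuracy is attached to the exception.
    """
    if spec.eps <= 0:
        raise DomainError("eps must be > 0")
    if a <= 0:
        raise DomainError(f"receptor distance a must be > 0, got {a}")
    rmax = _rho_max(spec, a)

    def inner(rho: float) -> float:
        val, _ = integrate.quad(
            lambda r: r * r * radial_density(r, spec, a), rho, rmax,
            epsrel=1e-10, limit=200,
        )
        return val

    def outer_integrand(rho: float) -> float:
        dens = radial_density(rho, spec, a)
        return inner(rho) ** 2 / (spec.D * rho * rho * dens)

    val, err = integrate.quad(outer_integrand, spec.eps, rmax,
                              epsrel=rel_tol, limit=400)
    if not math.isfinite(val) or val <= 0:
        raise NumericalError("first-passage quadrature returned a non-finite "
                             f"or non-positive value {val}")
    achieved = err / val
    if achieved > 10.0 * rel_tol:
        raise NumericalError(
            f"first-passage quadrature reached relative accuracy {achieved:.2e}"
            f" (requested {rel_tol:.2e})", achieved=achieved)
    return 2.0 * math.pi * val


def log_mfpt_closed_form(spec: ChainSpec, a: float) -> float:
    """Natural log of :func:`mfpt_closed_form`; always finite, never overflows."""
    if a < 0:
        raise DomainError(f"receptor distance a must be >= 0, got {a}")
    return _log_tau_on_real(spec.N, a, spec.b, spec.D, spec.eps)


def _log_tau_on_real(N: float, a: float, b: float, D: float, eps: float) -> float:
    # log of  N^2 b^4 / (9 D eps^2) * exp(3 a^2 / (2 N b^2));  N real-valued
    return (2.0 * math.log(N) + 4.0 * math.log(b)
            - math.log(9.0 * D) - 2.0 * math.log(eps)
            + 3.0 * a * a / (2.0 * N * b * b))


def _materialise(log_value: float, what: str) -> float:
    if log_value > _LOG_MAX:
        raise RangeOverflowError(
            f"{what} overflows double precision; ln(value) = {log_value:.6g}",
            log_value=log_value)
    return math.exp(log_value)


def mfpt_closed_form(spec: ChainSpec, a: float) -> float:
    """Closed-form tethered binding time across the entropic barrier.

    ``tau_on(a, N) = N^2 b^4 / (9 D eps^2) * exp(3 a^2 / (2 N b^2))``:
    the small-``eps`` limit of the first-passage integral (the ratio
    numeric/closed-form tends to 1 as ``eps -> 0``).  Evaluated in log-space;
    a result beyond double range raises :class:`RangeOverflowError` carrying
    the log of the value.
    """
    return _materialise(log_mfpt_closed_form(spec, a), "tethered binding time")


def _log_tau_1a(spec: ChainSpec) -> float:
    # single-step time tau_1a = tau_on(delta_a, N/M): sub-chain of delta_N
    # segments reaching one receptor spacing.
    return _log_tau_on_real(spec.delta_N, spec.delta_a, spec.b, spec.D, spec.eps)


def log_tau_q(q: int, spec: ChainSpec) -> float:
    """Natural log of :func:`tau_q` (overflow-safe)."""
    if not 1 <= q <= spec.M:
        raise DomainError(f"loop size q must lie in [1, M={spec.M}], got {q}")
    x = 3.0 * spec.M * spec.delta_a**2 / (2.0 * spec.N * spec.b**2)
    return 2.0 * math.log(q) + (q - 1) * x + _log_tau_1a(spec)


def tau_q(q: int, spec: ChainSpec) -> float:
    """Time to bind a receptor ``q`` spacings beyond the last bound site.

    A loop of ``q * delta_N`` monomers must stretch to ``q * delta_a``::

        tau_qa = q^2 exp(3 (q - 1) M delta_a^2 / (2 N b^2)) * tau_1a

    For ``delta_a = 0`` the ratio ``tau_qa / tau_1a`` is exactly ``q^2``;
    for ``delta_a > 0`` the entropic barrier makes long loops rapidly more
    expensive.
    """
    return _materialise(log_tau_q(q, spec), f"loop binding time tau_{q}a")


def loop_bind_time_nonspecific(q: int, spec: ChainSpec) -> float:
    """Binding time of the ``q``-th ligand along the chain to the *nearest* receptor.

    Relevant for non-specific binding, where any ligand can take the closest
    free receptor (distance ``delta_a``) by looping ``q * delta_N`` monomers::

        tau_1a(q) = q^2 exp((1/q - 1) * 3 M delta_a^2 / (2 N b^2)) * tau_1a
    """
    if q < 1:
        raise DomainError(f"loop size q must be >= 1, got {q}")
    x = 3.0 * spec.M * spec.delta_a**2 / (2.0 * spec.N * spec.b**2)
    return _materialise(2.0 * math.log(q) + (1.0 / q - 1.0) * x
                        + _log_tau_1a(spec), "non-specific loop binding time")


def zipper_dominance_coefficient(q: float) -> float:
    """Coefficient ``3 (1 - 1/q) / (4 ln q)`` in the zipper-dominance condition.

    Non-specific binding follows the sequential zipper pathway (no competition
    of distant ligands for the nearest receptor) when
    ``(N/M) b^2 >> [3 (1 - 1/q) / (4 ln q)] a^2`` for all loop sizes ``q``.
    The coefficient decreases with ``q``, so ``q = 2`` is the binding case:
    ``3 / (8 ln 2) = 0.5410...``, i.e. the condition ``N b^2 >> 0.54 a^2``.

    The public contract is integer ``q >= 2``; real-valued ``q`` is accepted
    for monotonicity probing only.
    """
    if q < 2:
        raise DomainError(f"q must be >= 2 (ln 1 = 0 at q = 1), got {q}")
    return 3.0 * (1.0 - 1.0 / q) / (4.0 * math.log(q))


# ---------------------------------------------------------------------------
# Stage 2: the accelerated zipper as an absorbing Markov chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateVector:
    """Binding rates ``k_q = 1/tau_qa`` for loop sizes ``q = 1..q_max``.

    Jumps larger than ``q_max`` are forbidden (rate exactly 0).  Rates are
    stored together with their logs so extremely slow channels survive
    underflow in downstream log-space work.
    """

    rates: np.ndarray
    M: int
    log_rates: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if rates.ndim != 1 or len(rates) < 1:
            raise DomainError("rates must be a non-empty 1-D array")
        if not 1 <= len(rates) <= self.M:
            raise DomainError(
                f"q_max={len(rates)} must lie in [1, M={self.M}]")
        if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
            raise DomainError("all rates k_q for q <= q_max must be finite and > 0")
        if self.log_rates is None:
            object.__setattr__(self, "log_rates", np.log(rates))

    @property
    def q_max(self) -> int:
        return len(self.rates)

    @classmethod
    def from_rates(cls, rates, M: int) -> "RateVector":
        return cls(rates=np.asarray(rates, dtype=float), M=M)


def build_rate_vector(spec: ChainSpec, q_max: int | None = None) -> RateVector:
    """Rates ``k_q = 1 / tau_q(q)`` for the accelerated zipper.

    ``q_max`` defaults to 2, the operative approximation for well-separated
    receptors (``delta_a^2 >= delta_N b^2``); pass ``q_max = M`` for the full
    loop spectrum.
    """
    if q_max is None:
        q_max = min(2, spec.M)
    if not 1 <= q_max <= spec.M:
        raise DomainError(f"q_max={q_max} must lie in [1, M={spec.M}]")
    logs = np.array([-log_tau_q(q, spec) for q in range(1, q_max + 1)])
    return RateVector(rates=np.exp(logs), M=spec.M, log_rates=logs)


def build_rate_matrix(rv: RateVector) -> np.ndarray:
    """Dense ``(M+1) x (M+1)`` generator of the absorbing zipper chain.

    Row ``r`` describes the state with ``R = M - r`` receptors remaining:
    off-diagonal entries ``k_1 .. k_min(R, q_max)`` (a jump of ``q`` binds the
    receptor ``q`` spacings ahead; the skipped "middle" ligands bind fast and
    are not rate-limiting), diagonal minus the row sum, and an all-zero final
    absorbing row.
    """
    M, qmax = rv.M, rv.q_max
    Q = np.zeros((M + 1, M + 1))
    for r in range(M):
        R = M - r
        ks = rv.rates[: min(R, qmax)]
        Q[r, r + 1: r + 1 + len(ks)] = ks
        Q[r, r] = -ks.sum()
    return Q


@dataclass(frozen=True)
class MfptSolution:
    """Mean times ``<tau(i)>`` to full adsorption from ``i`` remaining receptors.

    ``times[i]`` is the mean first-passage time to the absorbing state from
    the state with ``i`` receptors still unbound; ``times[0] = 0``.
    """

    times: np.ndarray
    method: str

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.method not in {"linear_solve", "recurrence", "closed_form",
                               "approximation"}:
            raise DomainError(f"unknown method tag {self.method!r}")
        if t[0] != 0.0:
            raise DomainError("<tau(0)> must be 0")

    @property
    def total(self) -> float:
        """Mean time to bind all ``M`` receptors from the bare tethered state."""
        return float(self.times[-1])


def mfpt_linear_solve(rv: RateVector) -> MfptSolution:
    """MFPTs from the backward-Kolmogorov relations of the zipper generator.

    Solves ``sum_j Q_ij <tau_j> = -1`` for every non-absorbing state.  Because
    the generator is triangular in the remaining-receptor count the system is
    solved by a single back-substitution sweep, O(M * q_max)::

        <tau(R)> = (1 + sum_{q<=min(R,q_max)} k_q <tau(R-q)>) / sum k_q
    """
    M, qmax = rv.M, rv.q_max
    t = np.zeros(M + 1)
    for R in range(1, M + 1):
        ks = rv.rates[: min(R, qmax)]
        t[R] = (1.0 + float(ks @ t[R - len(ks): R][::-1])) / ks.sum()
    return MfptSolution(times=t, method="linear_solve")


def mfpt_two_step_recurrence(k1: float, k2: float, M: int) -> MfptSolution:
    """Two-channel zipper MFPT by direct recurrence.

    With jumps truncated at ``q = 2`` the backward relations reduce to::

        <tau(1)> = 1/k1,   <tau(2)> = 2/(k1 + k2),
        (k1 + k2) <tau(M)> = 1 + k1 <tau(M-1)> + k2 <tau(M-2)>   (M >= 3)
    """
    if M < 1:
        raise DomainError(f"M must be >= 1, got {M}")
    if k1 <= 0 or k2 < 0:
        raise DomainError("need k1 > 0 and k2 >= 0")
    t = np.zeros(M + 1)
    t[1] = 1.0 / k1
    if M >= 2:
        t[2] = 2.0 / (k1 + k2)
    for R in range(3, M + 1):
        t[R] = (1.0 + k1 * t[R - 1] + k2 * t[R - 2]) / (k1 + k2)
    return MfptSolution(times=t, method="recurrence")


def mfpt_two_step_closed(k1: float, k2: float, M: int) -> float:
    """Generating-function solution of the two-channel zipper recurrence.

    ::

        <tau(M)> = [M k1^2 + 2 (M+1) k1 k2
                    + 2 k2^2 (1 + (-k2/(k1+k2))^{M-1})] / [k1 (k1 + 2 k2)^2]

    The alternating term is evaluated via powers of the exact ratio (never in
    log-space) to preserve its sign.
    """
    if M < 1:
        raise DomainError(f"M must be >= 1, got {M}")
    if k1 <= 0 or k2 < 0:
        raise DomainError("need k1 > 0 and k2 >= 0")
    ratio = -k2 / (k1 + k2)
    num = (M * k1 * k1 + 2.0 * (M + 1) * k1 * k2
           + 2.0 * k2 * k2 * (1.0 + ratio ** (M - 1)))
    return num / (k1 * (k1 + 2.0 * k2) ** 2)


def mfpt_zipper_approx(spec: ChainSpec) -> float:
    """First-order accelerated-zipper time for well-separated receptors.

    Taylor expansion of the two-channel closed form in ``k2/k1 << 1``::

        <tau(M)> ~= (M - (M-1)/2 * exp(-3 M delta_a^2 / (2 N b^2))) * tau_1a

    i.e. the pure zipper ``M tau_1a`` minus the mean saving from occasional
    double steps.  Intended for ``delta_a^2 >= delta_N b^2``; outside that
    regime a warning is logged (the expansion degrades, it does not fail).
    """
    x = 3.0 * spec.M * spec.delta_a**2 / (2.0 * spec.N * spec.b**2)
    if spec.delta_a**2 < spec.delta_N * spec.b**2:
        logger.warning(
            "mfpt_zipper_approx outside its validity regime: delta_a^2=%.4g "
            "< delta_N b^2=%.4g (k2 is not << k1)",
            spec.delta_a**2, spec.delta_N * spec.b**2)
    factor = spec.M - 0.5 * (spec.M - 1) * math.exp(-x)
    return factor * _materialise(_log_tau_1a(spec), "single-step time tau_1a")


# ---------------------------------------------------------------------------
# Stage 3: kinetic Monte-Carlo oracle for the zipper chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimResult:
    """Outcome of a batch of Gillespie trajectories of the zipper chain."""

    mean_time: float
    sem: float
    n_traj: int
    seed: int
    jump_histogram: np.ndarray      # counts of jump sizes q = 1..q_max
    times: np.ndarray               # per-trajectory absorption times
    jumps_per_traj: np.ndarray      # per-trajectory jump counts

    def to_table(self) -> pd.DataFrame:
        """Per-trajectory output: trajectory id, absorption time, number of jumps."""
        return pd.DataFrame({
            "trajectory": np.arange(self.n_traj),
            "absorption_time": self.times,
            "n_jumps": self.jumps_per_traj,
        })


@dataclass(frozen=True)
class DoubleStepFraction:
    """Fraction of all jumps that were loops (``q >= 2``), with binomial SE."""

    fraction: float
    stderr: float
    n_jumps: int


def simulate_absorption(rv: RateVector, n_traj: int, seed: int,
                        max_events: int = 10**8) -> SimResult:
    """Gillespie simulation of the absorbing zipper chain.

    Every trajectory starts with all ``M`` receptors unbound.  From a state
    with ``R`` remaining receptors the waiting time is exponential with total
    rate ``sum_{q <= min(R, q_max)} k_q`` and the jump size is chosen with
    probability proportional to ``k_q`` (a single uniform against cumulative
    rate fractions).  All randomness comes from one ``numpy`` generator seeded
    with ``seed``, so results are bitwise reproducible for a given
    ``(seed, n_traj)``.

    ``max_events`` caps the total number of jumps across all trajectories to
    guard against misconfigured near-zero-rate states.
    """
    if n_traj < 1:
        raise DomainError(f"n_traj must be >= 1, got {n_traj}")
    M, qmax = rv.M, rv.q_max
    rng = np.random.default_rng(seed)

    # per-state total rates and cumulative channel fractions, indexed by R
    total_rate = np.zeros(M + 1)
    cum = np.ones((M + 1, qmax))    # cum[R, j] = P(q <= j+1 | state R)
    for R in range(1, M + 1):
        ks = rv.rates[: min(R, qmax)]
        total_rate[R] = ks.sum()
        c = np.cumsum(ks) / total_rate[R]
        cum[R, : len(ks)] = c
        cum[R, len(ks):] = 1.0

    remaining = np.full(n_traj, M, dtype=np.int64)
    t = np.zeros(n_traj)
    n_jumps = np.zeros(n_traj, dtype=np.int64)
    hist = np.zeros(qmax, dtype=np.int64)
    events = 0
    while True:
        active = np.flatnonzero(remaining > 0)
        if active.size == 0:
            break
        R = remaining[active]
        t[active] += rng.exponential(1.0, active.size) / total_rate[R]
        u = rng.random(active.size)
        # jump size: first cumulative fraction exceeding u
        q = 1 + (u[:, None] > cum[R, :]).sum(axis=1)
        hist += np.bincount(q - 1, minlength=qmax)
        remaining[active] = R - q
        n_jumps[active] += 1
        events += active.size
        if events > max_events:
            raise NumericalError(
                f"simulation exceeded the event cap of {max_events} jumps; "
                "check the rate vector for near-zero rates")
    mean = float(t.mean())
    sem = float(t.std(ddof=1) / math.sqrt(n_traj)) if n_traj > 1 else 0.0
    return SimResult(mean_time=mean, sem=sem, n_traj=n_traj, seed=seed,
                     jump_histogram=hist, times=t, jumps_per_traj=n_jumps)


def estimate_double_step_fraction(rv: RateVector, n_traj: int,
                                  seed: int) -> DoubleStepFraction:
    """Fraction of binding events that proceeded through a loop (``q >= 2``).

    A rate vector with ``q_max = 1`` has the loop channel closed, so the
    fraction is exactly 0.
    """
    res = simulate_absorption(rv, n_traj, seed)
    n = int(res.jump_histogram.sum())
    frac = float(res.jump_histogram[1:].sum() / n)
    se = math.sqrt(frac * (1.0 - frac) / n)
    return DoubleStepFraction(fraction=frac, stderr=se, n_jumps=n)


# ---------------------------------------------------------------------------
# Stage 4: centre-of-mass drift and the optimal receptor number
# ---------------------------------------------------------------------------

def tau_com(N_f: float, delta_a: float, D: float = 1.0) -> float:
    """Time for the free-chain centre of mass to *diffuse* one receptor spacing.

    ``tau_com = N_f delta_a^2 / D``: the free chain of ``N_f`` monomers drags
    with friction ``N_f gamma``, so its centre-of-mass diffusivity is ``D/N_f``.
    """
    if N_f < 1:
        raise DomainError(f"N_f must be >= 1, got {N_f}")
    if delta_a < 0:
        raise DomainError(f"delta_a must be >= 0, got {delta_a}")
    return N_f * delta_a**2 / D


def tau_drift(N_f: float, b: float = 1.0, D: float = 1.0) -> float:
    """Relaxation time of the free chain to its new equilibrium position.

    After a binding event the remaining ``N_f`` free monomers find their
    centre of mass ``delta_a`` out of equilibrium; the entropic spring
    ``3 k_B T / (2 N_f b^2)`` pulls them back against friction ``N_f gamma``,
    giving ``tau_drift = 2 N_f^2 b^2 / (3 D)`` -- independent of the distance
    travelled.
    """
    if N_f < 1:
        raise DomainError(f"N_f must be >= 1, got {N_f}")
    return 2.0 * N_f**2 * b**2 / (3.0 * D)


def com_ratio(spec: ChainSpec, m: int) -> float:
    """Ratio ``tau_com / tau_1a`` at the ``m``-th binding event.

    ``9 N_f eps^2 delta_a^2 / (delta_N^2 b^4) * exp(-3 delta_a^2 / (2 delta_N b^2))``
    with ``N_f = (M - m + 1) delta_N`` free monomers remaining.  The
    equilibrium binding theory needs this ratio to be small.
    """
    if not 1 <= m <= spec.M:
        raise DomainError(f"event index m must lie in [1, M={spec.M}], got {m}")
    dN, da = spec.delta_N, spec.delta_a
    N_f = (spec.M - m + 1) * dN
    return (9.0 * N_f * spec.eps**2 * da**2 / (dN**2 * spec.b**4)
            * math.exp(-3.0 * da**2 / (2.0 * dN * spec.b**2)))


def _m_star_com_real(M: float, N: float, a: float, eps: float, b: float) -> float:
    if a <= 0:
        raise DomainError("m_star_com undefined at a = 0")
    return (M + 1.0
            - (M * N * b**4 / (9.0 * eps**2 * a**2))
            * math.exp(3.0 * a * a / (2.0 * M * N * b * b)))


def _m_star_drift_real(M: float, N: float, a: float, eps: float, b: float) -> float:
    return (M + 1.0
            - (b / (eps * math.sqrt(6.0)))
            * math.exp(3.0 * a * a / (4.0 * M * N * b * b)))


def m_star_com(spec: ChainSpec) -> float:
    """Crossover event index from equality of ``tau_com`` and ``tau_1a``.

    ``m*_com = M + 1 - (M N b^4 / 9 eps^2 a^2) exp(3 a^2 / 2 M N b^2)``.
    Events with ``m`` well below this are out of equilibrium.  The value is
    real and may be negative; it is *not* clamped here.
    """
    return _m_star_com_real(spec.M, spec.N, spec.a, spec.eps, spec.b)


def m_star_drift(spec: ChainSpec) -> float:
    """Crossover event index from equality of ``tau_drift`` and ``tau_1a``.

    ``m*_drift = M + 1 - (1/sqrt 6)(b/eps) exp(3 a^2 / 4 M N b^2)``.  Events
    before it are limited by centre-of-mass relaxation, events after it by the
    reaching time.  Unclamped real value.
    """
    return _m_star_drift_real(spec.M, spec.N, spec.a, spec.eps, spec.b)


def operative_m_star(spec: ChainSpec) -> int:
    """The integer crossover used to split the adhesion-time sum.

    The drift-condition crossover, floored and clamped into ``[0, M]``.  The
    two crossover expressions are numerically close; the drift one is used
    operatively because the total-time partition asks precisely whether the
    relaxation time dominates an event.
    """
    return _clamped_m_star(m_star_drift(spec), spec.M)


def _clamped_m_star(ms_real: float, M: int) -> int:
    return int(min(max(math.floor(ms_real), 0), M))


@dataclass(frozen=True)
class RegimeSplit:
    """Diagnostic view of the drift/reach partition of the ``M`` binding events."""

    m_star_com: float       # real crossover from the diffusion condition
    m_star_drift: float     # real crossover from the relaxation condition
    m_star: int             # operative integer crossover (floored, clamped)
    M: int
    delta_N: int

    def n_free(self, m: int) -> int:
        """Free monomers remaining at event ``m``: ``(M - m + 1) delta_N``."""
        if not 1 <= m <= self.M:
            raise DomainError(f"event index m must lie in [1, M={self.M}]")
        return (self.M - m + 1) * self.delta_N


def regime_split(spec: ChainSpec) -> RegimeSplit:
    """Compute both crossover indices and the operative split for ``spec``."""
    return RegimeSplit(
        m_star_com=m_star_com(spec),
        m_star_drift=m_star_drift(spec),
        m_star=operative_m_star(spec),
        M=spec.M,
        delta_N=spec.delta_N,
    )


@dataclass(frozen=True)
class AdhesionBreakdown:
    """Total adhesion time split into drift-limited and reach-limited parts."""

    total_time: float
    drift_part: float
    reach_part: float
    m_star: int


def _sum_sq(n: int) -> int:
    # sum of squares 1^2 + ... + n^2
    return n * (n + 1) * (2 * n + 1) // 6


def _total_adhesion_real(M: int, delta_N: float, delta_a: float, eps: float,
                         b: float, D: float,
                         accelerated: bool = False) -> AdhesionBreakdown:
    """Adhesion time with ``delta_N``, ``delta_a`` treated as reals (scan path)."""
    N = M * delta_N
    a = M * delta_a
    ms = _clamped_m_star(_m_star_drift_real(M, N, a, eps, b), M)
    # drift sum: sum_{m=1}^{m*} 2 ((M-m+1) delta_N)^2 b^2 / 3D
    #          = (2 delta_N^2 b^2 / 3D) * [S(M) - S(M - m*)]
    drift = (2.0 * delta_N**2 * b**2 / (3.0 * D)) * (_sum_sq(M) - _sum_sq(M - ms))
    n_reach = M - ms
    if n_reach == 0:
        reach = 0.0
    else:
        tau1 = _materialise(_log_tau_on_real(delta_N, delta_a, b, D, eps),
                            "single-step time tau_1a")
        if accelerated:
            x = 3.0 * delta_a**2 / (2.0 * delta_N * b**2)
            reach = (n_reach - 0.5 * (n_reach - 1) * math.exp(-x)) * tau1
        else:
            reach = n_reach * tau1
    return AdhesionBreakdown(total_time=drift + reach, drift_part=drift,
                             reach_part=reach, m_star=ms)


def total_adhesion_time(spec: ChainSpec,
                        accelerated: bool = False) -> AdhesionBreakdown:
    """Total time to adsorb the whole chain onto the receptor line.

    The first ``m*`` binding events (long free chain) are limited by
    centre-of-mass relaxation, the remaining ``M - m*`` by the reaching time::

        tau = sum_{m=1}^{m*} tau_drift(N_f(m)) + (M - m*) tau_1a

    with ``N_f(m) = (M - m + 1) delta_N`` and ``m*`` the operative crossover.
    When ``m* < 1`` (always the case at small ``M``) this reduces exactly to
    the simple linear zipper ``M tau_1a``.  The drift sum is evaluated through
    the sum-of-squares identity rather than term by term.

    ``accelerated=True`` replaces the reach part with the first-order
    accelerated-zipper time over the remaining ``M - m*`` receptors; by
    default the (weaker) loop acceleration is neglected.
    """
    return _total_adhesion_real(spec.M, spec.delta_N, spec.delta_a,
                                spec.eps, spec.b, spec.D, accelerated)


def adhesion_time_scan(N: float, a: float, M_values, eps: float = 1.0,
                       b: float = 1.0, D: float = 1.0,
                       accelerated: bool = False) -> np.ndarray:
    """Total adhesion time over a range of receptor numbers at fixed ``N, a``.

    ``delta_a = a/M`` and ``delta_N = N/M`` are treated as reals for every
    ``M`` (no divisibility requirement), matching the continuous treatment of
    ``M`` in the optimum analysis.
    """
    return np.array([
        _total_adhesion_real(int(M), N / M, a / M, eps, b, D,
                             accelerated).total_time
        for M in M_values])


def optimal_m_asymptotic(N: float, a: float, eps: float = 1.0,
                         b: float = 1.0) -> float:
    """Leading-order optimal receptor number in the far-stretched limit.

    For ``a^2 >> N b^2``::

        M_opt ~= (3 a^2 / 4 N b^2) / ln[(9 a^2 / 16 N b^2)(eps/b) sqrt(3/2)]

    The logarithm's prefactor ``(9/16) sqrt(3/2) = 0.6889...`` rounds to 0.69.
    """
    arg = (9.0 * a * a / (16.0 * N * b * b)) * (eps / b) * math.sqrt(1.5)
    if arg <= 1.0:
        raise DomainError(
            f"asymptotic optimum undefined: log argument {arg:.4g} <= 1 "
            "(need a^2 sufficiently above N b^2)")
    return (3.0 * a * a / (4.0 * N * b * b)) / math.log(arg)


@dataclass(frozen=True)
class OptimumSearchResult:
    """Optimal receptor number: discrete scan, stationarity root and asymptote."""

    M_discrete: int
    M_root: float
    M_asymptotic: float
    search_range: tuple[int, int]
    M_values: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)


def optimal_receptor_number(N: float, a: float, eps: float = 1.0,
                            b: float = 1.0, D: float = 1.0,
                            search_max: int | None = None) -> OptimumSearchResult:
    """Receptor number minimising the total adhesion time at fixed ``N`` and ``a``.

    Three routes, reported side by side:

    * ``M_discrete`` -- argmin of the drift/reach partitioned time over
      integer ``M`` in ``[1, search_max]`` with ``delta_a = a/M``,
      ``delta_N = N/M`` real;
    * ``M_root`` -- the real root of the stationarity condition
      ``16 N eps^3 M^4 = 2 sqrt(6) a^2 b exp(9 a^2 / 4 M N b^2)``, solved on
      the *logs* of the two sides (they differ by hundreds of orders of
      magnitude in linear space) with a bracket grown by doubling from
      ``M = 1``;
    * ``M_asymptotic`` -- the leading-order estimate,
      :func:`optimal_m_asymptotic`.

    Valid in the stretched regime ``a^2 > N b^2``.
    """
    if a * a <= N * b * b:
        raise DomainError(
            f"optimum analysis requires a^2 > N b^2, got a^2/(N b^2) = "
            f"{a * a / (N * b * b):.4g}")
    if search_max is not None and search_max < 2:
        raise DomainError(f"search_max must be >= 2, got {search_max}")

    M_asym = optimal_m_asymptotic(N, a, eps, b)
    if search_max is None:
        search_max = max(200, math.ceil(4.0 * M_asym))

    M_values = np.arange(1, search_max + 1)
    times = adhesion_time_scan(N, a, M_values, eps, b, D)
    M_discrete = int(M_values[int(np.argmin(times))])

    # log of LHS minus log of RHS: monotone increasing in M
    def g(M: float) -> float:
        return (math.log(16.0 * N * eps**3) + 4.0 * math.log(M)
                - math.log(2.0 * math.sqrt(6.0) * a * a * b)
                - 9.0 * a * a / (4.0 * M * N * b * b))

    lo, hi = 1.0, 2.0
    if g(lo) > 0.0:          # root below 1: shrink the lower edge instead
        lo, hi = 1e-6, 1.0
    else:
        while g(hi) < 0.0:
            lo, hi = hi, hi * 2.0
            if hi > 1e9:
                raise NoRootError(
                    "no sign change found for the optimum stationarity "
                    f"condition on [1, {hi:g}]", interval=(1.0, hi))
    if g(lo) * g(hi) > 0.0:
        raise NoRootError(
            "no sign change for the optimum stationarity condition "
            f"on [{lo:g}, {hi:g}]", interval=(lo, hi))
    M_root = float(optimize.brentq(g, lo, hi, xtol=1e-10, rtol=1e-12))

    return OptimumSearchResult(
        M_discrete=M_discrete, M_root=M_root, M_asymptotic=M_asym,
        search_range=(1, search_max), M_values=M_values, times=times)


# ---------------------------------------------------------------------------
# Experiment drivers: tabular regeneration of the standard scans
# ---------------------------------------------------------------------------

_EXPERIMENTS = ("loop_cutoff", "zipper_scan", "zipper_density",
                "adhesion_scan", "adhesion_density", "single", "optimal")


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment run.

    ``experiment`` is one of ``loop_cutoff`` (adsorption time vs maximum
    allowed loop size), ``zipper_scan`` (time vs M at fixed chain length),
    ``zipper_density`` (time vs M at fixed ligand density), ``adhesion_scan``
    (drift-partitioned time vs M at fixed chain length, several distances),
    ``adhesion_density`` (drift-partitioned time vs M at fixed density, with
    end slopes), ``single`` (one tethered binding time) or ``optimal``
    (optimal receptor number).  ``params`` overrides that experiment's
    keyword defaults.
    """

    experiment: str
    params: dict = field(default_factory=dict)
    out: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in _EXPERIMENTS:
            raise DomainError(
                f"unknown experiment {self.experiment!r}; "
                f"expected one of {_EXPERIMENTS}")


def loop_cutoff_table(M: int = 20, spacing_ratio: float = 1.0) -> pd.DataFrame:
    """Scaled adsorption time versus the largest allowed loop size.

    For a chain with ``M`` receptors, computes ``<tau(M)>`` in units of
    ``tau_1a`` as jumps up to ``q_max = 1..M`` are switched on, in two cases:

    * ``tau_dense`` -- receptors so close the entropic factor is 1
      (``delta_a = 0``: rates ``k_q = k_1/q^2``, the maximum acceleration);
    * ``tau_spaced`` -- spaced receptors with
      ``delta_a^2 = spacing_ratio * delta_N b^2`` (default ratio 1), where the
      acceleration beyond ``q_max = 2`` is nearly negligible.
    """
    rows = []
    for qmax in range(1, M + 1):
        qs = np.arange(1, qmax + 1)
        dense = RateVector.from_rates(1.0 / qs**2, M)
        spaced = RateVector.from_rates(
            np.exp(-1.5 * spacing_ratio * (qs - 1)) / qs**2, M)
        rows.append({
            "q_max": qmax,
            "tau_dense": mfpt_linear_solve(dense).total,
            "tau_spaced": mfpt_linear_solve(spaced).total,
        })
    return pd.DataFrame(rows)


def _two_step_rates_real(delta_N: float, delta_a: float, b: float, D: float,
                         eps: float) -> tuple[float, float]:
    log_k1 = -_log_tau_on_real(delta_N, delta_a, b, D, eps)
    x = 3.0 * delta_a**2 / (2.0 * delta_N * b**2)
    log_k2 = log_k1 - math.log(4.0) - x
    return math.exp(log_k1), math.exp(log_k2)


def receptor_count_table(N: float = 100.0, a: float = 40.0,
                         M_values=None, b: float = 1.0, D: float = 1.0,
                         eps: float | None = None) -> pd.DataFrame:
    """Adsorption time versus receptor number at fixed chain length.

    For each ``M`` (with ``delta_a = a/M``, ``delta_N = N/M`` real):
    the exact two-channel time ``tau_exact``, its first-order approximation
    ``tau_approx``, and the strict single-step zipper ``tau_zipper = M tau_1a``.
    Times in units of ``b^2/D``.
    """
    eps = b if eps is None else eps
    if M_values is None:
        M_values = np.arange(1, 21)
    rows = []
    for M in M_values:
        M = int(M)
        dN, da = N / M, a / M
        k1, k2 = _two_step_rates_real(dN, da, b, D, eps)
        x = 3.0 * da**2 / (2.0 * dN * b**2)
        tau1 = 1.0 / k1
        rows.append({
            "M": M,
            "tau_exact": mfpt_two_step_closed(k1, k2, M),
            "tau_approx": (M - 0.5 * (M - 1) * math.exp(-x)) * tau1,
            "tau_zipper": M * tau1,
        })
    return pd.DataFrame(rows)


def fixed_density_table(delta_N: int = 20, a_over_Nb: float = 0.3,
                        M_values=None, b: float = 1.0, D: float = 1.0,
                        eps: float | None = None) -> pd.DataFrame:
    """Adsorption time versus chain length at fixed ligand/receptor density.

    The chain grows with the receptor count (``N = M delta_N``) and the end
    target sits at ``a = a_over_Nb * N * b``, so ``delta_a = a/M`` is fixed.
    Adds ``tau_single``: the single-ligand chain reaching the same distance
    ``a`` in one step, whose time grows exponentially with ``N`` while the
    zipper grows only linearly.
    """
    eps = b if eps is None else eps
    if M_values is None:
        M_values = np.arange(1, 21)
    da = a_over_Nb * delta_N * b
    rows = []
    for M in M_values:
        M = int(M)
        N = M * delta_N
        a = a_over_Nb * N * b
        k1, k2 = _two_step_rates_real(delta_N, da, b, D, eps)
        x = 3.0 * da**2 / (2.0 * delta_N * b**2)
        tau1 = 1.0 / k1
        log_single = _log_tau_on_real(N, a, b, D, eps)
        rows.append({
            "M": M,
            "N": N,
            "tau_exact": mfpt_two_step_closed(k1, k2, M),
            "tau_approx": (M - 0.5 * (M - 1) * math.exp(-x)) * tau1,
            "tau_zipper": M * tau1,
            "tau_single": math.exp(log_single) if log_single < _LOG_MAX
            else math.inf,
            "log_tau_single": log_single,
        })
    return pd.DataFrame(rows)


def adhesion_distance_table(N: float = 100.0, a_values=(40.0, 60.0, 80.0),
                            M_values=None, eps: float = 1.0, b: float = 1.0,
                            D: float = 1.0) -> pd.DataFrame:
    """Drift-partitioned adhesion time versus ``M`` for several end distances.

    The default distances ``a in {40, 60, 80} b`` are representative package
    defaults.  Also emits the reach-limited reference ``M tau_1a`` (the
    dashed line the drift-limited curves peel away from) and the operative
    crossover ``m_star``.
    """
    if M_values is None:
        M_values = np.arange(1, 201)
    rows = []
    for a in a_values:
        for M in M_values:
            M = int(M)
            dN, da = N / M, a / M
            bd = _total_adhesion_real(M, dN, da, eps, b, D)
            log_t1 = _log_tau_on_real(dN, da, b, D, eps)
            rows.append({
                "a": a, "M": M,
                "tau_total": bd.total_time,
                "tau_reach_reference": M * math.exp(log_t1)
                if log_t1 + math.log(M) < _LOG_MAX else math.inf,
                "m_star": bd.m_star,
            })
    return pd.DataFrame(rows)


def adhesion_density_table(delta_N: float = 10.0,
                           spacing_factors=(1.0, 1.5, 2.0),
                           M_values=None, eps: float = 1.0, b: float = 1.0,
                           D: float = 1.0,
                           slope_window: int = 5) -> pd.DataFrame:
    """Drift-partitioned adhesion time versus ``M`` at fixed ligand density.

    For each spacing ``delta_a = factor * sqrt(delta_N b^2)`` the chain grows
    with the receptor count (``N = M delta_N``).  On a log-log scale the
    curves show a reach-limited region of slope 1 at small ``M`` (extended for
    larger spacings) crossing over to the relaxation-limited cubic regime,
    slope 3, at large ``M``.  The table carries local least-squares slopes
    fitted over the first/last ``slope_window`` points of each curve in the
    ``slope_small`` / ``slope_large`` columns.
    """
    if M_values is None:
        M_values = np.unique(np.round(np.logspace(0, 3, 25)).astype(int))
    M_values = np.asarray(M_values, dtype=int)
    frames = []
    for fac in spacing_factors:
        da = fac * math.sqrt(delta_N) * b
        recs = []
        for M in M_values:
            bd = _total_adhesion_real(int(M), delta_N, da, eps, b, D)
            recs.append({"spacing_factor": fac, "M": int(M),
                         "tau_total": bd.total_time, "m_star": bd.m_star})
        df = pd.DataFrame(recs)
        w = min(slope_window, len(df))
        df["slope_small"] = fit_loglog_slope(df["M"][:w], df["tau_total"][:w])
        df["slope_large"] = fit_loglog_slope(df["M"][-w:], df["tau_total"][-w:])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fit_loglog_slope(x, y) -> float:
    """Least-squares slope of ``log y`` against ``log x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise DomainError("need at least two points to fit a slope")
    return float(np.polyfit(np.log(x), np.log(y), 1)[0])


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Dispatch an :class:`ExperimentConfig` to its driver and return the table."""
    p = dict(cfg.params)
    if cfg.experiment == "loop_cutoff":
        return loop_cutoff_table(**p)
    if cfg.experiment == "zipper_scan":
        return receptor_count_table(**p)
    if cfg.experiment == "zipper_density":
        return fixed_density_table(**p)
    if cfg.experiment == "adhesion_scan":
        return adhesion_distance_table(**p)
    if cfg.experiment == "adhesion_density":
        return adhesion_density_table(**p)
    if cfg.experiment == "single":
        spec = ChainSpec(N=int(p.get("N", 100)), b=p.get("b", 1.0),
                         D=p.get("D", 1.0), eps=p.get("eps"))
        a = float(p.get("a", 10.0))
        row = {"N": spec.N, "a": a,
               "tau_closed_form": mfpt_closed_form(spec, a)}
        if p.get("numeric", False):
            row["tau_numeric"] = mfpt_numeric(spec, a)
        return pd.DataFrame([row])
    if cfg.experiment == "optimal":
        res = optimal_receptor_number(
            N=p.get("N", 100.0), a=p.get("a", 40.0), eps=p.get("eps", 1.0),
            b=p.get("b", 1.0), D=p.get("D", 1.0),
            search_max=p.get("search_max"))
        return pd.DataFrame([{
            "M_discrete": res.M_discrete, "M_root": res.M_root,
            "M_asymptotic": res.M_asymptotic,
            "search_lo": res.search_range[0], "search_hi": res.search_range[1],
            "tau_min": float(res.times.min()),
        }])
    raise DomainError(f"unknown experiment {cfg.experiment!r}")


# ---------------------------------------------------------------------------
# Delimited-text output with a commented provenance header
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a scan table as CSV with a ``#``-commented header of its config."""
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"# zipbind {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (header comments skipped)."""
    return pd.read_csv(path, comment="#")
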