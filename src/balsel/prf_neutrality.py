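"""Poisson-random-field expectation for shared intermediate-frequency sites.

Under neutral divergence of two populations from a common ancestor, the
standing variants of the ancestral population enter both daughters at their
ancestral frequency y and drift independently.  With standing variation
distributed as the neutral frequency spectrum (density 2/y on (0,1), per
unit θ), the expected number of sites whose derived allele sits at an
intermediate frequency in (x, 1−x) in *both* populations after diffusion
time t is θ·H_x with

    H_x = ∫₀¹ P⁰_y(x < ξ_t < 1−x)² · (2/y) dy,

where ξ_t is a neutral Wright–Fisher diffusion started at y with absorbing
boundaries at 0 and 1, and the square reflects the two independent
daughter populations.  The probability of observing at least one such site
is p(x) = 1 − exp(−θ·H_x).

The interval-occupancy probability is evaluated by the classical spectral
expansion of the transition density.  Writing u = 1−2y, the eigenfunctions
are Jacobi polynomials P⁽¹'¹⁾ and the integral of the density over the
symmetric interval (x, 1−x) telescopes into Legendre polynomials:

    P⁰_y(x < ξ_t < 1−x)
      = Σ_{i odd} y(1−y) (2i+1)/i · P⁽¹'¹⁾_{i−1}(1−2y)
        · exp(−i(i+1) t / 2) · 2 P_i(1−2x),

with t in coalescent units of 2N generations (even-i terms vanish by the
y ↔ 1−y symmetry of the interval).  A forward binomial Wright–Fisher
Monte-Carlo oracle is included for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import eval_jacobi, eval_legendre


class SeriesConvergenceError(RuntimeError):
    pass


@dataclass
class PRFConfig:
    """Inputs of the shared-polymorphism expectation.

    x : lower frequency bound, 0 < x < 0.5 (the interval is (x, 1−x)).
    t : divergence time of each daughter population, in coalescent units
        of 2N generations.
    N : diploid population size; used only by the Monte-Carlo oracle (the
        analytic path is size-free).
    theta : population mutation rate per gene, θ = 4Nμ_gene.
    """

    x: float
    t: float
    N: int = 5_000
    theta: float = 0.0
    series_terms: int = 1_000
    quad_limit: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 0.5:
            raise ValueError("x must lie in (0, 0.5)")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass
class PRFResult:
    H_x: float
    p_x: float
    config: PRFConfig


def wf_interval_prob(
    y: float,
    t: float,
    x: float,
    series_terms: int = 1_000,
    tol: float = 1e-12,
) -> float:
    """P that a neutral WF diffusion started at y is in (x, 1−x) at time t.

    Absorbing boundaries at 0 and 1; t in units of 2N generations.  The
    spectral series is truncated once a term magnitude drops below ``tol``
    (terms decay like exp(−i(i+1)t/2), so truncation is fast for t ≳ 0.05);
    reaching ``series_terms`` without convergence raises
    :class:`SeriesConvergenceError`.
    """
    if not 0.0 < y < 1.0:
        raise ValueError("y must lie in (0, 1)")
    if not 0.0 < x < 0.5:
        raise ValueError("x must lie in (0, 0.5)")
    total = 0.0
    u_y = 1.0 - 2.0 * y
    u_x = 1.0 - 2.0 * x
    yy = y * (1.0 - y)
    last = np.inf
    for i in range(1, series_terms + 1, 2):  # even i vanish by symmetry
        term = (
            yy
            * (2 * i + 1)
            / i
            * eval_jacobi(i - 1, 1, 1, u_y)
            * np.exp(-i * (i + 1) * t / 2.0)
            * 2.0
            * eval_legendre(i, u_x)
        )
        total += term
        last = abs(term)
        if last < tol and i > 3:
            return float(min(max(total, 0.0), 1.0))
    raise SeriesConvergenceError(
        f"series not converged after {series_terms} terms "
        f"(last term magnitude {last:.3e}); increase series_terms or t"
    )


def compute_Hx(
    x: float,
    t: float,
    series_terms: int = 1_000,
    quad_limit: int = 200,
    epsabs: float = 1e-9,
) -> float:
    """H_x = ∫₀¹ P⁰_y(x < ξ_t < 1−x)² (2/y) dy by adaptive quadrature.

    The y → 0 endpoint is integrable: the occupancy probability vanishes
    linearly in y, so the integrand behaves like O(y) near zero.
    """
    if not 0.0 < x < 0.5:
        raise ValueError("x must lie in (0, 0.5)")

    def integrand(y: float) -> float:
        p = wf_interval_prob(y, t, x, series_terms=series_terms)
        return p * p * 2.0 / y

    value, residual = quad(integrand, 0.0, 1.0, limit=quad_limit, epsabs=epsabs)
    if residual > max(1e-6, 1e-4 * abs(value)):
        raise RuntimeError(
            f"quadrature failed to converge (residual estimate {residual:.2e})"
        )
    return float(value)


def prob_at_least_one(theta: float, H_x: float) -> float:
    """p(x) = 1 − exp(−θ·H_x): at least one shared intermediate-MAF site."""
    if theta < 0 or H_x < 0:
        raise ValueError("theta and H_x must be non-negative")
    return float(-np.expm1(-theta * H_x))


def evaluate(config: PRFConfig) -> PRFResult:
    h = compute_Hx(config.x, config.t, config.series_terms, config.quad_limit)
    return PRFResult(H_x=h, p_x=prob_at_least_one(config.theta, h), config=config)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator θ_W = S / Σ_{i<n} 1/i for n gene copies."""
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    if S < 0:
        raise ValueError("S must be non-negative")
    return float(S / np.sum(1.0 / np.arange(1, n)))


def wf_monte_carlo_interval_prob(
    y: float,
    t: float,
    x: float,
    N: int = 5_000,
    reps: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Forward binomial Wright–Fisher oracle for :func:`wf_interval_prob`.

    Simulates 2N gene copies for round(t·2N) generations in ``reps``
    replicates and returns (fraction ending in (x, 1−x), binomial SE).
    """
    if reps < 1_000:
        raise ValueError("need at least 1,000 replicates")
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    count = np.full(reps, int(round(y * two_n)), dtype=np.int64)
    for _ in range(int(round(t * two_n))):
        seg = (count > 0) & (count < two_n)
        if not seg.any():
            break
        count[seg] = rng.binomial(two_n, count[seg] / two_n)
    freq = count / two_n
    est = float(np.mean((freq > x) & (freq < 1.0 - x)))
    se = float(np.sqrt(est * (1.0 - est) / reps))
    return est, se
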