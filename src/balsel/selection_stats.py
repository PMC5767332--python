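"""Site-frequency-spectrum and differentiation statistics with rank-P.

F_ST (Weir & Cockerham variance components, Hudson's estimator behind a
flag), Tajima's D, Fay & Wu's H, and the empirical-rank significance scheme
in which a candidate's P is the proportion of sites in a surrounding window
whose statistic is as high as or higher than the candidate's (candidate
included in numerator and denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedStatistic(ValueError):
    """The statistic is undefined for this input (e.g. no segregating sites)."""


# ---------------------------------------------------------------------------
# F_ST


def weir_cockerham_fst(
    derived_counts: np.ndarray, sizes: np.ndarray, estimator: str = "wc"
) -> float:
    """Single-locus F_ST from per-group derived-allele counts.

    Parameters
    ----------
    derived_counts : array of shape (r,)
        Derived (or alt) allele count in each of r groups.
    sizes : array of shape (r,)
        Gene copies sampled per group (each ≥ 2).
    estimator : {"wc", "hudson"}
        "wc" is the Weir & Cockerham (1984) variance-components estimator
        for allele-count data (may be slightly negative); "hudson" is
        Hudson's two-population estimator (r must be 2).

    Raises
    ------
    UndefinedStatistic
        if the locus is monomorphic across all groups.
    """
    counts = np.asarray(derived_counts, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if counts.shape != n.shape or counts.ndim != 1 or len(n) < 2:
        raise ValueError("need per-group counts and sizes for ≥2 groups")
    if np.any(n < 2):
        raise ValueError("each group needs ≥2 gene copies")
    p = counts / n
    total = counts.sum()
    if total == 0 or total == n.sum():
        raise UndefinedStatistic("monomorphic across all groups")

    if estimator == "hudson":
        if len(p) != 2:
            raise ValueError("Hudson's estimator is for exactly 2 groups")
        num = (p[0] - p[1]) ** 2 - p[0] * (1 - p[0]) / (n[0] - 1) - p[1] * (
            1 - p[1]
        ) / (n[1] - 1)
        den = p[0] * (1 - p[1]) + p[1] * (1 - p[0])
        return float(num / den)
    if estimator != "wc":
        raise ValueError(f"unknown estimator {estimator!r}")

    r = len(p)
    nbar = n.mean()
    pbar = (n * p).sum() / n.sum()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    msp = (n * (p - pbar) ** 2).sum() / (r - 1)  # between-group mean square
    msg = (n * p * (1 - p)).sum() / (n - 1).sum()  # within-group mean square
    denom = msp + (nc - 1) * msg
    if denom == 0:
        raise UndefinedStatistic("zero variance denominator")
    return float((msp - msg) / denom)


# ---------------------------------------------------------------------------
# Site-frequency-spectrum summaries


@dataclass
class SFSSummary:
    """Derived-allele counts per segregating site in a sample of n copies."""

    n: int
    derived_counts: np.ndarray

    def __post_init__(self) -> None:
        self.derived_counts = np.asarray(self.derived_counts, dtype=np.int64)
        if np.any(self.derived_counts < 0) or np.any(self.derived_counts > self.n):
            raise ValueError("derived counts must lie in [0, n]")
        # fixed/lost columns carry no SFS information
        seg = (self.derived_counts > 0) & (self.derived_counts < self.n)
        self.derived_counts = self.derived_counts[seg]

    @property
    def S(self) -> int:
        return len(self.derived_counts)

    @property
    def pi(self) -> float:
        """Mean pairwise diversity Σ 2 i (n−i) / (n(n−1)) over sites."""
        i = self.derived_counts.astype(float)
        n = self.n
        return float((2.0 * i * (n - i)).sum() / (n * (n - 1)))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, derived_is_one: bool = True) -> "SFSSummary":
        m = np.asarray(matrix)
        counts = m.sum(axis=0) if derived_is_one else (m.shape[0] - m.sum(axis=0))
        return cls(n=m.shape[0], derived_counts=counts)


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n, dtype=float)
    return float((1.0 / i**power).sum())


def tajimas_d(sfs: SFSSummary) -> float:
    """Tajima's D: standardized π − S/a₁ with the usual constants.

    Negative D marks an excess of rare variants; positive D an excess of
    intermediate-frequency variants, the signature of balancing selection.
    Polarity of the counts is irrelevant (π and S are fold-invariant).
    """
    n, S = sfs.n, sfs.S
    if n < 4:
        raise ValueError("Tajima's D needs n ≥ 4")
    if S == 0:
        raise UndefinedStatistic("no segregating sites")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((sfs.pi - S / a1) / np.sqrt(var))


def fay_wu_h(sfs: SFSSummary, standardized: bool = False) -> float:
    """Fay & Wu's H = θ_π − θ_H on polarized derived counts.

    θ_H up-weights high-frequency derived alleles; strongly negative H marks
    an excess of them (hitchhiking).  ``standardized=True`` returns the
    Zeng et al. (2006) normalized version.
    """
    n, S = sfs.n, sfs.S
    if S == 0:
        raise UndefinedStatistic("no polarizable segregating sites")
    i = sfs.derived_counts.astype(float)
    denom = n * (n - 1.0)
    theta_pi = float((2.0 * i * (n - i)).sum() / denom)
    theta_h = float((2.0 * i**2).sum() / denom)
    h = theta_pi - theta_h
    if not standardized:
        return h
    a1 = _harmonic(n)
    bn1 = _harmonic(n + 1, 2)
    theta_w = S / a1
    theta_sq = S * (S - 1.0) / (a1**2 + _harmonic(n, 2))
    var = (
        (n - 2.0) / (6.0 * (n - 1.0)) * theta_w
        + (
            18.0 * n**2 * (3.0 * n + 2.0) * bn1
            - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
        )
        / (9.0 * n * (n - 1.0) ** 2)
        * theta_sq
    )
    return float(h / np.sqrt(var))


# ---------------------------------------------------------------------------
# Empirical-rank significance


def empirical_rank_p(candidate_value: float, window_values: np.ndarray) -> float:
    """Rank-based empirical P of a candidate inside its window.

    P = (# window values ≥ candidate, candidate itself included) / (# window
    values).  The candidate must be a member of ``window_values``; the
    smallest attainable P is 1/len(window_values).
    """
    vals = np.asarray(window_values, dtype=float)
    if vals.size == 0:
        raise ValueError("window is empty")
    if not np.any(np.isclose(vals, candidate_value, rtol=0, atol=1e-12)):
        raise ValueError("candidate value is not among the window values")
    return float((vals >= candidate_value).sum() / vals.size)


@dataclass
class ScanResult:
    position: int
    statistic: str
    value: float
    window: tuple[int, int]
    rank_p: float


def window_scan(
    positions: np.ndarray,
    values: np.ndarray,
    candidate_position: int,
    statistic: str = "",
    window_bp: int = 2_000_000,
    chromosome_length: int | None = None,
) -> ScanResult:
    """Rank-P of a candidate site within a window centred on it.

    The window has total width ``window_bp`` (default 2 Mbp), centred on the
    candidate and clipped at position 1 and ``chromosome_length``.  Sites
    with non-finite values (e.g. monomorphic F_ST) are excluded from the
    rank distribution.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    half = window_bp // 2
    lo = max(1, candidate_position - half)
    hi = candidate_position + half
    if chromosome_length is not None:
        hi = min(hi, chromosome_length)
    inside = (positions >= lo) & (positions <= hi) & np.isfinite(values)
    idx = np.flatnonzero(positions == candidate_position)
    if idx.size == 0 or not inside[idx[0]]:
        raise ValueError("candidate position not in window")
    cand = values[idx[0]]
    return ScanResult(
        position=candidate_position,
        statistic=statistic,
        value=float(cand),
        window=(lo, hi),
        rank_p=empirical_rank_p(cand, values[inside]),
    )
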