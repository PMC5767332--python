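"""Windowed MAF-rank outlier test for nonsynonymous candidate sites.

A balanced polymorphism should have an unusually high minor allele
frequency compared with other nonsynonymous SNPs.  The test places a wide
window (90.3 Mbp by default — the length of human chromosome 16, so the
same width fits each chromosome studied) around the candidate, restricts
to biallelic nonsynonymous SNPs, and reports P = (number of such SNPs with
MAF ≥ the candidate's, the candidate itself included) / (total number in
the window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_BP = 90_300_000


@dataclass
class MafWindow:
    """Nonsynonymous-SNP MAFs in a fixed-width window around a candidate."""

    chromosome: str
    window: tuple[int, int]
    positions: np.ndarray
    mafs: np.ndarray
    candidate_position: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.positions.shape != self.mafs.shape:
            raise ValueError("positions and MAFs must align")
        if np.any((self.mafs < 0) | (self.mafs > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")
        lo, hi = self.window
        if not lo <= self.candidate_position <= hi:
            raise ValueError("candidate must lie inside the window")
        if self.candidate_position not in self.positions:
            raise ValueError("candidate position missing from site list")


def build_window(
    chromosome: str,
    positions: np.ndarray,
    mafs: np.ndarray,
    is_nonsynonymous: np.ndarray,
    candidate_position: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    chromosome_length: int | None = None,
) -> MafWindow:
    """Restrict a site list to biallelic nonsynonymous SNPs in the window.

    The window is centred on the candidate and clipped at position 1 and at
    ``chromosome_length`` without re-expansion.
    """
    positions = np.asarray(positions, dtype=np.int64)
    mafs = np.asarray(mafs, dtype=float)
    keep = np.asarray(is_nonsynonymous, dtype=bool)
    half = window_bp // 2
    lo = max(1, candidate_position - half)
    hi = candidate_position + half
    if chromosome_length is not None:
        hi = min(hi, chromosome_length)
    mask = keep & (positions >= lo) & (positions <= hi)
    return MafWindow(
        chromosome=chromosome,
        window=(lo, hi),
        positions=positions[mask],
        mafs=mafs[mask],
        candidate_position=candidate_position,
    )


def maf_rank_test(window: MafWindow) -> tuple[int, int, float]:
    """(count_ge, n_total, p) for the candidate's MAF rank in its window.

    ``count_ge`` counts sites with MAF ≥ the candidate's, the candidate
    itself included, so the smallest attainable P is 1/n_total.
    """
    n_total = int(window.mafs.size)
    if n_total == 0:
        raise ValueError("no nonsynonymous SNPs in window")
    cand = window.mafs[window.positions == window.candidate_position]
    candidate_maf = float(cand.max())
    count_ge = int((window.mafs >= candidate_maf).sum())
    return count_ge, n_total, count_ge / n_total


def rank_p_from_counts(count_ge: int, n_total: int) -> float:
    """P from pre-tabulated counts (count includes the candidate)."""
    if n_total <= 0 or count_ge <= 0 or count_ge > n_total:
        raise ValueError("counts must satisfy 0 < count_ge <= n_total")
    return count_ge / n_total
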