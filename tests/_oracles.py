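"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — direct
enumeration over haplotype pairs, textbook formula transcriptions — and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pairwise_pi(matrix: np.ndarray) -> float:
    """Mean pairwise difference by explicit all-pairs Hamming distance."""
    rows = np.asarray(matrix)
    total = 0
    n = rows.shape[0]
    for a, b in combinations(range(n), 2):
        total += int((rows[a] != rows[b]).sum())
    return total / (n * (n - 1) / 2)


def tajimas_d_reference(matrix: np.ndarray) -> float:
    """Tajima's D from the original constant definitions, written anew."""
    m = np.asarray(matrix)
    n = m.shape[0]
    counts = m.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    pi = pairwise_pi(m[:, seg])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def weir_cockerham_reference(derived: np.ndarray, sizes: np.ndarray) -> float:
    """θ̂ via the a/b variance components for haploid (gene-copy) samples."""
    derived = np.asarray(derived, float)
    n = np.asarray(sizes, float)
    p = derived / n
    r = len(p)
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    # Weir & Cockerham (1984) components for haploid (gene-copy) data:
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    )
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a / (a + b)


def ehh_by_pair_enumeration(
    matrix: np.ndarray, carrier_rows: np.ndarray, cols: list[int]
) -> float:
    """EHH over an ordered column span by enumerating carrier pairs."""
    rows = np.asarray(matrix)[np.asarray(carrier_rows)]
    k = rows.shape[0]
    identical = 0
    for a, b in combinations(range(k), 2):
        if all(rows[a, c] == rows[b, c] for c in cols):
            identical += 1
    return identical / (k * (k - 1) / 2)


def chi2_reference(observed: np.ndarray) -> tuple[float, int]:
    """Pearson χ² and df by direct cellwise summation."""
    obs = np.asarray(observed, float)
    n = obs.sum()
    chi2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / n
            chi2 += (obs[i, j] - e) ** 2 / e
    return chi2, (obs.shape[0] - 1) * (obs.shape[1] - 1)


def substitute_reference(
    cds: str, cds_indices: list[int], alts: list[str], carry: list[bool]
) -> str:
    """Per-base substitution of carried alt alleles into a CDS string."""
    out = list(cds)
    for idx, alt, c in zip(cds_indices, alts, carry):
        if c:
            out[idx] = alt
    return "".join(out)


def polarize_reference(
    ref: str, alt: str, outgroups: list[str]
) -> tuple[str, str] | None:
    """Unanimity polarization, re-derived: all outgroups must agree and
    match one human allele."""
    if len(set(outgroups)) != 1:
        return None
    state = outgroups[0]
    if state == ref:
        return (ref, alt)
    if state == alt:
        return (alt, ref)
    return None
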