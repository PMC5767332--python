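"""EHH decay, iHS and XP-EHH with frequency-bin z-score standardization.

EHH at distance x from a core site is the probability that two haplotypes
drawn without replacement from the carriers of a core allele are identical
over every SNP between the core and x (the unbiased pairwise form,
Σ C(k_j,2)/C(K,2) over prefix groups).  iHS is ln(iHH_ancestral /
iHH_derived) where iHH is the trapezoidal integral of EHH against physical
distance, both directions from the core, truncated where EHH drops below a
cutoff.  XP-EHH integrates the population-level EHH (all haplotypes, no
allele partition) and compares two populations at the same core.

Raw scores are standardized within derived-allele-frequency bins (20 equal
bins by default): z = (raw − bin mean)/bin sd, with a two-sided normal P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .haplotype_io import PhasedHaplotypeSet

EHH_TRUNCATION = 0.05      # stop integrating once EHH decays below this
MAX_GAP_BP = 200_000       # inter-SNP gap beyond which integration truncates
MAF_FLOOR = 0.05           # minimum core MAF for iHS


class BoundarySite(ValueError):
    """EHH never decayed below the cutoff within the data extent."""


@dataclass
class EHHDecay:
    core_position: int
    core_allele: str                 # "ancestral" | "derived" | "all"
    offsets: np.ndarray              # genomic positions, outward from core
    ehh: np.ndarray                  # EHH value at each offset; ehh[0] == 1


def _prefix_ehh(matrix: np.ndarray) -> np.ndarray:
    """EHH at each column for rows of ``matrix``, refining prefix groups.

    Column order is the order of traversal away from the core.  Returns the
    pairwise homozygosity after including each successive column.
    """
    k = matrix.shape[0]
    pairs_total = k * (k - 1) / 2.0
    groups = np.zeros(k, dtype=np.int64)
    out = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        # refine each identity group by the allele carried at column j
        groups = groups * 2 + matrix[:, j]
        _, counts = np.unique(groups, return_counts=True)
        out[j] = (counts * (counts - 1) / 2.0).sum() / pairs_total
        # re-label compactly so the group key cannot overflow
        _, groups = np.unique(groups, return_inverse=True)
    return out


def ehh(
    hapset: PhasedHaplotypeSet,
    core_index: int,
    core_allele: int | None,
    direction: str,
) -> EHHDecay:
    """EHH decay from a core site in one direction.

    ``core_allele`` is 0 (ref) or 1 (alt) to restrict to carriers, or None
    for the population-level EHH over all haplotypes (XP-EHH).  ``direction``
    is "left" or "right".  Needs ≥2 carrier haplotypes.
    """
    m = hapset.haplotype_matrix
    if core_allele is None:
        rows = np.arange(m.shape[0])
        label = "all"
    else:
        rows = np.flatnonzero(m[:, core_index] == core_allele)
        label = str(core_allele)
    if rows.size < 2:
        raise ValueError("EHH needs at least 2 carrier haplotypes")
    if direction == "right":
        cols = np.arange(core_index, hapset.n_sites)
    elif direction == "left":
        cols = np.arange(core_index, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    values = _prefix_ehh(m[np.ix_(rows, cols)])
    return EHHDecay(
        core_position=int(hapset.positions[core_index]),
        core_allele=label,
        offsets=hapset.positions[cols],
        ehh=values,
    )


def _ihh_one_side(
    decay: EHHDecay,
    truncation: float = EHH_TRUNCATION,
    max_gap: int = MAX_GAP_BP,
) -> tuple[float, bool]:
    """Trapezoidal integral of one EHH decay curve vs physical distance.

    Integration stops at the first SNP where EHH < ``truncation`` (the
    segment down to the cutoff is included via linear interpolation) or at a
    gap larger than ``max_gap``.  Returns (iHH, decayed_below_cutoff).
    """
    pos = np.abs(decay.offsets.astype(float) - decay.core_position)
    e = decay.ehh
    total = 0.0
    for j in range(1, len(e)):
        gap = pos[j] - pos[j - 1]
        if gap > max_gap:
            return total, False
        if e[j] < truncation:
            # integrate only up to where the curve crosses the cutoff
            frac = (e[j - 1] - truncation) / (e[j - 1] - e[j])
            total += 0.5 * (e[j - 1] + truncation) * gap * frac
            return total, True
        total += 0.5 * (e[j - 1] + e[j]) * gap
    return total, False


def integrated_ehh(
    hapset: PhasedHaplotypeSet,
    core_index: int,
    core_allele: int | None,
    truncation: float = EHH_TRUNCATION,
    max_gap: int = MAX_GAP_BP,
    require_decay: bool = True,
) -> float:
    """iHH: summed left+right trapezoidal integrals of the EHH curve."""
    total = 0.0
    decayed = []
    for direction in ("left", "right"):
        d = ehh(hapset, core_index, core_allele, direction)
        part, dec = _ihh_one_side(d, truncation, max_gap)
        total += part
        decayed.append(dec)
    if require_decay and not all(decayed):
        raise BoundarySite(
            f"EHH did not decay below {truncation} on both sides of "
            f"position {hapset.positions[core_index]}"
        )
    return total


def ihs(
    hapset: PhasedHaplotypeSet,
    core_index: int,
    derived_allele: str,
    maf_floor: float = MAF_FLOOR,
    require_decay: bool = False,
) -> float:
    """Raw iHS = ln(iHH_ancestral / iHH_derived) at a polarized core site."""
    alt_is_derived = derived_allele.upper() == hapset.alt_allele[core_index].upper()
    if not alt_is_derived and derived_allele.upper() != hapset.ref_allele[
        core_index
    ].upper():
        raise ValueError("derived allele matches neither ref nor alt")
    col = hapset.haplotype_matrix[:, core_index]
    p_alt = col.mean()
    maf = min(p_alt, 1 - p_alt)
    if maf < maf_floor:
        raise ValueError(f"core MAF {maf:.3f} below floor {maf_floor}")
    derived_code = 1 if alt_is_derived else 0
    ihh_d = integrated_ehh(hapset, core_index, derived_code, require_decay=require_decay)
    ihh_a = integrated_ehh(hapset, core_index, 1 - derived_code, require_decay=require_decay)
    if ihh_a <= 0 or ihh_d <= 0:
        raise UndefinedIHH(
            f"zero integrated EHH at position {hapset.positions[core_index]}"
        )
    return float(np.log(ihh_a / ihh_d))


class UndefinedIHH(ValueError):
    pass


def xp_ehh(
    hapset_a: PhasedHaplotypeSet,
    hapset_b: PhasedHaplotypeSet,
    core_position: int,
    require_decay: bool = False,
) -> float:
    """Raw XP-EHH = ln(iHH_A / iHH_B) at a shared core site (A over B)."""
    results = []
    for hs in (hapset_a, hapset_b):
        idx = np.flatnonzero(hs.positions == core_position)
        if idx.size == 0:
            raise ValueError(f"core position {core_position} absent from one group")
        results.append(
            integrated_ehh(hs, int(idx[0]), None, require_decay=require_decay)
        )
    if min(results) <= 0:
        raise UndefinedIHH(f"zero integrated EHH at position {core_position}")
    return float(np.log(results[0] / results[1]))


# ---------------------------------------------------------------------------
# Frequency-bin standardization


@dataclass
class StandardizedScore:
    raw: float
    bin_index: int
    z: float
    p: float


def standardize_by_frequency_bins(
    raw_scores: np.ndarray,
    derived_freqs: np.ndarray,
    n_bins: int = 20,
) -> list[StandardizedScore]:
    """z-score each raw score against the other SNPs in its frequency bin.

    Bins are equal-width on [0, 1].  A bin with fewer than two scores, or
    with zero spread, leaves its sites unstandardized (z = p = NaN) with a
    warning.  P is the two-sided standard-normal tail probability.
    """
    raw = np.asarray(raw_scores, dtype=float)
    freqs = np.asarray(derived_freqs, dtype=float)
    if raw.shape != freqs.shape:
        raise ValueError("scores and frequencies must align")
    bins = np.clip((freqs * n_bins).astype(int), 0, n_bins - 1)
    z = np.full_like(raw, np.nan)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        if mask.sum() < 2:
            warnings.warn(f"frequency bin {b} has a single site; left unstandardized")
            continue
        sd = raw[mask].std(ddof=0)
        if sd == 0:
            warnings.warn(f"frequency bin {b} has zero spread; left unstandardized")
            continue
        z[mask] = (raw[mask] - raw[mask].mean()) / sd
    p = 2.0 * norm.sf(np.abs(z))
    return [
        StandardizedScore(raw=float(r), bin_index=int(b), z=float(zz), p=float(pp))
        for r, b, zz, pp in zip(raw, bins, z, p)
    ]
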