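"""McDonald–Kreitman tests and the two-locus genotype-association LD test.

The MK test contrasts the nonsynonymous/synonymous split of within-species
polymorphisms against that of fixed differences from an outgroup CDS in a
2×2 table.  The genotype-association test asks whether two-locus genotype
counts (rows = copies of the derived allele at locus 1, columns = locus 2)
depart from independence by Pearson χ²; persistent association between
physically unlinked loci implicates selection on genotype combinations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import fisher_exact
from Bio.Seq import Seq


@dataclass
class MKTable:
    poly_ns: float
    poly_s: float
    fixed_ns: float
    fixed_s: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.poly_ns, self.poly_s], [self.fixed_ns, self.fixed_s]], float
        )


def _codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (nonsyn, syn) step counts over single-step mutational paths.

    For codons differing at k positions, every ordering of the k single-base
    steps is enumerated; paths passing through a stop codon are discarded.
    Standard MK path-averaging for multi-hit codons.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    ns_tot = s_tot = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = codon_a
        ns = s = 0
        ok = True
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i:][1:]
            aa_cur = str(Seq(cur).translate())
            aa_nxt = str(Seq(nxt).translate())
            if aa_nxt == "*":
                ok = False
                break
            if aa_cur == aa_nxt:
                s += 1
            else:
                ns += 1
            cur = nxt
        if ok:
            ns_tot += ns
            s_tot += s
            n_paths += 1
    if n_paths == 0:  # every path hits a stop; count nothing
        return 0.0, 0.0
    return ns_tot / n_paths, s_tot / n_paths


def mk_counts(human_alignment: list[str], outgroup_cds: str) -> MKTable:
    """Classify sites as polymorphic-within vs fixed-between, syn vs nonsyn.

    ``human_alignment`` is a list of equal-length coding sequences (one per
    gene copy); ``outgroup_cds`` is a single outgroup CDS of the same
    length.  A codon position that is polymorphic in humans contributes to
    the polymorphism counts only, never simultaneously to the fixed counts;
    a position monomorphic in humans but differing from the outgroup is a
    fixed difference.  Changes creating a stop (nonsense) are excluded.
    """
    if not human_alignment:
        raise ValueError("empty human alignment")
    L = len(outgroup_cds)
    if any(len(s) != L for s in human_alignment):
        raise ValueError("human and outgroup CDS lengths differ")
    if L % 3:
        raise ValueError("CDS length must be divisible by 3")

    human = [s.upper() for s in human_alignment]
    out = outgroup_cds.upper()
    table = MKTable(0.0, 0.0, 0.0, 0.0)

    for c in range(L // 3):
        sl = slice(3 * c, 3 * c + 3)
        codons = {h[sl] for h in human}
        poly_pos = [i for i in range(3) if len({cd[i] for cd in codons}) > 1]
        # within-human polymorphism: average over observed codon pairs is
        # overkill for biallelic data; classify each segregating position in
        # the context of the major-allele codon at the other positions.
        if poly_pos:
            common = Counter(h[sl] for h in human).most_common(1)[0][0]
            for i in poly_pos:
                alleles = {cd[i] for cd in codons}
                base_codon = common
                for alt in alleles - {base_codon[i]}:
                    alt_codon = base_codon[:i] + alt + base_codon[i + 1 :]
                    aa_ref = str(Seq(base_codon).translate())
                    aa_alt = str(Seq(alt_codon).translate())
                    if aa_alt == "*" or aa_ref == "*":
                        continue  # nonsense: excluded from MK counts
                    if aa_ref == aa_alt:
                        table.poly_s += 1
                    else:
                        table.poly_ns += 1
        # fixed differences at positions monomorphic in humans
        human_codon = next(iter(codons)) if len(codons) == 1 else None
        if human_codon is None:
            # compare only the monomorphic positions of a multi-state codon
            mono = [i for i in range(3) if i not in poly_pos]
            ref = next(iter(codons))
            fixed_pos = [i for i in mono if ref[i] != out[sl][i]]
            if fixed_pos:
                # substitute human major-allele context
                common = Counter(h[sl] for h in human).most_common(1)[0][0]
                target = "".join(
                    out[sl][i] if i in fixed_pos else common[i] for i in range(3)
                )
                ns, s = _codon_path_counts(common, target)
                table.fixed_ns += ns
                table.fixed_s += s
        else:
            ns, s = _codon_path_counts(human_codon, out[sl])
            table.fixed_ns += ns
            table.fixed_s += s
    return table


def mk_test(table: MKTable, fisher_fallback: bool = True) -> tuple[float, float]:
    """Pearson χ² (df=1, no continuity correction) on the 2×2 MK table.

    With a zero margin the χ² is undefined; Fisher's exact test is used
    instead when ``fisher_fallback`` (the default), else an error is raised.
    """
    obs = table.as_array()
    if obs.min() < 0:
        raise ValueError("negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if rows.min() == 0 or cols.min() == 0:
        if not fisher_fallback:
            raise ValueError("zero margin in MK table and Fisher fallback disabled")
        _, p = fisher_exact(np.round(obs).astype(int))
        return float("nan"), float(p)
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(chi2_dist.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Two-locus genotype association


@dataclass
class GenotypeContingency:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


def expected_independence(observed: np.ndarray) -> np.ndarray:
    """Independence expectations: E[i,j] = row_i · col_j / N."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n


def genotype_association(observed: np.ndarray) -> GenotypeContingency:
    """Pearson χ² test of two-locus genotype independence.

    Rows and columns with zero margin are dropped and the degrees of
    freedom adjusted to (r−1)(c−1) on the retained table.  No continuity
    correction is applied.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed must be a 2-D table")
    if obs.min() < 0:
        raise ValueError("negative counts")
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    trimmed = obs[np.ix_(keep_r, keep_c)]
    r, c = trimmed.shape
    if r < 2 or c < 2:
        raise ValueError("table is degenerate after dropping empty margins")
    expected = expected_independence(trimmed)
    chi2 = float(((trimmed - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return GenotypeContingency(
        observed=trimmed,
        expected=expected,
        chi2=chi2,
        df=df,
        p=float(chi2_dist.sf(chi2, df)),
    )
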