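"""Codon consequence, ancestral/derived polarization, allele frequencies.

Each biallelic coding SNP is classified by its effect on the codon it falls
in (synonymous / nonsynonymous / nonsense), polarized against one or more
outgroup alleles (unanimity required), and summarized as per-group derived
allele frequencies plus the pooled minor allele frequency (MAF, folded at
0.5 over all gene copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .haplotype_io import _COMPLEMENT, GeneModel, PhasedHaplotypeSet


@dataclass
class SiteAnnotation:
    label: str
    position: int
    codon_index: int          # 1-based codon number
    codon_position: int       # 1, 2 or 3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str          # synonymous | nonsynonymous | nonsense
    ancestral_allele: str | None = None
    derived_allele: str | None = None
    group_freqs: dict[str, float] = field(default_factory=dict)
    maf: float = float("nan")

    @property
    def polarizable(self) -> bool:
        return self.ancestral_allele is not None


def classify_site(gene: GeneModel, position: int, alt_base: str) -> SiteAnnotation:
    """Codon consequence of substituting ``alt_base`` at a genomic position.

    ``alt_base`` is given on the forward genomic strand (VCF convention) and
    is complemented internally for minus-strand genes.  Positions outside
    the gene's exons raise ValueError.
    """
    idx = gene.cds_index(position)  # raises outside exons
    alt = alt_base.upper()
    if gene.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    cds = gene.reference_cds.upper()
    codon_index = idx // 3 + 1
    codon_pos = idx % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start : start + 3]
    alt_codon = ref_codon[: codon_pos - 1] + alt + ref_codon[codon_pos:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        consequence = "nonsense"
    elif ref_aa == alt_aa:
        consequence = "synonymous"
    else:
        consequence = "nonsynonymous"
    return SiteAnnotation(
        label=f"{gene.chromosome}:{position}",
        position=position,
        codon_index=codon_index,
        codon_position=codon_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


def polarize(
    ref_allele: str, alt_allele: str, outgroup_alleles: list[str]
) -> tuple[str, str] | None:
    """(ancestral, derived) from unanimous outgroup evidence, else None.

    The ancestral state is the human allele matched by *all* supplied
    outgroup alleles; disagreement among outgroups, or an outgroup state
    matching neither human allele, leaves the site unpolarizable (None),
    which excludes it from Fay & Wu's H and iHS polarity.
    """
    if not outgroup_alleles:
        raise ValueError("at least one outgroup allele is required")
    states = {a.upper() for a in outgroup_alleles}
    if len(states) != 1:
        return None
    out = states.pop()
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if out == ref:
        return ref, alt
    if out == alt:
        return alt, ref
    return None


def allele_frequencies(
    hapset: PhasedHaplotypeSet,
    site_index: int,
    derived_allele: str | None = None,
) -> tuple[dict[str, float], float]:
    """Per-group derived-allele frequency and pooled folded MAF for a site.

    ``derived_allele`` names which of ref/alt is derived; when None (site
    unpolarizable) the ALT allele is used for the per-group frequencies.
    The MAF is computed over the pooled gene copies, min(p, 1-p), and does
    not depend on polarity.
    """
    col = hapset.haplotype_matrix[:, site_index].astype(float)
    if derived_allele is None or derived_allele.upper() == hapset.alt_allele[
        site_index
    ].upper():
        derived = col
    elif derived_allele.upper() == hapset.ref_allele[site_index].upper():
        derived = 1.0 - col
    else:
        raise ValueError(
            f"derived allele {derived_allele} matches neither ref nor alt"
        )
    groups = np.array(hapset.row_groups())
    freqs = {g: float(derived[groups == g].mean()) for g in sorted(set(groups))}
    p = float(derived.mean())
    maf = min(p, 1.0 - p)
    if maf == 0.0:
        import warnings

        warnings.warn(
            f"site {hapset.positions[site_index]} is monomorphic (MAF 0)",
            stacklevel=2,
        )
    return freqs, maf


def annotate_sites(
    hapset: PhasedHaplotypeSet,
    gene: GeneModel,
    outgroups: dict[int, list[str]] | None = None,
) -> list[SiteAnnotation]:
    """Full annotation for every site of a hapset that lies inside the gene.

    ``outgroups`` maps genomic position → list of outgroup alleles (forward
    strand); sites without outgroup data stay unpolarized.
    """
    out = []
    for j, pos in enumerate(hapset.positions):
        pos = int(pos)
        if not gene.contains(pos):
            continue
        ann = classify_site(gene, pos, hapset.alt_allele[j])
        if outgroups and pos in outgroups:
            pol = polarize(
                hapset.ref_allele[j], hapset.alt_allele[j], outgroups[pos]
            )
            if pol is not None:
                ann.ancestral_allele, ann.derived_allele = pol
        ann.group_freqs, ann.maf = allele_frequencies(
            hapset, j, ann.derived_allele
        )
        out.append(ann)
    return out


def read_outgroup_tsv(paths: list[str]) -> dict[int, list[str]]:
    """Combine two-column (position, base) TSVs, one per outgroup."""
    table: dict[int, list[str]] = {}
    for path in paths:
        df = pd.read_csv(path, sep="\t", header=None, names=["position", "base"],
                         comment="#")
        for pos, base in zip(df["position"].astype(int), df["base"].astype(str)):
            table.setdefault(pos, []).append(base)
    return table


def annotations_to_frame(annotations: list[SiteAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {
            "label": a.label,
            "position": a.position,
            "codon_index": a.codon_index,
            "codon_position": a.codon_position,
            "ref_codon": a.ref_codon,
            "alt_codon": a.alt_codon,
            "ref_aa": a.ref_aa,
            "alt_aa": a.alt_aa,
            "consequence": a.consequence,
            "ancestral_allele": a.ancestral_allele or "",
            "derived_allele": a.derived_allele or "",
            "maf": a.maf,
        }
        row.update({f"freq_{g}": f for g, f in sorted(a.group_freqs.items())})
        rows.append(row)
    return pd.DataFrame(rows)
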