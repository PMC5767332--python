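"""Phased-haplotype input and coding-haplotype tabulation.

Reads phased biallelic SNPs from VCF, applies each haplotype's alleles to a
reference coding sequence, and tabulates the unique full-length coding
haplotypes with per-population counts.  Coordinates are 1-based inclusive
throughout (VCF convention); minus-strand genes are handled by mapping
genomic positions onto the coding strand and complementing alleles.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger("balsel")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class VcfFormatError(ValueError):
    """A VCF record violates the phased biallelic-diploid contract."""


class EmptyRegionError(ValueError):
    """No biallelic phased SNPs were retained in the requested region."""


@dataclass
class GeneModel:
    """Exon structure and reference CDS for one gene.

    exons are 1-based inclusive genomic [start, end] intervals sorted by
    genomic coordinate; reference_cds is always given on the coding strand.
    """

    gene_name: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    reference_cds: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping and sorted")
        total = sum(e - s + 1 for s, e in self.exons)
        if total != len(self.reference_cds):
            raise ValueError(
                f"summed exon length {total} != CDS length {len(self.reference_cds)}"
            )
        if len(self.reference_cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        aa = str(Seq(self.reference_cds).translate())
        if "*" in aa[:-1]:
            raise ValueError("reference CDS contains an internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.reference_cds) // 3

    def cds_index(self, position: int) -> int:
        """0-based index into reference_cds for a genomic position.

        Raises ValueError for positions outside every exon.  On the minus
        strand the CDS runs 3'→5' in genomic coordinates, so indexing counts
        down from the last exon base.
        """
        offset = 0
        for s, e in self.exons:
            if s <= position <= e:
                fwd = offset + (position - s)
                if self.strand == "+":
                    return fwd
                return len(self.reference_cds) - 1 - fwd
            offset += e - s + 1
        raise ValueError(
            f"position {position} is outside the exons of {self.gene_name}"
        )

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    @classmethod
    def from_tsv(cls, path: str, reference_cds: str) -> "GeneModel":
        """Gene model from a TSV with columns gene, chrom, strand, start, end
        (one row per exon)."""
        df = pd.read_csv(path, sep="\t")
        exons = sorted(zip(df["start"].astype(int), df["end"].astype(int)))
        return cls(
            gene_name=str(df["gene"].iloc[0]),
            chromosome=str(df["chrom"].iloc[0]),
            strand=str(df["strand"].iloc[0]),
            exons=[(int(s), int(e)) for s, e in exons],
            reference_cds=reference_cds,
        )


@dataclass
class PhasedHaplotypeSet:
    """Phased biallelic haplotypes: a (2·n_samples) × n_sites 0/1 matrix.

    Row 2i is the first haplotype of sample i, row 2i+1 the second.
    """

    samples: list[str]
    population: dict[str, str]
    chromosome: str
    positions: np.ndarray
    ref_allele: list[str]
    alt_allele: list[str]
    haplotype_matrix: np.ndarray
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotype_matrix = np.asarray(self.haplotype_matrix, dtype=np.int8)
        n_hap, n_sites = self.haplotype_matrix.shape
        if n_hap != 2 * len(self.samples):
            raise ValueError("haplotype matrix must have 2 rows per sample")
        if n_sites != len(self.positions):
            raise ValueError("matrix columns must match positions")
        if n_sites and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haplotype_matrix, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    def group_of_row(self, row: int) -> str:
        return self.population.get(self.samples[row // 2], "all")

    def row_groups(self) -> list[str]:
        return [self.group_of_row(r) for r in range(self.n_haplotypes)]

    def subset_population(self, group: str) -> "PhasedHaplotypeSet":
        keep = [s for s in self.samples if self.population.get(s, "all") == group]
        idx = [self.samples.index(s) for s in keep]
        rows = np.array([r for i in idx for r in (2 * i, 2 * i + 1)], dtype=int)
        return PhasedHaplotypeSet(
            samples=keep,
            population={s: group for s in keep},
            chromosome=self.chromosome,
            positions=self.positions.copy(),
            ref_allele=list(self.ref_allele),
            alt_allele=list(self.alt_allele),
            haplotype_matrix=self.haplotype_matrix[rows],
        )


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if span:
        a, _, b = span.partition("-")
        return chrom, int(a), int(b)
    return chrom, 1, 2**62


def read_phased_vcf(
    path: str,
    region: str | None = None,
    populations: dict[str, str] | None = None,
) -> PhasedHaplotypeSet:
    """Read phased biallelic SNPs from a VCF into a PhasedHaplotypeSet.

    Multiallelic records, indels, and records with missing genotypes are
    skipped (counted in ``.skipped``).  A biallelic SNP with any unphased
    heterozygous genotype raises :class:`VcfFormatError` naming the record:
    phase is load-bearing for every haplotype statistic downstream.

    Parameters
    ----------
    path : str
        VCF file (plain text or bgzipped).
    region : str, optional
        ``chrom`` or ``chrom:start-end`` (1-based inclusive).
    populations : dict, optional
        sample ID → group label; samples absent from the map are labelled
        ``"all"``.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None

    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    skipped = Counter()
    chrom_seen: str | None = None

    for rec in vcf:
        if want is not None:
            c, lo, hi = want
            if rec.CHROM != c or not (lo <= rec.POS <= hi):
                continue
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        gts = rec.genotypes  # [allele_a, allele_b, phased]
        if any(g[0] < 0 or g[1] < 0 or len(g) != 3 for g in gts):
            skipped["missing"] += 1
            continue
        if any(max(g[0], g[1]) > 1 for g in gts):
            skipped["multiallelic"] += 1
            continue
        unphased_het = [i for i, g in enumerate(gts) if g[0] != g[1] and not g[2]]
        if unphased_het:
            raise VcfFormatError(
                f"unphased genotype for sample {samples[unphased_het[0]]} "
                f"at {rec.CHROM}:{rec.POS}"
            )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        columns.append(col)
        chrom_seen = rec.CHROM

    if skipped:
        log.info("read_phased_vcf(%s): skipped %s", path, dict(skipped))
    if not positions:
        raise EmptyRegionError(
            f"no phased biallelic SNPs retained from {path}"
            + (f" in region {region}" if region else "")
        )

    order = np.argsort(positions, kind="stable")
    matrix = np.stack([columns[i] for i in order], axis=1)
    return PhasedHaplotypeSet(
        samples=samples,
        population=dict(populations or {}),
        chromosome=chrom_seen or (want[0] if want else ""),
        positions=np.asarray(positions)[order],
        ref_allele=[refs[i] for i in order],
        alt_allele=[alts[i] for i in order],
        haplotype_matrix=matrix,
        skipped=dict(skipped),
    )


def extract_coding_haplotypes(
    hapset: PhasedHaplotypeSet, gene: GeneModel
) -> list[str]:
    """Apply each haplotype's alt alleles to the reference CDS.

    Returns one coding-strand CDS string per gene copy (2 per sample), each
    exactly the reference CDS length.  Sites outside the gene's exons are
    dropped with a log line.  A site whose REF allele disagrees with the
    reference CDS (strand-adjusted) raises ValueError naming the site.
    """
    cds = gene.reference_cds.upper()
    usable: list[tuple[int, int, str]] = []  # (site, cds index, coding-strand alt)
    dropped = 0
    for j, pos in enumerate(hapset.positions):
        if not gene.contains(int(pos)):
            dropped += 1
            continue
        idx = gene.cds_index(int(pos))
        ref = hapset.ref_allele[j].upper()
        alt = hapset.alt_allele[j].upper()
        if gene.strand == "-":
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        if cds[idx] != ref:
            raise ValueError(
                f"REF allele {hapset.ref_allele[j]} at {hapset.chromosome}:{pos} "
                f"disagrees with reference CDS base {cds[idx]} "
                f"(CDS index {idx}, gene {gene.gene_name})"
            )
        usable.append((j, idx, alt))
    if dropped:
        log.info(
            "extract_coding_haplotypes(%s): dropped %d sites outside exons",
            gene.gene_name,
            dropped,
        )

    out: list[str] = []
    for row in range(hapset.n_haplotypes):
        bases = list(cds)
        for j, idx, alt in usable:
            if hapset.haplotype_matrix[row, j] == 1:
                bases[idx] = alt
        out.append("".join(bases))
    return out


@dataclass
class HaplotypeTable:
    """Unique coding haplotypes with total and per-group counts."""

    entries: list[dict]
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"haplotype": e["sequence"], "count": e["count"],
                   "frequency": e["count"] / self.n_total}
            row.update({f"count_{g}": c for g, c in sorted(e["groups"].items())})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tabulate_haplotypes(
    coding_seqs: list[str], group_labels: list[str] | None = None
) -> HaplotypeTable:
    """Group identical coding sequences; sort entries by descending count."""
    if not coding_seqs:
        raise ValueError("no coding sequences to tabulate")
    if len({len(s) for s in coding_seqs}) != 1:
        raise ValueError("all coding sequences must have equal length")
    if group_labels is None:
        group_labels = ["all"] * len(coding_seqs)
    if len(group_labels) != len(coding_seqs):
        raise ValueError("one group label per sequence required")

    totals = Counter(coding_seqs)
    by_group: dict[str, Counter] = {}
    for seq, g in zip(coding_seqs, group_labels):
        by_group.setdefault(seq, Counter())[g] += 1
    entries = [
        {"sequence": seq, "count": n, "groups": dict(by_group[seq])}
        for seq, n in totals.most_common()
    ]
    return HaplotypeTable(entries=entries, n_total=len(coding_seqs))
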