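import numpy as np
import pytest

from balsel import GeneModel, PhasedHaplotypeSet


@pytest.fixture
def make_gene():
    """Factory for small plus/minus-strand gene models with one exon."""

    def _make(cds: str, start: int = 101, strand: str = "+", chrom: str = "chr1",
              name: str = "TOY") -> GeneModel:
        if strand == "+":
            exons = [(start, start + len(cds) - 1)]
        else:
            exons = [(start, start + len(cds) - 1)]
        return GeneModel(
            gene_name=name, chromosome=chrom, strand=strand, exons=exons,
            reference_cds=cds,
        )

    return _make


@pytest.fixture
def make_hapset():
    """Factory for in-memory phased haplotype sets."""

    def _make(matrix, positions, ref=None, alt=None, groups=None,
              chrom: str = "chr1") -> PhasedHaplotypeSet:
        matrix = np.asarray(matrix, dtype=np.int8)
        n_hap, n_sites = matrix.shape
        assert n_hap % 2 == 0
        samples = [f"s{i}" for i in range(n_hap // 2)]
        population = {}
        if groups is not None:
            for i, s in enumerate(samples):
                population[s] = groups[i]
        return PhasedHaplotypeSet(
            samples=samples,
            population=population,
            chromosome=chrom,
            positions=np.asarray(positions, dtype=np.int64),
            ref_allele=list(ref) if ref else ["A"] * n_sites,
            alt_allele=list(alt) if alt else ["T"] * n_sites,
            haplotype_matrix=matrix,
        )

    return _make


@pytest.fixture
def vcf_writer(tmp_path):
    """Write a raw VCF text body (list of data lines) with a valid header."""

    def _write(lines, samples, name="test.vcf", chrom="chr1"):
        path = tmp_path / name
        header = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom},length=1000000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples),
        ]
        path.write_text("\n".join(header + lines) + "\n")
        return str(path)

    return _write
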