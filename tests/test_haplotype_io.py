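"""Phased VCF reading, CDS substitution, and haplotype tabulation."""

import numpy as np
import pytest

from balsel import (
    GeneModel,
    SimConfig,
    extract_coding_haplotypes,
    read_phased_vcf,
    simulate_two_pop_haplotypes,
    tabulate_haplotypes,
    write_vcf,
)
from balsel.haplotype_io import (
    EmptyRegionError,
    VcfFormatError,
    reverse_complement,
)

from _oracles import substitute_reference


class TestReadPhasedVcf:
    def test_matrix_dimensions(self, vcf_writer):
        lines = [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0",
        ]
        hs = read_phased_vcf(vcf_writer(lines, ["a", "b", "c"]))
        assert hs.haplotype_matrix.shape == (6, 2)
        assert list(hs.positions) == [100, 200]
        assert hs.haplotype_matrix[:, 0].tolist() == [0, 1, 1, 1, 0, 0]

    def test_multiallelic_and_indel_records_skipped(self, vcf_writer):
        lines = [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1",
            "chr1\t150\t.\tA\tG,T\t.\tPASS\t.\tGT\t0|2",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|0",
            "chr1\t250\t.\tCA\tC\t.\tPASS\t.\tGT\t0|1",
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0|0",
            "chr1\t350\t.\tG\tA\t.\tPASS\t.\tGT\t.|.",
        ]
        hs = read_phased_vcf(vcf_writer(lines, ["a"]))
        assert hs.n_sites == 3
        assert hs.skipped == {"multiallelic": 1, "indel": 1, "missing": 1}

    def test_unphased_heterozygote_raises_naming_record(self, vcf_writer):
        lines = ["chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1"]
        with pytest.raises(VcfFormatError, match="chr1:100"):
            read_phased_vcf(vcf_writer(lines, ["a"]))

    def test_empty_region_signalled(self, vcf_writer):
        lines = ["chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1"]
        with pytest.raises(EmptyRegionError):
            read_phased_vcf(vcf_writer(lines, ["a"]), region="chr1:500-600")

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            read_phased_vcf("/nonexistent/file.vcf")

    def test_round_trip_preserves_everything(self, tmp_path):
        cfg = SimConfig(N=40, L=4000, mu=3e-6, rho=2e-6, split_generations=40,
                        s_het=0.1, seed=17, n_sample=12)
        hs, _ = simulate_two_pop_haplotypes(cfg)
        path = tmp_path / "sim.vcf"
        write_vcf(hs, str(path))
        back = read_phased_vcf(str(path), populations=hs.population)
        assert np.array_equal(back.haplotype_matrix, hs.haplotype_matrix)
        assert np.array_equal(back.positions, hs.positions)
        assert back.ref_allele == hs.ref_allele
        assert back.alt_allele == hs.alt_allele
        assert back.samples == hs.samples


class TestExtractCodingHaplotypes:
    def test_no_variants_returns_reference(self, make_gene, make_hapset):
        gene = make_gene("ATGGCTTAA")
        hs = make_hapset(np.zeros((4, 1)), [101], ref=["A"], alt=["C"])
        seqs = extract_coding_haplotypes(hs, gene)
        assert seqs == ["ATGGCTTAA"] * 4
        # carrying nothing means every copy equals the reference
        hs0 = make_hapset(np.zeros((4, 0)), [], ref=[], alt=[])
        assert extract_coding_haplotypes(hs0, gene) == ["ATGGCTTAA"] * 4

    def test_proline_to_serine_first_position_substitution(
        self, make_gene, make_hapset
    ):
        # CCG (Pro) at the second codon; alt T at its first position → TCG (Ser)
        gene = make_gene("ATGCCGTAA", start=101)
        hs = make_hapset([[1], [0]], [104], ref=["C"], alt=["T"])
        seqs = extract_coding_haplotypes(hs, gene)
        assert seqs[0] == "ATGTCGTAA"
        assert seqs[1] == "ATGCCGTAA"

    def test_matches_bruteforce_substitution(self, make_gene, make_hapset):
        rng = np.random.default_rng(5)
        cds = "".join(rng.choice(list("ACGT"), size=30))
        cds = "ATG" + cds[3:-3] + "TAA"
        gene = GeneModel("G", "chr1", "+", [(101, 130)], cds)
        n_sites = 10
        pos = np.sort(rng.choice(np.arange(101, 131), size=n_sites, replace=False))
        idx = [p - 101 for p in pos]
        ref = [cds[i] for i in idx]
        alt = [
            rng.choice([b for b in "ACGT" if b != r]) for r in ref
        ]
        matrix = rng.integers(0, 2, size=(8, n_sites))
        hs = make_hapset(matrix, pos, ref=ref, alt=alt)
        seqs = extract_coding_haplotypes(hs, gene)
        for row in range(8):
            expect = substitute_reference(
                cds, idx, alt, list(matrix[row].astype(bool))
            )
            assert seqs[row] == expect

    def test_minus_strand_equals_plus_on_revcomp_reference(
        self, make_hapset
    ):
        rng = np.random.default_rng(9)
        cds = "ATGACTGGTCATTGTCCGAGATTGCTATAA"  # 30 bp, no internal stop
        pos = [105, 112, 119, 126]
        fwd = GeneModel("F", "chr1", "+", [(101, 130)], cds)
        idx = [p - 101 for p in pos]
        ref = [cds[i] for i in idx]
        alt = [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
        matrix = rng.integers(0, 2, size=(6, 4))
        hs_fwd = make_hapset(matrix, pos, ref=ref, alt=alt)
        plus = extract_coding_haplotypes(hs_fwd, fwd)

        # same gene on the minus strand: genomic sequence is revcomp(cds),
        # so genomic position p maps to CDS index L-1-(p-start) and VCF
        # alleles are the complements of the coding-strand alleles
        rev = GeneModel("R", "chr1", "-", [(101, 130)], cds)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        genomic_pos = [101 + 130 - p for p in pos]  # mirrored coordinates
        order = np.argsort(genomic_pos)
        hs_rev = make_hapset(
            matrix[:, order],
            np.asarray(genomic_pos)[order],
            ref=[comp[ref[i]] for i in order],
            alt=[comp[alt[i]] for i in order],
        )
        minus = extract_coding_haplotypes(hs_rev, rev)
        assert minus == plus

    def test_ref_mismatch_identifies_site(self, make_gene, make_hapset):
        gene = make_gene("ATGGCTTAA")
        hs = make_hapset([[0], [1]], [104], ref=["T"], alt=["C"])  # CDS has G
        with pytest.raises(ValueError, match="104"):
            extract_coding_haplotypes(hs, gene)

    def test_sites_outside_exons_dropped(self, make_gene, make_hapset):
        gene = make_gene("ATGGCTTAA", start=101)
        hs = make_hapset([[1, 1], [0, 0]], [50, 104], ref=["A", "G"],
                         alt=["T", "A"])
        seqs = extract_coding_haplotypes(hs, gene)
        assert seqs[0] == "ATGACTTAA"


class TestTabulateHaplotypes:
    def test_identical_sequences_single_entry(self):
        table = tabulate_haplotypes(["AAA"] * 10)
        assert len(table.entries) == 1
        assert table.entries[0]["count"] == 10
        assert table.n_total == 10

    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(2)
        variants = ["AAA", "AAT", "ATT"]
        seqs = [variants[i] for i in rng.integers(0, 3, size=100)]
        groups = ["g1" if i < 50 else "g2" for i in range(100)]
        table = tabulate_haplotypes(seqs, groups)
        # brute-force sort-and-count
        from collections import Counter

        expect = Counter(seqs)
        assert {e["sequence"]: e["count"] for e in table.entries} == dict(expect)
        counts = [e["count"] for e in table.entries]
        assert counts == sorted(counts, reverse=True)
        for e in table.entries:
            assert sum(e["groups"].values()) == e["count"]
        assert sum(e["count"] for e in table.entries) == 100

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            tabulate_haplotypes([])

    def test_counts_sum_to_two_per_sample(self, make_gene, make_hapset):
        rng = np.random.default_rng(3)
        gene = make_gene("ATGGCTGGATAA")
        hs = make_hapset(rng.integers(0, 2, (12, 2)), [104, 108],
                         ref=["G", "G"], alt=["T", "C"])
        seqs = extract_coding_haplotypes(hs, gene)
        table = tabulate_haplotypes(seqs)
        assert sum(e["count"] for e in table.entries) == 2 * hs.n_samples


def test_reverse_complement_involution():
    assert reverse_complement(reverse_complement("ACGTTGCA")) == "ACGTTGCA"
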