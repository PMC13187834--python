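"""Mutation-class canonicalization, censuses and genome loading."""

import itertools
from collections import Counter

import numpy as np
import pytest

from uvmut.genome import (
    DBS78_LABELS,
    DBS_CANONICAL_REFS,
    PYRIMIDINE_TRINUCS,
    GeneAnnotation,
    GenomeAssembly,
    UncountableContextError,
    canonicalize_dbs,
    canonicalize_sbs,
    context_census,
    dinuc_strand_census,
    gene_strand_census,
    load_genes,
    load_genome,
    revcomp,
)


class TestCanonicalizeSbs:
    @pytest.mark.parametrize(
        "change,expected_label,expected_flag",
        [
            (("C", "T", "A", "G"), "A[C>T]G", True),  # pyrimidine already central
            (("G", "A", "C", "T"), "A[C>T]G", False),  # forced reverse complement
            (("T", "G", "T", "T"), "T[T>G]T", True),
            (("A", "C", "G", "G"), "C[T>G]C", False),
        ],
    )
    def test_examples(self, change, expected_label, expected_flag):
        cls, flag = canonicalize_sbs(*change)
        assert cls.label == expected_label
        assert flag is expected_flag

    def test_ambiguous_context_uncountable(self):
        with pytest.raises(UncountableContextError):
            canonicalize_sbs("A", "T", "T", "N")

    def test_equal_alleles_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_sbs("C", "C", "A", "A")

    def test_exhaustive_collapse_is_revcomp_invariant(self):
        """Every SNV in countable context maps to one of 96 classes, and the
        reverse-complemented report of the same event maps to the same class."""
        seen = set()
        for ref, up, down in itertools.product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == ref:
                    continue
                cls, _ = canonicalize_sbs(ref, alt, up, down)
                rc_cls, _ = canonicalize_sbs(
                    revcomp(ref), revcomp(alt), revcomp(down), revcomp(up)
                )
                assert cls == rc_cls
                seen.add(cls.label)
        assert len(seen) == 96


class TestCanonicalizeDbs:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("AC", "TT", "AC>TT"),
            ("GT", "AA", "AC>TT"),  # reverse complement of AC>TT
            ("CC", "TT", "CC>TT"),
            ("AG", "TC", "CT>GA"),
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert canonicalize_dbs(ref, alt).label == expected

    def test_rejects_single_position_changes(self):
        with pytest.raises(ValueError):
            canonicalize_dbs("AC", "AT")

    def test_exhaustive_collapse_vs_bruteforce(self):
        """All 144 directed doublet changes collapse to exactly 78 classes,
        agreeing with a brute-force orbit enumeration under reverse
        complementation."""
        changes = [
            (r1 + r2, a1 + a2)
            for r1, r2, a1, a2 in itertools.product("ACGT", repeat=4)
            if r1 != a1 and r2 != a2
        ]
        assert len(changes) == 144

        # oracle: group changes into orbits {x, revcomp(x)}
        orbits = set()
        for ref, alt in changes:
            orbit = frozenset({(ref, alt), (revcomp(ref), revcomp(alt))})
            orbits.add(orbit)
        assert len(orbits) == 78

        for ref, alt in changes:
            cls = canonicalize_dbs(ref, alt)
            rc_cls = canonicalize_dbs(revcomp(ref), revcomp(alt))
            assert cls == rc_cls, f"{ref}>{alt} and its revcomp diverge"
            assert cls.ref_dinucleotide in DBS_CANONICAL_REFS
        labels = {canonicalize_dbs(ref, alt).label for ref, alt in changes}
        assert labels == set(DBS78_LABELS)


def census_oracle(seq):
    """Brute-force both-strand trinucleotide census by window enumeration."""
    counts = Counter()
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - 2):
            w = strand_seq[i : i + 3]
            if "N" in w:
                continue
            counts[w if w[1] in "CT" else revcomp(w)] += 1
    return counts


class TestContextCensus:
    def test_acgt_both_strands(self):
        genome = GenomeAssembly({"c": "ACGT"}, ploidy=2)
        census = context_census(genome)
        assert census.counts["ACG"] == 4
        assert census.total == 4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGTN"))[rng.choice(5, 300, p=[0.24, 0.24, 0.24, 0.24, 0.04])])
        genome = GenomeAssembly({"c": seq}, ploidy=2)
        census = context_census(genome)
        oracle = census_oracle(seq)
        for key in PYRIMIDINE_TRINUCS:
            assert census.counts[key] == oracle.get(key, 0)

    def test_sum_is_twice_valid_windows(self, toy_genome):
        census = context_census(toy_genome)
        seq = toy_genome.contigs["chrI"]
        valid_windows = sum(1 for i in range(len(seq) - 2) if "N" not in seq[i : i + 3])
        assert census.total == 2 * valid_windows

    def test_reverse_complement_invariance(self, toy_genome):
        flipped = GenomeAssembly(
            {name: revcomp(seq) for name, seq in toy_genome.contigs.items()},
            toy_genome.excluded_contigs,
            toy_genome.ploidy,
        )
        assert context_census(toy_genome).counts == context_census(flipped).counts

    def test_excluded_contig_absent(self, toy_genome):
        census = context_census(toy_genome)
        # chrM is ACGT*25: would contribute ACG counts well above chrI's alone
        only_chr1 = census_oracle(toy_genome.contigs["chrI"])
        assert census.counts["ACG"] == only_chr1["ACG"]

    def test_region_outside_contig_errors(self, toy_genome):
        with pytest.raises(ValueError):
            context_census(toy_genome, [GeneAnnotation("g", "chrI", 0, 10_000, "+")])

    def test_empty_region_set(self, toy_genome):
        census = context_census(toy_genome, [])
        assert census.total == 0


class TestGeneStrandCensus:
    def test_homopolymer_gene_nts(self):
        genome = GenomeAssembly({"c": "CCCCCC"}, ploidy=2)
        gene = GeneAnnotation("g", "c", 0, 6, "+")
        nts, ts = gene_strand_census(genome, [gene])
        assert nts.counts["CCC"] == 4
        assert sum(nts.counts.values()) == 4
        assert sum(ts.counts.values()) == 0  # all centers are pyrimidines on +

    def test_minus_gene_swaps_strands(self):
        genome = GenomeAssembly({"c": "CCCCCC"}, ploidy=2)
        gene = GeneAnnotation("g", "c", 0, 6, "-")
        nts, ts = gene_strand_census(genome, [gene])
        assert ts.counts["CCC"] == 4
        assert sum(nts.counts.values()) == 0

    def test_strand_swap_exchanges_censuses(self, toy_genome, toy_genes):
        nts, ts = gene_strand_census(toy_genome, toy_genes)
        swapped = [
            GeneAnnotation(g.gene_id, g.contig, g.start, g.end, "-" if g.strand == "+" else "+")
            for g in toy_genes
        ]
        nts2, ts2 = gene_strand_census(toy_genome, swapped)
        assert nts.counts == ts2.counts
        assert ts.counts == nts2.counts

    def test_opposite_strand_overlap_excluded(self, toy_genome):
        overlapping = [
            GeneAnnotation("g1", "chrI", 50, 200, "+"),
            GeneAnnotation("g2", "chrI", 100, 300, "-"),
        ]
        nts, ts = gene_strand_census(toy_genome, overlapping)
        # only the non-overlapping parts [50,100) and [200,300) contribute
        disjoint = [
            GeneAnnotation("g1", "chrI", 50, 100, "+"),
            GeneAnnotation("g2", "chrI", 200, 300, "-"),
        ]
        nts2, ts2 = gene_strand_census(toy_genome, disjoint)
        assert nts.counts == nts2.counts
        assert ts.counts == ts2.counts

    def test_dinuc_census_palindromes_count_both_strands(self):
        genome = GenomeAssembly({"c": "ATATATAT"}, ploidy=2)
        gene = GeneAnnotation("g", "c", 0, 8, "+")
        nts, ts = dinuc_strand_census(genome, [gene])
        # TA and AT are their own reverse complements: same abundance both strands
        assert nts["TA"] == ts["TA"] > 0
        assert nts["AT"] == ts["AT"] > 0


class TestLoaders:
    def test_load_genome_sizes(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">a\n" + "ACGT" * 150 + "\n>b\n" + "ACGT" * 100 + "\n")
        genome = load_genome(fasta, ploidy=2)
        assert genome.haploid_size_kb == pytest.approx(1.0)

    def test_load_genome_excludes_mitochondrion(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chrI\n" + "ACGT" * 250 + "\n>chrM\n" + "ACGT" * 250 + "\n")
        genome = load_genome(fasta, {"chrM"}, ploidy=2)
        assert genome.haploid_size_kb == pytest.approx(1.0)
        assert "chrM" not in genome.counted_contigs

    def test_load_genome_lowercase_uppercased(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">a\nacgtacgtacgt\n")
        genome = load_genome(fasta)
        assert genome.contigs["a"] == "ACGTACGTACGT"

    def test_load_bed6(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chrI\t10\t50\tgeneA\t0\t+\nchrI\t60\t90\tgeneB\t0\t-\n")
        genes = load_genes(bed)
        assert genes[0] == GeneAnnotation("geneA", "chrI", 10, 50, "+")
        assert genes[1].strand == "-"

    def test_load_gff3_converts_coordinates(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chrI\tsrc\tgene\t11\t50\t.\t+\t.\tID=geneA\n"
            "chrI\tsrc\tgene\t61\t90\t.\t-\t.\tID=geneB\n"
        )
        genes = load_genes(gff)
        assert genes[0].start == 10 and genes[0].end == 50  # 1-based inclusive -> 0-based half-open

    def test_bed_without_strand_rejected(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chrI\t10\t50\tgeneA\n")
        with pytest.raises(ValueError):
            load_genes(bed)
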