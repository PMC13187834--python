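"""Strand assignment, normalized NTS/TS ratios and the reverse-asymmetry
(atypical photoproduct) inference."""

import numpy as np
import pytest
from scipy import stats as sps

from uvmut.asymmetry import (
    _chi2_1df,
    assign_transcriptional_strand,
    asymmetry_table,
    complementary_reading,
    reverse_asymmetry_report,
)
from uvmut.genome import GeneAnnotation, GeneIndex, GenomeAssembly, revcomp
from uvmut.variants import DbsRecord, VariantRecord


def snv(genome, contig, pos, alt, **kw):
    ref = genome.base(contig, pos)
    return VariantRecord(contig, pos, ref, alt, 30, 0.5,
                         kw.get("iso", "i1"), kw.get("strain", "NoPL"), kw.get("rep", "rep1"))


class TestAssignStrand:
    def make(self):
        genome = GenomeAssembly({"c": "AACCGGTTAACCGGTT" * 10}, ploidy=2)
        genes = [
            GeneAnnotation("plus", "c", 10, 50, "+"),
            GeneAnnotation("minus", "c", 60, 100, "-"),
            GeneAnnotation("ovA", "c", 110, 130, "+"),
            GeneAnnotation("ovB", "c", 120, 140, "-"),
        ]
        return genome, GeneIndex(genome, genes)

    def test_pyrimidine_in_plus_gene_is_nts(self):
        genome, index = self.make()
        pos = next(p for p in range(10, 50) if genome.base("c", p) == "C")
        assert assign_transcriptional_strand(snv(genome, "c", pos, "T"), index) == "NTS"

    def test_purine_in_plus_gene_is_ts(self):
        genome, index = self.make()
        pos = next(p for p in range(10, 50) if genome.base("c", p) == "G")
        assert assign_transcriptional_strand(snv(genome, "c", pos, "A"), index) == "TS"

    def test_pyrimidine_in_minus_gene_is_ts(self):
        genome, index = self.make()
        pos = next(p for p in range(60, 100) if genome.base("c", p) == "C")
        assert assign_transcriptional_strand(snv(genome, "c", pos, "T"), index) == "TS"

    def test_outside_genes_intergenic(self):
        genome, index = self.make()
        assert assign_transcriptional_strand(snv(genome, "c", 2, "T" if genome.base("c", 2) != "T" else "G"), index) == "intergenic"

    def test_opposite_overlap_ambiguous(self):
        genome, index = self.make()
        v = snv(genome, "c", 125, "T" if genome.base("c", 125) != "T" else "G")
        assert assign_transcriptional_strand(v, index) == "ambiguous"

    def test_doublet_strand_follows_canonical_reading(self):
        genome, index = self.make()
        # find GT (canonical reading AC on the minus strand) inside the + gene
        seq = genome.contigs["c"]
        pos = next(i for i in range(10, 48) if seq[i : i + 2] == "GT")
        d = DbsRecord("c", pos, "GT", "AA", "i1", "NoPL", "rep1")
        assert assign_transcriptional_strand(d, index) == "TS"

    def test_palindromic_doublet_ambiguous(self):
        genome, index = self.make()
        seq = genome.contigs["c"]
        pos = next(i for i in range(10, 48) if seq[i : i + 2] == "TA")
        d = DbsRecord("c", pos, "TA", "AT", "i1", "NoPL", "rep1")
        assert assign_transcriptional_strand(d, index) == "ambiguous"


class TestChiSquare:
    def test_closed_form_example(self):
        """90 vs 10 with equal abundances: chi2 = (40^2 + 40^2)/50 = 64."""
        stat, p = _chi2_1df(90, 10, 1.0, 1.0)
        assert stat == pytest.approx(64.0, abs=1e-12)
        assert p == pytest.approx(1.2e-15, rel=0.05)

    def test_balanced_counts_p_one(self):
        stat, p = _chi2_1df(50, 50, 1.0, 1.0)
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("n_nts,n_ts,a_nts,a_ts", [
        (30, 70, 1, 1), (120, 40, 3, 1), (55, 45, 2, 3), (10, 90, 1, 4),
    ])
    def test_matches_scipy_goodness_of_fit(self, n_nts, n_ts, a_nts, a_ts):
        stat, p = _chi2_1df(n_nts, n_ts, a_nts, a_ts)
        total = n_nts + n_ts
        f_exp = np.array([a_nts, a_ts]) / (a_nts + a_ts) * total
        ref = sps.chisquare([n_nts, n_ts], f_exp)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def place_per_occurrence(genome, genes, context):
    """One mutation at every coding- and template-strand occurrence of a
    pyrimidine-central context inside single-strand gene bodies."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    index = GeneIndex(genome, genes)
    out = []
    for contig in genome.counted_contigs:
        seq = genome.contigs[contig]
        cov = index.coverage(contig)
        for p in range(1, len(seq) - 1):
            code = cov[p]
            if code not in (GeneIndex.PLUS, GeneIndex.MINUS):
                continue
            w = seq[p - 1 : p + 2]
            coding = w if code == GeneIndex.PLUS else revcomp(w)
            template = revcomp(coding)
            pyr, alt = context[1], "T" if context[1] == "C" else "A"
            if coding == context:
                # pyrimidine on the coding strand
                if code == GeneIndex.PLUS:
                    out.append(snv(genome, contig, p, alt))
                else:
                    out.append(snv(genome, contig, p, comp[alt]))
            if template == context:
                if code == GeneIndex.PLUS:
                    out.append(snv(genome, contig, p, comp[alt]))
                else:
                    out.append(snv(genome, contig, p, alt))
    return out


class TestAsymmetryTable:
    def test_uniform_placement_normalizes_to_one(self, toy_genome, toy_genes):
        """Placing one mutation per context occurrence on each strand gives a
        normalized ratio of exactly 1 (raw counts equal the abundances)."""
        context = "TCA"
        variants = place_per_occurrence(toy_genome, toy_genes, context)
        assert variants, "fixture genome lacks the test context"
        rows = asymmetry_table(variants, toy_genes, toy_genome, min_total_mutations=1)
        row = next(r for r in rows if r.class_label == "T[C>T]A")
        assert row.n_nts == row.a_nts and row.n_ts == row.a_ts
        assert row.normalized_ratio == pytest.approx(1.0)
        assert row.chi2_stat == pytest.approx(0.0, abs=1e-12)

    def test_gene_strand_swap_inverts_ratio(self, toy_genome, toy_genes):
        variants = place_per_occurrence(toy_genome, toy_genes, "TCA")
        swapped = [
            GeneAnnotation(g.gene_id, g.contig, g.start, g.end,
                           "-" if g.strand == "+" else "+")
            for g in toy_genes
        ]
        rows = asymmetry_table(variants, toy_genes, toy_genome, min_total_mutations=1)
        rows_sw = asymmetry_table(variants, swapped, toy_genome, min_total_mutations=1)
        r1 = next(r for r in rows if r.class_label == "T[C>T]A")
        r2 = next(r for r in rows_sw if r.class_label == "T[C>T]A")
        assert (r1.n_nts, r1.n_ts) == (r2.n_ts, r2.n_nts)
        assert (r1.a_nts, r1.a_ts) == (r2.a_ts, r2.a_nts)
        if r1.n_ts and r2.n_ts:
            assert r1.normalized_ratio == pytest.approx(1 / r2.normalized_ratio)

    def test_chi2_of_every_row_matches_closed_form(self, sim_bundle):
        _, genome, genes, sim = sim_bundle
        rows = asymmetry_table(sim.variants, genes, genome, min_total_mutations=30)
        assert rows
        for r in rows:
            if np.isnan(r.chi2_stat):
                continue
            stat, p = _chi2_1df(r.n_nts, r.n_ts, r.a_nts, r.a_ts)
            assert r.chi2_stat == pytest.approx(stat, abs=1e-10)
            assert r.chi2_p == pytest.approx(p, abs=1e-10)

    def test_bonferroni_monotonic_in_tested_classes(self, sim_bundle):
        """Lowering the count threshold tests more classes; no shared row may
        gain significance."""
        _, genome, genes, sim = sim_bundle
        strict = asymmetry_table(sim.variants, genes, genome, min_total_mutations=120)
        loose = asymmetry_table(sim.variants, genes, genome, min_total_mutations=20)
        assert len(loose) >= len(strict)
        strict_sig = {r.class_label for r in strict if r.significant_after_bonferroni}
        loose_sig = {r.class_label for r in loose if r.significant_after_bonferroni}
        shared = {r.class_label for r in strict}
        assert (loose_sig & shared) <= strict_sig

    def test_ts_suppression_produces_nts_enrichment(self, sim_bundle):
        """With transcription-coupled suppression of template-strand lesions,
        pyrimidine-lesion (CPD) classes are NTS-enriched and the TA-photoproduct
        class is NTS-depleted (reverse asymmetric)."""
        config, genome, genes, sim = sim_bundle
        index = GeneIndex(genome, genes)
        truth = sim.ground_truth
        counts = {"CPD": [0, 0], "TA_PP": [0, 0]}
        by_key = truth.set_index(["isolate_id", "contig", "position"])["channel"].to_dict()
        for v in sim.variants:
            channel = by_key.get((v.isolate_id, v.contig, v.position))
            if channel not in counts:
                continue
            strand = assign_transcriptional_strand(v, index)
            if strand == "NTS":
                counts[channel][0] += 1
            elif strand == "TS":
                counts[channel][1] += 1
        cpd_nts, cpd_ts = counts["CPD"]
        ta_nts, ta_ts = counts["TA_PP"]
        assert cpd_nts > 1.5 * cpd_ts  # suppression factor 4, sampling slack
        assert ta_ts > 1.5 * ta_nts

    def test_empty_records_empty_table(self, toy_genome, toy_genes):
        assert asymmetry_table([], toy_genes, toy_genome) == []


class TestReverseAsymmetryReport:
    def test_complementary_reading_examples(self):
        assert complementary_reading("T[T>A]A") == "T[A>T]A"
        assert complementary_reading("A[C>T]G") == "C[G>A]T"
        assert complementary_reading("AC>TT") == "GT>AA"

    def test_flagged_rows_reported_with_reexpression(self):
        from uvmut.asymmetry import AsymmetryRow

        rows = [
            AsymmetryRow("T[T>A]A", 10, 90, 100, 100, 0.11, 64.0, 1e-15, True, True),
            AsymmetryRow("A[C>T]G", 90, 10, 100, 100, 9.0, 64.0, 1e-15, True, False),
        ]
        report = reverse_asymmetry_report(rows)
        assert list(report["class_label"]) == ["T[T>A]A"]
        assert report.loc[0, "lesion_strand_reading"] == "T[A>T]A"

    def test_all_ratios_above_one_empty_report(self):
        from uvmut.asymmetry import AsymmetryRow

        rows = [AsymmetryRow("A[C>T]G", 90, 10, 100, 100, 9.0, 64.0, 1e-15, True, False)]
        assert reverse_asymmetry_report(rows).empty
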