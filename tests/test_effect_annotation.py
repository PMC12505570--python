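"""Codon classification, ANN parsing, effect summaries and spectra."""

import math

import numpy as np
import pytest

from subgenome_scan import (
    GeneModel, SimParams, annotate_sites, classify_codon_change,
    classify_coding_snp, compare_afs, compare_proportions, effect_summary,
    impact_afs, parse_snpeff_ann, simulate,
)
from subgenome_scan.effect_annotation import EffectRecord

# independent codon table, spelled out rather than derived
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_classify(ref_codon, alt_codon):
    """Translate-and-compare oracle using the hand-written table."""
    a, b = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if a == b:
        return "silent", "Low"
    if b == "*":
        return "nonsense", "High"
    if a == "*":
        return "missense", "High"
    return "missense", "Moderate"


class TestCodonExamples:
    def test_synonymous(self):
        assert classify_codon_change("GAA", "GAG") == ("silent", "Low")

    def test_missense(self):
        assert classify_codon_change("GCT", "GTT") == ("missense", "Moderate")

    def test_stop_gain(self):
        assert classify_codon_change("CAA", "TAA") == ("nonsense", "High")

    def test_start_loss_is_high(self):
        assert classify_codon_change("ATG", "ACG", is_start=True) == \
            ("missense", "High")


class TestExhaustiveCodonOracle:
    def _gene_and_ref(self, codon, strand):
        """Chromosome carrying ATG + codon + TAA as a single-exon CDS."""
        cds = "ATG" + codon + "TAA"
        if strand == "+":
            ref = "CCCC" + cds + "CCCC"
            start = 5  # 1-based CDS start
        else:
            rc = "".join(COMP[b] for b in reversed(cds))
            ref = "CCCC" + rc + "CCCC"
            start = 5
        exon = (start, start + 8)
        gene = GeneModel("g.L", "g", "L", "c", strand, [exon], [(*exon, 0)])
        return gene, ref, start

    def test_all_codon_position_substitutions_both_strands(self):
        """64 codons x 3 positions x 3 alt bases on each strand agree with
        the translate-and-compare oracle."""
        n_checked = 0
        for codon in CODON_TABLE:
            for strand in ("+", "-"):
                gene, ref, start = self._gene_and_ref(codon, strand)
                for offset in range(3):
                    # genomic position of the codon base, strand-aware
                    if strand == "+":
                        pos = start + 3 + offset
                    else:
                        pos = start + 8 - 3 - offset
                    ref_base = ref[pos - 1]
                    cds_base = ref_base if strand == "+" else COMP[ref_base]
                    for alt_cds in "ACGT":
                        if alt_cds == cds_base:
                            continue
                        alt_genomic = alt_cds if strand == "+" else COMP[alt_cds]
                        got = classify_coding_snp(gene, ref, pos, ref_base,
                                                  alt_genomic)
                        alt_codon = codon[:offset] + alt_cds + codon[offset + 1:]
                        assert got == oracle_classify(codon, alt_codon), \
                            (codon, offset, alt_cds, strand)
                        n_checked += 1
        assert n_checked == 64 * 3 * 3 * 2

    def test_position_outside_cds_is_modifier(self):
        gene, ref, start = self._gene_and_ref("AAA", "+")
        assert classify_coding_snp(gene, ref, 2, ref[1], "A" if ref[1] != "A"
                                   else "G") == ("noncoding", "Modifier")

    def test_reference_mismatch_rejected(self):
        gene, ref, start = self._gene_and_ref("AAA", "+")
        wrong = "G" if ref[start + 3 - 1] != "G" else "T"
        with pytest.raises(ValueError, match="mismatch"):
            classify_coding_snp(gene, ref, start + 3, wrong, "A")


class TestAnnParsing:
    @pytest.mark.parametrize("ann,expect", [
        ("T|missense_variant|MODERATE|g|g|x|t1|c|1/2|...",
         ("missense", "Moderate")),
        ("T|synonymous_variant|LOW|g|g|x|t1|c|1/2|...", ("silent", "Low")),
        ("T|stop_gained|HIGH|g|g|x|t1|c|1/2|...", ("nonsense", "High")),
        ("T|intergenic_region|MODIFIER|g|g|x|t1|c|1/2|...",
         ("noncoding", "Modifier")),
    ])
    def test_vocabulary_mapping(self, ann, expect):
        assert parse_snpeff_ann(ann) == expect

    def test_first_entry_wins(self):
        ann = ("T|stop_gained|HIGH|g||||||,T|synonymous_variant|LOW|g||||||")
        assert parse_snpeff_ann(ann) == ("nonsense", "High")

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_snpeff_ann("oops")


def _rec(impact, fc, freq, sub="L"):
    return EffectRecord("c", 1, impact, fc, freq, sub)


class TestEffectSummary:
    def test_ratio_and_conservation(self):
        recs = [_rec("Moderate", "missense", 0.1)] * 10 + \
               [_rec("Low", "silent", 0.1)] * 10 + \
               [_rec("High", "nonsense", 0.1)] * 2
        df = effect_summary(recs)
        row = df[df.subgenome == "L"].iloc[0]
        assert row["missense_silent_ratio"] == pytest.approx(1.0)
        assert row["impact_High_prop"] + row["impact_Moderate_prop"] + \
            row["impact_Low_prop"] == pytest.approx(1.0)

    def test_zero_silent_ratio_undefined(self):
        df = effect_summary([_rec("Moderate", "missense", 0.1)] * 3)
        assert math.isnan(df.iloc[0]["missense_silent_ratio"])

    def test_proportion_test_symmetric(self):
        z, p = compare_proportions(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0
        z2, _ = compare_proportions(80, 100, 50, 100)
        assert z2 > 0


class TestImpactAfs:
    def test_deflated_class_shifts_left(self):
        """High-impact variants simulated with a frequency deflation factor
        sit at lower mean frequency than Low-impact ones."""
        params = SimParams(seed=21, n_chrom_pairs=1, chrom_length=400_000,
                           pop_sizes=(10, 10), n_genes_per_chrom=20,
                           exon_length_range=(600, 900),
                           intron_length_range=(100, 300),
                           gene_gap_range=(500, 2_000), theta=2e-2,
                           trough_depth=0.0,  # isolate the impact deflation
                           impact_mix=(0.4, 0.4, 0.2))
        c = simulate(params)
        recs = annotate_sites(c.gm, c.genes, c.reference, c.subgenome_map,
                              c.pop_map, "pop1")
        mean = {imp: np.mean([r.derived_freq for r in recs if r.impact == imp])
                for imp in ("High", "Moderate", "Modifier")}
        assert mean["High"] < mean["Moderate"] < mean["Modifier"]

    def test_single_frequency_single_bin(self):
        recs = [_rec("Low", "silent", 0.42)] * 5
        df = impact_afs(recs, n_bins=10)
        occupied = df[df["count"] > 0]
        assert len(occupied) == 1
        assert occupied.iloc[0]["bin_start"] == pytest.approx(0.4)
        assert occupied.iloc[0]["proportion"] == 1.0

    def test_ground_truth_classes_recovered(self, cohort):
        """The annotator reproduces the generator's committed effect classes
        at every coding site."""
        recs = annotate_sites(cohort.gm, cohort.genes, cohort.reference,
                              cohort.subgenome_map, cohort.pop_map, "pop1")
        by_pos = {(r.chrom, r.pos): r for r in recs}
        n_coding = 0
        for i in range(cohort.gm.n_sites):
            key = (cohort.gm.chrom[i], int(cohort.gm.pos[i]))
            if key not in by_pos:
                continue
            truth_fc = cohort.ground_truth.func_class[i]
            assert by_pos[key].func_class == truth_fc
            n_coding += truth_fc != "noncoding"
        assert n_coding > 0

    def test_compare_afs_needs_both_subgenomes(self):
        recs = [_rec("High", "nonsense", 0.1, "L")] * 5 + \
               [_rec("High", "nonsense", 0.2, "S")] * 5
        res = compare_afs(recs, "High")
        assert res.n1 == 5 and res.n2 == 5
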