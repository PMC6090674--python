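"""Unit tests for junction merging, circRNA classification and lncRNA filters."""

import numpy as np
import pandas as pd
import pytest

from cernaforge.annotation import (
    GenomeIndex,
    TranscriptCandidate,
    classify_all,
    classify_circ,
    filter_lncrna_candidates,
    junctions_to_frame,
    longest_orf,
    merge_junction_calls,
)
from tests.conftest import make_junction


def frame(rows, samples=("Day4", "Day6")):
    recs = []
    for chrom, start, end, name, strand, reads in rows:
        rec = dict(chrom=chrom, start=start, end=end, name=name, score=max(reads), strand=strand)
        rec.update(dict(zip(samples, reads)))
        recs.append(rec)
    return pd.DataFrame(recs)


class TestMergeJunctionCalls:
    def test_union_and_max_support(self):
        a = frame([("chr1", 10, 200, "j1", "+", [3, 0])])
        b = frame([("chr1", 10, 200, "j1", "+", [1, 0])])
        out = merge_junction_calls({"A": a, "B": b})
        assert len(out) == 1
        assert out[0].callers == {"A", "B"}
        assert out[0].junction_reads.max() == 3

    def test_single_read_junction_filtered(self):
        a = frame([("chr1", 10, 200, "weak", "+", [1, 1]),
                   ("chr1", 300, 500, "ok", "+", [0, 2])])
        out = merge_junction_calls({"A": a})
        assert [j.name for j in out] == ["ok"]

    def test_summed_mode(self):
        a = frame([("chr1", 10, 200, "weak", "+", [1, 1])])
        assert len(merge_junction_calls({"A": a}, support_mode="summed")) == 1

    def test_empty_inputs(self):
        empty = frame([]).reindex(columns=["chrom", "start", "end", "name", "score", "strand"])
        assert merge_junction_calls({"A": empty, "B": empty}) == []

    def test_idempotent(self):
        a = frame([("chr1", 10, 200, "j1", "+", [3, 0]), ("chr1", 400, 600, "j2", "-", [0, 5])])
        b = frame([("chr1", 10, 200, "j1", "+", [2, 2])])
        once = merge_junction_calls({"A": a, "B": b})
        again = merge_junction_calls({"merged": junctions_to_frame(once)})
        assert [(j.key, j.junction_reads.max()) for j in once] == \
               [(j.key, j.junction_reads.max()) for j in again]

    def test_malformed_row_reports_line(self):
        bad = frame([("chr1", 500, 200, "j1", "+", [3, 0])])
        with pytest.raises(ValueError, match="line 2"):
            merge_junction_calls({"A": bad})

    def test_inconsistent_chromosomes_rejected(self):
        a = frame([("chr1", 10, 200, "j1", "+", [3, 0])])
        b = frame([("1", 10, 200, "j1", "+", [3, 0])])
        with pytest.raises(ValueError, match="inconsistent chromosome names"):
            merge_junction_calls({"A": a, "B": b})


class TestClassifyCirc:
    def test_exonic_single_gene(self, toy_genes):
        j = make_junction("chr1", 150, 950, "+")  # ends inside exon1 and exon3 of g1
        assert classify_circ(j, toy_genes) == "exonic"
        assert j.parent_genes == {"g1"}

    def test_two_genes_is_other(self, toy_genes):
        j = make_junction("chr1", 150, 2500, "+")
        assert classify_circ(j, toy_genes) == "other"
        assert j.parent_genes == {"g1", "g2"}

    def test_gene_desert_is_intergenic(self, toy_genes):
        j = make_junction("chr1", 1200, 1800, "+")
        assert classify_circ(j, toy_genes) == "intergenic"
        assert j.parent_genes == set()

    def test_intronic(self, toy_genes):
        j = make_junction("chr1", 320, 480, "+")  # inside g1's first intron
        assert classify_circ(j, toy_genes) == "intronic"

    def test_unknown_strand_hits_minus_gene(self, toy_genes):
        j = make_junction("chr2", 80, 450, ".")
        assert classify_circ(j, toy_genes) == "exonic"
        # a plus-strand junction over the same span misses the minus-strand gene
        j2 = make_junction("chr2", 80, 450, "+")
        assert classify_circ(j2, toy_genes) == "intergenic"

    def test_partition_and_bruteforce_agreement(self, default_dataset):
        """Every fixture junction gets exactly one class, equal to a brute-force scan."""
        calls = default_dataset.junction_calls
        junctions = merge_junction_calls(calls, min_reads=1)
        classify_all(junctions, default_dataset.genes)
        genes = default_dataset.genes
        for j in junctions:
            assert j.circ_class in ("exonic", "intronic", "intergenic", "other")
            hits = [g for g in genes
                    if g.chrom == j.chrom and g.start < j.end and j.start < g.end
                    and (j.strand == "." or g.strand == j.strand)]
            coding = [g for g in hits if g.biotype == "protein_coding"]
            if not hits:
                expected = "intergenic"
            elif len(coding) >= 2:
                expected = "other"
            elif len(coding) == 1:
                g = coding[0]
                in_exon = lambda p: any(s <= p < e for s, e in g.exons)
                if in_exon(j.start) and in_exon(j.end - 1):
                    expected = "exonic"
                elif any(s <= j.start and j.end <= e for s, e in g.introns):
                    expected = "intronic"
                else:
                    expected = "other"
            else:
                expected = "other"
            assert j.circ_class == expected, j.name

    def test_fixture_classes_match_ground_truth(self, default_dataset):
        junctions = merge_junction_calls(default_dataset.junction_calls, min_reads=1)
        classify_all(junctions, default_dataset.genes)
        for j in junctions:
            assert j.circ_class == default_dataset.truth.circ_classes[j.name], j.name


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAG", 2),        # Met-Lys
            ("CCCCCC", 0),            # no start codon
            ("ATGTAA", 1),            # bare Met
            ("AATGAAATAGC", 2),       # frame 1
            ("ATGAAAATGAAATAA", 4),   # nested starts, longest wins
        ],
    )
    def test_examples(self, seq, expected):
        assert longest_orf(seq) == expected

    def test_120aa_boundary_sequence(self):
        rng = np.random.default_rng(0)
        body = "".join(rng.choice(["AAA", "GGT", "GCA"], size=119).tolist())
        seq = "ATG" + body + "TAA"  # 363 nt encoding a 120-aa ORF
        assert len(seq) == 363
        assert longest_orf(seq) == 120

    def test_rejects_non_nucleotides(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            longest_orf("ATGXXX")


class TestLncrnaFilter:
    def cand(self, length=300, code="u", orf_codons=10, coding=None):
        seq = "ATG" + "GCA" * (orf_codons - 1) + "TAA"
        seq = seq + "C" * max(0, length - len(seq))
        return TranscriptCandidate("t", code, seq[:max(length, len(seq))], coding=coding)

    def test_length_boundary(self):
        short = TranscriptCandidate("t", "u", "C" * 199)
        exact = TranscriptCandidate("t", "u", "C" * 200)
        assert filter_lncrna_candidates([short]) == []
        assert filter_lncrna_candidates([exact]) == [exact]

    def test_orf_boundary_inclusive(self):
        ok = self.cand(length=400, orf_codons=120)
        too_long = self.cand(length=400, orf_codons=121)
        assert ok.longest_orf_aa == 120 and too_long.longest_orf_aa == 121
        assert filter_lncrna_candidates([ok, too_long]) == [ok]

    def test_class_code_and_coding_flag(self):
        wrong_code = TranscriptCandidate("t", "j", "C" * 300)
        flagged = TranscriptCandidate("t", "u", "C" * 300, coding=True)
        keep = TranscriptCandidate("t", "x", "C" * 300)
        assert filter_lncrna_candidates([wrong_code, flagged, keep]) == [keep]

    def test_fixture_rejects(self, default_dataset):
        retained = {c.transcript_id for c in filter_lncrna_candidates(default_dataset.lnc_candidates)}
        assert not retained & {"lncrej_short", "lncrej_orf", "lncrej_code", "lncrej_cnci"}
        assert len(retained) == default_dataset.config.n_lncrna


def test_genome_index_matches_linear_scan(toy_genes):
    idx = GenomeIndex(toy_genes)
    rng = np.random.default_rng(5)
    for _ in range(100):
        start = int(rng.integers(0, 2800))
        end = start + int(rng.integers(10, 800))
        fast = {g.gene_id for g in idx.overlapping("chr1", start, end)}
        slow = {g.gene_id for g in toy_genes
                if g.chrom == "chr1" and g.start < end and start < g.end}
        assert fast == slow
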