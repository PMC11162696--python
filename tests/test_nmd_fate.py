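import numpy as np
import pytest

from readthrough.iar_partition import GeneRecord
from readthrough.nmd_fate import (
    anchor_band,
    anchor_reads,
    classify_fate,
    consensus_insert,
    edit_distance,
    gene_spliced_seq,
    predict_fate,
    spliced_cds_start,
)
from readthrough.simulate import apply_errors
from readthrough.sketch import reverse_complement

ALA = "GCT"  # stop-free filler codon


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _nonstop(n_codons):
    return ALA * n_codons


def build_locus(insert_codons=0, stop="", filler=0, d1_len=60, d2_seq=None):
    """Single-exon upstream CDS gene + two-exon downstream gene on '+'.

    The fused model is U(93) + insert + Dexon1(d1_len) + Dexon2; the insert
    is ``insert_codons`` stop-free codons, an optional stop codon, then
    ``filler`` junk bases.
    """
    rng = np.random.default_rng(123)
    u_seq = "ATG" + _nonstop(30)  # 93 nt, stop-free, in frame from 0
    d2 = d2_seq if d2_seq is not None else _rand(rng, 80)
    d1 = _nonstop(d1_len // 3) + "A" * (d1_len % 3)
    intron = _rand(rng, 50)
    gap = _rand(rng, 40)
    chrom = u_seq + gap + d1 + intron + d2
    u = GeneRecord("U", "U", "c", "+", 1, 93, exons=[(1, 93)], cds=(1, 93))
    d_start = 93 + len(gap) + 1
    d = GeneRecord(
        "D",
        "D",
        "c",
        "+",
        d_start,
        d_start + len(d1) + 50 + len(d2) - 1,
        exons=[
            (d_start, d_start + len(d1) - 1),
            (d_start + len(d1) + 50, d_start + len(d1) + 50 + len(d2) - 1),
        ],
    )
    insert = _nonstop(insert_codons) + stop + _rand(rng, filler)
    return {"c": chrom}, u, d, insert


class TestClassifyFate:
    def test_in_frame_stop_far_from_junction_is_nmd(self):
        # TAA lands 120 nt upstream of the last junction (filler 60 + d1 60)
        genome, u, d, insert = build_locus(insert_codons=30, stop="TAA", filler=60, d1_len=60)
        res = classify_fate(None, insert, u, d, genome)
        assert res.ptc_found
        assert res.stop_codon == "TAA"
        assert res.distance_to_last_junction == 120
        assert res.classification == "NMD"

    def test_stop_within_55nt_escapes(self):
        genome, u, d, insert = build_locus(insert_codons=30, stop="TAA", filler=20, d1_len=9)
        res = classify_fate(None, insert, u, d, genome)
        assert res.distance_to_last_junction == 29
        assert res.classification == "protein_coding"

    def test_boundary_exactly_55_escapes(self):
        genome, u, d, insert = build_locus(insert_codons=30, stop="TAA", filler=0, d1_len=55)
        res = classify_fate(None, insert, u, d, genome)
        assert res.distance_to_last_junction == 55
        assert res.classification == "protein_coding"

    def test_distance_56_is_nmd(self):
        genome, u, d, insert = build_locus(insert_codons=30, stop="TAA", filler=0, d1_len=56)
        res = classify_fate(None, insert, u, d, genome)
        assert res.distance_to_last_junction == 56
        assert res.classification == "NMD"

    def test_stop_only_in_downstream_last_exon(self):
        # in-frame fusion, stop first appears after the last junction
        genome, u, d, insert = build_locus(
            insert_codons=10, stop="", filler=0, d1_len=60, d2_seq="TAA" + ALA * 10
        )
        res = classify_fate(None, insert, u, d, genome)
        assert res.ptc_found
        assert res.distance_to_last_junction == -3
        assert res.classification == "protein_coding"

    def test_no_stop_anywhere_flagged_protein_coding(self):
        genome, u, d, insert = build_locus(
            insert_codons=10, stop="", filler=0, d1_len=60, d2_seq=ALA * 20
        )
        res = classify_fate(None, insert, u, d, genome)
        assert not res.ptc_found
        assert res.classification == "protein_coding"
        assert res.no_valid_stop

    def test_missing_cds_indeterminate(self):
        genome, u, d, insert = build_locus()
        u.cds = None
        res = classify_fate(None, insert, u, d, genome)
        assert res.classification == "indeterminate"

    def test_frame_conservation_empty_insert(self):
        # empty in-frame insert introduces no PTC before the last exon
        genome, u, d, _ = build_locus(d1_len=60, d2_seq="TAA" + ALA * 10)
        res = classify_fate(None, "", u, d, genome)
        assert res.classification == "protein_coding"

    def test_determinism(self):
        genome, u, d, insert = build_locus(insert_codons=30, stop="TAA", filler=60)
        assert classify_fate(None, insert, u, d, genome) == classify_fate(
            None, insert, u, d, genome
        )


class TestSplicedHelpers:
    def test_spliced_cds_start_plus(self):
        gene = GeneRecord("g", "g", "c", "+", 1, 100, exons=[(1, 40), (61, 100)], cds=(70, 90))
        assert spliced_cds_start(gene) == 40 + (70 - 61)

    def test_spliced_cds_start_minus(self):
        gene = GeneRecord("g", "g", "c", "-", 1, 100, exons=[(1, 40), (61, 100)], cds=(10, 90))
        # 5' CDS start is the genomic end (90) on the minus strand
        assert spliced_cds_start(gene) == 100 - 90

    def test_gene_spliced_seq_minus_strand(self):
        genome = {"c": "AACCGGTTAACC"}
        gene = GeneRecord("g", "g", "c", "-", 1, 12, exons=[(1, 4), (9, 12)])
        exon_seqs, spliced = gene_spliced_seq(genome, gene)
        assert spliced == reverse_complement("AACC" + "AACC")
        assert exon_seqs == ["GGTT", "GGTT"]


class TestConsensus:
    def test_majority_vote_fixes_single_substitution(self):
        segs = ["ACGTACGT", "ACGTACGT", "ACGAACGT"]
        assert consensus_insert(segs) == "ACGTACGT"

    def test_single_segment_identity(self):
        assert consensus_insert(["ACGT"]) == "ACGT"

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            consensus_insert([])

    def test_mostly_empty_segments_give_empty(self):
        assert consensus_insert(["", "", "", "ACGT"]) == ""

    def test_noisy_recovery_within_two_edits(self):
        rng = np.random.default_rng(21)
        truth = _rand(rng, 200)
        copies = [
            apply_errors(truth, np.random.default_rng(100 + i), 0.01, 0.01, 0.01)
            for i in range(10)
        ]
        consensus = consensus_insert(copies)
        assert edit_distance(consensus, truth) <= 2


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("", "", 0), ("A", "", 1), ("ACGT", "ACGT", 0), ("ACGT", "AGGT", 1), ("ACGT", "AC", 2),
         ("kitten".upper().replace("K", "G").replace("I", "A").replace("E", "C"), "", 6)],
    )
    def test_known_values(self, a, b, expected):
        # brute-force-checkable small cases
        assert edit_distance(a, b) == expected

    def test_insertion_and_deletion(self):
        assert edit_distance("ACGTACGT", "ACGACGT") == 1


def _two_exon_pair(rng):
    """Two-exon upstream and downstream genes for anchoring tests."""
    u_e1, u_e2 = _rand(rng, 90), _rand(rng, 60)
    d_e1, d_e2 = _rand(rng, 60), _rand(rng, 80)
    u_intron, d_intron, gap = _rand(rng, 50), _rand(rng, 40), _rand(rng, 70)
    chrom = u_e1 + u_intron + u_e2 + gap + d_e1 + d_intron + d_e2
    u = GeneRecord(
        "U", "U", "c", "+", 1, 200,
        exons=[(1, 90), (141, 200)], cds=(1, 200),
    )
    d_start = 200 + 70 + 1
    d = GeneRecord(
        "D", "D", "c", "+", d_start, d_start + 179,
        exons=[(d_start, d_start + 59), (d_start + 100, d_start + 179)],
    )
    return {"c": chrom}, u, d, u_e1 + u_e2, d_e1 + d_e2


class TestAnchorReads:
    def test_error_free_insert_recovered_exactly(self):
        rng = np.random.default_rng(31)
        genome, u, d, u_mrna, d_mrna = _two_exon_pair(rng)
        insert = _rand(rng, 37)
        read = u_mrna + insert + d_mrna
        result = anchor_reads([("r1", read)], u, d, genome)
        assert result.segments == [insert]
        assert result.boundary_exon == 1
        assert result.first_down_exon == 0
        assert result.n_failed == 0

    def test_reverse_oriented_read_is_handled(self):
        rng = np.random.default_rng(32)
        genome, u, d, u_mrna, d_mrna = _two_exon_pair(rng)
        insert = _rand(rng, 37)
        read = reverse_complement(u_mrna + insert + d_mrna)
        result = anchor_reads([("r1", read)], u, d, genome)
        assert result.segments == [insert]

    def test_upstream_only_read_excluded(self):
        rng = np.random.default_rng(33)
        genome, u, d, u_mrna, _ = _two_exon_pair(rng)
        result = anchor_reads([("r1", u_mrna)], u, d, genome)
        assert result.segments == []
        assert result.n_failed == 1

    def test_noisy_read_recovered_within_band(self):
        rng = np.random.default_rng(34)
        genome, u, d, u_mrna, d_mrna = _two_exon_pair(rng)
        insert = _rand(rng, 100)
        clean = u_mrna + insert + d_mrna
        noisy = apply_errors(clean, np.random.default_rng(35), 0.02, 0.015, 0.015)
        result = anchor_reads([("r1", noisy)], u, d, genome)
        assert len(result.segments) == 1
        assert edit_distance(result.segments[0], insert) <= anchor_band(len(insert))

    def test_junk_read_fails(self):
        rng = np.random.default_rng(36)
        genome, u, d, _, _ = _two_exon_pair(rng)
        result = anchor_reads([("r1", _rand(rng, 300))], u, d, genome)
        assert result.n_failed == 1


class TestPredictFateOnSimulation:
    def test_spliced_out_fusions_classify_nmd(self, small_calls, small_sim):
        # upstream's own stop is retained far upstream of the fused last junction
        _cfg, sim, _reads = small_sim
        sim_, reads, calls = small_calls
        reads_by_id = {r.read_id: r.seq for r in reads}
        for call in calls:
            res = predict_fate(call, reads_by_id, sim.chrom_seqs)
            assert res.classification == "NMD"
            assert res.consensus_insert == ""
            again = predict_fate(call, reads_by_id, sim.chrom_seqs)
            assert res == again
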