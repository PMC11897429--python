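import numpy as np
import pytest

from scnanosim.counts import CountMatrix
from scnanosim.paf import PafRecord
from scnanosim.templates import (
    ReadStructure,
    TranscriptomeIndex,
    TruncationModel,
    apply_truncation,
    assemble_molecule,
    assign_barcodes,
    estimate_truncation_model,
    generate_perfect_reads,
    generate_umi,
    load_transcriptome,
    orient,
    pick_transcript,
    reverse_complement,
    unspliced_sequence,
    write_molecules_fasta,
)


def _paf(tstart, tend, tlen=1000, name="r"):
    span = tend - tstart
    return PafRecord(name, span, 0, span, "+", "t", tlen, tstart, tend,
                     span, span, 60, {"tp": "P"})


class TestLoadTranscriptome:
    def test_counts_and_gene_map(self, toy_index, toy_reference):
        assert toy_index.n_transcripts == len(toy_reference.transcripts)
        for gene, tids in toy_reference.gene_to_transcripts.items():
            assert sorted(toy_index.gene_to_transcripts[gene]) == sorted(tids)

    def test_sequences_unaltered(self, toy_index, toy_reference):
        for tid, seq in toy_reference.transcripts.items():
            assert toy_index.transcript_seq[tid] == seq

    def test_without_gtf_each_transcript_own_gene(self, toy_reference_paths):
        idx = load_transcriptome(toy_reference_paths["transcripts"])
        assert all(v == [k] for k, v in idx.gene_to_transcripts.items())

    def test_empty_fasta_rejected(self, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            load_transcriptome(empty)

    def test_gtf_transcript_missing_from_fasta_skipped(self, tmp_path):
        (tmp_path / "t.fa").write_text(">tx1\nACGTACGT\n")
        (tmp_path / "a.gtf").write_text(
            'chr1\tx\texon\t1\t8\t.\t+\t.\tgene_id "g"; transcript_id "tx1";\n'
            'chr1\tx\texon\t1\t4\t.\t+\t.\tgene_id "g"; transcript_id "tx_gone";\n'
        )
        with pytest.warns(UserWarning, match="tx_gone"):
            idx = load_transcriptome(tmp_path / "t.fa", tmp_path / "a.gtf")
        assert idx.gene_to_transcripts == {"g": ["tx1"]}


class TestPickTranscript:
    def test_single_transcript_gene(self, rng):
        idx = TranscriptomeIndex({"t1": "ACGT" * 10}, {"g": ["t1"]})
        assert pick_transcript("g", idx, rng=rng) == "t1"

    def test_unknown_gene(self, rng):
        idx = TranscriptomeIndex({"t1": "ACGT"}, {"g": ["t1"]})
        with pytest.raises(KeyError):
            pick_transcript("nope", idx, rng=rng)

    def test_equal_lengths_are_symmetric(self, rng):
        idx = TranscriptomeIndex(
            {"a": "A" * 100, "b": "C" * 100}, {"g": ["a", "b"]}
        )
        n = 10000
        hits = sum(pick_transcript("g", idx, rng=rng) == "a" for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) <= 3 * se

    def test_short_transcript_preference_closed_form(self, rng):
        # lengths 500 and 5000, tau 2000:
        # P(short) = exp(-0.25) / (exp(-0.25) + exp(-2.5)) ~ 0.905
        idx = TranscriptomeIndex(
            {"short": "A" * 500, "long": "C" * 5000}, {"g": ["short", "long"]}
        )
        expect = np.exp(-0.25) / (np.exp(-0.25) + np.exp(-2.5))
        n = 10000
        hits = sum(
            pick_transcript("g", idx, tau=2000.0, rng=rng) == "short"
            for _ in range(n)
        )
        assert abs(hits / n - expect) <= 0.01


class TestUnspliced:
    def test_single_exon_equals_spliced(self):
        genome = {"c": "AAACCCGGGTTT"}
        idx = TranscriptomeIndex(
            {"t": "CCCGGG"}, {"g": ["t"]},
            exon_structure={"t": ("c", "+", [(3, 9)])}, genome_seq=genome,
        )
        assert unspliced_sequence("t", idx) == "CCCGGG"

    def test_intron_retained_length(self, toy_reference, toy_index):
        # retained introns add exactly the intronic span
        for tid, (chrom, strand, exons) in toy_reference.exons.items():
            span = exons[-1][1] - exons[0][0]
            assert len(unspliced_sequence(tid, toy_index)) == span

    def test_minus_strand_is_reverse_complement_of_span(self, toy_reference, toy_index):
        minus = [
            tid for tid, (_, strand, _) in toy_reference.exons.items() if strand == "-"
        ]
        assert minus, "toy reference should contain minus-strand genes"
        for tid in minus:
            chrom, _, exons = toy_reference.exons[tid]
            span = toy_reference.genome[chrom][exons[0][0] : exons[-1][1]]
            assert unspliced_sequence(tid, toy_index) == reverse_complement(span)

    def test_missing_annotation_instructs(self):
        idx = TranscriptomeIndex({"t": "ACGT"}, {"g": ["t"]})
        with pytest.raises(ValueError, match="GTF"):
            unspliced_sequence("t", idx)


class TestTruncation:
    def test_full_length_alignments_concentrate_in_corner(self, rng):
        model = estimate_truncation_model([_paf(0, 1000) for _ in range(20)], n_bins=10)
        assert model.probs[0, -1] == 1.0
        # corner bin of full-length records: start bin [0, .1), end bin (.9, 1]
        s, e = model.sample(rng)
        assert s < 0.1 and e > 0.9

    def test_constructed_quarter_truncation_single_bin(self):
        model = estimate_truncation_model(
            [_paf(250, 750) for _ in range(50)], n_bins=4
        )
        # rel end 0.75 sits on an interior edge and belongs to the right bin
        assert model.probs[1, 3] == 1.0
        assert (model.probs > 0).sum() == 1

    def test_probabilities_sum_to_one(self, rng):
        recs = [_paf(int(s), int(e))
                for s, e in rng.integers(0, 500, (100, 2)) * [1, 1] + [0, 500]]
        model = estimate_truncation_model(recs, n_bins=7)
        assert model.probs.sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_truncation_model([], n_bins=5)

    def test_degenerate_full_length_model_is_identity(self, rng):
        cdna = "ACGT" * 100
        sub, start, end = apply_truncation(cdna, TruncationModel.full_length(), rng)
        assert (sub, start, end) == (cdna, 0, len(cdna))

    def test_concentrated_model_retained_length(self, rng):
        model = estimate_truncation_model([_paf(100, 900) for _ in range(10)], n_bins=10)
        cdna = "A" * 1000
        lengths = [len(apply_truncation(cdna, model, rng)[0]) for _ in range(200)]
        # (0.1, 0.9) bin pair, bin width 0.1 -> retained 800 +- 100 each side
        assert all(600 <= L <= 1000 for L in lengths)
        assert abs(np.mean(lengths) - 800) < 50

    def test_truncation_invariant(self, rng):
        model = estimate_truncation_model(
            [_paf(int(s), int(s) + 10, tlen=100) for s in rng.integers(0, 90, 50)],
            n_bins=13,
        )
        cdna = "ACGT" * 25
        for _ in range(2000):
            sub, start, end = apply_truncation(cdna, model, rng)
            assert 0 <= start < end <= len(cdna)
            assert sub == cdna[start:end]


class TestAssembly:
    def test_umi_alphabet_and_determinism(self):
        rng = np.random.default_rng(7)
        umi = generate_umi(12, rng)
        assert len(umi) == 12 and not set(umi) - set("ACGT")
        assert generate_umi(12, np.random.default_rng(7)) == umi

    def test_umi_base_frequencies(self, rng):
        draws = "".join(generate_umi(1, rng) for _ in range(100000))
        se = np.sqrt(0.25 * 0.75 / 100000)
        for base in "ACGT":
            assert abs(draws.count(base) / 100000 - 0.25) <= 3 * se

    def test_polyt_spacer_is_20_t(self):
        s = ReadStructure()
        mol = assemble_molecule("A" * 16, "C" * 12, "GGG", s)
        offset = len(s.adapter) + 16 + 12
        assert mol[offset : offset + 20] == "T" * 20
        assert s.polyt_length == 20

    def test_component_order_and_length(self):
        s = ReadStructure(adapter="AACC", tso="GGTT", cb_length=2, umi_length=2,
                          polyt_length=3)
        mol = assemble_molecule("CA", "GT", "ACGTA", s)
        assert mol == "AACC" + "CA" + "GT" + "TTT" + "ACGTA" + "GGTT"
        mol_empty = assemble_molecule("CA", "GT", "", s)
        assert mol_empty == "AACC" + "CA" + "GT" + "TTT" + "GGTT"

    def test_length_mismatch_rejected(self):
        s = ReadStructure()
        with pytest.raises(ValueError):
            assemble_molecule("A" * 15, "C" * 12, "G", s)
        with pytest.raises(ValueError):
            assemble_molecule("A" * 16, "C" * 11, "G", s)

    def test_reverse_complement(self):
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("AAAC") == "GTTT"
        assert reverse_complement("ANC") == "GNT"

    def test_orientation_balance(self, rng):
        n = 10000
        minus = sum(orient("ACGTACGT", rng)[1] == "-" for _ in range(n))
        assert abs(minus / n - 0.5) <= 0.015


class TestAssignBarcodes:
    def test_valid_barcode_ids_pass_through(self, rng):
        ids = ["ACGTACGTACGTACGT", "TTTTACGTACGTACGT"]
        assert assign_barcodes(ids, None, 16, rng) == {i: i for i in ids}

    def test_whitelist_drawn_without_replacement(self, rng):
        wl = ["AAAA", "CCCC", "GGGG", "TTTT"]
        mapping = assign_barcodes(["c1", "c2", "c3"], wl, 4, rng)
        assert len(set(mapping.values())) == 3
        assert set(mapping.values()) <= set(wl)

    def test_whitelist_too_small(self, rng):
        with pytest.raises(ValueError, match="whitelist"):
            assign_barcodes(["c1", "c2"], ["AAAA"], 4, rng)

    def test_generated_barcodes_distinct(self, rng):
        mapping = assign_barcodes([f"c{i}" for i in range(50)], None, 16, rng)
        assert len(set(mapping.values())) == 50


class TestGeneratePerfectReads:
    def test_count_conservation_exact(self, toy_index):
        genes = list(toy_index.gene_to_transcripts)[:2]
        mat = CountMatrix(genes, ["c1", "c2"], np.array([[3, 0], [1, 2]]))
        records = generate_perfect_reads(mat, toy_index, seed=1)
        assert len(records) == 6
        by_cell = {}
        for r in records:
            by_cell[(r.gene_id, r.cell_barcode)] = by_cell.get(
                (r.gene_id, r.cell_barcode), 0
            ) + 1
        barcodes = {r.cell_barcode for r in records if r.gene_id == genes[0]}
        assert len(barcodes) == 1  # cell c2 has no counts for gene 0
        assert sorted(by_cell.values()) == [1, 2, 3]

    def test_all_zero_matrix(self, toy_index, tmp_path):
        genes = list(toy_index.gene_to_transcripts)[:1]
        mat = CountMatrix(genes, ["c1"], np.zeros((1, 1), dtype=int))
        records = generate_perfect_reads(mat, toy_index, seed=1)
        assert records == []
        fasta = write_molecules_fasta(records, tmp_path / "empty.fasta")
        assert fasta.read_text() == ""

    def test_total_reads_for_random_matrix(self, toy_index, rng):
        genes = list(toy_index.gene_to_transcripts)[:5]
        counts = rng.integers(0, 4, size=(5, 4))
        mat = CountMatrix(genes, [f"c{i}" for i in range(4)], counts)
        records = generate_perfect_reads(mat, toy_index, seed=2)
        assert len(records) == counts.sum()

    def test_unresolvable_feature_listed(self, toy_index):
        mat = CountMatrix(["no_such_gene"], ["c1"], np.array([[1]]))
        with pytest.raises(KeyError, match="no_such_gene"):
            generate_perfect_reads(mat, toy_index, seed=1)

    def test_structural_invariant_after_undoing_orientation(self, toy_index):
        genes = list(toy_index.gene_to_transcripts)
        mat = CountMatrix(genes, ["c1", "c2"],
                          np.full((len(genes), 2), 3, dtype=int))
        structure = ReadStructure()
        records = generate_perfect_reads(mat, toy_index, structure, seed=3)
        assert {r.strand for r in records} == {"+", "-"}
        for r in records:
            seq = r.sequence if r.strand == "+" else reverse_complement(r.sequence)
            assert seq.startswith(structure.adapter)
            assert seq.endswith(structure.tso)
            offset = len(structure.adapter) + structure.cb_length + structure.umi_length
            assert seq[offset : offset + 20] == "T" * 20
            assert seq[len(structure.adapter) : offset - 12] == r.cell_barcode
            cdna_len = r.trunc_end - r.trunc_start
            expected_len = (
                len(structure.adapter) + 16 + 12 + 20 + cdna_len + len(structure.tso)
            )
            assert len(seq) == expected_len
            assert 0 <= r.trunc_start < r.trunc_end

    def test_transcript_level_matrix(self, toy_index):
        tids = list(toy_index.transcript_seq)[:2]
        mat = CountMatrix(tids, ["c1"], np.array([[2], [1]]))
        records = generate_perfect_reads(mat, toy_index, seed=4)
        assert sorted({r.transcript_id for r in records}) == sorted(tids)

    def test_determinism_byte_identical(self, toy_index, toy_matrix, tmp_path):
        a = generate_perfect_reads(toy_matrix, toy_index, seed=99)
        b = generate_perfect_reads(toy_matrix, toy_index, seed=99)
        fa = write_molecules_fasta(a, tmp_path / "a.fasta")
        fb = write_molecules_fasta(b, tmp_path / "b.fasta")
        assert fa.read_bytes() == fb.read_bytes()

    def test_intron_retention_produces_longer_molecules(self, toy_index, toy_reference):
        genes = list(toy_index.gene_to_transcripts)
        mat = CountMatrix(genes, ["c1"], np.full((len(genes), 1), 5, dtype=int))
        spliced = generate_perfect_reads(mat, toy_index, seed=5)
        retained = generate_perfect_reads(
            mat, toy_index, intron_retention_prob=1.0, seed=5
        )
        assert all(r.unspliced for r in retained)
        assert not any(r.unspliced for r in spliced)
        assert sum(len(r.sequence) for r in retained) > sum(
            len(r.sequence) for r in spliced
        )
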