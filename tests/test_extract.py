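"""Flanking-anchor insert extraction and the k-mer count table."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tfy1h.extract import KmerTable, extract_all, extract_insert, unique_inserts
from tfy1h.library_model import (
    design_template,
    enumerate_inserts,
    reverse_complement,
)
from tfy1h.qc import ReadRecord
from tfy1h.simulate import SimulationConfig, run_simulation


def _oracle_anchor_hits(seq, anchor, max_mismatch):
    """Exhaustive alignment oracle: all placements within the budget."""
    return [
        i
        for i in range(len(seq) - len(anchor) + 1)
        if sum(a != b for a, b in zip(seq[i : i + len(anchor)], anchor)) <= max_mismatch
    ]


class TestExtractInsert:
    def test_amplicon_with_gcc_box_insert(self, design7):
        read = design7.with_insert("AGCCGCC")
        assert extract_insert(read, design7) == ("AGCCGCC", "extracted")

    def test_strand_invariance_on_amplicon(self, design7):
        read = design7.with_insert("AGCCGCC")
        assert extract_insert(reverse_complement(read), design7) == (
            "AGCCGCC",
            "extracted",
        )

    def test_random_read_has_no_anchor(self, design7):
        # fixed arbitrary sequence; oracle confirms no anchor placement
        read = ("ACGGT" * 30)[:125]
        up = design7.upstream_flank[-12:]
        down = design7.downstream_flank[:12]
        for strand in (read, reverse_complement(read)):
            assert not _oracle_anchor_hits(strand, up, 1)
            assert not _oracle_anchor_hits(strand, down, 1)
        assert extract_insert(read, design7) == (None, "no_anchor")

    def test_one_mismatch_in_anchor_tolerated(self, design7):
        read = design7.with_insert("AGCCGCC")
        start, _ = design7.insert_interval
        pos = start - 5  # inside the upstream anchor window
        mutated = read[:pos] + ("A" if read[pos] != "A" else "C") + read[pos + 1 :]
        assert extract_insert(mutated, design7, max_mismatch=1) == (
            "AGCCGCC",
            "extracted",
        )
        assert extract_insert(mutated, design7, max_mismatch=0) == (None, "no_anchor")

    def test_wrong_gap_reason(self, design7):
        up, down = design7.upstream_flank, design7.downstream_flank
        read = up + "AGCCGCCA" + down  # 8-base gap, k=7
        assert extract_insert(read, design7) == (None, "wrong_gap")

    def test_ambiguous_two_placements(self, design7):
        read = design7.with_insert("AGCCGCC") + design7.with_insert("TTTTTTT")
        assert extract_insert(read, design7) == (None, "ambiguous")

    def test_insert_with_n_rejected(self, design7):
        read = design7.upstream_flank + "AGCNGCC" + design7.downstream_flank
        assert extract_insert(read, design7) == (None, "contains_N")

    def test_anchor_longer_than_flank_rejected(self):
        short = design_template(7)
        with pytest.raises(ValueError, match="anchor_len"):
            extract_insert("ACGT" * 40, short, anchor_len=100)

    @given(st.text(alphabet="ACGT", min_size=100, max_size=150))
    def test_strand_invariance_property(self, seq):
        design7 = design_template(7)
        assert extract_insert(seq, design7) == extract_insert(
            reverse_complement(seq), design7
        )


class TestExtractAll:
    def test_counts_example(self, design7):
        reads = [
            ReadRecord(f"r{i}", design7.with_insert(ins), [40] * design7.full_length)
            for i, ins in enumerate(["AGCCGCC", "AGCCGCC", "GGCCGAA"])
        ]
        table, stats = extract_all(reads, design7)
        assert table.counts == {"AGCCGCC": 2, "GGCCGAA": 1}
        assert table.unique_count == 2 and table.total == 3
        assert stats.extracted == 3

    def test_empty_input(self, design7):
        table, stats = extract_all([], design7)
        assert table.counts == {} and stats.input_reads == 0

    def test_conservation_on_noisy_simulation(self, design7):
        cfg = SimulationConfig(
            n_colonies=3_000, fp_rate=0.05, depth=2, error_rate=0.02, seed=13
        )
        res = run_simulation(cfg)
        table, stats = extract_all(res.reads, design7)
        assert stats.input_reads == len(res.reads)
        assert table.total == stats.extracted

    def test_noiseless_table_equals_ground_truth(self, design7):
        cfg = SimulationConfig(
            n_colonies=5_000, fp_rate=0.02, depth=3, error_rate=0.0, seed=21
        )
        res = run_simulation(cfg)
        table, stats = extract_all(res.reads, design7, max_mismatch=0)
        truth = res.colony_truth
        expected = (
            truth.loc[truth["survived"], "insert"].value_counts() * cfg.depth
        ).to_dict()
        assert stats.success_rate == 1.0
        assert table.counts == expected

    def test_paired_concordant_counts_once(self, design7):
        amp = design7.with_insert("AGCCGCC")
        q = [40] * len(amp)
        mate1 = ReadRecord("p/1", amp, q)
        mate2 = ReadRecord("p/2", reverse_complement(amp), q)
        table, stats = extract_all([(mate1, mate2)], design7, paired=True)
        assert table.counts == {"AGCCGCC": 1} and stats.extracted == 1

    def test_paired_discordant_discarded(self, design7):
        q = [40] * design7.full_length
        mate1 = ReadRecord("p/1", design7.with_insert("AGCCGCC"), q)
        mate2 = ReadRecord("p/2", design7.with_insert("TTTTTTT"), q)
        table, stats = extract_all([(mate1, mate2)], design7, paired=True)
        assert table.counts == {} and stats.ambiguous == 1


class TestKmerTable:
    def test_unique_inserts_sorted(self):
        table = KmerTable(k=7, counts={"GGCCGAA": 1, "AGCCGCC": 2})
        assert unique_inserts(table) == ["AGCCGCC", "GGCCGAA"]

    def test_unique_inserts_empty(self):
        assert unique_inserts(KmerTable(k=7, counts={})) == []

    def test_saturated_k2_table(self):
        table = KmerTable(k=2, counts={km: 1 for km in enumerate_inserts(2)})
        assert unique_inserts(table) == enumerate_inserts(2)
        assert table.unique_count == 16

    def test_invalid_key_rejected(self):
        with pytest.raises(ValueError):
            KmerTable(k=7, counts={"ACGT": 1})

    def test_tsv_round_trip(self, tmp_path):
        table = KmerTable(k=3, counts={"ACG": 5, "TTT": 2})
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = KmerTable.from_tsv(path)
        assert back.k == 3 and back.counts == table.counts
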