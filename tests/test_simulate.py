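"""Synthetic-experiment generator: sampling, selection and read emission."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tfy1h.extract import extract_all, extract_insert
from tfy1h.library_model import enumerate_inserts, iupac_search
from tfy1h.simulate import (
    SimulationConfig,
    apply_selection,
    emit_reads,
    run_simulation,
    sample_prey_library,
)
from tfy1h.saturation import expected_distinct


class TestSamplePreyLibrary:
    def test_empty_library(self):
        assert sample_prey_library(0, 7, seed=0) == []

    def test_distinct_count_matches_coupon_collector(self):
        # closed-form mean and variance of the number of distinct inserts
        m, S = 150_000, 4**7
        colonies = sample_prey_library(m, 7, seed=11)
        distinct = len(set(colonies))
        mean = expected_distinct(m, S)
        q1 = (1 - 1 / S) ** m
        q2 = (1 - 2 / S) ** m
        var = S * q1 + S * (S - 1) * q2 - S**2 * q1**2
        assert abs(distinct - mean) <= 4 * math.sqrt(var) + 1

    def test_uniform_multinomial_chi_square(self):
        # goodness of fit against the uniform 4**2-cell multinomial
        pvals = []
        for seed in range(20):
            colonies = sample_prey_library(10_000, 2, seed=seed)
            counts = [colonies.count(km) for km in enumerate_inserts(2)]
            pvals.append(sps.chisquare(counts).pvalue)
        assert all(p > 0.001 for p in pvals)


class TestApplySelection:
    def test_zero_fp_exact_pattern(self):
        colonies = ["AGCCGCC", "AGCCGCC", "TTTTTTT", "ACGTACG"]
        survivors, truth = apply_selection(
            colonies, ["AGCCGCC"], match_mode="exact", fp_rate=0.0, seed=0
        )
        assert survivors == ["AGCCGCC", "AGCCGCC"]
        assert truth["matched"].tolist() == [True, True, False, False]
        assert truth["survived"].tolist() == truth["matched"].tolist()

    def test_fp_one_keeps_everything(self):
        colonies = ["AAAAAAA", "CCCCCCC"]
        survivors, _ = apply_selection(colonies, ["AGCCGCC"], "exact", 1.0, seed=0)
        assert survivors == colonies

    def test_pattern_wider_than_k_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            apply_selection(["ACG"], ["RGCCGA"], "substring", 0.0, seed=0)

    def test_survivor_fraction_matches_exhaustive_oracle(self):
        # oracle: scan all 16,384 7-mers for an RGCCGA substring match
        f = sum(iupac_search("RGCCGA", km) for km in enumerate_inserts(7)) / 4**7
        fp = 0.01
        expected_frac = f + fp * (1 - f)
        n = 150_000
        colonies = sample_prey_library(n, 7, seed=5)
        survivors, _ = apply_selection(colonies, ["RGCCGA"], "substring", fp, seed=6)
        sd = math.sqrt(expected_frac * (1 - expected_frac) / n)
        assert abs(len(survivors) / n - expected_frac) <= 5 * sd


class TestEmitReads:
    def test_noiseless_single_survivor_round_trip(self, design7):
        reads, truth = emit_reads(
            ["AGCCGCC"], design7, depth=5, error_rate=0.0, read_len=150, seed=3
        )
        assert len(reads) == 5
        assert len(truth) == 5
        for read in reads:
            insert, reason = extract_insert(read, design7)
            assert (insert, reason) == ("AGCCGCC", "extracted")

    def test_read_count_conservation(self, design7):
        survivors = ["AAAAAAA", "CCCCCCC", "GGGGGGG"]
        reads, truth = emit_reads(survivors, design7, depth=4, seed=0)
        assert len(reads) == len(survivors) * 4
        assert truth["colony_id"].nunique() == 3

    def test_paired_mode_emits_both_mates(self, design7):
        reads, _ = emit_reads(
            ["AGCCGCC"], design7, depth=2, error_rate=0.0, paired=True, seed=0
        )
        assert len(reads) == 4
        assert {r.identifier[-2:] for r in reads} == {"/1", "/2"}

    def test_short_read_len_rejected_with_guidance(self, design7):
        with pytest.raises(ValueError, match="read_len"):
            emit_reads(["AGCCGCC"], design7, read_len=50, seed=0)

    def test_error_fraction_matches_closed_form(self, design7):
        err = 0.005
        survivors = ["ACGTACG"] * 200
        reads, _ = emit_reads(survivors, design7, depth=10, error_rate=err, seed=9)
        amplicon = design7.with_insert("ACGTACG")
        rc = amplicon.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        n_errorful = sum(
            min(
                sum(a != b for a, b in zip(r.bases, amplicon)),
                sum(a != b for a, b in zip(r.bases, rc)),
            )
            > 0
            for r in reads
        )
        p = 1 - (1 - err) ** design7.full_length
        sd = math.sqrt(p * (1 - p) / len(reads))
        assert abs(n_errorful / len(reads) - p) <= 5 * sd

    def test_quality_scores_track_error_rate(self, design7):
        reads, _ = emit_reads(["AGCCGCC"], design7, depth=1, error_rate=0.001, seed=0)
        assert set(reads[0].qualities) == {30}
        reads, _ = emit_reads(["AGCCGCC"], design7, depth=1, error_rate=0.0, seed=0)
        assert set(reads[0].qualities) == {40}


class TestRunSimulation:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_colonies=500, depth=3, seed=42)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_simulation(cfg).write(out1)
        run_simulation(cfg).write(out2)
        assert (out1 / "reads.fastq").read_bytes() == (out2 / "reads.fastq").read_bytes()

    def test_noiseless_recoverable_inserts_equal_planted_matches(self, design7):
        cfg = SimulationConfig(
            n_colonies=20_000,
            binding_patterns=("AGCCGCC",),
            match_mode="exact",
            fp_rate=0.0,
            error_rate=0.0,
            depth=3,
            seed=7,
        )
        res = run_simulation(cfg)
        table, stats = extract_all(res.reads, design7)
        planted = set(
            res.colony_truth.loc[res.colony_truth["matched"], "insert"]
        )
        assert stats.success_rate == 1.0
        assert set(table.counts) == planted == {"AGCCGCC"}

    def test_survivor_count_binomial_given_truth(self):
        # replicate selection of non-matching colonies; survivors ~ Binomial(n, fp)
        fp, n = 0.05, 4_000
        colonies = ["AAAAAAA"] * n
        counts = []
        for seed in range(15):
            survivors, _ = apply_selection(colonies, ["CCCCCCC"], "exact", fp, seed)
            counts.append(len(survivors))
        mean, sd = n * fp, math.sqrt(n * fp * (1 - fp))
        assert abs(np.mean(counts) - mean) <= 4 * sd / math.sqrt(len(counts))
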