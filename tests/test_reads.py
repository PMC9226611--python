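"""Junction-read processing: approximate matching, extraction, quality gates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tnscreen._util import revcomp
from tnscreen.reads import (Insert, ProcessingConfig, RawRead, extract_insert,
                            find_approx, process_fastq, quality_truncate)

from _oracles import brute_find_approx

# Worked-example config: short junction, exact construct layouts.
EXAMPLE_CFG = ProcessingConfig(adapter_seq="AGATCGGAAGAGC", junction_seq="TCCGAC",
                               ir_remnant_len=4)
Q30 = chr(33 + 30)


def make_read(insert, cfg=EXAMPLE_CFG, ir="ACGG", trailer="", qual_char=Q30,
              read_id="r"):
    seq = revcomp(cfg.junction_seq) + ir + insert + cfg.adapter_seq + trailer
    return RawRead(read_id, seq, qual_char * len(seq))


class TestFindApprox:
    @pytest.mark.parametrize("seq,pattern,mm,expected", [
        ("AAAGATTACAAA", "GATTACA", 0, 3),
        ("AAAGATTTCAAA", "GATTACA", 2, 3),   # one mismatch
        ("AAAGATTTCAAA", "GATTACA", 0, None),
        ("AAAA", "GATTACAGATTACA", 2, None),  # pattern longer than seq
    ])
    def test_examples(self, seq, pattern, mm, expected):
        assert find_approx(seq, pattern, mm) == expected

    def test_planted_pattern_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        pattern = "GATTACAGATTACA"
        for _ in range(50):
            seq = list(rng.choice(list("ACGT"), size=200))
            p = int(rng.integers(0, 200 - len(pattern)))
            planted = list(pattern)
            for j in rng.choice(len(pattern), size=2, replace=False):
                planted[j] = rng.choice([b for b in "ACGT" if b != pattern[j]])
            seq[p:p + len(pattern)] = planted
            seq = "".join(seq)
            assert find_approx(seq, pattern, 2) == brute_find_approx(seq, pattern, 2)

    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=60),
           pattern=st.text(alphabet="ACGT", min_size=1, max_size=8),
           mm=st.integers(min_value=0, max_value=3))
    @settings(max_examples=300, derandomize=True)
    def test_agrees_with_bruteforce(self, seq, pattern, mm):
        assert find_approx(seq, pattern, mm) == brute_find_approx(seq, pattern, mm)


class TestQualityTruncate:
    def test_truncates_before_first_low_quality_base(self):
        qual = "".join(chr(33 + q) for q in [30, 30, 30, 15, 30])
        assert quality_truncate("ACGTA", qual, EXAMPLE_CFG) == ("ACG", qual[:3])

    def test_all_high_quality_unchanged(self):
        assert quality_truncate("ACGT", Q30 * 4, EXAMPLE_CFG) == ("ACGT", Q30 * 4)

    def test_all_low_quality_empty(self):
        q10 = chr(33 + 10)
        assert quality_truncate("ACGT", q10 * 4, EXAMPLE_CFG) == ("", "")


class TestExtractInsert:
    def test_documented_layout_yields_planted_insert(self):
        insert = "TACGTACGTACGTA"
        out = extract_insert(make_read(insert), EXAMPLE_CFG)
        assert isinstance(out, Insert)
        assert out.seq == insert and out.qual == Q30 * 14

    def test_non_ta_insert_rejected(self):
        assert extract_insert(make_read("GGCGTACGTACGTA"), EXAMPLE_CFG) == "non_ta_start"

    def test_short_insert_rejected(self):
        assert (extract_insert(make_read("TACGTACGTACGT"), EXAMPLE_CFG)
                == "length_out_of_range")

    def test_canonical_geometry_gives_14bp(self):
        # the MmeI geometry leaves exactly 14 genomic bases before the adapter
        out = extract_insert(make_read("TACGGCTTGCATGC"), EXAMPLE_CFG)
        assert isinstance(out, Insert) and len(out.seq) == 14

    def test_missing_junction_rejected(self):
        read = RawRead("r", "ACGT" * 20, Q30 * 80)
        assert extract_insert(read, EXAMPLE_CFG) == "no_junction"

    def test_no_adapter_keeps_whole_read(self):
        # a read that stops right at the insert (no adapter present) still works
        insert = "TACGGCTTGCATGC"
        cfg = EXAMPLE_CFG
        seq = revcomp(cfg.junction_seq) + "ACGG" + insert
        out = extract_insert(RawRead("r", seq, Q30 * len(seq)), cfg)
        assert isinstance(out, Insert) and out.seq == insert

    def test_trailer_after_adapter_does_not_change_insert(self):
        insert = "TACGGCTTGCATGC"
        a = extract_insert(make_read(insert), EXAMPLE_CFG)
        b = extract_insert(make_read(insert, trailer="GGTTCCAAGGTTCC"), EXAMPLE_CFG)
        assert a.seq == b.seq and a.qual == b.qual

    def test_low_quality_tail_rejected_as_quality_fail(self):
        insert = "TACGGCTTGCATGC"
        cfg = EXAMPLE_CFG
        seq = revcomp(cfg.junction_seq) + "ACGG" + insert + cfg.adapter_seq
        # degrade quality from 4 bases into the insert onward
        good = 6 + 4 + 4
        qual = Q30 * good + chr(33 + 2) * (len(seq) - good)
        assert extract_insert(RawRead("r", seq, qual), cfg) == "quality_fail"


def _write_fastq(path, reads):
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


class TestProcessFastq:
    # Bulk tests use the default config: its junction anchor is long enough
    # that a 2-mismatch budget cannot fire spuriously inside random inserts.
    def test_well_formed_reads_all_accepted(self, tmp_path):
        cfg = ProcessingConfig()
        rng = np.random.default_rng(0)
        reads = []
        for i in range(1000):
            insert = "TA" + "".join(rng.choice(list("ACGT"), size=12))
            reads.append(make_read(insert, cfg=cfg, read_id=f"r{i}"))
        path = tmp_path / "in.fq"
        _write_fastq(path, reads)
        inserts, stats = process_fastq(path, cfg)
        assert stats.n_accepted == 1000 and stats.n_input == 1000
        assert stats.mean_insert_len == pytest.approx(14.0)
        assert [i.read_id for i in inserts[:3]] == ["r0", "r1", "r2"]  # order kept

    def test_planted_non_ta_fraction_counted(self, tmp_path):
        cfg = ProcessingConfig()
        rng = np.random.default_rng(1)
        reads, planted = [], 0
        for i in range(500):
            if rng.random() < 0.1:
                insert = "GG" + "".join(rng.choice(list("ACGT"), size=12))
                planted += 1
            else:
                insert = "TA" + "".join(rng.choice(list("ACGT"), size=12))
            reads.append(make_read(insert, cfg=cfg, read_id=f"r{i}"))
        path = tmp_path / "in.fq"
        _write_fastq(path, reads)
        _, stats = process_fastq(path, cfg)
        assert stats.rejected["non_ta_start"] == planted
        assert stats.n_accepted + stats.n_rejected == stats.n_input  # conservation

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fq"
        path.write_text("")
        inserts, stats = process_fastq(path, EXAMPLE_CFG)
        assert inserts == [] and stats.n_input == 0

    def test_malformed_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.fq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n")
        with pytest.raises(ValueError, match="record"):
            process_fastq(path, EXAMPLE_CFG)


class TestInsertValidation:
    def test_rejects_non_ta(self):
        with pytest.raises(ValueError):
            Insert("r", "GGCGTACGTACGTA", "I" * 14)

    def test_rejects_bad_length(self):
        with pytest.raises(ValueError):
            Insert("r", "TACGT", "I" * 5)
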