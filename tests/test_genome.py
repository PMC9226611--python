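"""Genome loading, TA-site enumeration/uniqueness, gene profiles, motifs."""

import numpy as np
import pytest

from tnscreen.genome import (Gene, Genome, Replicon, enumerate_ta_sites, first95_mask,
                             gene_ta_profile, genome_stats, load_annotation,
                             load_genome, mark_duplicated_sites, scan_heme_motifs)

from _oracles import (brute_duplicated_flags, brute_gene_profile, brute_ta_positions,
                      rc)


def _genome(*reps, topology="linear"):
    return Genome(replicons=tuple(
        Replicon(id=f"r{i}", seq=s, topology=topology) for i, s in enumerate(reps)))


def _random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadGenome:
    def test_multi_record_construction_and_uppercasing(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr\n" + "ACGT" * 25 + "\n>plasmid\nacgtacgtacgtacgtacgt\n")
        g = load_genome(fasta)
        assert g.ids == ("chr", "plasmid")
        assert len(g["chr"]) == 100 and len(g["plasmid"]) == 20
        assert g["plasmid"].seq == "ACGT" * 5  # lowercase input normalized

    def test_bad_alphabet_names_record(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">ok\nACGT\n>bad\nACXT\n")
        with pytest.raises(ValueError, match="bad"):
            load_genome(fasta)

    def test_empty_file_errors(self, tmp_path):
        fasta = tmp_path / "empty.fa"
        fasta.write_text("")
        with pytest.raises(ValueError):
            load_genome(fasta)


class TestLoadAnnotation:
    GFF = (
        "##gff-version 3\n"
        "chr\tsrc\tgene\t101\t300\t.\t+\t.\tID=gA;product=thing A\n"
        "chr\tsrc\tgene\t401\t460\t.\t-\t.\tID=gB\n"
        "chr\tsrc\tgene\t500\t520\t.\t+\t.\tID=gC\n"
    )

    def test_coordinate_conversion_and_ids(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr\n" + "A" * 600 + "\n")
        gff = tmp_path / "g.gff"
        gff.write_text(self.GFF)
        genes = load_annotation(gff, load_genome(fasta))
        assert [g.gene_id for g in genes] == ["gA", "gB", "gC"]
        ga = genes[0]
        assert (ga.start, ga.end, ga.strand) == (100, 300, "+")  # 1-based -> half-open
        assert ga.product == "thing A"

    def test_unknown_replicon_rejected(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr\n" + "A" * 600 + "\n")
        gff = tmp_path / "g.gff"
        gff.write_text("##gff-version 3\nplasmid\tsrc\tgene\t1\t50\t.\t+\t.\tID=gX\n")
        with pytest.raises(ValueError, match="gX"):
            load_annotation(gff, load_genome(fasta))

    def test_coordinates_outside_replicon_rejected(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr\n" + "A" * 100 + "\n")
        gff = tmp_path / "g.gff"
        gff.write_text("##gff-version 3\nchr\tsrc\tgene\t50\t200\t.\t+\t.\tID=gX\n")
        with pytest.raises(ValueError, match="gX"):
            load_annotation(gff, load_genome(fasta))


# ---------------------------------------------------------------------------
# TA enumeration
# ---------------------------------------------------------------------------

class TestEnumerateTASites:
    @pytest.mark.parametrize("seq,expected", [
        ("TATA", [0, 2]),    # overlapping TAs both count
        ("GGCCGG", []),
        ("TA", [0]),
    ])
    def test_examples(self, seq, expected):
        idx = enumerate_ta_sites(_genome(seq))
        assert idx.positions("r0").tolist() == expected

    def test_matches_bruteforce_on_random_sequence(self):
        rng = np.random.default_rng(42)
        seq = _random_seq(rng, 10_000)
        idx = enumerate_ta_sites(_genome(seq))
        assert idx.positions("r0").tolist() == brute_ta_positions(seq)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(7)
        seq = _random_seq(rng, 5_000)
        fwd = set(enumerate_ta_sites(_genome(seq)).positions("r0").tolist())
        rev = set(enumerate_ta_sites(_genome(rc(seq))).positions("r0").tolist())
        assert rev == {len(seq) - 2 - p for p in fwd}


class TestDuplicatedSites:
    def test_shared_forward_kmer_flags_both(self):
        seq = "TA" + "A" * 16 + "TA" + "A" * 16  # both sites read TAAAAAAAAAAAAA
        g = _genome(seq)
        idx = mark_duplicated_sites(enumerate_ta_sites(g), g)
        assert idx.duplicated("r0").all()

    def test_distinct_contexts_not_flagged(self):
        left = "GCGCGCGCGCGC"
        mid = "CCGGCCGGCCGGCC"
        right = "GGTTGGCCAAGGCC"
        seq = left + "TA" + mid + "TA" + right  # no other TA anywhere
        g = _genome(seq, topology="circular")
        idx = mark_duplicated_sites(enumerate_ta_sites(g), g)
        assert not idx.duplicated("r0").any()

    def test_linear_edge_sites_flagged(self):
        # TA at position 0 of a linear replicon has no upstream 14-mer
        seq = "TACCGGCCGGCCAAGGCCAAGGCCAAGG"
        g = _genome(seq, topology="linear")
        idx = mark_duplicated_sites(enumerate_ta_sites(g), g)
        assert idx.duplicated("r0")[0]

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_matches_bruteforce_all_pairs(self, topology):
        rng = np.random.default_rng(99)
        reps = [_random_seq(rng, 20_000, gc=0.3), _random_seq(rng, 3_000, gc=0.3)]
        g = Genome(replicons=tuple(
            Replicon(id=f"r{i}", seq=s, topology=topology) for i, s in enumerate(reps)))
        idx = mark_duplicated_sites(enumerate_ta_sites(g), g)
        expected = brute_duplicated_flags(
            [(f"r{i}", s, topology == "circular") for i, s in enumerate(reps)])
        got = {(rid, pos): dup for rid, pos, _, _, dup in idx.iter_sites()}
        assert got == expected


# ---------------------------------------------------------------------------
# gene profiles
# ---------------------------------------------------------------------------

class TestGeneTAProfile:
    def test_first95_boundary_plus_strand(self):
        gene = Gene(gene_id="g", replicon_id="r0", start=100, end=300, strand="+")
        # floor(0.95 * 200) = 190: offset 189 is in, offset 190 is out
        mask = first95_mask(np.array([289, 290]), gene)
        assert mask.tolist() == [True, False]

    def test_first95_boundary_minus_strand(self):
        gene = Gene(gene_id="g", replicon_id="r0", start=100, end=300, strand="-")
        # offset = (end-2) - p; p=109 -> 189 in, p=108 -> 190 out
        mask = first95_mask(np.array([108, 109]), gene)
        assert mask.tolist() == [False, True]

    def test_half_unique_counting(self):
        # 10 TA sites, 4 with unique context
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 2_000, gc=0.7)
        g = _genome(seq, topology="circular")
        idx = enumerate_ta_sites(g)
        n = len(idx.positions("r0"))
        assert n >= 10
        idx.per_replicon["r0"].duplicated[:] = True
        idx.per_replicon["r0"].duplicated[:4] = False
        gene = Gene(gene_id="g", replicon_id="r0", start=0, end=2000, strand="+")
        prof = gene_ta_profile([gene], idx)[0]
        assert prof.n_ta_total == n and prof.n_ta_unique == 4

    def test_matches_bruteforce_interval_scan(self):
        rng = np.random.default_rng(17)
        seq = _random_seq(rng, 30_000, gc=0.6)
        g = _genome(seq, topology="circular")
        idx = mark_duplicated_sites(enumerate_ta_sites(g), g)
        dup_flags = {(rid, pos): dup for rid, pos, _, _, dup in idx.iter_sites()}
        genes = []
        pos = 100
        for i in range(20):
            length = int(rng.integers(150, 1500))
            if pos + length > len(seq) - 10:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gene_id=f"g{i}", replicon_id="r0", start=pos,
                              end=pos + length, strand=strand))
            pos += length + int(rng.integers(0, 200))
        assert len(genes) >= 10
        profiles = gene_ta_profile(genes, idx)
        for gene, prof in zip(genes, profiles):
            expect = brute_gene_profile(seq, gene.start, gene.end, gene.strand,
                                        dup_flags, "r0")
            assert (prof.n_ta_total, prof.n_ta_unique, prof.n_ta_first95) == expect


# ---------------------------------------------------------------------------
# stats and motifs
# ---------------------------------------------------------------------------

class TestGenomeStats:
    @pytest.mark.parametrize("seq,gc", [("ATGC", 50.0), ("GGGG", 100.0), ("ATNN", 0.0)])
    def test_gc_examples(self, seq, gc):
        df = genome_stats(_genome(seq))
        assert df.loc[0, "length_bp"] == len(seq)
        assert df.loc[0, "gc_percent"] == pytest.approx(gc)

    def test_matches_character_count_oracle(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 5_000, gc=0.64)
        df = genome_stats(_genome(seq))
        expect = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        assert df.loc[0, "gc_percent"] == pytest.approx(expect)


class TestHemeMotifScan:
    @pytest.mark.parametrize("seq,n", [
        ("CAACH", 1),             # CX2CH
        ("CCH", 0),               # spacer too short
        ("MCAACHCAAAACHR", 2),    # CX2CH then CX4CH
        ("CAAAAACH", 0),          # spacer too long
        ("CAACHAACH", 1),         # non-overlapping
    ])
    def test_examples(self, seq, n):
        (hit,) = scan_heme_motifs({"p": seq})
        assert hit.n_motifs == n
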