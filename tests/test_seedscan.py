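"""Seed-pattern derivation and 3'UTR scanning."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedshift.seedscan import (
    ALL_CLASSES,
    AlphabetError,
    MatureMiRNA,
    SiteClass,
    UTRRecord,
    derive_site_patterns,
    read_utr_fasta,
    reverse_complement,
    scan_collection,
    scan_utr,
    site_gene_set,
)

from conftest import LET7, naive_scan, random_seq

nt = st.sampled_from("ACGU")
rna = st.text(alphabet="ACGU", min_size=0, max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,alphabet,expected",
        [
            ("GCAUCCC", "RNA", "GGGAUGC"),
            ("", "RNA", ""),
            ("ACGT", "DNA", "ACGT"),  # self-reverse-complementary palindrome
            ("acgu", "RNA", "ACGU"),
            ("AAAA", "DNA", "TTTT"),
        ],
    )
    def test_examples(self, seq, alphabet, expected):
        assert reverse_complement(seq, alphabet) == expected

    def test_invalid_character_is_located(self):
        with pytest.raises(AlphabetError, match=r"'X' at position 3"):
            reverse_complement("ACXGU")

    @given(seq=rna)
    @settings(max_examples=200, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq.upper()


class TestPatternDerivation:
    def test_let7_patterns(self, let7_patterns):
        assert let7_patterns[SiteClass.SIX_MER] == "UACCUC"
        assert let7_patterns[SiteClass.SEVEN_MER_M8] == "CUACCUC"
        assert let7_patterns[SiteClass.SEVEN_MER_1A] == "UACCUCA"
        assert let7_patterns[SiteClass.EIGHT_MER] == "CUACCUCA"

    def test_homopolymer(self):
        p = derive_site_patterns(MatureMiRNA("polyA", "AAAAAAAA"))
        assert p[SiteClass.SIX_MER] == "UUUUUU"
        assert p[SiteClass.SEVEN_MER_M8] == "UUUUUUU"
        assert p[SiteClass.SEVEN_MER_1A] == "UUUUUUA"
        assert p[SiteClass.EIGHT_MER] == "UUUUUUUA"

    def test_too_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="length"):
            MatureMiRNA("short", "ACGUACG")

    @given(seq=st.text(alphabet="ACGU", min_size=8, max_size=25))
    @settings(max_examples=200, derandomize=True)
    def test_structural_invariants(self, seq):
        p = derive_site_patterns(MatureMiRNA("x", seq))
        eight = p[SiteClass.EIGHT_MER]
        m8 = p[SiteClass.SEVEN_MER_M8]
        one_a = p[SiteClass.SEVEN_MER_1A]
        six = p[SiteClass.SIX_MER]
        assert eight == m8 + "A"
        assert one_a == six + "A"
        assert m8.endswith(six)
        assert (len(eight), len(m8), len(one_a), len(six)) == (8, 7, 7, 6)


class TestScanUtr:
    def test_nested_classes_collapse_to_strongest(self, let7_patterns):
        sites = scan_utr(UTRRecord("g", "AAACUACCUCAAA"), let7_patterns)
        assert [(s.start, s.end, s.site_class) for s in sites] == [(4, 11, SiteClass.EIGHT_MER)]

    def test_no_match_possible(self, let7_patterns):
        assert scan_utr(UTRRecord("g", "GGGGGGGG"), let7_patterns) == []

    def test_two_m8_sites_no_8mer(self, let7_patterns):
        sites = scan_utr(UTRRecord("g", "CUACCUCUCUACCUCU"), let7_patterns)
        assert [(s.start, s.site_class) for s in sites] == [
            (1, SiteClass.SEVEN_MER_M8),
            (9, SiteClass.SEVEN_MER_M8),
        ]

    def test_n_matches_nothing(self, let7_patterns):
        assert scan_utr(UTRRecord("g", "AAACUANCUCAAA"), let7_patterns) == []

    def test_coordinate_round_trip(self, let7_patterns, rng):
        for _ in range(50):
            seq = random_seq(rng, 300)
            utr = UTRRecord("g", seq)
            for s in scan_utr(utr, let7_patterns):
                assert seq[s.start - 1 : s.end] == s.matched_sequence

    def test_u_t_insensitivity(self, let7_patterns, rng):
        for _ in range(25):
            seq = random_seq(rng, 400)
            as_rna = scan_utr(UTRRecord("g", seq), let7_patterns)
            as_dna = scan_utr(UTRRecord("g", seq.replace("U", "T")), let7_patterns)
            assert [(s.start, s.end, s.site_class) for s in as_rna] == [
                (s.start, s.end, s.site_class) for s in as_dna
            ]

    def test_oracle_equivalence_random_pairs(self, rng):
        """Production scanner == brute-force window enumeration, exactly."""
        for _ in range(200):
            mirna = MatureMiRNA("m", random_seq(rng, int(rng.integers(8, 25))))
            patterns = derive_site_patterns(mirna)
            utr = UTRRecord("g", random_seq(rng, int(rng.integers(50, 500))))
            got = [(s.start, s.end, s.site_class.value) for s in scan_utr(utr, patterns)]
            assert got == naive_scan(utr.sequence, patterns)

    def test_oracle_equivalence_class_subsets(self, let7_patterns, rng):
        subsets = [["7mer-m8"], ["8mer", "6mer"], ["7mer-1a", "7mer-m8"]]
        for _ in range(40):
            seq = random_seq(rng, 300)
            for classes in subsets:
                got = [
                    (s.start, s.end, s.site_class.value)
                    for s in scan_utr(UTRRecord("g", seq), let7_patterns, classes)
                ]
                assert got == naive_scan(seq, let7_patterns, classes)

    def test_class_nesting_reported_8mer_contains_m8(self, let7_patterns, rng):
        """Every 8mer locus re-scans as a 7mer-m8 at the same match start."""
        found = 0
        for _ in range(200):
            seq = random_seq(rng, 500)
            utr = UTRRecord("g", seq)
            eights = [s for s in scan_utr(utr, let7_patterns) if s.site_class is SiteClass.EIGHT_MER]
            m8_starts = {s.start for s in scan_utr(utr, let7_patterns, ["7mer-m8"])}
            for s in eights:
                found += 1
                assert s.start in m8_starts
        assert found > 0


class TestScanCollection:
    def _write_fasta(self, path, records):
        with open(path, "w") as fh:
            for gid, seq in records:
                fh.write(f">{gid}\n{seq}\n")

    def test_counts_compose_from_scan_utr(self, tmp_path, let7_patterns):
        fasta = tmp_path / "u.fa"
        self._write_fasta(fasta, [("geneA", "AAACUACCUCAAA"), ("geneB", "GGGGGGGGGG")])
        res = scan_collection(fasta, let7_patterns)
        assert res.counts["geneA"] == {"8mer": 1}
        assert res.counts["geneB"] == {}
        assert res.total_sites == 1

    def test_empty_fasta(self, tmp_path, let7_patterns):
        fasta = tmp_path / "empty.fa"
        fasta.write_text("")
        res = scan_collection(fasta, let7_patterns)
        assert res.counts == {} and res.sites == []

    def test_gzipped_fasta(self, tmp_path, let7_patterns):
        fasta = tmp_path / "u.fa.gz"
        with gzip.open(fasta, "wt") as fh:
            fh.write(">geneA\nAAACUACCUCAAA\n")
        res = scan_collection(fasta, let7_patterns)
        assert res.counts["geneA"] == {"8mer": 1}

    def test_missing_file_names_path(self, let7_patterns, tmp_path):
        with pytest.raises(IOError, match="nope.fa"):
            read_utr_fasta(tmp_path / "nope.fa")

    def test_duplicate_ids_merged_with_warning(self, tmp_path, let7_patterns, caplog):
        fasta = tmp_path / "dup.fa"
        self._write_fasta(fasta, [("g", "AAACUACCUCAAA"), ("g", "CUACCUCUAAA")])
        with caplog.at_level("WARNING"):
            res = scan_collection(fasta, let7_patterns)
        assert "duplicate" in caplog.text
        assert res.counts["g"] == {"8mer": 1, "7mer-m8": 1}

    def test_requested_class_monotonicity(self, tmp_path, let7_patterns, rng):
        fasta = tmp_path / "m.fa"
        self._write_fasta(fasta, [(f"g{i}", random_seq(rng, 400)) for i in range(20)])
        all_counts = scan_collection(fasta, let7_patterns).counts
        m8_counts = scan_collection(fasta, let7_patterns, ["7mer-m8"]).counts
        for g in all_counts:
            assert sum(m8_counts[g].values()) <= sum(all_counts[g].values())


class TestSiteGeneSet:
    def test_min_class_thresholding(self, tmp_path, let7_patterns):
        fasta = tmp_path / "u.fa"
        with open(fasta, "w") as fh:
            fh.write(">geneA\nAAACUACCUCAAA\n>geneB\nAAUACCUCGAUACCUCGG\n")
        res = scan_collection(fasta, let7_patterns)  # geneA: 8mer, geneB: 6mers
        assert site_gene_set(res, "7mer-1a") == {"geneA"}
        assert site_gene_set(res, "8mer") == {"geneA"}
        assert site_gene_set(res, "6mer") == {"geneA", "geneB"}

    def test_nesting_cardinality(self, tmp_path, let7_patterns, rng):
        fasta = tmp_path / "n.fa"
        with open(fasta, "w") as fh:
            for i in range(30):
                fh.write(f">g{i}\n{random_seq(rng, 600)}\n")
        res = scan_collection(fasta, let7_patterns)
        sizes = [len(site_gene_set(res, c)) for c in ("6mer", "7mer-1a", "7mer-m8", "8mer")]
        assert sizes == sorted(sizes, reverse=True)
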