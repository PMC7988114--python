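"""FASTA reading, sequence sanitization and special-residue scans."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteomap import proteome_io
from proteomap.proteome_io import (
    FastaFormatError,
    ProteinRecord,
    SpeciesMetadata,
    count_special_residues,
    read_fasta,
    sanitize,
    sanitize_all,
    scan_descriptions,
    write_fasta,
)

RAW_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBJZXUO*"


class TestReadFasta:
    def test_wrapped_records_are_concatenated(self, tmp_path):
        seq1 = "MKV" * 40  # 120 residues wrapped at 60 columns
        seq2 = "GAL" * 25
        text = f">sp1 first protein\n{seq1[:60]}\n{seq1[60:]}\n>sp2\n{seq2}\n"
        path = tmp_path / "two.faa"
        path.write_text(text)
        records = read_fasta(path)
        assert [r.accession for r in records] == ["sp1", "sp2"]
        assert records[0].raw_sequence == seq1
        assert records[0].description == "first protein"
        assert records[1].raw_sequence == seq2

    def test_three_line_sequence_contributes_full_length(self, tmp_path):
        path = tmp_path / "x.faa"
        path.write_text(">p\n" + "ALGKMVSTEW\n" * 3)
        rec = read_fasta(path)[0]
        assert len(sanitize(rec).clean_sequence) == 30

    def test_blank_file_is_format_error(self, tmp_path):
        path = tmp_path / "blank.faa"
        path.write_text("\n\n\n")
        with pytest.raises(FastaFormatError):
            read_fasta(path)

    def test_gzip_input(self, tmp_path):
        import gzip

        path = tmp_path / "z.faa.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">a\nMKV\n")
        assert read_fasta(path)[0].raw_sequence == "MKV"

    def test_lowercase_is_uppercased(self, tmp_path):
        path = tmp_path / "lc.faa"
        path.write_text(">a\nmkv\n")
        assert read_fasta(path)[0].raw_sequence == "MKV"


class TestSanitize:
    @pytest.mark.parametrize("raw, clean, counts", [
        ("MBJZ", "MNLQ", {"B": 1, "J": 1, "Z": 1}),
        ("ML*", "ML", {"*": 1}),
        ("mxa", "MXA", {"X": 1}),
    ])
    def test_translation_rules(self, raw, clean, counts):
        rec = sanitize(ProteinRecord(accession="t", raw_sequence=raw))
        assert rec.clean_sequence == clean
        assert rec.ambiguity_counts == counts

    def test_internal_stop_is_stripped(self):
        rec = sanitize(ProteinRecord(accession="t", raw_sequence="MK*LV"))
        assert rec.clean_sequence == "MKLV"

    def test_empty_after_sanitization_is_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sanitize(ProteinRecord(accession="t", raw_sequence="***"))

    def test_dropped_records_are_counted_not_fatal(self):
        records = [ProteinRecord(accession="ok", raw_sequence="MKV"),
                   ProteinRecord(accession="bad", raw_sequence="*")]
        kept, dropped = sanitize_all(records)
        assert [r.accession for r in kept] == ["ok"]
        assert dropped == ["bad"]

    @given(st.text(alphabet=RAW_ALPHABET, min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_sanitize_is_idempotent_and_counts_substitutions(self, raw):
        rec = ProteinRecord(accession="t", raw_sequence=raw)
        if not raw.replace("*", ""):
            with pytest.raises(ValueError):
                sanitize(rec)
            return
        once = sanitize(rec)
        twice = sanitize(once)
        assert twice.clean_sequence == once.clean_sequence
        assert len(once.clean_sequence) == len(raw) - raw.count("*")
        # every B/J/Z becomes exactly one N/L/Q
        for code, target in [("B", "N"), ("J", "L"), ("Z", "Q")]:
            extra = once.clean_sequence.count(target) - raw.count(target)
            assert extra == raw.count(code)


@given(st.lists(st.text(alphabet=RAW_ALPHABET.replace("*", ""), min_size=1,
                        max_size=40), min_size=1, max_size=8))
@settings(max_examples=50, deadline=None)
def test_fasta_round_trip_preserves_clean_sequences(tmp_path_factory, seqs):
    records = [sanitize(ProteinRecord(accession=f"r{i}", raw_sequence=s))
               for i, s in enumerate(seqs)]
    path = tmp_path_factory.mktemp("rt") / "rt.faa"
    write_fasta(records, path)
    back = [sanitize(r) for r in read_fasta(path)]
    assert [r.accession for r in back] == [r.accession for r in records]
    assert [r.clean_sequence for r in back] == [r.clean_sequence for r in records]


class TestScans:
    def make(self, desc):
        return ProteinRecord(accession="a1", description=desc)

    def test_keyword_scan_matches_substring(self):
        recs = [self.make("putative selenocysteine lyase"), self.make("kinase")]
        assert scan_descriptions(recs, "selenocysteine") == [
            ("a1", "putative selenocysteine lyase")]

    def test_keyword_scan_is_case_insensitive(self):
        recs = [self.make("selenocysteine-containing")]
        assert len(scan_descriptions(recs, "Selenocysteine")) == 1

    def test_no_match_returns_empty(self):
        assert scan_descriptions([self.make("kinase")], "selenocysteine") == []

    def test_special_residue_counts(self):
        recs = [sanitize(ProteinRecord(accession="a", species_label="sp1",
                                       raw_sequence="MUM")),
                sanitize(ProteinRecord(accession="b", species_label="sp1",
                                       raw_sequence="MBXB"))]
        table = count_special_residues(recs)
        row = table.loc["sp1"]
        assert row["U"] == 1 and row["B"] == 2 and row["X"] == 1 and row["O"] == 0

    def test_synthetic_proteomes_are_sec_and_pyl_free(self, small_kingdom):
        _, outdir, _ = small_kingdom
        recs = []
        for fasta in sorted(outdir.glob("*.faa")):
            recs.extend(sanitize(r) for r in read_fasta(fasta, fasta.stem))
        table = count_special_residues(recs)
        assert (table["U"] == 0).all() and (table["O"] == 0).all()


class TestMetadata:
    def test_phylum_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="phylum"):
            SpeciesMetadata(species="x", phylum="Animalia")

    def test_genome_size_must_be_positive(self):
        with pytest.raises(ValueError):
            SpeciesMetadata(species="x", phylum="Ascomycota", genome_size_mb=-1)

    def test_read_metadata_requires_columns(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("species\nonly\n")
        with pytest.raises(ValueError, match="phylum"):
            proteome_io.read_metadata(path)
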