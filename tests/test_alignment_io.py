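import logging

import pytest

from mtprov.alignment_io import (
    AlignmentError,
    DuplicateSampleError,
    MetadataError,
    RangeError,
    ReferenceFrame,
    apply_sample_table,
    extract_region,
    infer_metadata_from_ids,
    load_alignment,
    write_dataset,
)

from conftest import make_dataset


def _write_inputs(tmp_path, records, meta_rows):
    fasta = tmp_path / "aln.fasta"
    fasta.write_text("".join(f">{sid}\n{seq}\n" for sid, seq in records))
    meta = tmp_path / "meta.tsv"
    lines = ["sample_id\tlocality\tcountry\tspecies"]
    lines += ["\t".join(r) for r in meta_rows]
    meta.write_text("\n".join(lines) + "\n")
    return fasta, meta


class TestLoadAlignment:
    def test_three_records_round_trip(self, tmp_path):
        records = [("AA0001", "ACGTACGTAC"), ("AA0002", "ACGTACGTAT"), ("BB0001", "ACGTACGTAA")]
        meta = [
            ("AA0001", "AA", "C01", "savanna"),
            ("AA0002", "AA", "C01", "savanna"),
            ("BB0001", "BB", "C01", "forest"),
        ]
        fasta, meta_path = _write_inputs(tmp_path, records, meta)
        ds = load_alignment(fasta, meta_path)
        assert len(ds) == 3 and ds.length == 10
        assert ds.get("BB0001").species == "forest"

        out_fa = tmp_path / "out.fasta"
        out_meta = tmp_path / "out.tsv"
        write_dataset(ds, out_fa, out_meta)
        again = load_alignment(out_fa, out_meta)
        assert [(s.sample_id, s.sequence, s.locality, s.country, s.species) for s in ds] == [
            (s.sample_id, s.sequence, s.locality, s.country, s.species) for s in again
        ]

    def test_length_mismatch_names_offender(self, tmp_path):
        records = [("AA0001", "ACGTACGTAC"), ("AA0002", "ACGTACGTA")]
        meta = [("AA0001", "AA", "C01", "savanna"), ("AA0002", "AA", "C01", "savanna")]
        fasta, meta_path = _write_inputs(tmp_path, records, meta)
        with pytest.raises(AlignmentError, match="AA0002"):
            load_alignment(fasta, meta_path)

    def test_iupac_ambiguity_collapses_to_n_with_warning(self, tmp_path, caplog):
        records = [("AA0001", "ACGTRCGTAC"), ("AA0002", "ACGTACGTAC")]
        meta = [("AA0001", "AA", "C01", "savanna"), ("AA0002", "AA", "C01", "savanna")]
        fasta, meta_path = _write_inputs(tmp_path, records, meta)
        with caplog.at_level(logging.WARNING, logger="mtprov.alignment_io"):
            ds = load_alignment(fasta, meta_path)
        assert ds.get("AA0001").sequence[4] == "N"
        assert any("AA0001" in r.message for r in caplog.records)

    def test_missing_metadata_and_duplicates_rejected(self, tmp_path):
        records = [("AA0001", "ACGT"), ("AA0002", "ACGT")]
        meta = [("AA0001", "AA", "C01", "savanna")]
        fasta, meta_path = _write_inputs(tmp_path, records, meta)
        with pytest.raises(MetadataError, match="AA0002"):
            load_alignment(fasta, meta_path)
        with pytest.raises(DuplicateSampleError):
            make_dataset(["ACGT", "ACGT"], ids=["X1", "X1"])


class TestInferMetadata:
    def test_prefix_lookup(self):
        ds = make_dataset(["ACGT", "ACGT"], ids=["KR0001", "GR0023"])
        table = infer_metadata_from_ids(
            ds, 2, locality_to_country={"KR": "South Africa", "GR": "D.R. Congo"}
        )
        recs = {r[0]: r for r in table.records}
        assert recs["KR0001"][1:3] == ("KR", "South Africa")
        assert recs["GR0023"][1] == "GR"

    def test_unknown_prefix_is_permissive(self, caplog):
        ds = make_dataset(["ACGT"], ids=["XX0001"])
        with caplog.at_level(logging.WARNING):
            table = infer_metadata_from_ids(ds, 2, locality_to_country={})
        assert table.records[0][1:] == ("XX", "unknown", "unknown")

    def test_apply_sample_table(self):
        ds = make_dataset(["ACGT"], ids=["KR0001"])
        table = infer_metadata_from_ids(ds, 2, locality_to_country={"KR": "South Africa"})
        ds2 = apply_sample_table(ds, table)
        assert ds2.get("KR0001").locality == "KR"


class TestReferenceFrame:
    def test_gapped_frame_mapping_invertible_on_non_gap_columns(self):
        frame = ReferenceFrame.from_gapped_reference("ref", 100, "AC-GT")
        assert frame.ref_position(3) is None
        for col in (1, 2, 4, 5):
            assert frame.column_of(frame.ref_position(col)) == col

    def test_interval_outside_frame_rejected(self, toy_frame):
        with pytest.raises(RangeError):
            toy_frame.columns_for_interval(90, 105)


class TestExtractRegion:
    def test_identity_interval_is_identity(self, toy_frame):
        ds = make_dataset(["ACGTACGTAC", "ACGTACGTAT"], frame=toy_frame)
        out = extract_region(ds, (101, 110))
        assert [s.sequence for s in out] == [s.sequence for s in ds]
        assert out.frame.ref_start == 101 and out.frame.ref_end == 110

    def test_window_lengths_and_coordinate_translation(self, toy_frame):
        ds = make_dataset(["ACGTACGTAC", "ACGTACGTAT"], frame=toy_frame)
        out = extract_region(ds, (103, 107))
        assert all(len(s.sequence) == 5 for s in out)
        assert out.frame.ref_position(1) == 103

    def test_sample_with_trailing_n_retained(self, toy_frame):
        ds = make_dataset(["ACGTACGTAC", "ACGTACNNNN"], frame=toy_frame)
        out = extract_region(ds, (105, 110))
        assert out.get(out.sample_ids[1]).sequence == "ACNNNN"
        assert len(out) == 2

    def test_window_outside_frame_raises(self, toy_frame):
        ds = make_dataset(["ACGTACGTAC"], frame=toy_frame)
        with pytest.raises(RangeError):
            extract_region(ds, (99, 104))
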