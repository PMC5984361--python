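"""MAF ingestion, consequence calling, and filters."""

import numpy as np
import pandas as pd
import pytest

import ssbdnds as s
from ssbdnds import errors
from ssbdnds.mutations import DEFAULT_DIALECT

MAF_HEADER = ("Tumor_Sample_Barcode\tTranscript_ID\tStart_position\t"
              "Reference_Allele\tTumor_Seq_Allele2")


def _write_maf(path, rows):
    path.write_text(MAF_HEADER + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestReadMutations:
    def test_drops_non_snv_rows(self, tmp_path):
        maf = _write_maf(tmp_path / "m.maf", [
            "S1\tt1\t4\tA\tG",
            "S1\tt1\t5\tAT\t-",      # indel
            "S2\tt1\t6\tC\tT",
        ])
        df = s.read_mutations(maf)
        assert len(df) == 2
        assert df["cds_pos"].tolist() == [3, 5]  # 1-based file -> 0-based

    def test_empty_file_with_header(self, tmp_path):
        df = s.read_mutations(_write_maf(tmp_path / "m.maf", []))
        assert df.empty

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "m.maf"
        p.write_text("Tumor_Sample_Barcode\tStart_position\n")
        with pytest.raises(errors.DialectError):
            s.read_mutations(p)

    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame({"sample": ["S1"], "transcript": ["t1"],
                           "cds_pos": [3], "ref": ["A"], "alt": ["G"]})
        s.write_maf(df, tmp_path / "out.maf", header_comments=["seed=1"])
        back = s.read_mutations(tmp_path / "out.maf")
        pd.testing.assert_frame_equal(back, df)


class TestAnnotate:
    tx_gga = s.TranscriptModel("tA", "gA", "ATGGGA", has_stop=False)
    tx_trp = s.TranscriptModel("tB", "gB", "ATGTGG", has_stop=False)

    @pytest.mark.parametrize("tx,pos,ref,alt,expected", [
        (tx_gga, 5, "A", "G", "synonymous"),   # GGA -> GGG, still Gly
        (tx_trp, 5, "G", "A", "nonsense"),     # TGG -> TGA, stop gained
        (tx_gga, 3, "G", "A", "missense"),     # GGA -> AGA, Gly -> Arg
    ])
    def test_consequences(self, tx, pos, ref, alt, expected):
        rec = s.annotate_consequence(
            {"cds_pos": pos, "ref": ref, "alt": alt}, tx)
        assert rec["consequence"] == expected

    def test_out_of_bounds(self):
        with pytest.raises(errors.OutOfBounds):
            s.annotate_consequence(
                {"cds_pos": 6, "ref": "A", "alt": "G"}, self.tx_gga)

    def test_reference_mismatch(self):
        with pytest.raises(errors.ReferenceMismatch):
            s.annotate_consequence(
                {"cds_pos": 5, "ref": "C", "alt": "G"}, self.tx_gga)

    def test_table_annotation_matches_scalar(self):
        txome = s.Transcriptome([self.tx_gga, self.tx_trp])
        df = pd.DataFrame({
            "sample": ["S1"] * 3,
            "transcript": ["tA", "tB", "tA"],
            "cds_pos": [5, 5, 3],
            "ref": ["A", "G", "G"], "alt": ["G", "A", "A"],
        })
        out = s.annotate_mutations(df, txome)
        assert out["consequence"].tolist() == ["synonymous", "nonsense",
                                               "missense"]

    def test_mismatch_rows_dropped_in_table(self):
        txome = s.Transcriptome([self.tx_gga])
        df = pd.DataFrame({"sample": ["S1", "S1"], "transcript": ["tA", "tA"],
                           "cds_pos": [5, 5], "ref": ["A", "C"],
                           "alt": ["G", "G"]})
        out = s.annotate_mutations(df, txome)
        assert len(out) == 1

    def test_reannotation_is_stable(self, toy_tx, neutral_cohort):
        again = s.annotate_mutations(
            neutral_cohort.drop(columns=["consequence", "class7"]), toy_tx)
        assert (again["consequence"].to_numpy()
                == neutral_cohort["consequence"].to_numpy()).all()
        assert (again["class7"].to_numpy()
                == neutral_cohort["class7"].to_numpy()).all()


class TestQualityFilters:
    def _record(self, **kw):
        base = {"sample": "S1", "transcript": "t1", "cds_pos": 0,
                "ref": "A", "alt": "G", "vaf": 0.5, "alt_reads": 20,
                "pop_af": 0.0, "segdup": 0.0, "in_repeat": 0, "abb": 1.0}
        base.update(kw)
        return base

    def test_each_criterion_drops_one(self):
        df = pd.DataFrame([
            self._record(vaf=0.05),
            self._record(alt_reads=3),
            self._record(pop_af=0.02),
            self._record(segdup=0.9),
            self._record(in_repeat=1),
            self._record(abb=0.5),
        ])
        kept, ledger = s.apply_quality_filters(df)
        assert kept.empty
        assert all(v == 1 for v in ledger.values())

    @pytest.mark.parametrize("kw,kept", [
        ({"vaf": 0.1}, True),       # exclusion is strict '< 0.1'
        ({"abb": 0.7}, False),      # exclusion is inclusive '<= 0.7'
        ({"alt_reads": 5}, True),
        ({"pop_af": 0.01}, False),  # '>= 1%'
        ({"segdup": 0.5}, True),    # strict '> 0.5'
    ])
    def test_boundaries(self, kw, kept):
        df = pd.DataFrame([self._record(**kw)])
        out, _ = s.apply_quality_filters(df)
        assert (len(out) == 1) is kept

    def test_missing_annotations_pass(self):
        df = pd.DataFrame([{"sample": "S1", "transcript": "t1",
                            "cds_pos": 0, "ref": "A", "alt": "G"}])
        out, ledger = s.apply_quality_filters(df)
        assert len(out) == 1
        assert sum(ledger.values()) == 0

    def test_idempotent_and_ledger_conserves(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame([self._record(
            vaf=rng.uniform(0, 0.3), abb=rng.uniform(0, 1),
            alt_reads=rng.integers(0, 12)) for _ in range(200)])
        once, ledger = s.apply_quality_filters(df)
        twice, ledger2 = s.apply_quality_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert sum(ledger2.values()) == 0
        # a record dropped by several criteria is ledgered exactly once
        assert len(once) + sum(ledger.values()) == len(df)


class TestDiploidFilter:
    @pytest.mark.parametrize("sm,kept", [
        (0.0, True), (0.02, False), (-0.01, True), (0.01, True),
        (-0.011, False),
    ])
    def test_band(self, sm, kept):
        df = pd.DataFrame([{"sample": "S1", "transcript": "t1", "cds_pos": 0,
                            "ref": "A", "alt": "G", "segment_mean": sm}])
        assert (len(s.filter_diploid(df)) == 1) is kept

    def test_missing_segment_dropped(self):
        df = pd.DataFrame([{"sample": "S1", "transcript": "t1", "cds_pos": 0,
                            "ref": "A", "alt": "G",
                            "segment_mean": float("nan")}])
        assert s.filter_diploid(df).empty

    def test_join_table(self):
        df = pd.DataFrame([{"sample": "S1", "transcript": "t1", "cds_pos": 0,
                            "ref": "A", "alt": "G"}])
        sm = pd.DataFrame({"sample": ["S1"], "transcript": ["t1"],
                           "segment_mean": [0.005]})
        assert len(s.filter_diploid(df, sm)) == 1


class TestGeneFilters:
    def test_na_ns_ratio_and_zero_count_rules(self):
        # gB is all-Trp after the start codon: every change is non-synonymous,
        # so its Na/Ns ratio is infinite and it must be removed
        txome = s.Transcriptome([
            s.TranscriptModel("tA", "gA", "ATGGGAGGCCTT", has_stop=False),
            s.TranscriptModel("tB", "gB", "ATGTGGTGGTGG", has_stop=False),
        ])
        spectra = s.count_sites_by_gene(txome)
        df = pd.DataFrame({
            "sample": ["S1"] * 3,
            "transcript": ["tA", "tA", "tB"],
            "cds_pos": [5, 3, 5], "ref": ["A", "G", "G"],
            "alt": ["G", "A", "A"],
        })
        df = s.annotate_mutations(df, txome)
        kept, removed = s.apply_gene_filters(df, txome, spectra)
        assert set(kept["transcript"]) == {"tA"}
        assert removed["na_ns_ratio"] == ["gB"]

    def test_blocklist_and_retention(self, toy_tx, toy_spectra,
                                     neutral_cohort):
        bad = toy_tx.gene_of(toy_tx.ids[0])
        kept, removed = s.apply_gene_filters(
            neutral_cohort, toy_tx, toy_spectra, blocklist={bad})
        assert bad in removed["blocklist"]
        assert bad not in set(kept["gene"])
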