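"""Summary-statistics I/O, validation, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from medimr.exceptions import EmptyOverlapError, FormatError
from medimr.summaries import (LDMatrix, SummaryStats, harmonize,
                              harmonized_to_stats, read_ld_matrix,
                              read_summary_stats, write_ld_matrix,
                              write_summary_stats)

from conftest import stats, va


class TestReadWrite:
    def test_round_trip_preserves_fields(self, tmp_path):
        records = [va("rs1", beta=0.123456789012345, se=0.01, eaf=0.25),
                   va("rs2", ea="C", oa="T", beta=-0.05, se=0.002, eaf=None, pos=2000)]
        s = stats(records, name="hba1c")
        path = tmp_path / "s.tsv"
        write_summary_stats(s, path)
        back = read_summary_stats(path, "hba1c", "quantitative")
        assert len(back) == 2
        for orig, new in zip(records, back.records):
            assert new.variant_id == orig.variant_id
            assert (new.effect_allele, new.other_allele) == \
                (orig.effect_allele, orig.other_allele)
            assert new.beta == pytest.approx(orig.beta, abs=1e-12)
            assert new.se == pytest.approx(orig.se, abs=1e-12)
            assert (new.eaf is None) == (orig.eaf is None)

    def test_invalid_rows_rejected_with_reason(self, tmp_path):
        df = stats([va("rs1"), va("rs2")]).to_frame()
        df.loc[1, "se"] = 0.0
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        s = read_summary_stats(path, "t", "quantitative")
        assert s.variant_ids == ["rs1"]
        assert s.load_report.iloc[0].tolist() == ["rs2", "nonpositive se"]

    def test_missing_column_names_the_column(self, tmp_path):
        df = stats([va("rs1")]).to_frame().drop(columns=["beta"])
        path = tmp_path / "nobeta.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="beta"):
            read_summary_stats(path, "t", "quantitative")

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_summary_stats(path, "t", "quantitative")

    def test_column_map_renames_source_headers(self, tmp_path):
        df = stats([va("rs1")]).to_frame().rename(columns={"beta": "BETA_GC"})
        path = tmp_path / "mapped.tsv"
        df.to_csv(path, sep="\t", index=False)
        s = read_summary_stats(path, "t", "quantitative",
                               column_map={"beta": "BETA_GC"})
        assert s.get("rs1").beta == pytest.approx(0.1)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            stats([va("rs1"), va("rs1")])


class TestLDMatrix:
    def test_one_by_one(self, tmp_path):
        path = tmp_path / "ld.tsv"
        write_ld_matrix(LDMatrix(["rs1"], np.array([[1.0]])), path)
        ld = read_ld_matrix(path)
        assert ld.variant_ids == ["rs1"] and ld.r[0, 0] == 1.0

    def test_out_of_range_entry(self, tmp_path):
        path = tmp_path / "ld.tsv"
        pd.DataFrame([[1.0, 1.2], [1.2, 1.0]], index=["a", "b"],
                     columns=["a", "b"]).to_csv(path, sep="\t")
        with pytest.raises(FormatError, match="> 1"):
            read_ld_matrix(path)

    def test_tiny_asymmetry_symmetrized(self, tmp_path):
        path = tmp_path / "ld.tsv"
        r = np.array([[1.0, 0.5], [0.5 + 1e-12, 1.0]])
        pd.DataFrame(r, index=["a", "b"], columns=["a", "b"]).to_csv(path, sep="\t")
        ld = read_ld_matrix(path)
        assert np.array_equal(ld.r, ld.r.T)
        assert np.all(np.diag(ld.r) == 1.0)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        pd.DataFrame([[1.0, 0.5]], index=["a"], columns=["a", "b"]).to_csv(
            path, sep="\t")
        with pytest.raises(FormatError, match="square"):
            read_ld_matrix(path)


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = stats([va("rs1", beta=0.1)], "exp")
        out = stats([va("rs1", beta=0.3)], "out", "binary")
        h = harmonize([exp], out)
        assert h.beta_exp[0, 0] == 0.1 and h.beta_out[0] == 0.3

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = stats([va("rs1", ea="A", oa="G", beta=0.1, eaf=0.3)], "exp")
        out = stats([va("rs1", ea="G", oa="A", beta=0.3, eaf=0.7)], "out")
        h = harmonize([exp], out)
        assert h.beta_out[0] == -0.3
        assert h.eaf_out[0] == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        # T/C on the outcome is the reverse-strand reading of A/G
        exp = stats([va("rs1", ea="A", oa="G", beta=0.1)], "exp")
        out = stats([va("rs1", ea="T", oa="C", beta=0.3)], "out")
        h = harmonize([exp], out)
        assert h.beta_out[0] == 0.3
        out_sw = stats([va("rs1", ea="C", oa="T", beta=0.3)], "out")
        h2 = harmonize([exp], out_sw)
        assert h2.beta_out[0] == -0.3

    def test_palindromic_ambiguous_dropped(self):
        exp = stats([va("rs1", ea="A", oa="T", eaf=0.50),
                     va("rs2", beta=0.2)], "exp")
        out = stats([va("rs1", ea="A", oa="T", eaf=0.50, beta=0.3),
                     va("rs2", beta=0.1)], "out")
        h = harmonize([exp], out, palindrome_policy="infer_by_eaf")
        assert ("rs1", "palindromic ambiguous") in h.dropped
        assert h.variant_ids == ["rs2"]

    def test_palindromic_drop_all_policy(self):
        exp = stats([va("rs1", ea="C", oa="G", eaf=0.1), va("rs2")], "exp")
        out = stats([va("rs1", ea="C", oa="G", eaf=0.1), va("rs2")], "out")
        h = harmonize([exp], out, palindrome_policy="drop_all")
        assert ("rs1", "palindromic") in h.dropped

    def test_palindromic_inferred_by_eaf(self):
        # frequencies on opposite sides of 0.5: outcome strand is flipped
        exp = stats([va("rs1", ea="A", oa="T", eaf=0.10, beta=0.1)], "exp")
        out = stats([va("rs1", ea="A", oa="T", eaf=0.90, beta=0.3)], "out")
        h = harmonize([exp], out, palindrome_policy="infer_by_eaf")
        assert h.beta_out[0] == -0.3
        assert h.eaf_out[0] == pytest.approx(0.10)

    def test_palindromic_missing_eaf_always_dropped(self):
        exp = stats([va("rs1", ea="A", oa="T", eaf=None), va("rs2")], "exp")
        out = stats([va("rs1", ea="A", oa="T", eaf=0.1), va("rs2")], "out")
        h = harmonize([exp], out, palindrome_policy="infer_by_eaf")
        assert ("rs1", "palindromic missing eaf") in h.dropped

    def test_incompatible_alleles_dropped(self):
        exp = stats([va("rs1", ea="A", oa="G"), va("rs2")], "exp")
        out = stats([va("rs1", ea="A", oa="C"), va("rs2")], "out")
        h = harmonize([exp], out)
        assert ("rs1", "incompatible alleles") in h.dropped

    def test_zero_shared_variants_is_error(self):
        with pytest.raises(EmptyOverlapError):
            harmonize([stats([va("rs1")], "exp")], stats([va("rs9")], "out"))

    def test_missing_in_outcome_recorded(self):
        exp = stats([va("rs1"), va("rs2")], "exp")
        out = stats([va("rs1")], "out")
        h = harmonize([exp], out)
        assert ("rs2", "missing in out") in h.dropped

    def test_idempotent(self):
        exp = stats([va("rs1", ea="A", oa="G", beta=0.1, eaf=0.3),
                     va("rs2", ea="C", oa="T", beta=-0.2, eaf=0.6, pos=200)],
                    "exp")
        out = stats([va("rs1", ea="G", oa="A", beta=0.3, eaf=0.7),
                     va("rs2", ea="C", oa="T", beta=0.1, eaf=0.6, pos=200)],
                    "out", "binary")
        h1 = harmonize([exp], out)
        exps2, out2 = harmonized_to_stats(h1)
        h2 = harmonize(exps2, out2)
        assert h2.variant_ids == h1.variant_ids
        np.testing.assert_array_equal(h2.beta_exp, h1.beta_exp)
        np.testing.assert_array_equal(h2.beta_out, h1.beta_out)

    def test_sign_flip_equivariance(self):
        """Negating an exposure's betas AND swapping its allele labels is a
        pure relabeling: the harmonized matrix must not change."""
        exp = stats([va("rs1", ea="A", oa="G", beta=0.1, eaf=0.3),
                     va("rs2", ea="C", oa="T", beta=-0.2, eaf=0.6, pos=200)],
                    "exp")
        out = stats([va("rs1", ea="A", oa="G", beta=0.3, eaf=0.3),
                     va("rs2", ea="T", oa="C", beta=0.1, eaf=0.4, pos=200)],
                    "out")
        h_ref = harmonize([exp], out)
        flipped = stats(
            [va(r.variant_id, ea=r.other_allele, oa=r.effect_allele,
                beta=-r.beta, eaf=1 - r.eaf, pos=r.pos) for r in exp.records],
            "exp")
        h_flip = harmonize([flipped], out)
        # reference orientation differs (the first exposure defines it), but
        # the relationship between exposure and outcome betas is preserved
        np.testing.assert_allclose(
            h_flip.beta_out / h_flip.beta_exp[:, 0],
            h_ref.beta_out / h_ref.beta_exp[:, 0], rtol=1e-12)
        np.testing.assert_allclose(np.abs(h_flip.beta_exp), np.abs(h_ref.beta_exp))
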