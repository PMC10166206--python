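"""Summary-table I/O and exposure/outcome allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrlink.gwas_io import (
    COLUMNS,
    SummaryTable,
    harmonize,
    read_summary_table,
    retained_pairs,
    write_summary_table,
)

from conftest import make_table, random_table


def _row(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=1e-6, n=10000,
         chrom="1", pos=1000):
    return (snp, chrom, pos, ea, oa, eaf, beta, se, p, n)


class TestReadWrite:
    def test_round_trip_identity_full_precision(self, rng, tmp_path):
        t = random_table(rng, n=100)
        p1 = tmp_path / "a.tsv"
        write_summary_table(t, p1)
        back = read_summary_table(p1, trait_id=t.trait_id)
        pd.testing.assert_frame_equal(t.df, back.df)
        # byte-stable on rewrite
        p2 = tmp_path / "b.tsv"
        write_summary_table(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_column_map_parses_like_canonical(self, rng, tmp_path):
        t = random_table(rng, n=5)
        canonical = tmp_path / "canon.tsv"
        write_summary_table(t, canonical)
        renamed = tmp_path / "renamed.tsv"
        txt = canonical.read_text().splitlines()
        txt[0] = "rsid\tchrom\tbp\tA1\tA2\tfreq\tb\tse\tpval\tnsamp"
        renamed.write_text("\n".join(txt) + "\n")
        cmap = {"rsid": "SNP", "chrom": "CHR", "bp": "POS", "A1": "EA", "A2": "OA",
                "freq": "EAF", "b": "BETA", "se": "SE", "pval": "P", "nsamp": "N"}
        back = read_summary_table(renamed, column_map=cmap)
        pd.testing.assert_frame_equal(t.df, back.df)

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        t = make_table([
            _row("rs1"),
            _row("rs2", se=0.0),          # invalid: zero SE
            _row("rs3", ea="A", oa="A"),  # invalid: identical alleles
        ])
        path = tmp_path / "t.tsv"
        t.df.to_csv(path, sep="\t", index=False)
        back = read_summary_table(path)
        assert len(back) == 1 and back.n_dropped == 2

    def test_missing_eaf_round_trips_as_dot(self, tmp_path):
        t = make_table([_row("rs1", eaf=np.nan)])
        path = write_summary_table(t, tmp_path / "t.tsv")
        assert "\t.\t" in path.read_text()
        back = read_summary_table(path)
        assert np.isnan(back.df["EAF"].iloc[0])

    def test_empty_table_writes_header_only(self, tmp_path):
        t = make_table([])
        path = write_summary_table(t, tmp_path / "t.tsv")
        assert path.read_text().strip() == "\t".join(COLUMNS)
        assert len(read_summary_table(path)) == 0

    def test_missing_column_is_hard_error_naming_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tCHR\n" + "rs1\t1\n")
        with pytest.raises(ValueError, match="POS"):
            read_summary_table(path)

    def test_zero_byte_file_is_hard_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.touch()
        with pytest.raises(ValueError, match="empty"):
            read_summary_table(path)

    def test_duplicate_snp_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table([_row("rs1"), _row("rs1")])


def _pair_tables(exp_rows, out_rows):
    return (make_table(exp_rows, trait_id="exp"),
            make_table(out_rows, trait_id="out", trait_type="binary"))


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        e, o = _pair_tables([_row(beta=0.1)], [_row(beta=0.05)])
        h = harmonize(e, o)
        assert h["action"].tolist() == ["unchanged"]
        assert h["beta_out"].iloc[0] == 0.05

    def test_swapped_alleles_flip_sign_and_complement_eaf(self):
        e, o = _pair_tables(
            [_row(ea="A", oa="G", beta=0.1)],
            [_row(ea="G", oa="A", beta=0.05, eaf=0.3)],
        )
        h = harmonize(e, o)
        assert h["action"].iloc[0] == "flipped"
        assert h["beta_out"].iloc[0] == -0.05
        assert h["eaf_out"].iloc[0] == pytest.approx(0.7)

    def test_palindrome_at_half_frequency_dropped(self):
        e, o = _pair_tables(
            [_row(ea="A", oa="T", eaf=0.50)],
            [_row(ea="A", oa="T", eaf=0.50)],
        )
        h = harmonize(e, o, palindrome_eaf_window=0.08)
        assert h["action"].iloc[0] == "dropped_palindromic"

    # exposure is fixed A/G (eaf 0.2); every outcome allele configuration
    # has a hand-derived expected action / transform
    TRUTH_TABLE = [
        # ea_o, oa_o, eaf_o, action, beta_out_final
        ("A", "G", 0.2, "unchanged", 0.05),
        ("G", "A", 0.8, "flipped", -0.05),
        ("T", "C", 0.2, "unchanged", 0.05),   # strand flip only
        ("C", "T", 0.8, "flipped", -0.05),    # strand flip + swap
        ("A", "C", 0.2, "dropped_mismatch", None),
        ("C", "G", 0.2, "dropped_mismatch", None),
        ("T", "G", 0.2, "dropped_mismatch", None),  # complement is A/C: mismatch
        ("A", "T", 0.2, "dropped_mismatch", None),  # different variant class
    ]

    @pytest.mark.parametrize("ea_o,oa_o,eaf_o,action,beta_final", TRUTH_TABLE)
    def test_allele_configuration_truth_table(self, ea_o, oa_o, eaf_o, action, beta_final):
        e, o = _pair_tables(
            [_row(ea="A", oa="G", eaf=0.2, beta=0.1)],
            [_row(ea=ea_o, oa=oa_o, eaf=eaf_o, beta=0.05)],
        )
        h = harmonize(e, o)
        assert h["action"].iloc[0] == action
        if beta_final is not None:
            assert h["beta_out"].iloc[0] == pytest.approx(beta_final)

    # palindromic A/T exposure at eaf 0.2: frequency decides strand
    PALINDROME_TABLE = [
        # ea_o, oa_o, eaf_o, action, beta_out_final, eaf_out_final
        ("A", "T", 0.2, "unchanged", 0.05, 0.2),   # concordant frequency
        ("A", "T", 0.8, "flipped", -0.05, 0.2),    # discordant: strand-flipped
        ("T", "A", 0.8, "flipped", -0.05, 0.2),    # swapped labels, concordant after flip
        ("T", "A", 0.2, "unchanged", 0.05, 0.2),   # swap + strand flip cancel
    ]

    @pytest.mark.parametrize("ea_o,oa_o,eaf_o,action,beta_final,eaf_final", PALINDROME_TABLE)
    def test_palindrome_frequency_inference(self, ea_o, oa_o, eaf_o, action,
                                            beta_final, eaf_final):
        e, o = _pair_tables(
            [_row(ea="A", oa="T", eaf=0.2, beta=0.1)],
            [_row(ea=ea_o, oa=oa_o, eaf=eaf_o, beta=0.05)],
        )
        h = harmonize(e, o)
        assert h["action"].iloc[0] == action
        assert h["beta_out"].iloc[0] == pytest.approx(beta_final)
        assert h["eaf_out"].iloc[0] == pytest.approx(eaf_final)

    def test_palindrome_with_missing_eaf_dropped(self):
        e, o = _pair_tables(
            [_row(ea="A", oa="T", eaf=0.2)],
            [_row(ea="A", oa="T", eaf=np.nan)],
        )
        assert harmonize(e, o)["action"].iloc[0] == "dropped_palindromic"

    def test_non_palindrome_with_missing_eaf_kept_by_alleles(self):
        e, o = _pair_tables(
            [_row(ea="A", oa="G", eaf=0.2)],
            [_row(ea="G", oa="A", eaf=np.nan, beta=0.05)],
        )
        h = harmonize(e, o)
        assert h["action"].iloc[0] == "flipped"
        assert h["beta_out"].iloc[0] == -0.05

    def test_no_overlap_is_hard_error(self):
        e, o = _pair_tables([_row("rs1")], [_row("rs2")])
        with pytest.raises(ValueError, match="no overlapping"):
            harmonize(e, o)

    def test_action_counts_sum_to_intersection(self, rng):
        e = random_table(rng, n=30, trait_id="exp")
        out_df = e.df.copy()
        # scramble a third of the outcome rows into swaps and mismatches
        out_df.loc[:9, ["EA", "OA"]] = out_df.loc[:9, ["OA", "EA"]].to_numpy()
        out_df.loc[10:14, "EA"] = "C"
        o = SummaryTable("out", "binary", out_df)
        h = harmonize(e, o)
        assert len(h) == 30
        counts = h["action"].value_counts()
        assert counts.sum() == 30
        assert set(counts.index) <= {"unchanged", "flipped", "dropped_palindromic",
                                     "dropped_mismatch"}
        assert len(retained_pairs(h)) == counts.get("unchanged", 0) + counts.get("flipped", 0)

    def test_harmonization_is_involution_safe(self, rng):
        """Re-harmonizing an already-aligned outcome changes nothing."""
        e = random_table(rng, n=25, trait_id="exp")
        out_df = e.df.copy()
        out_df["BETA"] = rng.normal(0, 0.05, len(out_df))
        o = SummaryTable("out", "binary", out_df)
        h1 = retained_pairs(harmonize(e, o))
        aligned = e.df.copy()
        aligned["BETA"] = h1["beta_out"].to_numpy()
        aligned["EAF"] = h1["eaf_out"].to_numpy()
        h2 = retained_pairs(harmonize(e, SummaryTable("out", "binary", aligned)))
        assert (h2["action"] == "unchanged").all()
        np.testing.assert_allclose(h2["beta_out"], h1["beta_out"])

    def test_relabelled_outcome_gives_identical_retained_pairs(self, rng):
        """Swapping outcome EA/OA with beta negated and EAF complemented is a no-op."""
        e = random_table(rng, n=25, trait_id="exp")
        out_df = e.df.copy()
        out_df["BETA"] = rng.normal(0, 0.05, len(out_df))
        o = SummaryTable("out", "binary", out_df)
        relabelled = out_df.copy()
        relabelled[["EA", "OA"]] = relabelled[["OA", "EA"]].to_numpy()
        relabelled["BETA"] = -relabelled["BETA"]
        relabelled["EAF"] = 1.0 - relabelled["EAF"]
        o2 = SummaryTable("out", "binary", relabelled)
        h1 = retained_pairs(harmonize(e, o))
        h2 = retained_pairs(harmonize(e, o2))
        assert h1["SNP"].tolist() == h2["SNP"].tolist()
        np.testing.assert_allclose(h1["beta_out"], h2["beta_out"])
        np.testing.assert_allclose(h1["eaf_out"], h2["eaf_out"])
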