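"""IO, validation and allele harmonisation of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from mcpmr.sumstats import (
    LDMatrix,
    VariantAssociation,
    harmonize,
    read_ld_matrix,
    read_sumstats,
    write_ld_matrix,
    write_sumstats,
)

from conftest import make_sumstats


class TestReadSumstats:
    def test_invariant_violations_dropped_and_counted(self, tmp_path):
        df = make_sumstats(
            SNP=["rs1", "rs2", "rs3", "rs4"], CHR=["1"] * 4,
            POS=[1, 2, 3, 4], EA=["A"] * 4, OA=["G"] * 4,
            EAF=[0.3, 1.2, 0.4, 0.5], BETA=[0.1] * 4, SE=[0.01] * 4,
            P=[0.5] * 4, N=[1000] * 4,
        )
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        out, rejections = read_sumstats(path)
        assert len(out) == 3
        assert sum(rejections.values()) == 1
        assert rejections == {"eaf_out_of_range": 1}

    def test_column_alias_via_column_map(self, tmp_path):
        df = make_sumstats().rename(columns={"EA": "A1", "OA": "A2"})
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        out, _ = read_sumstats(path, column_map={"A1": "EA", "A2": "OA"})
        canonical, _ = read_sumstats(_write(tmp_path, make_sumstats()))
        pd.testing.assert_frame_equal(out, canonical)

    def test_round_trip_identity(self, tmp_path):
        df = make_sumstats()
        path = tmp_path / "s.tsv"
        write_sumstats(df, path)
        out, rej = read_sumstats(path)
        assert not rej
        pd.testing.assert_frame_equal(out, df, check_dtype=False)

    def test_missing_column_named_in_error(self, tmp_path):
        df = make_sumstats().drop(columns=["EAF"])
        path = _write(tmp_path, df)
        with pytest.raises(ValueError, match="EAF"):
            read_sumstats(path)

    def test_empty_file_is_hard_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_sumstats(path)


def _write(tmp_path, df, name="x.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestVariantAssociation:
    @pytest.mark.parametrize("field,value", [
        ("eaf", 1.2), ("se", 0.0), ("pvalue", 0.0), ("pos", 0), ("n", 1),
        ("other_allele", "A"),
    ])
    def test_invariants_enforced(self, field, value):
        kwargs = dict(snp_id="rs1", chrom="1", pos=100, effect_allele="A",
                      other_allele="G", eaf=0.3, beta=0.1, se=0.01,
                      pvalue=0.5, n=1000)
        kwargs[field] = value
        with pytest.raises(ValueError):
            VariantAssociation(**kwargs)


class TestHarmonize:
    def test_allele_swap_flips_sign_and_complements_eaf(self):
        expo = make_sumstats(SNP=["rs1"], CHR=["1"], POS=[100], EA=["A"],
                             OA=["G"], EAF=[0.25], BETA=[0.2], SE=[0.02],
                             P=[1e-9], N=[5000])
        outc = make_sumstats(SNP=["rs1"], CHR=["1"], POS=[100], EA=["G"],
                             OA=["A"], EAF=[0.3], BETA=[0.1], SE=[0.02],
                             P=[1e-4], N=[9000])
        pairs = harmonize(expo, outc)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row.beta_gy == pytest.approx(-0.1)
        assert row.eaf_gy == pytest.approx(0.7)
        assert bool(row.flipped)

    def test_palindromic_near_half_dropped(self):
        expo = make_sumstats(SNP=["rs1"], EA=["A"], OA=["T"], EAF=[0.30],
                             CHR=["1"], POS=[1], BETA=[0.1], SE=[0.01],
                             P=[1e-9], N=[5000])
        outc = expo.assign(EAF=[0.50])
        assert len(harmonize(expo, outc, palindrome_eaf_window=0.08)) == 0

    def test_palindromic_frequency_discordant_is_flipped(self):
        expo = make_sumstats(SNP=["rs1"], EA=["A"], OA=["T"], EAF=[0.2],
                             CHR=["1"], POS=[1], BETA=[0.1], SE=[0.01],
                             P=[1e-9], N=[5000])
        outc = expo.assign(EAF=[0.8], BETA=[0.3])
        pairs = harmonize(expo, outc)
        assert bool(pairs.iloc[0].flipped)
        assert pairs.iloc[0].beta_gy == pytest.approx(-0.3)

    def test_incompatible_alleles_dropped(self):
        expo = make_sumstats(SNP=["rs1"], EA=["A"], OA=["G"], EAF=[0.3],
                             CHR=["1"], POS=[1], BETA=[0.1], SE=[0.01],
                             P=[1e-9], N=[5000])
        outc = expo.assign(EA=["A"], OA=["C"])
        assert len(harmonize(expo, outc)) == 0

    def test_duplicate_snp_is_hard_error(self):
        expo = make_sumstats(SNP=["rs1", "rs1", "rs3"])
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(expo, make_sumstats())

    def test_idempotent_on_aligned_inputs(self):
        expo = make_sumstats()
        outc = make_sumstats(BETA=[0.05, 0.01, -0.1])
        first = harmonize(expo, outc)
        assert not first["flipped"].any()
        # re-expressing the aligned outcome and re-harmonizing is a no-op
        realigned = outc.assign(BETA=first["beta_gy"].to_numpy())
        again = harmonize(expo, realigned)
        pd.testing.assert_frame_equal(first, again)

    def test_double_swap_restores_outcome_beta(self):
        expo = make_sumstats()
        outc = make_sumstats(BETA=[0.05, 0.01, -0.1])
        swapped = outc.assign(EA=outc["OA"], OA=outc["EA"],
                              BETA=-outc["BETA"], EAF=1 - outc["EAF"])
        pairs = harmonize(expo, swapped)
        np.testing.assert_allclose(pairs["beta_gy"], outc["BETA"])

    def test_output_never_exceeds_input_counts(self):
        expo = make_sumstats()
        outc = make_sumstats(SNP=["rs1", "rs9", "rs3"])
        pairs = harmonize(expo, outc)
        assert len(pairs) <= min(len(expo), len(outc))


class TestLDMatrix:
    def test_round_trip(self, tmp_path):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r, ld.r, atol=1e-12)

    def test_identity_has_zero_offdiag_r2(self):
        ld = LDMatrix(["a", "b"], np.eye(2))
        assert ld.r2("a", "b") == 0.0

    @pytest.mark.parametrize("r", [
        np.array([[1.0, 0.9], [0.2, 1.0]]),        # asymmetric
        np.array([[1.0, 1.2], [1.2, 1.0]]),        # |r| > 1
        np.array([[0.5, 0.1], [0.1, 1.0]]),        # diagonal != 1
    ])
    def test_invalid_matrices_rejected(self, r):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], r)
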