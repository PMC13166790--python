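"""Instrument strength and cis-pQTL selection."""

import numpy as np
import pandas as pd
import pytest

from mcpmr.instruments import (
    GeneAnnotation,
    compute_strength,
    ld_clump,
    select_cis_instruments,
)
from mcpmr.sumstats import LDMatrix

from conftest import make_sumstats


class TestComputeStrength:
    def test_null_effect(self):
        r2, f = compute_strength(0.3, 0.0, 1000)
        assert r2 == 0.0 and f == 0.0

    def test_printed_formulas_on_reference_point(self):
        # R2 = 2*0.5*0.5*0.01 = 0.005; F = 0.005*9998/0.995
        r2, f = compute_strength(0.5, 0.1, 10_000)
        assert r2 == pytest.approx(0.005)
        assert f == pytest.approx(0.005 * 9998 / 0.995)
        assert f == pytest.approx(50.24, abs=0.01)

    def test_r2_vanishes_with_eaf(self):
        r2s = [compute_strength(eaf, 0.1, 1000)[0]
               for eaf in (0.4, 0.2, 0.1, 0.01, 0.001)]
        assert all(a > b for a, b in zip(r2s, r2s[1:]))

    def test_r2_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            compute_strength(0.5, 2.0, 1000)

    def test_f_increases_with_n_at_fixed_r2(self):
        fs = [compute_strength(0.3, 0.1, n)[1] for n in (100, 1000, 10_000)]
        assert fs[0] < fs[1] < fs[2]


def _clump_oracle(df, ld, r2_max, window_kb):
    """Direct restatement of the greedy definition, kept independent of the
    implementation's vector bookkeeping."""
    rows = df.sort_values(["P", "CHR", "POS", "SNP"]).to_dict("records")
    accepted = []
    for row in rows:
        ok = True
        for acc in accepted:
            if acc["CHR"] != row["CHR"]:
                continue
            if abs(acc["POS"] - row["POS"]) > window_kb * 1000:
                continue
            if ld.r2(acc["SNP"], row["SNP"]) >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(row)
    return [r["SNP"] for r in accepted]


class TestLdClump:
    def _two_snps(self, r2):
        df = make_sumstats(SNP=["a", "b"], CHR=["1", "1"],
                           POS=[1000, 6000], EA=["A", "A"], OA=["G", "G"],
                           EAF=[0.3, 0.3], BETA=[0.1, 0.1], SE=[0.01, 0.01],
                           P=[1e-12, 1e-9], N=[10_000, 10_000])
        r = np.sqrt(r2)
        ld = LDMatrix(["a", "b"], np.array([[1.0, r], [r, 1.0]]))
        return df, ld

    def test_dominated_neighbor_removed(self):
        df, ld = self._two_snps(0.5)
        out = ld_clump(df, ld, r2_max=0.001, window_kb=10_000)
        assert out["SNP"].tolist() == ["a"]

    def test_below_threshold_both_kept(self):
        df, ld = self._two_snps(0.0005)
        out = ld_clump(df, ld, r2_max=0.001, window_kb=10_000)
        assert sorted(out["SNP"]) == ["a", "b"]

    def test_matches_bruteforce_oracle_on_random_ld(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            k = 6
            a = rng.uniform(-1, 1, size=(k, k + 2))
            r = np.corrcoef(a)
            ids = [f"s{j}" for j in range(k)]
            ld = LDMatrix(ids, r)
            df = make_sumstats(
                SNP=ids, CHR=["1"] * k,
                POS=(1000 + 5000 * np.arange(k)).tolist(),
                EA=["A"] * k, OA=["G"] * k, EAF=[0.3] * k,
                BETA=[0.1] * k, SE=[0.01] * k,
                P=rng.uniform(1e-12, 1e-6, size=k).tolist(), N=[10_000] * k,
            )
            got = ld_clump(df, ld, r2_max=0.1, window_kb=10_000)
            assert got["SNP"].tolist() == _clump_oracle(df, ld, 0.1, 10_000)

    def test_empty_input_empty_output(self):
        df = make_sumstats().iloc[:0]
        assert len(ld_clump(df, None)) == 0


class TestSelectCisInstruments:
    gene = GeneAnnotation("G1", "1", 2_000_000)

    def _frame(self, **kw):
        base = dict(SNP=["rs1"], CHR=["1"], POS=[2_999_999], EA=["A"],
                    OA=["G"], EAF=[0.3], BETA=[0.15], SE=[0.01],
                    P=[1e-10], N=[50_000])
        base.update(kw)
        return make_sumstats(**base)

    def test_boundary_inside_cis_window_retained(self):
        df = self._frame()
        out, attr = select_cis_instruments(df, self.gene, None)
        assert out["SNP"].tolist() == ["rs1"]
        assert attr["strong"] == 1

    def test_mhc_position_excluded(self):
        gene6 = GeneAnnotation("G6", "6", 30_500_000)
        df = self._frame(CHR=["6"], POS=[30_000_000])
        out, attr = select_cis_instruments(df, gene6, None)
        assert len(out) == 0
        assert attr["non_mhc"] == 0

    def test_subthreshold_pvalue_excluded(self):
        out, _ = select_cis_instruments(self._frame(P=[1e-7]), self.gene, None)
        assert len(out) == 0

    def test_weak_f_excluded(self):
        out, _ = select_cis_instruments(
            self._frame(BETA=[0.01], N=[500]), self.gene, None)
        assert len(out) == 0

    def test_missing_gene_is_hard_error(self):
        with pytest.raises(ValueError, match="gene"):
            select_cis_instruments(self._frame(), None, None)

    def test_unstandardized_betas_refused(self):
        with pytest.raises(ValueError, match="standardized"):
            select_cis_instruments(self._frame(), self.gene, None,
                                   standardized=False)

    def test_invariant_to_input_row_order(self):
        k = 8
        rng = np.random.default_rng(1)
        df = make_sumstats(
            SNP=[f"rs{j}" for j in range(k)], CHR=["1"] * k,
            POS=(1_500_000 + 40_000 * np.arange(k)).tolist(),
            EA=["A"] * k, OA=["G"] * k, EAF=[0.3] * k, BETA=[0.15] * k,
            SE=[0.01] * k, P=rng.uniform(1e-12, 1e-9, k).tolist(),
            N=[50_000] * k,
        )
        ld = LDMatrix([f"rs{j}" for j in range(k)], np.eye(k))
        a, _ = select_cis_instruments(df, self.gene, ld)
        b, _ = select_cis_instruments(
            df.sample(frac=1, random_state=0).reset_index(drop=True),
            self.gene, ld)
        pd.testing.assert_frame_equal(a, b)

    def test_retained_pairs_below_clump_r2(self):
        k = 5
        ids = [f"rs{j}" for j in range(k)]
        r = np.full((k, k), 0.9)
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix(ids, r)
        df = make_sumstats(
            SNP=ids, CHR=["1"] * k,
            POS=(1_900_000 + 10_000 * np.arange(k)).tolist(),
            EA=["A"] * k, OA=["G"] * k, EAF=[0.3] * k, BETA=[0.15] * k,
            SE=[0.01] * k, P=[1e-10] * k, N=[50_000] * k,
        )
        out, _ = select_cis_instruments(df, self.gene, ld)
        kept = out["SNP"].tolist()
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2(a, b) < 0.001
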