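"""Harmonization: allele alignment rules, the palindromic MAF-0.4 rule,
proxy substitution, orientation to the HbA1c-lowering allele, and
randomized strand/swap invariance properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import targetmr as tm
from conftest import make_ld, make_summary
from targetmr.datatypes import COMPLEMENT
from targetmr.harmonize import KEPT_ACTIONS, harmonize, orient_to_lowering


def one_row_exposure(ea="A", oa="G", beta=0.1, eaf=0.3, snp="rs0"):
    return make_summary([{"SNP": snp, "EA": ea, "OA": oa, "BETA": beta, "EAF": eaf,
                          "SE": 0.01, "P": 1e-5}]).df


class TestAlleleAlignment:
    def test_swapped_alleles_negate_beta(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rs0", "EA": "G", "OA": "A", "BETA": 0.2, "EAF": 0.7}])
        tbl = harmonize(exp, out)
        row = tbl.df.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_outcome"] == pytest.approx(-0.2)
        assert row["eaf_outcome"] == pytest.approx(0.3)

    def test_matching_alleles_kept_verbatim(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rs0", "EA": "A", "OA": "G", "BETA": 0.2, "EAF": 0.3}])
        row = harmonize(exp, out).df.iloc[0]
        assert row["action"] == "kept"
        assert row["beta_outcome"] == pytest.approx(0.2)

    def test_strand_complement_resolved(self):
        # T/C on the other strand is A/G on this one
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rs0", "EA": "T", "OA": "C", "BETA": 0.2, "EAF": 0.3}])
        row = harmonize(exp, out).df.iloc[0]
        assert row["action"] == "kept"
        assert row["beta_outcome"] == pytest.approx(0.2)

    def test_irreconcilable_alleles_dropped_with_warning(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rs0", "EA": "A", "OA": "C", "BETA": 0.2}])
        with pytest.warns(UserWarning):
            row = harmonize(exp, out).df.iloc[0]
        assert row["action"] == "allele_mismatch"


class TestPalindromicRule:
    def test_ambiguous_maf_dropped(self):
        exp = one_row_exposure("A", "T", beta=0.1, eaf=0.45)
        out = make_summary([{"SNP": "rs0", "EA": "A", "OA": "T", "BETA": 0.2, "EAF": 0.45}])
        assert harmonize(exp, out).df.iloc[0]["action"] == "dropped_palindromic"

    def test_either_side_over_threshold_drops(self):
        exp = one_row_exposure("C", "G", beta=0.1, eaf=0.2)
        out = make_summary([{"SNP": "rs0", "EA": "C", "OA": "G", "BETA": 0.2, "EAF": 0.45}])
        assert harmonize(exp, out).df.iloc[0]["action"] == "dropped_palindromic"

    def test_polar_frequency_kept(self):
        exp = one_row_exposure("A", "T", beta=0.1, eaf=0.2)
        out = make_summary([{"SNP": "rs0", "EA": "A", "OA": "T", "BETA": 0.2, "EAF": 0.22}])
        row = harmonize(exp, out).df.iloc[0]
        assert row["action"] == "kept"
        assert row["beta_outcome"] == pytest.approx(0.2)

    def test_frequency_conflict_implies_strand_flip(self):
        # same letters but the outcome frequency sits on the other side of 0.5
        exp = one_row_exposure("A", "T", beta=0.1, eaf=0.2)
        out = make_summary([{"SNP": "rs0", "EA": "A", "OA": "T", "BETA": 0.2, "EAF": 0.8}])
        row = harmonize(exp, out).df.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_outcome"] == pytest.approx(-0.2)


class TestProxySubstitution:
    def _ld(self, r_ab=0.92, r_ac=0.97):
        r = np.array([[1.0, r_ab, r_ac], [r_ab, 1.0, 0.9], [r_ac, 0.9, 1.0]])
        return make_ld(["rs0", "rsB", "rsC"], r, pos=[1000, 2000, 3000])

    def test_highest_r2_proxy_chosen(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rsB", "BETA": 0.15, "EAF": 0.3},
                            {"SNP": "rsC", "BETA": 0.25, "EAF": 0.3}])
        tbl = harmonize(exp, out, ld=self._ld())  # r2: B 0.846, C 0.941
        row = tbl.df.iloc[0]
        assert row["action"] == "proxied"
        assert row["proxy_snp"] == "rsC"
        assert row["beta_outcome"] == pytest.approx(0.25)
        assert row["beta_exposure"] == pytest.approx(0.1)  # exposure side untouched

    def test_negative_ld_sign_flips_outcome(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rsC", "BETA": 0.25, "EAF": 0.3}])
        tbl = harmonize(exp, out, ld=self._ld(r_ac=-0.97))
        row = tbl.df.iloc[0]
        assert row["action"] == "proxied"
        assert row["beta_outcome"] == pytest.approx(-0.25)

    def test_no_adequate_proxy_drops(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rsB", "BETA": 0.15}])
        tbl = harmonize(exp, out, ld=self._ld(r_ab=0.5))
        assert tbl.df.iloc[0]["action"] == "dropped_missing"

    def test_missing_without_ld_reference_drops(self):
        exp = one_row_exposure("A", "G", beta=0.1)
        out = make_summary([{"SNP": "rsZ", "BETA": 0.15}])
        assert harmonize(exp, out).df.iloc[0]["action"] == "dropped_missing"


class TestOrientation:
    def test_raising_allele_flipped_to_lowering(self):
        exp = one_row_exposure("A", "G", beta=0.05)
        out = make_summary([{"SNP": "rs0", "EA": "A", "OA": "G", "BETA": 0.02, "EAF": 0.3}])
        tbl = orient_to_lowering(harmonize(exp, out))
        row = tbl.df.iloc[0]
        assert row["beta_exposure"] == pytest.approx(0.05)  # SD lowered per allele
        assert row["beta_outcome"] == pytest.approx(-0.02)
        assert row["EA"] == "G"  # effect allele is now the lowering allele

    def test_idempotent(self, oriented_bmi):
        again = orient_to_lowering(oriented_bmi)
        pd.testing.assert_frame_equal(again.df, oriented_bmi.df)

    def test_pipeline_sign_convention(self, all_targets_iv, study):
        """Protective generating truth: continuous IVW negative, binary OR < 1."""
        bmi = orient_to_lowering(harmonize(all_targets_iv, study.outcomes["bmi"]))
        assert tm.ivw(bmi).beta < 0
        cad = orient_to_lowering(harmonize(all_targets_iv, study.outcomes["cad"]))
        est = tm.scale_estimate(tm.ivw(cad), outcome_type="binary")
        assert est.odds_ratio < 1


class TestNormalFormAndAccounting:
    def test_reharmonizing_harmonized_output_changes_nothing(self, all_targets_iv, study):
        tbl = harmonize(all_targets_iv, study.outcomes["bmi"])
        kept = tbl.kept()
        # rebuild an outcome dataset from the harmonized rows
        out2 = make_summary([
            {"SNP": r["SNP"], "EA": r["EA"], "OA": r["OA"], "BETA": r["beta_outcome"],
             "SE": r["se_outcome"], "EAF": r["eaf_outcome"]}
            for _, r in kept.iterrows()], trait="bmi")
        exp2 = all_targets_iv.table[all_targets_iv.table["SNP"].isin(kept["SNP"])]
        tbl2 = harmonize(exp2, out2)
        k2 = tbl2.kept().set_index("SNP")
        k1 = kept.set_index("SNP")
        np.testing.assert_allclose(k1["beta_outcome"], k2.loc[k1.index, "beta_outcome"], rtol=1e-12)

    def test_every_row_accounted_once(self, all_targets_iv, study):
        for outcome in study.outcomes.values():
            tbl = harmonize(all_targets_iv, outcome, ld=study.ld["all"])
            assert len(tbl.df) == len(all_targets_iv.table)
            assert tbl.df["action"].notna().all()


nonpal_pairs = [(a, b) for a in "ACGT" for b in "ACGT" if a != b and COMPLEMENT[a] != b]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pair=st.sampled_from(nonpal_pairs),
    beta=st.floats(-0.5, 0.5, allow_nan=False),
    eaf=st.floats(0.05, 0.95),
    swap=st.booleans(),
    strand=st.booleans(),
)
def test_strand_flip_and_swap_invariance(pair, beta, eaf, swap, strand):
    """Any representation of the same non-palindromic outcome record (allele
    swap and/or strand complement) harmonizes to identical betas."""
    ea, oa = pair
    exp = one_row_exposure(ea, oa, beta=0.1, eaf=0.3)
    o_ea, o_oa, o_beta, o_eaf = ea, oa, beta, eaf
    if swap:
        o_ea, o_oa, o_beta, o_eaf = o_oa, o_ea, -o_beta, 1 - o_eaf
    if strand:
        o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    out = make_summary([{"SNP": "rs0", "EA": o_ea, "OA": o_oa, "BETA": o_beta, "EAF": o_eaf}])
    row = harmonize(exp, out).df.iloc[0]
    assert row["action"] in KEPT_ACTIONS
    assert row["beta_outcome"] == pytest.approx(beta, abs=1e-12)
    assert row["eaf_outcome"] == pytest.approx(eaf, abs=1e-12)
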