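"""Overlap-adjusted differential statistic, standardization, p-values,
candidate selection and clumping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from diffgwas import (ConfigError, DegenerateVarianceError, SelectionConfig,
                      StandardizationError, clump, delta_variance, delta_z_raw,
                      harmonize, loci_table, p_two_sided, run_diff_gwas,
                      select_candidates, standardize)


class TestDeltaVariance:
    def test_uncorrelated_is_sum_of_squares(self):
        assert delta_variance(0.011, 0.006, 0.0) == pytest.approx(1.57e-4)

    def test_overlap_subtracts_covariance(self):
        # 1.57e-4 - 2*0.3*0.011*0.006
        assert delta_variance(0.011, 0.006, 0.3) == pytest.approx(1.174e-4)

    def test_perfect_correlation_equal_se_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            delta_variance(0.01, 0.01, 1.0)

    def test_parameter_validation(self):
        with pytest.raises(ConfigError):
            delta_variance(-0.01, 0.01, 0.0)
        with pytest.raises(ConfigError):
            delta_variance(0.01, 0.01, 1.5)


class TestDeltaZ:
    def test_identical_effects_give_zero(self):
        assert delta_z_raw(0.1, 0.1, 0.02, 0.03, 0.4) == 0.0

    def test_worked_example_no_overlap(self):
        # -0.091 / sqrt(1.57e-4)
        z = delta_z_raw(-0.068, 0.023, 0.011, 0.006, 0.0)
        assert z == pytest.approx(-7.263, abs=5e-4)

    def test_worked_example_with_overlap(self):
        # same betas, rho = 0.3: variance shrinks, |z| grows
        z = delta_z_raw(-0.068, 0.023, 0.011, 0.006, 0.3)
        assert z == pytest.approx(-8.399, abs=5e-4)

    def test_abs_z_increases_with_rho(self):
        zs = [abs(delta_z_raw(0.05, -0.03, 0.01, 0.008, r))
              for r in np.linspace(0, 0.9, 10)]
        assert np.all(np.diff(zs) > 0)


class TestStandardize:
    def test_sample_sd_convention(self):
        np.testing.assert_allclose(standardize([2.0, 4.0, 6.0]), [-1, 0, 1])

    def test_idempotent_on_standardized_input(self):
        z = standardize(np.random.default_rng(0).standard_normal(100))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(StandardizationError):
            standardize([1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=200))
    def test_affine_map_properties(self, values):
        z = np.asarray(values)
        if np.ptp(z) == 0:
            with pytest.raises(StandardizationError):
                standardize(z)
            return
        assume(np.ptp(z) > 1e-3)  # keep cancellation error negligible
        out = standardize(z)
        assert out.mean() == pytest.approx(0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(1, rel=1e-9)
        # monotone (affine with positive scale)
        assert np.all(np.diff(out[np.argsort(z)]) >= 0)

    def test_robust_matches_plain_on_clean_normal(self):
        z = np.random.default_rng(1).standard_normal(20_000)
        np.testing.assert_allclose(standardize(z, robust=True), standardize(z),
                                   atol=0.05)


class TestPTwoSided:
    @pytest.mark.parametrize("z, p, rel", [
        (0.0, 1.0, 1e-12),
        (5.631, 1.79e-8, 0.01),   # replication worked example
        (-5.58, 2.40e-8, 0.05),   # z printed to 2 decimals
        (1.96, 0.05, 0.01),
    ])
    def test_reference_values(self, z, p, rel):
        assert p_two_sided(z) == pytest.approx(p, rel=rel)

    def test_extreme_tail_no_underflow_to_wrong_zero(self):
        assert 0 < p_two_sided(37.0) < 1e-290

    def test_symmetry(self):
        z = np.linspace(-10, 10, 101)
        np.testing.assert_allclose(p_two_sided(z), p_two_sided(-z))


class TestRunDiffGwas:
    def test_reduces_to_classical_test_at_rho_zero(self, harmonized_null):
        d = run_diff_gwas(harmonized_null, rho=0.0)
        classical = (harmonized_null["beta1"] - harmonized_null["beta2"]) / np.sqrt(
            harmonized_null["se1"] ** 2 + harmonized_null["se2"] ** 2)
        np.testing.assert_array_equal(d["z_raw"].to_numpy(),
                                      classical.to_numpy())

    def test_antisymmetry_under_study_swap(self, harmonized_null):
        swapped = harmonized_null.rename(columns={
            "beta1": "beta2", "beta2": "beta1", "se1": "se2", "se2": "se1",
            "p1": "p2", "p2": "p1"})
        a = run_diff_gwas(harmonized_null, rho=0.3)
        b = run_diff_gwas(swapped, rho=0.3)
        np.testing.assert_allclose(b["z_raw"], -a["z_raw"], atol=1e-12)
        np.testing.assert_allclose(b["z_std"], -a["z_std"], atol=1e-12)
        np.testing.assert_allclose(b["p_diff"], a["p_diff"], rtol=1e-9)

    def test_self_comparison_surfaces_standardization_error(self, toy_pair):
        t1, _ = toy_pair
        h = harmonize(t1, t1, ambiguous="keep")
        with pytest.raises(StandardizationError):
            run_diff_gwas(h, rho=0.0)

    def test_p_consistent_with_z_std(self, harmonized_null):
        d = run_diff_gwas(harmonized_null, rho=0.3)
        np.testing.assert_allclose(d["p_diff"], p_two_sided(d["z_std"].to_numpy()))
        # the location shift may push a few near-zero scores across zero;
        # those rows are flagged rather than silently passed
        assert (~d["sign_ok"]).mean() < 0.05
        assert np.all(d.loc[~d["sign_ok"], "z_raw"].abs() < 0.1)
        assert ((d["p_diff"] > 0) & (d["p_diff"] <= 1)).all()
        assert (d["var_adj"] > 0).all()


def _diff_rows(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "beta1", "p1",
                                       "beta2", "p2", "p_diff"])


class TestSelectCandidates:
    BASE = [
        ("1", 1000, "a", 0.1, 1e-9, -0.1, 0.01, 1e-9),    # passes everything
        ("1", 2000, "b", 0.1, 1e-9, -0.1, 0.20, 1e-9),    # fails nominal trait 2
        ("1", 3000, "c", 0.1, 1e-9, 0.1, 0.01, 1e-9),     # same direction
        ("1", 4000, "d", 0.1, 1e-9, -0.1, 0.01, 1e-6),    # fails genome-wide diff
    ]

    def test_composite_rule(self):
        out = select_candidates(_diff_rows(self.BASE))
        assert out["rsid"].tolist() == ["a"]

    def test_same_direction_allowed_when_flag_off(self):
        cfg = SelectionConfig(require_opposite=False)
        out = select_candidates(_diff_rows(self.BASE), cfg)
        assert out["rsid"].tolist() == ["a", "c"]

    def test_monotone_in_thresholds(self):
        rows = _diff_rows(self.BASE)
        loose = select_candidates(rows, SelectionConfig(p_diff_threshold=1e-5))
        tight = select_candidates(rows, SelectionConfig(p_diff_threshold=1e-10))
        assert set(tight["rsid"]) <= set(loose["rsid"])

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            SelectionConfig(p_diff_threshold=0.05, p_nominal_threshold=0.05)


class TestClump:
    def _rows(self, specs):
        return pd.DataFrame([
            {"chrom": c, "pos": p, "rsid": r, "p_diff": pd_, "a1": "A",
             "a2": "G", "beta1": 0.1, "se1": 0.01, "p1": 1e-9, "beta2": -0.1,
             "se2": 0.01, "p2": 0.01, "z_std": -5.0}
            for c, p, r, pd_ in specs])

    def test_within_window_merge(self):
        loci = clump(self._rows([("1", 100_000, "a", 1e-9),
                                 ("1", 200_000, "b", 1e-12)]), 1_000_000)
        assert len(loci) == 1
        assert loci[0].rsid == "b"
        assert loci[0].span == (100_000, 200_000)

    def test_chromosome_separation(self):
        loci = clump(self._rows([("1", 100_000, "a", 1e-9),
                                 ("2", 100_000, "b", 1e-12)]), 1_000_000)
        assert [l.rsid for l in loci] == ["b", "a"]

    def test_greedy_absorbs_middle_snp(self):
        # p_diff decreasing along position: best lead at 1.8 Mb absorbs the
        # 0.9 Mb SNP, leaving the SNP at 0 as its own locus
        loci = clump(self._rows([("1", 0, "a", 1e-9),
                                 ("1", 900_000, "b", 1e-10),
                                 ("1", 1_800_000, "c", 1e-11)]), 1_000_000)
        assert [l.rsid for l in loci] == ["c", "a"]
        assert len(loci[0].members) == 2

    def test_loci_table_layout(self):
        loci = clump(self._rows([("1", 100_000, "a", 1e-9)]), 1_000_000)
        tab = loci_table(loci)
        assert tab.loc[0, "rsid"] == "a" and tab.loc[0, "n_members"] == 1
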