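import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twinace as tw
from twinace import models as M
from twinace.errors import IdentificationError
from twinace.likelihood import build_stats, fit_stats


def params(**kw):
    base = dict(a_m=0.7, c_m=0.4, e_m=0.6, a_f=0.7, c_f=0.4, e_f=0.6)
    base.update(kw)
    return M.ACEParams(**base)


class TestExpectedMoments:
    def test_mz_covariance_is_a2_plus_c2(self):
        p = params(a_m=np.sqrt(0.55), c_m=0.0, e_m=np.sqrt(0.45))
        mom = M.expected_moments(p, "MZM")
        assert mom.sigma[0, 0] == pytest.approx(1.0)
        assert mom.sigma[0, 1] == pytest.approx(0.55)

    def test_dz_implied_correlation_halves_A(self):
        p = params(a_m=np.sqrt(0.55), c_m=0.0, e_m=np.sqrt(0.45))
        mom = M.expected_moments(p, "DZM")
        assert mom.sigma[0, 1] / mom.sigma[0, 0] == pytest.approx(0.275)

    def test_dzos_equals_same_sex_dz_under_homogeneity(self):
        p = params(r_A_mf=0.5, r_C_mf=1.0)
        assert M.expected_moments(p, "DZOS").sigma[0, 1] == pytest.approx(
            M.expected_moments(p, "DZM").sigma[0, 1]
        )

    def test_singletons_get_sex_variance(self):
        p = params(k=1.3)
        v_f = M.expected_moments(p, "SGF").sigma[0, 0]
        assert v_f == pytest.approx(1.3**2 * (0.7**2 + 0.4**2 + 0.6**2))

    def test_sex_relabel_invariance_under_homogeneity(self):
        p = params()
        for g_m, g_f in (("MZM", "MZF"), ("DZM", "DZF"), ("SGM", "SGF")):
            m, f = M.expected_moments(p, g_m), M.expected_moments(p, g_f)
            assert np.allclose(m.sigma, f.sigma) and np.allclose(m.mu, f.mu)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 1.5),
        c=st.floats(0.0, 1.5),
        e=st.floats(0.05, 1.5),
    )
    def test_correlation_ordering_rmz_ge_rdz_ge_ros(self, a, c, e):
        p = params(a_m=a, c_m=c, e_m=e, a_f=a, c_f=c, e_f=e, r_A_mf=0.5, r_C_mf=1.0)
        v = a**2 + c**2 + e**2
        r_mz = M.expected_moments(p, "MZM").sigma[0, 1] / v
        r_dz = M.expected_moments(p, "DZM").sigma[0, 1] / v
        r_os = M.expected_moments(p, "DZOS").sigma[0, 1] / v
        assert r_mz >= r_dz - 1e-12
        assert r_dz >= r_os - 1e-12  # equal-sex case: rOS == rDZ


class TestSpecs:
    def test_saturated_parameter_count(self):
        assert M.saturated_spec(constrain=True).n_free == 9

    def test_homogeneity_parameter_count(self):
        assert M.ace_spec(M.HOMOGENEITY).n_free == 5

    def test_scalar_adds_exactly_one_parameter(self):
        assert M.ace_spec(M.SCALAR_NO_SEXDIF).n_free == M.ace_spec(M.HOMOGENEITY).n_free + 1

    def test_qual_specs_have_nine_parameters(self):
        assert M.ace_spec(M.FULL_HET_QUAL_A).n_free == 9
        assert M.ace_spec(M.FULL_HET_QUAL_C).n_free == 9
        assert M.ace_spec(M.QUANT_HET).n_free == 8

    def test_freeing_both_cross_sex_correlations_rejected(self):
        with pytest.raises(IdentificationError):
            M.ace_spec(M.FULL_HET_QUAL_A, free_r_c=True)

    def test_qual_a_with_fixed_half_reproduces_quant_het(self, small_cohort):
        stats = build_stats(small_cohort.pair_arrays("trait"))
        quant = fit_stats(M.ace_spec(M.QUANT_HET), stats, starts=2, seed=0)
        qual_fixed = fit_stats(
            M.ace_spec(M.FULL_HET_QUAL_A),
            stats,
            starts=2,
            seed=0,
            fix={"r_A_mf": 0.5},
            extra_starts=[quant.params],
        )
        assert qual_fixed.minus2LL == pytest.approx(quant.minus2LL, abs=1e-5)

    def test_saturated_correlations_match_pearson(self):
        # balanced complete data: FIML correlation ~= per-group Pearson
        cfg = tw.SimConfig(
            n_pairs={g: 600 for g in ("MZM", "DZM", "MZF", "DZF", "DZOS")},
            n_singletons={},
            seed=51,
        )
        ds = tw.simulate(cfg)
        arrays = ds.pair_arrays("trait")
        res = fit_stats(M.saturated_spec(), build_stats(arrays), starts=3, seed=0)
        for code, arr in arrays.items():
            if arr.shape[1] == 1:
                continue
            r_pearson = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
            assert res.params[f"r_{code}"] == pytest.approx(r_pearson, abs=0.02)

    def test_saturated_invariant_to_twin_order_swap(self):
        cfg = tw.SimConfig(
            n_pairs={"MZM": 300, "DZM": 300, "MZF": 300, "DZF": 300, "DZOS": 300},
            n_singletons={},
            seed=52,
        )
        ds = tw.simulate(cfg)
        df = ds.df.copy()
        same_sex = df["zygosity"].isin(["MZM", "DZM", "MZF", "DZF"])
        df.loc[same_sex, "birth_order"] = 3 - df.loc[same_sex, "birth_order"]
        swapped = tw.TwinDataset(df, ds.measure_names)
        a = fit_stats(M.saturated_spec(), build_stats(ds.pair_arrays("trait")), starts=2, seed=0)
        b = fit_stats(M.saturated_spec(), build_stats(swapped.pair_arrays("trait")), starts=2, seed=0)
        for code in ("MZM", "DZM", "MZF", "DZF"):
            assert a.params[f"r_{code}"] == pytest.approx(b.params[f"r_{code}"], abs=1e-4)


class TestStandardize:
    def test_equal_paths_thirds(self):
        out = M.standardize(params(a_m=1, c_m=1, e_m=1, a_f=1, c_f=1, e_f=1))
        assert out["male"] == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_zero_path_exact_zero(self):
        out = M.standardize(params(c_m=0.0))
        assert out["male"][1] == 0.0

    def test_scalar_k_leaves_proportions_unchanged(self):
        base = M.standardize(params(k=1.0))
        scaled = M.standardize(params(k=0.67))
        assert scaled["female"] == pytest.approx(base["female"], abs=1e-12)

    def test_proportions_sum_to_one(self):
        out = M.standardize(params(a_m=0.83, c_m=0.11, e_m=0.52))
        assert sum(out["male"]) == pytest.approx(1.0, abs=1e-12)


class TestRecovery:
    @pytest.mark.parametrize(
        "label, ace_m, ace_f, k",
        [
            (M.HOMOGENEITY, (0.40, 0.20, 0.40), (0.40, 0.20, 0.40), 1.0),
            (M.QUANT_HET, (0.45, 0.10, 0.45), (0.15, 0.35, 0.50), 1.0),
            (M.SCALAR_NO_SEXDIF, (0.40, 0.20, 0.40), (0.40, 0.20, 0.40), 0.7),
        ],
    )
    def test_parameter_recovery_under_generating_label(self, label, ace_m, ace_f, k):
        """Mean standardized estimates over replicates recover the truth."""
        reps = 6
        got_m = np.zeros(3)
        got_f = np.zeros(3)
        for i in range(reps):
            cfg = tw.SimConfig(
                n_pairs={g: 2000 for g in ("MZM", "DZM", "MZF", "DZF", "DZOS")},
                n_singletons={},
                ace_male=ace_m,
                ace_female=ace_f,
                var_female=k**2,
                seed=600 + i,
            )
            ds = tw.simulate(cfg)
            f = fit_stats(M.ace_spec(label), build_stats(ds.pair_arrays("trait")),
                          starts=2, seed=i)
            full = dict(f.params)
            for sex in "mf":
                if f"a_{sex}" not in full:
                    full.update({f"{q}_{sex}": full[f"{q}_s"] for q in "ace"})
            props = M.standardize(full)
            got_m += np.array(props["male"]) / reps
            got_f += np.array(props["female"]) / reps
        assert np.allclose(got_m, ace_m, atol=0.04)
        assert np.allclose(got_f, ace_f, atol=0.04)
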