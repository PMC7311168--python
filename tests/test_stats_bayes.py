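import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import ssvep_tuning as st
from ssvep_tuning.contrasts import ContrastWeights
from ssvep_tuning.stats_bayes import MODELS

from oracles import mc_jzs_bf


class TestJZSBF:
    def test_affine_invariance_of_weights(self, fixture_table_6x6, li_weights):
        base = st.jzs_bf(fixture_table_6x6, li_weights, model="M1")
        scaled = ContrastWeights("scaled", tuple(10.0 * w for w in li_weights.weights))
        res_scaled = st.jzs_bf(fixture_table_6x6, scaled, model="M1")
        assert res_scaled.bf == pytest.approx(base.bf, rel=1e-6)
        shifted = np.array(li_weights.weights) + 3.0
        recentered = ContrastWeights("recentered", tuple(shifted - shifted.mean()))
        res_shift = st.jzs_bf(fixture_table_6x6, recentered, model="M1")
        assert res_shift.bf == pytest.approx(base.bf, rel=1e-6)

    @pytest.mark.parametrize("model", MODELS)
    def test_against_mc_oracle(self, fixture_table_6x6, li_weights, model):
        res = st.jzs_bf(fixture_table_6x6, li_weights, model=model)
        mc = mc_jzs_bf(fixture_table_6x6, li_weights.as_array(), model,
                       n_draws=200_000, seed=99)
        assert res.bf == pytest.approx(mc, rel=0.05)

    def test_null_data_median_bf_below_one(self):
        bfs = []
        for i in range(30):
            profs = st.sample_subjects(40, seed=700 + i)
            tab = st.simulate_snr_table(profs, pattern=None,
                                        include_phases=("generalization",),
                                        seed=800 + i)
            bfs.append(st.jzs_bf(tab, st.contrast_weights("lateral_inhibition"),
                                 model="M1").bf)
        assert np.median(bfs) < 1.0

    def test_planted_pattern_supported(self, gen_table40, li_weights):
        res = st.jzs_bf(gen_table40, li_weights, model="M1")
        assert res.bf > 10.0

    def test_nested_consistency(self, gen_table40, li_weights):
        """BF(M3 vs 0) equals the product along the nested chain."""
        bf1 = st.jzs_bf(gen_table40, li_weights, model="M1").bf
        bf2 = st.jzs_bf(gen_table40, li_weights, model="M2").bf
        bf3 = st.jzs_bf(gen_table40, li_weights, model="M3").bf
        chain = (st.transitive_bf(bf3, bf2) * st.transitive_bf(bf2, bf1) * bf1)
        assert bf3 == pytest.approx(chain, rel=1e-9)

    def test_error_reported(self, fixture_table_6x6, li_weights):
        res = st.jzs_bf(fixture_table_6x6, li_weights, model="M2")
        assert 0 <= res.rel_err < 0.01

    def test_unknown_model(self, fixture_table_6x6, li_weights):
        with pytest.raises(ValueError):
            st.jzs_bf(fixture_table_6x6, li_weights, model="M4")

    def test_missing_values_raise(self, fixture_table_6x6, li_weights):
        tab = fixture_table_6x6.copy()
        tab.loc[tab.index[0], "snr"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            st.jzs_bf(tab, li_weights, model="M1")

    def test_rscale_settings_echoed(self, fixture_table_6x6, li_weights):
        res = st.jzs_bf(fixture_table_6x6, li_weights, model="M1",
                        rscale_fixed=0.7, rscale_random=1.2)
        assert res.settings["rscale_fixed"] == 0.7
        assert res.settings["rscale_random"] == 1.2


class TestTransitive:
    def test_basic_ratio(self):
        assert st.transitive_bf(10.0, 2.0) == 5.0

    def test_self_ratio_one(self):
        assert st.transitive_bf(3.3, 3.3) == 1.0

    def test_inverse_product(self):
        assert st.transitive_bf(7.0, 2.0) * st.transitive_bf(2.0, 7.0) \
            == pytest.approx(1.0)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            st.transitive_bf(0.0, 1.0)
        with pytest.raises(ValueError):
            st.transitive_bf(1.0, -2.0)


def test_bayes_comparison_table(gen_table40):
    frame = st.bayes_comparison(gen_table40)
    assert list(frame["model"]) == list(MODELS)
    for name in ("lateral_inhibition", "quadratic", "linear"):
        assert f"bf_{name}" in frame.columns
    assert "lateral_inhibition_vs_quadratic" in frame.columns
    row = frame.iloc[0]
    assert row["lateral_inhibition_vs_quadratic"] == pytest.approx(
        row["bf_lateral_inhibition"] / row["bf_quadratic"], rel=1e-12)


class TestTuningIndex:
    def test_weights_as_snr(self, li_weights):
        assert st.tuning_index(li_weights.as_array(), li_weights) == pytest.approx(13.5)

    def test_constant_snr_zero(self, li_weights):
        assert st.tuning_index(np.full(6, 4.2), li_weights) == pytest.approx(0.0)

    def test_unit_csplus(self, li_weights):
        assert st.tuning_index(np.array([1, 0, 0, 0, 0, 0]), li_weights) == 2.0

    def test_length_mismatch(self, li_weights):
        with pytest.raises(ValueError):
            st.tuning_index(np.ones(5), li_weights)

    @given(a=hst.floats(-5, 5), b=hst.floats(-5, 5))
    def test_linearity(self, a, b):
        w = st.contrast_weights("lateral_inhibition")
        rng = np.random.default_rng(0)
        s1, s2 = rng.normal(size=6), rng.normal(size=6)
        lhs = st.tuning_index(a * s1 + b * s2, w)
        rhs = a * st.tuning_index(s1, w) + b * st.tuning_index(s2, w)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_table(self, gen_table40):
        tab = st.tuning_index_table(gen_table40)
        assert len(tab) == 40 * 3
        assert set(tab["contrast"]) == {"lateral_inhibition", "quadratic", "linear"}
        # planted lateral-inhibition gain: mean index positive
        li = tab[tab["contrast"] == "lateral_inhibition"]
        assert li["index"].mean() > 0

    def test_incomplete_subject_raises(self, gen_table40):
        with pytest.raises(ValueError, match="incomplete"):
            st.tuning_index_table(gen_table40.iloc[1:])


class TestCorrelation:
    def test_perfect_linear(self):
        spai = np.linspace(30, 120, 20)
        res = st.correlate_with_covariate(0.5 * spai - 3.0, spai)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12
        assert res.bf_rho > 100

    def test_null_large_n(self):
        rng = np.random.default_rng(3)
        res = st.correlate_with_covariate(rng.normal(size=10_000),
                                          rng.normal(size=10_000))
        assert abs(res.r) < 0.05

    def test_refinement_oracle(self):
        """Adaptive quadrature matches a 10x-refined fixed grid within 1%."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        r = float(np.corrcoef(x, y)[0, 1])
        coarse = st.pearson_bf(r, 20, n_grid=2001)
        fine = st.pearson_bf(r, 20, n_grid=20001)
        adaptive = st.pearson_bf(r, 20)
        assert adaptive == pytest.approx(fine, rel=0.01)
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_matches_pingouin(self):
        import pingouin as pg

        for r, n in ((0.288, 67), (-0.4, 30), (0.05, 100)):
            assert st.pearson_bf(r, n) == pytest.approx(
                float(pg.bayesfactor_pearson(r, n)), rel=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            st.correlate_with_covariate(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            st.correlate_with_covariate(np.arange(3.0), np.arange(3.0))

    def test_planted_covariate_link_detected(self):
        """Accentuation rising with the covariate yields a positive index
        correlation with covariate support."""
        profs = st.sample_subjects(
            60, accentuation_params=st.AccentuationParams(0.4, 0.35, 0.1), seed=21)
        tab = st.simulate_snr_table(profs, pattern=st.contrast_weights("lateral_inhibition"),
                                    noise_sd=0.4, include_phases=("generalization",),
                                    seed=22)
        idx = st.tuning_index_table(tab)
        li = idx[idx["contrast"] == "lateral_inhibition"]
        res = st.correlate_with_covariate(li["index"].to_numpy(), li["spai"].to_numpy())
        assert res.r > 0.3
        assert res.bf_rho > 3.0


def test_model_selection_recovery_smoke():
    """Planted lateral-inhibition data: its M3 model beats the alternatives."""
    profs = st.sample_subjects(40, seed=301)
    tab = st.simulate_snr_table(profs, pattern=st.contrast_weights("lateral_inhibition"),
                                include_phases=("generalization",), seed=302)
    bfs = {name: st.jzs_bf(tab, st.contrast_weights(name), model="M3").bf
           for name in ("lateral_inhibition", "quadratic", "linear")}
    assert max(bfs, key=bfs.get) == "lateral_inhibition"
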