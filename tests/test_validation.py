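"""Reference/validation construction and validation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcombine import (
    SplitSpec,
    build_reference,
    build_validation,
    choose_cutoff_years,
    genomic_gain,
    make_eval_frame,
    parent_average_pi,
    weighted_bias_regression,
    weighted_corr_reliability,
)


def frame(**cols):
    defaults = {
        "bull_id": [f"b{i}" for i in range(len(next(iter(cols.values()))))],
        "population": "A",
        "sire_id": None,
    }
    defaults.update(cols)
    return pd.DataFrame(defaults)


SPLIT = SplitSpec(cutoff_year={"A": 2000, "B": 2000}, min_edc=20.0)


class TestBuildReference:
    def test_edc_filter_keeps_at_least_20(self):
        f = frame(
            birth_year=[1995] * 5,
            edc=[10.0, 20.0, 25.0, 19.0, 100.0],
            drp=[0.1] * 5,
            rel=[0.8] * 5,
        )
        ref = build_reference(f, SPLIT, "national", "A")
        assert ref.n == 3
        assert set(ref.bull_ids) == {"b1", "b2", "b4"}

    def test_zero_min_edc_keeps_everyone(self):
        f = frame(birth_year=[1995] * 4, edc=[1.0, 5.0, 0.5, 3.0],
                  drp=[0.1] * 4, rel=[0.8] * 4)
        split = SplitSpec(cutoff_year={"A": 2000}, min_edc=0.0)
        assert build_reference(f, split, "national", "A").n == 4

    def test_combined_scope_is_additive_over_populations(self):
        f = frame(
            birth_year=[1995] * 8,
            population=["A"] * 4 + ["B"] * 4,
            edc=[30.0] * 8,
            drp=[0.1] * 8,
            rel=[0.8] * 8,
        )
        nat_a = build_reference(f, SPLIT, "national", "A").n
        nat_b = build_reference(f, SPLIT, "national", "B").n
        comb = build_reference(f, SPLIT, "combined", "A")
        assert comb.n == nat_a + nat_b
        assert comb.domestic.sum() == nat_a

    def test_empty_reference_raises(self):
        f = frame(birth_year=[2003], edc=[30.0], drp=[0.1], rel=[0.8])
        with pytest.raises(ValueError, match="empty reference"):
            build_reference(f, SPLIT, "national", "A")


class TestBuildValidation:
    def base_frame(self):
        return frame(
            birth_year=[1995, 1995, 2002, 2002, 2002],
            population=["A", "B", "A", "A", "A"],
            sire_id=[None, None, "b0", "b1", "zz"],
            edc=[50.0, 50.0, 30.0, 30.0, 30.0],
            drp=[0.1] * 5,
            rel=[0.8] * 5,
        )

    def test_national_sire_scope(self):
        f = self.base_frame()
        ref = build_reference(f, SPLIT, "combined", "A")
        valid = build_validation(f, SPLIT, ref, "A")
        # b3's sire b1 is foreign: excluded under national scope; b4's sire
        # is unknown: excluded; b2's sire b0 is domestic reference: kept
        assert list(valid["bull_id"]) == ["b2"]

    def test_combined_sire_scope_admits_foreign_sires(self):
        f = self.base_frame()
        split = SplitSpec(cutoff_year={"A": 2000, "B": 2000}, sire_scope="combined")
        ref = build_reference(f, split, "combined", "A")
        valid = build_validation(f, split, ref, "A")
        assert set(valid["bull_id"]) == {"b2", "b3"}

    def test_disjoint_from_reference(self, small_study):
        f = make_eval_frame(small_study, "yield", "A")
        cut = choose_cutoff_years(small_study.bulls, 0.25)
        split = SplitSpec(cutoff_year=cut, min_edc=20.0)
        ref = build_reference(f, split, "combined", "A")
        valid = build_validation(f, split, ref, "A")
        assert not set(valid["bull_id"]) & set(ref.bull_ids)

    def test_empty_validation_raises_with_filters(self):
        f = self.base_frame()
        ref = build_reference(f, SPLIT, "national", "A")
        bad_split = SplitSpec(cutoff_year={"A": 2005, "B": 2000})
        ref2 = build_reference(f, bad_split, "national", "A")
        with pytest.raises(ValueError, match="sire scope"):
            build_validation(f, bad_split, ref2, "A")


class TestParentAverage:
    def test_halving_and_quartering(self):
        ref = frame(birth_year=[1995], drp=[2.0 / 0.96], rel=[0.96],
                    edc=[500.0])
        valid = frame(birth_year=[2002], sire_id=["b0"], drp=[0.0],
                      rel=[0.5], edc=[30.0])
        pi, rel_pi = parent_average_pi(valid, ref)
        assert pi[0] == pytest.approx(1.0)
        assert rel_pi[0] == pytest.approx(0.24)

    def test_missing_sire_estimate_gives_nan(self, caplog):
        ref = frame(birth_year=[1995], drp=[1.0], rel=[0.9], edc=[100.0])
        valid = frame(birth_year=[2002], sire_id=["nope"], drp=[0.0],
                      rel=[0.5], edc=[30.0])
        with caplog.at_level("WARNING", logger="gpcombine"):
            pi, rel_pi = parent_average_pi(valid, ref)
        assert np.isnan(pi[0]) and np.isnan(rel_pi[0])

    def test_pi_reliability_calibrates_on_simulation(self, small_study):
        """Empirical squared correlation of PI with u matches 0.25·rel_sire."""
        study = small_study
        trait = study.config.traits[0]
        f = make_eval_frame(study, "yield", "A")
        cut = choose_cutoff_years(study.bulls, 0.3)
        split = SplitSpec(cutoff_year=cut, min_edc=0.0)
        ref = build_reference(f, split, "national", "A")
        ref_frame = f[f["bull_id"].isin(set(ref.bull_ids))]
        valid = build_validation(f, split, ref, "A")
        pi, rel_pi = parent_average_pi(valid, ref_frame)
        ok = ~np.isnan(pi)
        rows = study.genotypes.rows(valid.loc[ok, "bull_id"])
        u = study.u["yield"][rows, trait.pop_index("A")]
        realized = np.corrcoef(pi[ok], u)[0, 1] ** 2
        # small-n check: direction and rough magnitude
        assert realized == pytest.approx(rel_pi[ok].mean(), abs=0.15)


class TestWeightedStatistics:
    def test_perfect_prediction_gives_rel_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rel = weighted_corr_reliability(x, x, np.ones(4), np.ones(4))
        assert rel == pytest.approx(1.0)

    def test_formula_against_unweighted_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(50)
        d = 0.6 * g + rng.standard_normal(50)
        rel_drp = np.full(50, 0.8)
        mine = weighted_corr_reliability(g, d, np.ones(50), rel_drp)
        oracle = np.corrcoef(g, d)[0, 1] ** 2 / 0.8
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.standard_normal(20)
        d = g + rng.standard_normal(20)
        w = rng.uniform(0.5, 2.0, 20)
        rel = rng.uniform(0.5, 0.9, 20)
        a = weighted_corr_reliability(g, d, w, rel)
        p = rng.permutation(20)
        b = weighted_corr_reliability(g[p], d[p], w[p], rel[p])
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            weighted_corr_reliability(
                np.ones(5), np.arange(5.0), np.ones(5), np.full(5, 0.8)
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equal_weights_match_unweighted(self, seed):
        """With equal weights, weighted statistics equal their unweighted
        counterparts to near machine precision."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = rng.standard_normal(n)
        d = g + rng.standard_normal(n)
        rel = rng.uniform(0.3, 0.95, n)
        mine = weighted_corr_reliability(g, d, np.full(n, 3.7), rel)
        oracle = np.corrcoef(g, d)[0, 1] ** 2 / rel.mean()
        assert mine == pytest.approx(oracle, abs=1e-12)
        b0, _, b1 = weighted_bias_regression(d, g, np.full(n, 3.7), 1.0)
        ob1, ob0 = np.polyfit(g, d, 1)
        assert b0 == pytest.approx(ob0, abs=1e-9)
        assert b1 == pytest.approx(ob1, abs=1e-9)


class TestBiasRegression:
    def test_exact_linear_data(self):
        g = np.array([0.0, 1.0, 2.0, 3.0])
        b0, b0s, b1 = weighted_bias_regression(g, g, np.ones(4), 2.0)
        assert (b0, b1) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))
        b0, b0s, b1 = weighted_bias_regression(2 * g + 1, g, np.ones(4), 2.0)
        assert b0 == pytest.approx(1.0)
        assert b0s == pytest.approx(0.5)  # intercept in genetic-SD units
        assert b1 == pytest.approx(2.0)

    def test_hand_solved_weighted_triple(self):
        """Weights (1,1,4): normal equations solved by hand as the oracle."""
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 2.0, 3.0])
        w = np.array([1.0, 1.0, 4.0])
        # WLS normal equations: [Σw Σwx; Σwx Σwx²] [b0 b1]' = [Σwy Σwxy]
        A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        rhs = np.array([(w * y).sum(), (w * x * y).sum()])
        exp_b0, exp_b1 = np.linalg.solve(A, rhs)
        b0, _, b1 = weighted_bias_regression(y, x, w, 1.0)
        assert b0 == pytest.approx(exp_b0, abs=1e-10)
        assert b1 == pytest.approx(exp_b1, abs=1e-10)

    def test_degenerate_regressor(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighted_bias_regression(np.arange(4.0), np.ones(4), np.ones(4), 1.0)


def test_genomic_gain_is_plain_difference():
    assert genomic_gain(0.42, 0.13) == pytest.approx(0.29)
    assert genomic_gain(0.3, 0.3) == 0.0
    assert genomic_gain(0.1, 0.3) == pytest.approx(-0.2)  # not clipped


def test_pi_selected_validation_underestimates_rel_pi():
    """When validation candidates are pre-selected on parent average,
    the estimated REL_PI drops relative to random candidates from the
    same population (directional selection shrinks the correlation)."""
    from gpcombine import PopulationConfig, SimConfig, TraitSpec, simulate_study
    from gpcombine.gp_models import compute_weights

    import numpy as _np

    def rel_pi_for(select, seed):
        pops = [PopulationConfig("A", 400, 100, (1990, 2005), edc_mean=150.0)]
        trait = TraitSpec("t", 0.3, 1.0, _np.eye(1), ["A"])
        cfg = SimConfig(populations=pops, traits=[trait], m_markers=200,
                        n_qtl=50, n_chromosomes=5, seed=seed,
                        select_on_pi=select)
        study = simulate_study(cfg)
        f = make_eval_frame(study, "t", "A")
        cand = study.validation_candidate
        ref_frame = f[~cand]
        valid = f[cand]
        pi, _ = parent_average_pi(valid, ref_frame)
        ok = ~_np.isnan(pi)
        w = compute_weights(valid.loc[ok, "rel"].to_numpy())
        return weighted_corr_reliability(
            pi[ok], valid.loc[ok, "drp"].to_numpy(), w,
            valid.loc[ok, "rel"].to_numpy(),
        )

    random_rel, selected_rel = [], []
    for seed in range(10):
        random_rel.append(rel_pi_for(False, seed))
        selected_rel.append(rel_pi_for(True, seed))
    assert np.mean(selected_rel) < np.mean(random_rel), (
        np.mean(selected_rel), np.mean(random_rel))
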