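import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlvhkit import (
    MatchedSet,
    ValidationError,
    compute_dlvh,
    conditional_loglik,
    export_pvalue_map,
    fit_clr,
    import_pvalue_map,
    scan_pvalue_map,
    simulate_cohort,
)
from dlvhkit.matched_stats import (
    STATUS_MONOTONE,
    STATUS_NON_INFORMATIVE,
    STATUS_OK,
    matched_sets_at,
)
from dlvhkit.synthetic_cohort import CohortSpec


def grid_search_beta(sets, lo=-16.0, hi=16.0, n=801, refinements=4):
    """Dense grid-search maximiser of the conditional log-likelihood,
    refined around the argmax until the spacing is below 1e-5 (valid
    because the log-likelihood is concave)."""
    for _ in range(refinements):
        grid = np.linspace(lo, hi, n)
        lls = [conditional_loglik(b, sets) for b in grid]
        k = int(np.argmax(lls))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, n - 1)]
    return grid[k]


class TestConditionalLoglik:
    def test_beta_zero_closed_form(self):
        sets = [MatchedSet("a", 1.0, (0.0,)),
                MatchedSet("b", 3.0, (1.0, 2.0)),
                MatchedSet("c", 0.0, (5.0, 1.0, 2.0, 7.0))]
        expected = -(np.log(2) + np.log(3) + np.log(5))
        assert conditional_loglik(0.0, sets) == pytest.approx(expected, abs=1e-12)

    def test_hand_evaluated_instance(self):
        sets = [MatchedSet("a", 2.0, (1.0,))]
        expected = 2.0 - np.log(np.exp(2.0) + np.exp(1.0))
        assert conditional_loglik(1.0, sets) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(-3, 3), st.floats(-50, 50),
           st.lists(st.floats(-5, 5), min_size=2, max_size=5))
    def test_within_set_location_invariance(self, beta, shift, values):
        base = [MatchedSet("s", values[0], tuple(values[1:]))]
        shifted = [MatchedSet("s", values[0] + shift,
                              tuple(v + shift for v in values[1:]))]
        assert conditional_loglik(beta, base) == pytest.approx(
            conditional_loglik(beta, shifted), abs=1e-9)

    def test_single_set_enumeration_oracle(self):
        """For one set the conditional likelihood equals the probability
        that the case carries the largest linear predictor draw, computed
        by explicit enumeration over hypothetical case assignments."""
        values = (2.0, 0.5, 1.0, 3.0)  # case first
        s = MatchedSet("s", values[0], values[1:])
        for beta in (-1.0, 0.0, 0.7, 2.0):
            weights = np.exp(beta * np.array(values))
            prob = weights[0] / sum(
                weights[j] for j in range(len(values)))
            assert np.exp(conditional_loglik(beta, [s])) == pytest.approx(prob)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.lists(st.floats(-3, 3), min_size=2, max_size=4),
                    min_size=1, max_size=4),
           st.floats(-2, 2))
    def test_concavity(self, raw_sets, beta):
        sets = [MatchedSet(f"s{i}", v[0], tuple(v[1:]))
                for i, v in enumerate(raw_sets)]
        h = 0.05
        second_diff = (conditional_loglik(beta + h, sets)
                       - 2 * conditional_loglik(beta, sets)
                       + conditional_loglik(beta - h, sets))
        assert second_diff <= 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            conditional_loglik(0.0, [])


class TestFitCLR:
    def test_mirror_symmetry_gives_null(self):
        sets = [MatchedSet("a", 1.0, (0.0,)), MatchedSet("b", 0.0, (1.0,))]
        fit = fit_clr(sets)
        assert fit.status == STATUS_OK
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-10)
        assert fit.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sets = rng.integers(1, 4)
        sets = []
        for i in range(n_sets):
            vals = rng.integers(0, 3, size=rng.integers(2, 4)).astype(float)
            sets.append(MatchedSet(f"s{i}", vals[0], tuple(vals[1:])))
        fit = fit_clr(sets)
        if fit.status != STATUS_OK:
            return
        assert fit.beta_hat == pytest.approx(
            grid_search_beta(sets, lo=-16, hi=16), abs=1e-4)

    def test_separation_flagged(self):
        up = [MatchedSet("a", 3.0, (1.0, 2.0)), MatchedSet("b", 9.0, (7.0,))]
        assert fit_clr(up).status == STATUS_MONOTONE
        down = [MatchedSet("a", 0.0, (1.0, 2.0)), MatchedSet("b", 5.0, (7.0,))]
        assert fit_clr(down).status == STATUS_MONOTONE

    def test_constant_sets_dropped(self):
        sets = [MatchedSet("a", 1.0, (1.0, 1.0)),
                MatchedSet("b", 1.0, (0.0, 2.0))]
        fit = fit_clr(sets)
        assert fit.n_dropped_sets == 1
        assert fit.n_informative_sets == 1
        all_const = [MatchedSet("a", 2.0, (2.0,))]
        assert fit_clr(all_const).status == STATUS_NON_INFORMATIVE

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        sets = []
        for i in range(6):
            vals = rng.uniform(0, 100, size=3)
            sets.append(MatchedSet(f"s{i}", vals[0], tuple(vals[1:])))
        fit1 = fit_clr(sets)
        k = 7.5
        scaled = [MatchedSet(s.set_id, k * s.case_value,
                             tuple(k * v for v in s.control_values))
                  for s in sets]
        fit2 = fit_clr(scaled)
        assert fit2.beta_hat == pytest.approx(fit1.beta_hat / k, rel=1e-6)
        assert fit2.p_value == pytest.approx(fit1.p_value, rel=1e-6)

    def test_agrees_with_statsmodels_clogit(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        sets = []
        y, x, g = [], [], []
        for i in range(12):
            vals = rng.uniform(0, 50, size=3)
            sets.append(MatchedSet(f"s{i}", vals[0], tuple(vals[1:])))
            y += [1, 0, 0]
            x += vals.tolist()
            g += [i] * 3
        fit = fit_clr(sets)
        res = sm.ConditionalLogit(np.array(y), np.array(x)[:, None],
                                  groups=np.array(g)).fit(disp=0)
        assert fit.beta_hat == pytest.approx(res.params[0], rel=1e-4)
        assert fit.se == pytest.approx(res.bse[0], rel=1e-4)
        assert fit.p_value == pytest.approx(res.pvalues[0], rel=1e-3)

    def test_lr_p_method(self):
        rng = np.random.default_rng(4)
        sets = [MatchedSet(f"s{i}", rng.uniform(0, 10),
                           tuple(rng.uniform(0, 10, 2)))
                for i in range(8)]
        wald = fit_clr(sets, p_method="wald")
        lr = fit_clr(sets, p_method="lr")
        assert wald.beta_hat == pytest.approx(lr.beta_hat)
        assert 0 < lr.p_value <= 1
        with pytest.raises(ValidationError):
            fit_clr(sets, p_method="bayes")


class TestScan:
    def _small_scan(self, beta_true, seed=21, n_sets=12):
        spec = CohortSpec(seed=seed, n_sets=n_sets, beta_true=beta_true)
        patients, table = simulate_cohort(spec)
        dose_grid = np.arange(0.0, 61.0, 10.0)
        let_grid = np.arange(0.0, 8.1, 1.0)
        surfaces = {p.patient_id: compute_dlvh(p.dose, p.letd, p.mask,
                                               dose_grid, let_grid)
                    for p in patients}
        return scan_pvalue_map(surfaces, table), table, surfaces

    def test_origin_and_far_nodes_masked(self):
        pmap, _, _ = self._small_scan(0.0)
        assert pmap.status[0, 0] == STATUS_NON_INFORMATIVE  # everyone at 100%
        assert np.isnan(pmap.p[0, 0])
        assert pmap.beta_sign[0, 0] == 0
        assert pmap.status[-1, -1] == STATUS_NON_INFORMATIVE  # beyond max dose
        # mask bookkeeping: p/sign populated exactly on ok nodes
        ok = pmap.ok
        assert not np.isnan(pmap.p[ok]).any()
        assert np.isnan(pmap.p[~ok]).all()
        assert (pmap.beta_sign[~ok] == 0).all()

    def test_positive_effect_detected_at_generating_index(self):
        pmap, _, _ = self._small_scan(0.6, seed=5, n_sets=20)
        a = np.searchsorted(pmap.dose_grid, 30.0)
        b = np.searchsorted(pmap.let_grid, 4.0)
        assert pmap.status[a, b] == STATUS_OK
        assert pmap.beta_sign[a, b] == 1

    def test_grid_mismatch_rejected(self):
        pmap, table, surfaces = self._small_scan(0.0)
        pid = next(iter(surfaces))
        patients, _ = simulate_cohort(CohortSpec(seed=99, n_sets=12))
        other = compute_dlvh(patients[0].dose, patients[0].letd,
                             patients[0].mask)
        surfaces[pid] = other
        with pytest.raises(ValidationError, match="grid"):
            scan_pvalue_map(surfaces, table)

    def test_pvalue_map_round_trip(self, tmp_path):
        pmap, _, _ = self._small_scan(0.3, seed=8)
        path = tmp_path / "pmap.csv"
        export_pvalue_map(pmap, path)
        back = import_pvalue_map(path)
        np.testing.assert_array_equal(back.dose_grid, pmap.dose_grid)
        np.testing.assert_allclose(back.p, pmap.p)
        np.testing.assert_array_equal(back.beta_sign, pmap.beta_sign)
        np.testing.assert_array_equal(back.status, pmap.status)

    def test_bh_adjustment_monotone(self):
        pmap, table, surfaces = self._small_scan(0.5, seed=13, n_sets=15)
        adjusted = scan_pvalue_map(surfaces, table, adjust="bh")
        ok = pmap.ok
        assert (adjusted.p[ok] >= pmap.p[ok] - 1e-12).all()
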