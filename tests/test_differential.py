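"""Differential-uptake statistics against independent reference oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from hdxkit.differential import (
    classify_regions,
    compare_states,
    consecutive_rule,
    delta_uptake,
    global_threshold,
    state_t_test,
    variance_gate,
)


class TestDeltaUptake:
    def test_identical_sets_give_zero(self):
        d, sd = delta_uptake([3.0, 3.1, 3.2], [3.0, 3.1, 3.2])
        assert d == 0.0 and sd > 0

    def test_arithmetic_example(self):
        d, sd = delta_uptake([3.0, 3.2, 3.1], [2.0, 2.2, 2.1])
        assert d == pytest.approx(1.0)
        assert sd == pytest.approx(np.sqrt(2 * np.var([3.0, 3.2, 3.1], ddof=1)))

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            delta_uptake([3.0], [2.0, 2.1])

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(3, 0.1, 4), rng.normal(2.5, 0.2, 3)
        d1, sd1 = delta_uptake(a, b)
        d2, sd2 = delta_uptake(b, a)
        assert d1 == -d2 and sd1 == sd2
        assert state_t_test(a, b).p_value == pytest.approx(
            state_t_test(b, a).p_value, abs=1e-15
        )


class TestVarianceGate:
    def test_equal_variances_pass(self):
        assert variance_gate([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])

    def test_grossly_unequal_variances_fail(self):
        rng = np.random.default_rng(1)
        wide = rng.normal(0, 10, 6)
        narrow = rng.normal(0, 1, 3)
        assert not variance_gate(wide, narrow)

    def test_zero_variance_both_sides_is_equal_by_convention(self):
        assert variance_gate([1.0, 1.0], [2.0, 2.0])


class TestStateTTest:
    def test_identical_samples_give_p_one(self):
        out = state_t_test([3.0, 3.1, 3.2], [3.0, 3.1, 3.2])
        assert out.p_value == pytest.approx(1.0)

    def test_clear_shift_is_significant(self):
        out = state_t_test([3.0, 3.1, 3.2], [2.0, 2.1, 2.2])
        assert out.p_value < 0.01

    def test_pvalues_match_reference_implementations(self):
        """Both t variants (statsmodels) and the F gate (numerical
        integration of the F density) agree to 1e-10 on random samples."""
        sm = pytest.importorskip("statsmodels.stats.weightstats")
        rng = np.random.default_rng(17)
        for _ in range(50):
            n1, n2 = rng.integers(2, 7, size=2)
            a = rng.normal(0, rng.uniform(0.5, 2), n1)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n2)
            for equal_var, usevar in [(True, "pooled"), (False, "unequal")]:
                mine = state_t_test(a, b, equal_var=equal_var).p_value
                _, ref, _ = sm.ttest_ind(a, b, usevar=usevar)
                assert mine == pytest.approx(ref, abs=1e-10)
            # F-test oracle: two-sided tail mass by quadrature
            v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
            f = v1 / v2
            d1, d2 = n1 - 1, n2 - 1
            upper = integrate.quad(
                lambda x: stats.f.pdf(x, d1, d2), f, np.inf, epsabs=1e-13
            )[0]
            lower = integrate.quad(
                lambda x: stats.f.pdf(x, d1, d2), 0, f, epsabs=1e-13
            )[0]
            p_ref = min(2 * min(upper, lower), 1.0)
            p_mine = min(
                2 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2)), 1.0
            )
            assert p_mine == pytest.approx(p_ref, abs=1e-10)


class TestConsecutiveRule:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.5, 0.005, 0.005, 0.5, 0.5], True),
            ([0.005, 0.5, 0.005, 0.5, 0.005], False),
            ([0.011] * 5, False),
        ],
    )
    def test_examples(self, pvals, expected):
        assert consecutive_rule(pvals) is expected


class TestGlobalThreshold:
    def _comparison(self, sds):
        from hdxkit.differential import StateComparison

        table = pd.DataFrame(
            {
                "peptide_id": [f"p{i}" for i in range(len(sds))],
                "time_min": 1.0,
                "delta_hdx": 0.0,
                "propagated_sd": sds,
                "p_value": 1.0,
                "variant": "homoscedastic",
            }
        )
        return StateComparison("apo", "Na+", table)

    def test_critical_value_n3_95(self):
        spec = global_threshold(self._comparison([0.1, 0.1]), n=3)
        assert spec.t_crit == pytest.approx(4.303, abs=5e-4)

    def test_zero_sigma_gives_zero_threshold(self):
        spec = global_threshold(self._comparison([0.0, 0.0]))
        assert spec.threshold == 0.0

    def test_published_scale_example(self):
        """A pooled SD of 0.1047 Da at n=3 puts the threshold at 0.26 Da."""
        spec = global_threshold(self._comparison([0.1047] * 10), n=3)
        assert spec.threshold == pytest.approx(0.26, abs=5e-3)

    def test_scaling_in_sigma_and_n(self):
        base = global_threshold(self._comparison([0.1] * 4), n=3).threshold
        doubled = global_threshold(self._comparison([0.2] * 4), n=3).threshold
        assert doubled == pytest.approx(2 * base)
        n12 = global_threshold(self._comparison([0.1] * 4), n=12).threshold
        # threshold ~ t(n-1)/sqrt(n): check the exact closed form
        expected = stats.t.ppf(0.975, 11) * 0.1 / np.sqrt(12)
        assert n12 == pytest.approx(expected)

    def test_empty_comparison_errors(self):
        with pytest.raises(ValueError):
            global_threshold(self._comparison([]))


def _uptake_frame(rng, n_pep=10, shift=None, sd=0.03, times=(0.25, 1, 10, 60, 480)):
    rows = []
    for p in range(n_pep):
        mu = rng.uniform(1, 6, len(times))
        for state in ("apo", "Na+"):
            for ti, t in enumerate(times):
                m = mu[ti]
                if state == "Na+" and shift is not None and p == 0:
                    m -= shift  # protection in the perturbed state
                for rep in range(3):
                    rows.append(
                        {
                            "peptide_id": f"p{p:02d}",
                            "state": state,
                            "exposure_min": float(t),
                            "replicate": rep + 1,
                            "uptake_da": m + rng.normal(0, sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestClassification:
    def test_protected_peptide_called_stabilized(self):
        rng = np.random.default_rng(8)
        up = _uptake_frame(rng, shift=1.0)
        comp = compare_states(up, "apo", "Na+")
        spec = global_threshold(comp)
        classes = classify_regions(comp, spec)
        assert (
            classes.loc[classes["peptide_id"] == "p00", "classification"].item()
            == "stabilized"
        )

    def test_null_peptides_unchanged(self):
        rng = np.random.default_rng(9)
        up = _uptake_frame(rng, shift=None)
        comp = compare_states(up, "apo", "Na+")
        classes = classify_regions(comp, global_threshold(comp))
        assert (classes["classification"] == "unchanged").all()

    def test_mixed_sign_nonadjacent_significance_stays_unchanged(self):
        from hdxkit.differential import StateComparison

        table = pd.DataFrame(
            {
                "peptide_id": "p0",
                "time_min": [0.25, 1.0, 10.0, 60.0, 480.0],
                "delta_hdx": [0.9, 0.0, -0.9, 0.0, 0.9],
                "propagated_sd": 0.05,
                "p_value": [0.001, 0.5, 0.001, 0.5, 0.001],
                "variant": "homoscedastic",
            }
        )
        comp = StateComparison("apo", "Na+", table)
        classes = classify_regions(comp, 0.3)
        assert classes["classification"].item() == "unchanged"
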