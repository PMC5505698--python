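import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enuscreen.denovo import (
    DenovoCall,
    TrioDenovoModel,
    TrioPriors,
    call_denovo,
    estimate_frequency,
    genotype_likelihoods,
    trio_posteriors,
)
from enuscreen.simulate import ReadCountSet

from _oracles import trio_posterior_oracle


def _counts(sites, table):
    """Build a ReadCountSet from {ind: [(ref, alt), ...]} over n sites."""
    n = sites
    rcs = ReadCountSet(["chr1"], [0] * n, list(range(1, n + 1)), ["A"] * n, ["G"] * n)
    for ind, pairs in table.items():
        rcs.add_individual(ind, [p[0] for p in pairs], [p[1] for p in pairs])
    return rcs


class TestGenotypeLikelihoods:
    def test_homref_closed_form(self):
        L = genotype_likelihoods(10, 0, 0.01)
        assert L[0] == pytest.approx(0.99**10, rel=1e-12)
        assert L[1] == pytest.approx(2**-10, rel=1e-12)
        assert L[2] == pytest.approx(0.01**10, rel=1e-9)

    def test_balanced_favors_het(self):
        L = genotype_likelihoods(5, 5, 0.01)
        assert np.argmax(L) == 1

    def test_zero_depth_flat(self):
        assert genotype_likelihoods(0, 0) == (1.0, 1.0, 1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            genotype_likelihoods(-1, 0)
        with pytest.raises(ValueError):
            genotype_likelihoods(1, 1, epsilon=0.6)


class TestTrioPosteriors:
    def test_clean_denovo(self):
        pr = TrioPriors()
        f = genotype_likelihoods(30, 0)
        m = genotype_likelihoods(30, 0)
        c = genotype_likelihoods(15, 15)
        pp_dnm, pp_null = trio_posteriors(f, m, c, pr)
        assert pp_dnm > 0.99

    def test_homref_child_no_signal(self):
        pr = TrioPriors()
        f = m = c = genotype_likelihoods(30, 0)
        pp_dnm, _ = trio_posteriors(f, m, c, pr)
        assert pp_dnm < 1e-6

    def test_inherited_het_is_null(self):
        pr = TrioPriors()
        f = genotype_likelihoods(15, 15)
        m = genotype_likelihoods(30, 0)
        c = genotype_likelihoods(15, 15)
        pp_dnm, pp_null = trio_posteriors(f, m, c, pr)
        assert pp_null > 0.99
        assert pp_dnm < 0.001

    def test_sum_bounded(self):
        pr = TrioPriors()
        f = genotype_likelihoods(8, 2)
        m = genotype_likelihoods(3, 3)
        c = genotype_likelihoods(5, 5)
        pp_dnm, pp_null = trio_posteriors(f, m, c, pr)
        assert pp_dnm + pp_null <= 1 + 1e-9

    def test_matches_enumeration_oracle(self):
        """Machine-precision agreement with direct 27-configuration
        enumeration on randomized likelihood triples."""
        rng = np.random.default_rng(42)
        pr = TrioPriors(mu=3e-6, pop_alt_freq=2e-4, epsilon=0.02)
        for _ in range(500):
            triples = [tuple(rng.random(3)) for _ in range(3)]
            got = trio_posteriors(*triples, pr)
            want = trio_posterior_oracle(*triples, mu=pr.mu, q=pr.pop_alt_freq)
            assert got[0] == pytest.approx(want[0], rel=1e-12, abs=1e-15)
            assert got[1] == pytest.approx(want[1], rel=1e-12, abs=1e-15)


@given(st.lists(st.floats(1e-12, 1.0), min_size=9, max_size=9))
@settings(max_examples=150, derandomize=True, deadline=None)
def test_posterior_properties_hold_for_arbitrary_likelihoods(values):
    """Posteriors are probabilities, sum to at most one, and agree with the
    enumeration oracle for any positive likelihood triples."""
    pr = TrioPriors()
    f, m, c = tuple(values[:3]), tuple(values[3:6]), tuple(values[6:])
    pp_dnm, pp_null = trio_posteriors(f, m, c, pr)
    assert 0.0 <= pp_dnm <= 1.0
    assert 0.0 <= pp_null <= 1.0
    assert pp_dnm + pp_null <= 1 + 1e-9
    want = trio_posterior_oracle(f, m, c, mu=pr.mu, q=pr.pop_alt_freq)
    assert pp_dnm == pytest.approx(want[0], rel=1e-10, abs=1e-13)
    assert pp_null == pytest.approx(want[1], rel=1e-10, abs=1e-13)


class TestCallDenovo:
    def test_planted_denovo_called(self):
        rcs = _counts(3, {
            "F": [(20, 0), (20, 0), (20, 0)],
            "M": [(20, 0), (20, 0), (20, 0)],
            "C": [(20, 0), (9, 11), (20, 0)],
        })
        calls, callable_sites = call_denovo(rcs, [("C", "F", "M")])
        assert [c.position for c in calls] == [2]
        assert callable_sites[0] == 3

    def test_inherited_het_not_called(self):
        rcs = _counts(1, {
            "F": [(10, 10)], "M": [(20, 0)], "C": [(11, 9)],
        })
        calls, _ = call_denovo(rcs, [("C", "F", "M")])
        assert calls == []

    def test_low_depth_not_callable(self):
        rcs = _counts(1, {
            "F": [(8, 0)], "M": [(20, 0)], "C": [(10, 10)],
        })
        calls, callable_sites = call_denovo(rcs, [("C", "F", "M")], min_depth=10)
        assert calls == []
        assert callable_sites[0] == 0
        # under the permissive "any member" reading the site is callable
        calls_any, cs_any = call_denovo(
            rcs, [("C", "F", "M")], min_depth=10, depth_rule="any"
        )
        assert cs_any[0] == 1
        assert len(calls_any) == 1

    def test_cross_trio_exclusion_removes_both(self):
        table = {
            "F": [(20, 0)], "M": [(20, 0)],
            "C1": [(10, 10)], "C2": [(9, 11)],
            "F2": [(20, 0)], "M2": [(20, 0)],
        }
        rcs = _counts(1, table)
        trios = [("C1", "F", "M"), ("C2", "F2", "M2")]
        calls, _ = call_denovo(rcs, trios)
        assert calls == []
        calls_keep, _ = call_denovo(rcs, trios, cross_trio_exclusion=False)
        assert len(calls_keep) == 2

    def test_monotone_in_pp_dnm_threshold(self, trio_family):
        from enuscreen.simulate import emulate_rad

        rad = emulate_rad(
            trio_family,
            individuals=["G0-BOAR", "G0-SOW", "G1-1", "G1-2"],
            rad_fraction=0.05, seed=8,
        )
        trios = [("G1-1", "G0-BOAR", "G0-SOW"), ("G1-2", "G0-BOAR", "G0-SOW")]
        previous = None
        for thr in (0.5, 0.9, 0.99):
            calls, _ = call_denovo(rad, trios, pp_dnm_min=thr)
            if previous is not None:
                assert len(calls) <= previous
            previous = len(calls)


class TestEstimateFrequency:
    def test_zero_calls_exact_poisson_upper(self):
        est = estimate_frequency(0, 10**6)
        assert est.rate == 0.0
        assert est.ci95[0] == 0.0
        assert est.ci95[1] == pytest.approx(3.689e-6, rel=1e-3)

    def test_printed_rate_fixture(self):
        est = estimate_frequency(12, 2_048_000)
        assert est.rate == pytest.approx(5.86e-6, rel=1e-3)

    def test_scale_invariance(self):
        a = estimate_frequency(7, 10**6)
        b = estimate_frequency(14, 2 * 10**6)
        assert a.rate == pytest.approx(b.rate)

    def test_ci_from_chi2_bounds(self):
        n, total = 9, 10**6
        est = estimate_frequency(n, total)
        lo = stats.chi2.ppf(0.025, 2 * n) / 2 / total
        hi = stats.chi2.ppf(0.975, 2 * (n + 1)) / 2 / total
        assert est.ci95 == pytest.approx((lo, hi))

    def test_zero_callable_raises(self):
        with pytest.raises(ValueError):
            estimate_frequency(0, 0)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self):
        rcs = _counts(2, {
            "F": [(20, 0), (20, 0)],
            "M": [(20, 0), (20, 0)],
            "C": [(10, 10), (20, 0)],
        })
        res = TrioDenovoModel(rcs, [("C", "F", "M")]).fit()
        assert res.frequency.n_mutations == 1
        assert "de novo calls:       1" in res.summary()
        frame = res.calls_frame()
        assert list(frame["pos"]) == [1]
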