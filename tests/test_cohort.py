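import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bari.cine_io import ParticipantRecord
from bari.cohort import (classify_growth, compute_bari, growth_rate,
                         run_comparisons)
from bari.fitting import FitRecord, RelaxationFit


def fit_with_tau2(tau2, accepted=True, x=0, cycle=0):
    f = RelaxationFit(a=3.0, b1=0.4, b2=0.2, c=0.0, tau1=tau2 / 10,
                      tau2=tau2, rmse=0.001, converged=True,
                      accepted=accepted)
    return FitRecord(x=x, cycle=cycle, fit=f)


class TestComputeBari:
    def test_single_fit_is_identity(self):
        res = compute_bari([fit_with_tau2(1.2)])
        assert res.bari == pytest.approx(1.2)
        assert res.n_accepted == 1

    def test_mean_of_slow_constants(self):
        fits = [fit_with_tau2(v, x=i) for i, v in enumerate([0.8, 1.0, 1.2])]
        assert compute_bari(fits).bari == pytest.approx(1.0)

    def test_rejected_fits_do_not_contribute(self):
        fits = [fit_with_tau2(1.0), fit_with_tau2(99.0, accepted=False)]
        assert compute_bari(fits).bari == pytest.approx(1.0)

    def test_no_accepted_fits_gives_missing_bari(self):
        res = compute_bari([fit_with_tau2(1.0, accepted=False)])
        assert res.bari is None
        assert res.reason == "no accepted relaxation fits"

    def test_fast_constant_aggregation_is_opt_in(self):
        res = compute_bari([fit_with_tau2(1.0)], use_fast_constant=True)
        assert res.bari == pytest.approx(0.1)

    @given(st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=2,
                    max_size=8),
           st.floats(min_value=0.5, max_value=3.0))
    def test_permutation_invariant_and_scale_equivariant(self, taus, k):
        fits = [fit_with_tau2(v, x=i) for i, v in enumerate(taus)]
        rng = np.random.default_rng(0)
        perm = [fits[i] for i in rng.permutation(len(fits))]
        assert compute_bari(perm).bari == pytest.approx(
            compute_bari(fits).bari)
        scaled = [fit_with_tau2(k * v, x=i) for i, v in enumerate(taus)]
        assert compute_bari(scaled).bari == pytest.approx(
            k * compute_bari(fits).bari)


class TestClassifyGrowth:
    def test_threshold_separates_sides(self):
        assert classify_growth(1.6, threshold=1.5, fast_side="above") == "fast"
        assert classify_growth(1.4, threshold=1.5, fast_side="above") == "slow"
        assert classify_growth(1.6, threshold=1.5, fast_side="below") == "slow"

    def test_tie_goes_to_the_above_side(self):
        assert classify_growth(1.5, threshold=1.5, fast_side="above") == "fast"
        assert classify_growth(1.5, threshold=1.5, fast_side="below") == "slow"

    def test_zero_threshold_puts_everything_above(self):
        for b in (0.1, 1.0, 10.0):
            assert classify_growth(b, threshold=0.0,
                                   fast_side="above") == "fast"

    def test_direction_is_mandatory(self):
        with pytest.raises(ValueError):
            classify_growth(1.0, threshold=1.5)

    def test_missing_bari_raises(self):
        with pytest.raises(ValueError):
            classify_growth(None, fast_side="above")


class TestGrowthRate:
    def test_ten_percent_per_year(self):
        r = ParticipantRecord(id="p", group="moderate", apd_baseline=40.0,
                              apd_followup=44.0, days_elapsed=365.0)
        assert growth_rate(r) == pytest.approx(10.0)

    def test_no_change_is_zero(self):
        r = ParticipantRecord(id="p", group="moderate", apd_baseline=40.0,
                              apd_followup=40.0, days_elapsed=200.0)
        assert growth_rate(r) == 0.0

    def test_half_year_follow_up(self):
        r = ParticipantRecord(id="p", group="moderate", apd_baseline=50.0,
                              apd_followup=52.0, days_elapsed=182.5)
        assert growth_rate(r) == pytest.approx(8.0)

    def test_missing_follow_up_gives_missing_rate(self):
        r = ParticipantRecord(id="p", group="small", apd_baseline=35.0)
        assert growth_rate(r) is None

    @given(st.floats(min_value=0.5, max_value=10.0))
    def test_homogeneous_in_diameter_scale(self, k):
        a = ParticipantRecord(id="p", group="moderate", apd_baseline=40.0,
                              apd_followup=43.0, days_elapsed=300.0)
        b = ParticipantRecord(id="p", group="moderate",
                              apd_baseline=40.0 * k, apd_followup=43.0 * k,
                              days_elapsed=300.0)
        assert growth_rate(b) == pytest.approx(growth_rate(a))


def record(pid, group="moderate", apd=45.0, bari=None, follow=None,
           days=None):
    return ParticipantRecord(id=pid, group=group, apd_baseline=apd,
                             apd_followup=follow, days_elapsed=days,
                             bari=bari)


def mann_whitney_permutation_p(x, y):
    """Exact two-sided p by enumerating every relabelling of the pooled data."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a in xs for b in ys)

    u_obs = u_stat(x, y)
    mean_u = len(x) * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestRunComparisons:
    def test_identical_groups_are_null(self):
        vals = [0.8, 0.9, 1.0, 1.1, 1.2]
        recs = [record(f"h{i}", group="HV", apd=None, bari=v)
                for i, v in enumerate(vals)]
        recs += [record(f"a{i}", bari=v) for i, v in enumerate(vals)]
        out = run_comparisons(recs)
        assert out.two_group["t_test"]["p"] == pytest.approx(1.0)
        assert out.two_group["HV"]["median"] == \
            out.two_group["cohort"]["median"]

    def test_spearman_is_one_on_monotone_growth(self):
        recs = []
        for i in range(8):
            apd = 40.0 + i
            follow = apd * (1 + 0.01 * (i + 1))  # strictly increasing rate
            recs.append(record(f"p{i}", apd=apd, bari=0.5 + 0.1 * i,
                               follow=follow, days=365.0))
        out = run_comparisons(recs)
        assert out.growth["spearman"]["rho"] == pytest.approx(1.0)

    def test_mann_whitney_matches_exact_permutation_oracle(self):
        x = np.array([0.61, 0.72, 0.83, 0.94, 1.05, 1.16])
        y = np.array([0.55, 0.66, 0.91, 1.22, 1.33, 1.44])
        recs = [record(f"h{i}", group="HV", apd=None, bari=v)
                for i, v in enumerate(x)]
        recs += [record(f"a{i}", bari=v) for i, v in enumerate(y)]
        out = run_comparisons(recs)
        p_oracle = mann_whitney_permutation_p(x, y)
        assert out.two_group["mann_whitney"]["p"] == pytest.approx(p_oracle,
                                                                   abs=1e-12)

    def test_ols_and_spearman_match_closed_forms_on_hand_data(self):
        growth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        bari = np.array([0.9, 1.3, 1.1, 1.7, 1.5])
        recs = []
        for i, (g, b) in enumerate(zip(growth, bari)):
            apd = 40.0
            follow = apd * (1 + g / 100.0)
            recs.append(record(f"p{i}", apd=apd, bari=b, follow=follow,
                               days=365.0))
        out = run_comparisons(recs)
        # closed forms: slope = cov(x,y)/var(x); Spearman = Pearson on ranks
        slope = (np.cov(growth, bari, ddof=1)[0, 1]
                 / np.var(growth, ddof=1))
        assert out.growth["ols"]["slope"] == pytest.approx(slope, rel=1e-9)
        rx = np.argsort(np.argsort(growth))
        ry = np.argsort(np.argsort(bari))
        rho = np.corrcoef(rx, ry)[0, 1]
        assert out.growth["spearman"]["rho"] == pytest.approx(rho, rel=1e-9)

    def test_size_group_comparison_reports_kruskal_and_pairwise(self):
        rng = np.random.default_rng(1)
        recs = []
        for g, apd in (("small", 35.0), ("moderate", 48.0), ("large", 58.0)):
            for i in range(6):
                recs.append(record(f"{g}{i}", group=g, apd=apd,
                                   bari=float(rng.uniform(0.7, 1.3))))
        out = run_comparisons(recs)
        assert 0.0 <= out.size_groups["kruskal_wallis"]["p"] <= 1.0
        assert len(out.size_groups["pairwise"]) == 3
        for pr in out.size_groups["pairwise"].values():
            assert pr["p_bonferroni"] >= pr["p_raw"]
        for summ in out.size_groups["summaries"].values():
            lo, hi = summ["iqr"]
            assert lo <= summ["median"] <= hi
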