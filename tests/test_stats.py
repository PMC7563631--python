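from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from rrest.stats import (
    StatsError,
    categorical_comparison,
    fisher_exact_2x2,
    mann_whitney,
    report_markdown,
    round_half_up,
    summarize_cohort,
    tukey_hinges,
)


def _mw_exact_oracle(x, y):
    """Independent exact two-sided Mann-Whitney p by rational enumeration."""
    nx = len(x)
    combined = list(x) + list(y)
    # mid-ranks computed by counting, not via scipy
    ranks = []
    for v in combined:
        less = sum(1 for w in combined if w < v)
        equal = sum(1 for w in combined if w == v)
        ranks.append(Fraction(2 * less + equal + 1, 2))
    mn = nx * len(y)
    offset = Fraction(nx * (nx + 1), 2)
    u_obs = sum(ranks[:nx]) - offset
    lo = min(u_obs, mn - u_obs)
    total = extreme = 0
    for idx in combinations(range(len(combined)), nx):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if u <= lo or u >= mn - lo:
            extreme += 1
    return min(1.0, extreme / total)


class TestMannWhitney:
    def test_small_sample_enumeration(self):
        res = mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.U == 0
        assert res.p_two_sided == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact")
        assert res.p_two_sided == pytest.approx(1.0)

    def test_exact_matches_independent_oracle_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            x = rng.integers(0, 5, nx).tolist()  # small range forces ties
            y = rng.integers(0, 5, ny).tolist()
            ours = mann_whitney(x, y, mode="exact").p_two_sided
            assert ours == pytest.approx(_mw_exact_oracle(x, y), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(0, 1, 8).tolist()
            y = rng.normal(0.5, 1, 8).tolist()
            pe = mann_whitney(x, y, mode="exact").p_two_sided
            pa = mann_whitney(x, y, mode="approximate").p_two_sided
            assert abs(pe - pa) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1, 2])

    def test_exact_mode_size_limit(self):
        with pytest.raises(StatsError, match="<= 20"):
            mann_whitney(list(range(11)), list(range(11)), mode="exact")


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_printed_study_cell(self):
        # 1/5 control vs 0/11 intervention teams with the deviation
        assert fisher_exact_2x2([[1, 4], [0, 11]]) == pytest.approx(0.3125)

    def test_two_by_two_enumeration(self):
        assert fisher_exact_2x2([[2, 3], [2, 9]]) == pytest.approx(
            _fisher_oracle(2, 3, 2, 9)
        )
        assert round(fisher_exact_2x2([[2, 3], [2, 9]]), 2) == 0.55

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_exact_2x2([[0, 5], [0, 11]]) == pytest.approx(1.0)

    def test_matches_oracle_over_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 8, 4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                _fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_negative_cell_rejected(self):
        with pytest.raises(StatsError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestSummaries:
    @pytest.mark.parametrize("k,n,pct", [(2, 11, 18), (1, 5, 20), (2, 5, 40), (1, 11, 9)])
    def test_percent_rounding_half_up(self, k, n, pct):
        assert round_half_up(100 * k / n) == pct

    def test_tukey_hinges(self):
        # n=7: halves include the median -> hinges at depth 2.5
        q1, med, q3 = tukey_hinges([1, 2, 3, 4, 5, 6, 7])
        assert (q1, med, q3) == (2.5, 4, 5.5)
        q1, med, q3 = tukey_hinges([1, 2, 3, 4])
        assert (q1, med, q3) == (1.5, 2.5, 3.5)

    def test_categorical_comparison_uses_fisher_for_sparse_cells(self):
        comp = categorical_comparison(1, 5, 0, 11)
        assert comp["test"] == "fisher"
        assert comp["control_pct"] == 20
        assert comp["p_value"] == pytest.approx(0.3125)


def _toy_scores(arms, ratio_faults):
    import pandas as pd

    rows = []
    for i, (arm, fault) in enumerate(zip(arms, ratio_faults)):
        rows.append(
            {
                "team_id": f"T{i}",
                "arm": arm,
                "ratio_incorrect": fault,
                "dose_or_dilution_incorrect": 0,
                "reversible_causes_missed": 0,
                "cdev_total": fault,
                "cpt_total": 13 - fault,
                "time_to_epi_s": 100.0 + i,
            }
        )
    return pd.DataFrame(rows)


class TestSummarizeCohort:
    def test_study_style_cells(self):
        arms = ["control"] * 5 + ["intervention"] * 11
        faults = [1, 0, 0, 0, 0] + [0] * 11
        table = summarize_cohort(_toy_scores(arms, faults))
        row = table[table["variable"] == "ratio_incorrect"].iloc[0]
        assert row["control_summary"] == "1 (20)"
        assert row["intervention_summary"] == "0 (0)"
        assert row["p_value"] == pytest.approx(0.3125)

    def test_identical_arms_give_p_one(self):
        arms = ["control"] * 4 + ["intervention"] * 4
        table = summarize_cohort(_toy_scores(arms, [0] * 8))
        row = table[table["variable"] == "ratio_incorrect"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)

    def test_single_arm_reports_without_p_values(self):
        table = summarize_cohort(_toy_scores(["control"] * 5, [1, 0, 0, 0, 0]))
        assert table["p_value"].isna().all() or table["p_value"].isnull().all()

    def test_markdown_rendering(self):
        arms = ["control"] * 3 + ["intervention"] * 3
        md = report_markdown(summarize_cohort(_toy_scores(arms, [0] * 6)))
        assert md.startswith("# ")
        assert "| Performance |" in md
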