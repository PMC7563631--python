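"""Small-sample group comparisons and study-style report tables.

Continuous outcomes are compared with the Mann-Whitney U test — exact by
full enumeration of rank splits (mid-ranks for ties) for combined n <= 20,
otherwise the tie-corrected normal approximation.  Categorical outcomes use
the Fisher exact test (two-sided by the "as or less probable" rule) when
any expected cell is below 5, else the chi-squared test.  Summaries follow
the conventions of small pilot trials: median (Tukey-hinge quartiles) for
continuous variables, count (percent, rounded half-up) for categorical
ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


def round_half_up(x: float) -> int:
    """Round ties away from zero toward +inf for nonnegative x (18.5 -> 19)."""
    return int(math.floor(x + 0.5))


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge): hinges are medians of the two
    halves, each half including the overall median when n is odd."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise StatsError("no data")

    def med(a: list[float]) -> float:
        m = len(a)
        mid = m // 2
        return a[mid] if m % 2 else (a[mid - 1] + a[mid]) / 2.0

    half = (n + 1) // 2
    return med(xs[:half]), med(xs), med(xs[-half:])


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    mode: str


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates all C(nx+ny, nx) rank splits with mid-ranks for
    ties; the two-sided p sums both tails at least as extreme as the
    observed U.  ``approximate`` is the tie-corrected, continuity-corrected
    normal approximation.  ``auto`` picks exact for combined n <= 20.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise StatsError("both groups must be nonempty")
    nx, ny = len(x), len(y)
    if mode == "auto":
        mode = "exact" if nx + ny <= 20 else "approximate"
    ranks = sps.rankdata(x + y)
    u_obs = float(ranks[:nx].sum()) - nx * (nx + 1) / 2.0

    if mode == "approximate":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return MannWhitneyResult(U=u_obs, p_two_sided=float(res.pvalue), mode=mode)
    if mode != "exact":
        raise StatsError(f"unknown mode {mode!r}")
    if nx + ny > 20:
        raise StatsError("exact mode requires combined n <= 20")

    mn = nx * ny
    lo_tail = min(u_obs, mn - u_obs)
    eps = 1e-9
    n_total = 0
    n_extreme = 0
    offset = nx * (nx + 1) / 2.0
    for idx in combinations(range(nx + ny), nx):
        u = float(ranks[list(idx)].sum()) - offset
        n_total += 1
        if u <= lo_tail + eps or u >= mn - lo_tail - eps:
            n_extreme += 1
    return MannWhitneyResult(
        U=u_obs, p_two_sided=min(1.0, n_extreme / n_total), mode="exact"
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables (margins fixed) as or less probable than the observed one."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise StatsError("cells must be nonnegative integers")
        arr = arr.astype(int)
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def chi_squared_2x2(table) -> float:
    """Pearson chi-squared p (no continuity correction)."""
    arr = np.asarray(table, dtype=float)
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.pvalue)


def expected_counts(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    return sps.contingency.expected_freq(arr)


def categorical_comparison(
    k_control: int, n_control: int, k_intervention: int, n_intervention: int
) -> dict:
    """Compare one binary outcome between arms: counts, percents (rounded
    half-up), and Fisher or chi-squared p per the expected-count rule."""
    table = np.array(
        [
            [k_control, n_control - k_control],
            [k_intervention, n_intervention - k_intervention],
        ],
        dtype=int,
    )
    if np.any(table < 0):
        raise StatsError("counts exceed group size")
    use_fisher = bool((expected_counts(table) < 5).any())
    p = fisher_exact_2x2(table) if use_fisher else chi_squared_2x2(table)
    return {
        "control_count": k_control,
        "control_pct": round_half_up(100.0 * k_control / n_control),
        "intervention_count": k_intervention,
        "intervention_pct": round_half_up(100.0 * k_intervention / n_intervention),
        "p_value": p,
        "test": "fisher" if use_fisher else "chi_squared",
    }


# --- cohort report ----------------------------------------------------------

_CATEGORICAL = (
    ("ratio_incorrect", "Incorrect compressions-to-ventilations ratio"),
    ("dose_or_dilution_incorrect", "Incorrect dose or dilution of epinephrine"),
    ("reversible_causes_missed", "Lack of search and treatment of reversible causes"),
)
_CONTINUOUS = (
    ("cdev_total", "Deviation checklist total score"),
    ("time_to_epi_s", "Time (seconds) to first epinephrine administration"),
    ("cpt_total", "Clinical performance total score"),
)


def summarize_cohort(scores: pd.DataFrame) -> pd.DataFrame:
    """Build a study-style performance table from a scored cohort.

    Binary deviation variables get count (percent) per arm with a Fisher or
    chi-squared p; continuous scores get median (hinge quartiles) per arm
    with an exact Mann-Whitney p.  With a single arm, summaries are
    reported without p-values.
    """
    if "arm" not in scores.columns:
        raise StatsError("scores table must carry an 'arm' column")
    ctrl = scores[scores["arm"] == "control"]
    itv = scores[scores["arm"] == "intervention"]
    two_arms = len(ctrl) > 0 and len(itv) > 0

    rows = []
    for col, label in _CATEGORICAL:
        if col not in scores.columns:
            continue
        if two_arms:
            comp = categorical_comparison(
                int(ctrl[col].sum()), len(ctrl), int(itv[col].sum()), len(itv)
            )
            rows.append(
                {
                    "variable": col,
                    "label": label,
                    "control_summary": f"{comp['control_count']} ({comp['control_pct']})",
                    "intervention_summary": (
                        f"{comp['intervention_count']} ({comp['intervention_pct']})"
                    ),
                    "p_value": comp["p_value"],
                    "test": comp["test"],
                }
            )
        else:
            grp = ctrl if len(ctrl) else itv
            k, n = int(grp[col].sum()), len(grp)
            summary = f"{k} ({round_half_up(100.0 * k / n)})"
            rows.append(
                {
                    "variable": col,
                    "label": label,
                    "control_summary": summary if len(ctrl) else "",
                    "intervention_summary": summary if len(itv) else "",
                    "p_value": None,
                    "test": None,
                }
            )

    def cont_summary(series: pd.Series) -> str:
        vals = series.dropna().to_list()
        if not vals:
            return "-"
        q1, med, q3 = tukey_hinges(vals)
        return f"{med:g} ({q1:g}-{q3:g})"

    for col, label in _CONTINUOUS:
        if col not in scores.columns:
            continue
        row = {
            "variable": col,
            "label": label,
            "control_summary": cont_summary(ctrl[col]) if len(ctrl) else "",
            "intervention_summary": cont_summary(itv[col]) if len(itv) else "",
            "p_value": None,
            "test": None,
        }
        if two_arms:
            xc = ctrl[col].dropna().to_list()
            xi = itv[col].dropna().to_list()
            if xc and xi:
                res = mann_whitney(xc, xi, mode="auto")
                row["p_value"] = res.p_two_sided
                row["test"] = f"mann_whitney_{res.mode}"
        rows.append(row)

    return pd.DataFrame(rows)


def report_markdown(summary: pd.DataFrame, title: str = "Team performance") -> str:
    """Render a cohort summary as a Markdown table."""
    lines = [
        f"# {title}",
        "",
        "| Performance | Control | Intervention | p-value | Test |",
        "|---|---|---|---|---|",
    ]
    for _, row in summary.iterrows():
        p = "" if row["p_value"] is None or pd.isna(row["p_value"]) else f"{row['p_value']:.3f}"
        test = row["test"] or ""
        lines.append(
            f"| {row['label']} | {row['control_summary']} | "
            f"{row['intervention_summary']} | {p} | {test} |"
        )
    return "\n".join(lines) + "\n"
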