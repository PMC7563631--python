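"""Usability and workload questionnaire scoring.

UEQ: 26 bipolar items on a 7-point -3..+3 scale grouped into six scales
(attractiveness, perspicuity, efficiency, dependability, stimulation,
novelty).  A respondent's scale score is the mean of the polarity-adjusted
items; cohort summaries report mean, sample SD, a normal-approximation 95%
CI (mean +/- 1.96 * sd / sqrt(n)) and Cronbach's alpha.  Scores above 0.8
are read as positive, below -0.8 negative, the band between as neutral.

NASA RTLX: the raw (unweighted) task-load index — six subscales on a
0-100 scale with 5-point steps, simply averaged; overall workload is low
(<40), moderate (40-60) or high (>60).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

RTLX_SUBSCALES = ("mental", "physical", "temporal", "performance", "effort", "frustration")
Z_95 = 1.96


class QuestionnaireError(ValueError):
    pass


class UEQScaleMap(BaseModel):
    """Item-to-scale assignment plus per-item polarity (+1/-1)."""

    scales: dict[str, list[int]]
    polarity: list[int]

    @model_validator(mode="after")
    def _partition(self) -> "UEQScaleMap":
        expected = {
            "attractiveness", "perspicuity", "efficiency",
            "dependability", "stimulation", "novelty",
        }
        if set(self.scales) != expected:
            raise ValueError(f"scales must be exactly {sorted(expected)}")
        indices = sorted(i for idxs in self.scales.values() for i in idxs)
        if indices != list(range(1, 27)):
            raise ValueError("scale item indices must partition 1..26")
        if len(self.polarity) != 26 or any(p not in (-1, 1) for p in self.polarity):
            raise ValueError("polarity must list 26 values of +/-1")
        return self


def default_ueq_scale_map() -> UEQScaleMap:
    text = resources.files("rrest.data").joinpath("ueq_scales.yaml").read_text()
    return UEQScaleMap(**yaml.safe_load(text))


class ScaleSummary(BaseModel):
    """Cohort-level summary of one scale score."""

    mean: float
    sd: float
    ci95: tuple[float, float]
    alpha: Optional[float]  # None when undefined (zero variance or <2 items)
    n: int

    @model_validator(mode="after")
    def _ordered(self) -> "ScaleSummary":
        lo, hi = self.ci95
        if not lo <= self.mean <= hi:
            raise ValueError("CI must bracket the mean")
        return self


def normal_ci95(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI; collapses to the mean when sd = 0."""
    half = Z_95 * sd / math.sqrt(n)
    return (mean - half, mean + half)


def cronbach_alpha(items: np.ndarray) -> Optional[float]:
    """Coefficient alpha of an (n_respondents, k_items) score matrix.

    ``None`` (undefined, not NaN) when k < 2 or the total score has zero
    variance.
    """
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 2 or n < 2:
        return None
    var_total = items.sum(axis=1).var(ddof=1)
    if var_total == 0:
        return None
    var_items = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - var_items / var_total))


def _ueq_items_matrix(responses: pd.DataFrame) -> np.ndarray:
    cols = [f"item_{i:02d}" for i in range(1, 27)]
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise QuestionnaireError(f"missing UEQ item columns: {missing}")
    mat = responses[cols].to_numpy(dtype=float)
    bad = np.argwhere((mat < -3) | (mat > 3) | (mat != np.round(mat)))
    if bad.size:
        r, c = bad[0]
        rid = responses.iloc[int(r)].get("respondent_id", f"row {r}")
        raise QuestionnaireError(
            f"respondent {rid}: item {int(c) + 1} value {mat[r, c]} outside -3..3 grid"
        )
    return mat


def score_ueq(
    responses: pd.DataFrame, scale_map: Optional[UEQScaleMap] = None
) -> dict[str, ScaleSummary]:
    """Score a UEQ response table (one row per respondent, columns
    ``item_01``..``item_26``) into per-scale cohort summaries."""
    scale_map = scale_map or default_ueq_scale_map()
    mat = _ueq_items_matrix(responses)
    if mat.shape[0] < 2:
        raise QuestionnaireError("need >=2 respondents for sd and alpha")
    adjusted = mat * np.asarray(scale_map.polarity, dtype=float)
    out: dict[str, ScaleSummary] = {}
    for scale, idxs in scale_map.scales.items():
        cols = [i - 1 for i in idxs]
        scores = adjusted[:, cols].mean(axis=1)
        mean = float(scores.mean())
        sd = float(scores.std(ddof=1))
        out[scale] = ScaleSummary(
            mean=mean,
            sd=sd,
            ci95=normal_ci95(mean, sd, len(scores)),
            alpha=cronbach_alpha(adjusted[:, cols]),
            n=len(scores),
        )
    return out


def ueq_respondent_scores(
    responses: pd.DataFrame, scale_map: Optional[UEQScaleMap] = None
) -> pd.DataFrame:
    """Per-respondent scale scores (mean of polarity-adjusted items)."""
    scale_map = scale_map or default_ueq_scale_map()
    mat = _ueq_items_matrix(responses) * np.asarray(scale_map.polarity, dtype=float)
    out = pd.DataFrame(
        {
            scale: mat[:, [i - 1 for i in idxs]].mean(axis=1)
            for scale, idxs in scale_map.scales.items()
        }
    )
    if "respondent_id" in responses.columns:
        out.insert(0, "respondent_id", responses["respondent_id"].to_numpy())
    return out


def interpret_ueq(score: float) -> str:
    """Standard UEQ interpretation bands: neutral within +/-0.8."""
    if not -3 <= score <= 3:
        raise QuestionnaireError(f"UEQ scale score {score} outside [-3, 3]")
    if score > 0.8:
        return "positive"
    if score < -0.8:
        return "negative"
    return "neutral"


def score_rtlx(subscales) -> dict:
    """Overall raw task-load: the plain average of the six subscale ratings,
    plus its interpretation band (<40 low, 40-60 moderate, >60 high)."""
    if isinstance(subscales, dict):
        missing = set(RTLX_SUBSCALES) - set(subscales)
        if missing:
            raise QuestionnaireError(f"missing RTLX subscales: {sorted(missing)}")
        values = [subscales[k] for k in RTLX_SUBSCALES]
    else:
        values = list(subscales)
    if len(values) != 6:
        raise QuestionnaireError(f"RTLX needs exactly 6 subscales, got {len(values)}")
    for v in values:
        if not 0 <= v <= 100 or v % 5 != 0:
            raise QuestionnaireError(f"RTLX rating {v} is not a multiple of 5 in 0-100")
    overall = float(np.mean(values))
    if overall < 40:
        band = "low"
    elif overall <= 60:
        band = "moderate"
    else:
        band = "high"
    return {"overall": overall, "band": band}


def score_rtlx_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a table of RTLX responses (one row per respondent)."""
    rows = []
    for _, row in responses.iterrows():
        res = score_rtlx({k: row[k] for k in RTLX_SUBSCALES})
        rows.append(
            {
                "respondent_id": row.get("respondent_id", ""),
                "overall": res["overall"],
                "band": res["band"],
            }
        )
    return pd.DataFrame(rows)


def ueq_summary_table(summaries: dict[str, ScaleSummary]) -> pd.DataFrame:
    """Usability summary table: mean (SD), 95% CI, alpha, per scale."""
    rows = []
    for scale, s in summaries.items():
        rows.append(
            {
                "scale": scale,
                "mean": round(s.mean, 3),
                "sd": round(s.sd, 3),
                "ci95_low": round(s.ci95[0], 3),
                "ci95_high": round(s.ci95[1], 3),
                "cronbach_alpha": None if s.alpha is None else round(s.alpha, 2),
                "n": s.n,
                "evaluation": interpret_ueq(s.mean),
            }
        )
    return pd.DataFrame(rows)
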