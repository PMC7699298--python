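"""Random-effects meta-analysis of case-control standardized mean differences.

Effect scale: Hedges' g, the pooled-SD standardized mean difference with the
small-sample bias correction J = 1 - 3 / (4 df - 1), df = n1 + n2 - 2, and
the standard large-sample variance J^2 * ((n1+n2)/(n1 n2) + d^2/(2(n1+n2))).
Between-study variance tau^2 uses the DerSimonian-Laird moment estimator
truncated at zero; the 95% confidence interval uses the normal quantile 1.96.
A log-fold-change effect scale (difference of log-scale means with variance
s1^2/n1 + s2^2/n2) is available for completeness.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudySummary",
    "MetaResult",
    "hedges_g",
    "log_fc_effect",
    "dersimonian_laird",
    "RandomEffectsMeta",
    "MetaResults",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class StudySummary:
    """Summary statistics of one case-control study (log-scale expression)."""

    study_id: str
    n_case: int
    mean_case: float
    sd_case: float
    n_control: int
    mean_control: float
    sd_control: float

    def __post_init__(self):
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(f"study {self.study_id!r}: each arm needs n >= 2")
        if self.sd_case <= 0 or self.sd_control <= 0:
            raise ValueError(f"study {self.study_id!r}: standard deviations must be positive")


def hedges_g(study: StudySummary) -> tuple[float, float]:
    """Bias-corrected standardized mean difference and its variance."""
    n1, n2 = study.n_case, study.n_control
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * study.sd_case**2 + (n2 - 1) * study.sd_control**2) / df
    if sp2 <= 0:
        raise ValueError(f"study {study.study_id!r}: zero pooled standard deviation")
    d = (study.mean_case - study.mean_control) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return float(g), float(var)


def log_fc_effect(study: StudySummary) -> tuple[float, float]:
    """Mean difference of log-scale expression (a log fold change) and variance."""
    eff = study.mean_case - study.mean_control
    var = study.sd_case**2 / study.n_case + study.sd_control**2 / study.n_control
    return float(eff), float(var)


@dataclass
class MetaResult:
    study_ids: list[str]
    effects: np.ndarray  # per-study g (or log FC)
    variances: np.ndarray
    weights: np.ndarray  # random-effects weights, normalised to sum 1
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_statistic: float
    df: int


def dersimonian_laird(
    studies: Sequence[StudySummary],
    effect_scale: str = "smd",
) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of study summaries.

    Q is computed from fixed-effect (inverse-variance) weights;
    tau2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w); the pooled
    estimate is the mean weighted by 1/(v_i + tau2) with a 1.96-normal CI.
    """
    if len(studies) == 0:
        raise ValueError("need at least one study")
    if effect_scale not in ("smd", "log_fc"):
        raise ValueError(f"unknown effect scale {effect_scale!r}")
    fn = hedges_g if effect_scale == "smd" else log_fc_effect
    pairs = [fn(s) for s in studies]
    g = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])

    w = 1.0 / v
    pooled_fe = float((w * g).sum() / w.sum())
    q = float((w * (g - pooled_fe) ** 2).sum())
    df = len(studies) - 1
    if df == 0:
        tau2 = 0.0
    else:
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / c)
    ws = 1.0 / (v + tau2)
    pooled = float((ws * g).sum() / ws.sum())
    se = float(np.sqrt(1.0 / ws.sum()))
    return MetaResult(
        study_ids=[s.study_id for s in studies],
        effects=g,
        variances=v,
        weights=ws / ws.sum(),
        pooled=pooled,
        se=se,
        ci_low=pooled - _Z95 * se,
        ci_high=pooled + _Z95 * se,
        tau2=tau2,
        q_statistic=q,
        df=df,
    )


class RandomEffectsMeta:
    """Random-effects meta-analysis model over study summaries."""

    def __init__(self, studies: Sequence[StudySummary], effect_scale: str = "smd"):
        self.studies = list(studies)
        self.effect_scale = effect_scale

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect_scale: str = "smd") -> "RandomEffectsMeta":
        """Build from a frame with columns study, n_case, mean_case, sd_case,
        n_control, mean_control, sd_control."""
        studies = [
            StudySummary(
                study_id=str(r["study"]),
                n_case=int(r["n_case"]),
                mean_case=float(r["mean_case"]),
                sd_case=float(r["sd_case"]),
                n_control=int(r["n_control"]),
                mean_control=float(r["mean_control"]),
                sd_control=float(r["sd_control"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(studies, effect_scale=effect_scale)

    def fit(self) -> "MetaResults":
        return MetaResults(model=self, result=dersimonian_laird(self.studies, self.effect_scale))


@dataclass
class MetaResults:
    model: RandomEffectsMeta
    result: MetaResult

    @property
    def pooled(self) -> float:
        return self.result.pooled

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.result.ci_low, self.result.ci_high)

    def forest_table(self) -> pd.DataFrame:
        """Per-study effects, variances and weights plus the pooled row."""
        r = self.result
        rows = pd.DataFrame(
            {
                "study": r.study_ids,
                "effect": r.effects,
                "variance": r.variances,
                "weight": r.weights,
                "ci_low": r.effects - _Z95 * np.sqrt(r.variances),
                "ci_high": r.effects + _Z95 * np.sqrt(r.variances),
            }
        )
        pooled = pd.DataFrame(
            {
                "study": ["pooled"],
                "effect": [r.pooled],
                "variance": [r.se**2],
                "weight": [1.0],
                "ci_low": [r.ci_low],
                "ci_high": [r.ci_high],
            }
        )
        return pd.concat([rows, pooled], ignore_index=True)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Random-effects meta-analysis (DerSimonian-Laird)",
            f"  studies: {len(r.study_ids)}   effect scale: {self.model.effect_scale}",
            f"  pooled effect: {r.pooled:.3f}  (95% CI {r.ci_low:.3f}; {r.ci_high:.3f})",
            f"  tau^2: {r.tau2:.4f}   Q: {r.q_statistic:.3f} on {r.df} df",
        ]
        return "\n".join(lines)
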