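"""Fixed-effects meta-analysis of MR estimates and presentation-scale ORs.

Per-outcome-sample estimates of the same exposure–outcome effect are pooled
with inverse-variance weights; Cochran's Q tests their heterogeneity.  Log
scale estimates are converted to odds ratios per 1 SD *lower* exposure (the
direction induced by a lipid-lowering drug) or per *halving* of a biomarker
measured in natural-log units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z95, _finish
from .exceptions import IncompatibleSourcesError, ScaleMismatchError

DIRECTIONS = ("per_sd_lower", "per_halving", "per_unit_higher")


@dataclass
class MetaResult:
    theta_meta: float
    se_meta: float
    ci_low: float
    ci_high: float
    pvalue: float
    q_statistic: float
    q_df: int
    q_pvalue: float
    inputs: list[tuple[str, MREstimate]]

    def as_dict(self) -> dict:
        return {
            "labels": ",".join(lbl for lbl, _ in self.inputs),
            "theta_meta": self.theta_meta,
            "se_meta": self.se_meta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "q_statistic": self.q_statistic,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
        }


@dataclass
class PresentationOR:
    """An odds ratio and 95% CI on the requested presentation scale."""

    or_point: float
    or_low: float
    or_high: float
    direction: str


def meta_fixed(estimates: Sequence[tuple[str, MREstimate]]) -> MetaResult:
    """Fixed-effects inverse-variance pooling with Cochran's Q.

    With a single input the pooled estimate is the input itself and Q is
    undefined (reported as NaN with 0 degrees of freedom).
    """
    if not estimates:
        raise IncompatibleSourcesError("meta_fixed needs at least one estimate")
    theta = np.array([e.theta for _, e in estimates])
    se = np.array([e.se for _, e in estimates])
    w = se**-2.0
    theta_meta = float((w * theta).sum() / w.sum())
    se_meta = float(w.sum() ** -0.5)
    m = len(estimates)
    if m > 1:
        q = float((w * (theta - theta_meta) ** 2).sum())
        q_p = float(stats.chi2.sf(q, df=m - 1))
    else:
        q, q_p = math.nan, math.nan
    p = float(2.0 * stats.norm.sf(abs(theta_meta) / se_meta))
    return MetaResult(
        theta_meta=theta_meta,
        se_meta=se_meta,
        ci_low=theta_meta - Z95 * se_meta,
        ci_high=theta_meta + Z95 * se_meta,
        pvalue=p,
        q_statistic=q,
        q_df=m - 1,
        q_pvalue=q_p,
        inputs=list(estimates),
    )


def or_from_ci(or_point: float, ci_low: float, ci_high: float) -> MREstimate:
    """Back-transform a printed OR and symmetric 95% CI to (theta, se).

    theta = ln(OR); se = (ln CI_high − ln CI_low)/(2 × 1.959964).  Lets
    published per-study odds ratios be pooled on the log scale.
    """
    if min(or_point, ci_low, ci_high) <= 0:
        raise ValueError("odds ratios and CI bounds must be positive")
    if not ci_low <= or_point <= ci_high:
        raise ValueError("require ci_low <= or_point <= ci_high")
    theta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if se <= 0:
        raise ValueError("degenerate CI: zero width implies se = 0")
    return _finish("ivw", theta, se, n_variants=0)


def present_or(
    theta: float,
    se: float,
    direction: str = "per_sd_lower",
    exposure_scale: str | None = None,
) -> PresentationOR:
    """Convert a log-scale estimate to an OR in the requested direction.

    ``per_sd_lower`` multiplies theta by −1 (drug-induced lowering of an
    SD-unit exposure); ``per_halving`` by −ln 2 (valid only for exposures in
    natural-log units); ``per_unit_higher`` by +1.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if not se > 0:
        raise ValueError("se must be positive")
    if direction == "per_halving" and exposure_scale not in (None, "ln_units"):
        raise ScaleMismatchError(
            "per-halving presentation requires an exposure in natural-log units"
        )
    c = {"per_sd_lower": -1.0, "per_halving": -math.log(2.0), "per_unit_higher": 1.0}[
        direction
    ]
    point = math.exp(c * theta)
    lo = math.exp(c * (theta - Z95 * se))
    hi = math.exp(c * (theta + Z95 * se))
    if c < 0:
        lo, hi = hi, lo
    return PresentationOR(or_point=point, or_low=lo, or_high=hi, direction=direction)
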