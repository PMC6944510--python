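"""Causal-effect estimators for two-sample summary-data Mendelian randomization.

Given per-variant exposure effects γ_j (standard error σ_Xj) and outcome
log-odds effects Γ_j (standard error σ_Yj) aligned to a common effect
allele, the causal log-odds ratio θ of the outcome per unit of exposure is
estimated by:

* the Wald ratio Γ_j/γ_j for a single variant;
* fixed-effects inverse-variance weighting (IVW), the precision-weighted
  combination of Wald ratios, equivalent to weighted least squares of Γ on
  γ through the origin with weights σ_Y^{-2};
* MR-Egger regression, which frees the intercept to absorb directional
  pleiotropy (consistent under the InSIDE assumption) and reports the
  intercept test plus the I²_GX instrument-strength statistic;
* the weighted median of Wald ratios, consistent when valid instruments
  carry more than half the weight, with a parametric-bootstrap SE;
* a principal-components generalized IVW for correlated (LD-linked)
  variants, which projects the weighted instrument matrix onto the leading
  eigenvectors capturing a fraction κ of its variance before solving the
  generalized least-squares normal equations.

All confidence intervals are Wald-type at 95% (normal quantile 1.959964)
and p-values are two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CollinearInstrumentsError,
    IllConditionedError,
    InsufficientInstrumentsError,
)
from .harmonize import HarmonizedSet
from .instruments import LDMatrix

Z95 = 1.959964
#: eigenvalues below this fraction of the largest are never selected
EIGENVALUE_FLOOR = 1e-10

METHODS = ("wald", "ivw", "egger_slope", "weighted_median", "pc_givw")


@dataclass
class MREstimate:
    """A causal-effect estimate: log-OR of outcome per unit higher exposure."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    kappa: float | None = None
    n_components: int | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_variants": self.n_variants,
            "kappa": self.kappa,
            "n_components": self.n_components,
        }


@dataclass
class EggerDiagnostics:
    """MR-Egger intercept (average directional pleiotropy) and I²_GX.

    ``i2_gx`` is reported as a fraction in (-inf, 1]; values near 1 indicate
    negligible regression-dilution attenuation of the Egger slope.
    """

    intercept: float
    intercept_se: float
    intercept_p: float
    i2_gx: float


def _finish(method: str, theta: float, se: float, n_variants: int, **extra) -> MREstimate:
    if not se > 0:
        raise ValueError(f"{method}: standard error must be positive, got {se}")
    p = float(2.0 * stats.norm.sf(abs(theta) / se))
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pvalue=p,
        n_variants=n_variants,
        **extra,
    )


def wald_ratio(gamma: float, Gamma: float, se_y: float) -> MREstimate:
    """Single-variant ratio estimate with first-order SE σ_Y/|γ|."""
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    return _finish("wald", Gamma / gamma, se_y / abs(gamma), n_variants=1)


def ivw(h: HarmonizedSet) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate.

    θ = Σ γ_j Γ_j σ_Yj^{-2} / Σ γ_j² σ_Yj^{-2}, SE = (Σ γ_j² σ_Yj^{-2})^{-1/2};
    the moment form needs no per-variant division, so γ_j = 0 is tolerated.
    """
    if h.n_variants < 1:
        raise InsufficientInstrumentsError("IVW needs at least 1 variant")
    g, G, sy = h.gamma, h.Gamma, h.se_y
    denom = float(np.sum(g**2 / sy**2))
    if denom == 0:
        raise CollinearInstrumentsError("all exposure effects are zero")
    theta = float(np.sum(g * G / sy**2)) / denom
    return _finish("ivw", theta, denom**-0.5, n_variants=h.n_variants)


def egger(h: HarmonizedSet) -> tuple[MREstimate, EggerDiagnostics]:
    """MR-Egger regression with intercept test and I²_GX.

    Variants are first oriented so every γ_j ≥ 0 (a joint sign flip of γ_j
    and Γ_j, i.e. relabeling to the exposure-raising allele), then
    Γ_j = β₀ + θ γ_j is fit by weighted least squares with weights σ_Yj^{-2}.
    """
    J = h.n_variants
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 variants")
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    g = h.gamma * sign
    G = h.Gamma * sign
    w = h.se_y**-2.0
    sw, swg, swgg = w.sum(), (w * g).sum(), (w * g * g).sum()
    det = sw * swgg - swg**2
    if det <= 0 or np.isclose(det / (sw * swgg), 0.0):
        raise CollinearInstrumentsError(
            "all instrument strengths equal after orientation"
        )
    swy, swgy = (w * G).sum(), (w * g * G).sum()
    # 2x2 weighted normal equations; fixed-effect covariance (no residual scaling)
    slope = (sw * swgy - swg * swy) / det
    intercept = (swgg * swy - swg * swgy) / det
    se_slope = (sw / det) ** 0.5
    se_int = (swgg / det) ** 0.5
    p_int = float(2.0 * stats.norm.sf(abs(intercept) / se_int))

    # instrument-strength heterogeneity of the gamma estimates
    wx = h.se_x**-2.0
    gbar = float((wx * g).sum() / wx.sum())
    q_gx = float(((g - gbar) ** 2 * wx).sum())
    i2 = max(0.0, (q_gx - (J - 1)) / q_gx) if q_gx > 0 else 0.0

    est = _finish("egger_slope", slope, se_slope, n_variants=J)
    diag = EggerDiagnostics(
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=p_int,
        i2_gx=i2,
    )
    return est, diag


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative s_j = Σ_{i≤j} w_i − w_j/2,
    linear interpolation in s at 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1_000, seed: int = 0
) -> MREstimate:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Weights are w_j = γ_j²/σ_Yj² (the IVW weights of the ratios).  The SE is
    the standard deviation of the estimate over ``n_boot`` replicates drawing
    γ* ~ N(γ, σ_X²) and Γ* ~ N(Γ, σ_Y²).
    """
    J = h.n_variants
    if J < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 variants")
    g, G, sx, sy = h.gamma, h.Gamma, h.se_x, h.se_y
    if np.any(g == 0):
        raise ZeroDivisionError("weighted median requires all gamma != 0")
    est = _weighted_median(G / g, g**2 / sy**2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = rng.normal(g, sx)
        Gb = rng.normal(G, sy)
        gb[gb == 0] = np.finfo(float).tiny  # measure-zero guard
        boots[b] = _weighted_median(Gb / gb, gb**2 / sy**2)
    se = float(boots.std(ddof=1))
    return _finish("weighted_median", est, se, n_variants=J)


def pc_givw(h: HarmonizedSet, ld: LDMatrix, kappa: float = 0.99) -> MREstimate:
    """Principal-components generalized IVW for correlated variants.

    The weighted instrument matrix Φ_jk = γ_j γ_k ρ_jk/(σ_Yj σ_Yk) is
    eigendecomposed and the smallest number k of leading components whose
    eigenvalue sum reaches a fraction κ of the total is retained.  With
    W the matrix of those eigenvectors, the estimate solves the generalized
    least-squares normal equations in the transformed space
    (γ' = Wᵀγ, Γ' = WᵀΓ, Ω' = WᵀΩW with Ω_jk = σ_Yj σ_Yk ρ_jk):
    θ = γ'ᵀΩ'⁻¹Γ' / γ'ᵀΩ'⁻¹γ', SE = (γ'ᵀΩ'⁻¹γ')^{-1/2}.
    """
    if not 0 < kappa <= 1:
        raise ValueError("kappa must be in (0, 1]")
    if h.n_variants < 1:
        raise InsufficientInstrumentsError("pc_givw needs at least 1 variant")
    sub = ld.subset(h.keys)
    g, G, sy = h.gamma, h.Gamma, h.se_y
    rho = sub.r
    phi = np.outer(g / sy, g / sy) * rho
    evals, evecs = np.linalg.eigh(phi)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise CollinearInstrumentsError("degenerate weighted instrument matrix")
    usable = evals > EIGENVALUE_FLOOR * evals[0]
    cum = np.cumsum(evals) / total
    k = int(np.searchsorted(cum, kappa - 1e-12) + 1)
    k = min(k, int(usable.sum()))
    W = evecs[:, :k]

    omega = np.outer(sy, sy) * rho
    gp = W.T @ g
    Gp = W.T @ G
    omega_p = W.T @ omega @ W
    try:
        oinv_g = np.linalg.solve(omega_p, gp)
        oinv_G = np.linalg.solve(omega_p, Gp)
    except np.linalg.LinAlgError as err:
        raise IllConditionedError(
            f"transformed covariance singular with kappa={kappa}; try a smaller kappa"
        ) from err
    denom = float(gp @ oinv_g)
    if not np.isfinite(denom) or denom <= 0:
        raise IllConditionedError(
            f"ill-conditioned system with kappa={kappa}; try a smaller kappa"
        )
    theta = float(gp @ oinv_G) / denom
    return _finish(
        "pc_givw", theta, denom**-0.5, n_variants=h.n_variants,
        kappa=kappa, n_components=k,
    )


def estimate(h: HarmonizedSet, method: str, **kwargs) -> MREstimate:
    """Dispatch by method name ('ivw', 'egger', 'weighted_median', 'pc_givw')."""
    if method == "ivw":
        return ivw(h)
    if method in ("egger", "egger_slope"):
        return egger(h)[0]
    if method == "weighted_median":
        return weighted_median(
            h, n_boot=kwargs.get("n_boot", 1_000), seed=kwargs.get("seed", 0)
        )
    if method == "pc_givw":
        return pc_givw(h, kwargs["ld"], kappa=kwargs.get("kappa", 0.99))
    raise ValueError(f"unknown method {method!r}")


def leave_one_out(h: HarmonizedSet, method: str = "ivw", **kwargs) -> pd.DataFrame:
    """Re-estimate with each variant omitted in turn.

    Returns one row per omitted variant key; used to spot single outlying
    Wald estimators driving the overall result.
    """
    if h.n_variants < 2:
        raise InsufficientInstrumentsError("leave-one-out needs at least 2 variants")
    rows = []
    for key in h.keys:
        est = estimate(h.drop(key), method, **kwargs)
        d = est.as_dict()
        d["omitted_key"] = key
        rows.append(d)
    cols = ["omitted_key"] + [c for c in rows[0] if c != "omitted_key"]
    return pd.DataFrame(rows)[cols]


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant Wald ratios against precision |γ_j|/σ_Yj (plot-ready).

    Asymmetry of the funnel around the combined estimate suggests
    directional pleiotropy among the less precise instruments.
    """
    g, G, sy = h.gamma, h.Gamma, h.se_y
    if np.any(g == 0):
        raise ZeroDivisionError("funnel data requires all gamma != 0")
    return pd.DataFrame(
        {
            "variant_key": h.keys,
            "theta_j": G / g,
            "precision": np.abs(g) / sy,
        }
    )
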