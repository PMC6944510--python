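"""Synthetic reference panels and two-sample GWAS summary statistics.

The generator emulates the data layout of a multi-source cis-MR study of a
quantitative exposure (SD units) on a binary outcome (log-odds): three
partially overlapping exposure GWAS sources of very different sample size,
two independent case–control outcome samples, an LD-structured variant
panel, and an optional strongly pleiotropic locus whose direct outcome
effect must be handled by exclusion (an APOE analogue).

Summary statistics are drawn directly from their asymptotic sampling model:
with effect-allele frequency f_j, the per-allele SE of a standardized-trait
GWAS with n individuals is 1/sqrt(n · 2 f_j (1 − f_j)), and a case–control
log-odds GWAS behaves like one with effective size
n_eff = 4/(1/n_cases + 1/n_controls).  True per-variant exposure effects
are γ_j with |γ_j| ~ |N(0, 0.02²)|; by convention the effect allele is
labeled as the exposure-raising allele, so γ_j ≥ 0 (a pure relabeling).
Outcome effects are Γ_j = θ γ_j + α_j with α_j set by the pleiotropy mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._alleles import variant_key
from .instruments import LDMatrix, ld_from_panel
from .sumstats import SummaryDataset, attach_keys

PLEIOTROPY_MODES = ("none", "balanced", "directional", "invalid_fraction")

#: per-source sample-size fractions and variant densities; the n spread
#: mirrors consortium reality (one very large source, one mid-size, one small)
SOURCE_N_FRACTIONS = (1.0, 0.34, 0.047)
SOURCE_DENSITIES = (1.0, 0.6, 0.3)

#: second outcome sample scaled from the first like a register-based
#: replication sample relative to a large case-control consortium
OUTCOME2_CASE_FRACTION = 0.1245
OUTCOME2_CONTROL_FRACTION = 0.3515

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generating-model parameters; every draw is a pure function of these."""

    n_variants: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    n_exposure: int = 100_000
    n_cases: int = 20_000
    n_controls: int = 40_000
    theta_true: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.0
    invalid_fraction: float = 0.0
    n_ref_panel: int = 503
    seed: int = 0
    gamma_sd: float = 0.02
    palindromic_fraction: float = 0.15
    n_cases2: int | None = None
    n_controls2: int | None = None

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not 0 <= self.invalid_fraction < 1:
            raise ValueError("invalid_fraction must be in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def outcome_sizes(self) -> list[tuple[int, int]]:
        cases2 = self.n_cases2 or max(1, round(OUTCOME2_CASE_FRACTION * self.n_cases))
        controls2 = self.n_controls2 or max(
            1, round(OUTCOME2_CONTROL_FRACTION * self.n_controls)
        )
        return [(self.n_cases, self.n_controls), (cases2, controls2)]


@dataclass
class SyntheticStudy:
    """A complete simulated two-sample MR study with known truth."""

    exposure_sources: list[SummaryDataset]
    outcome_samples: list[SummaryDataset]
    truth: pd.DataFrame  # key, gamma_true, alpha_true, maf
    theta_true: float
    ld: LDMatrix
    panel: np.ndarray
    config: SimulationConfig
    pleiotropic_block: list[str] = field(default_factory=list)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _variant_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant metadata: positions, allele pairs, frequencies.

    MAFs follow a Gaussian copula with the panel's lag-1 correlation, so
    tightly linked neighbours have similar frequencies (as shared genealogy
    produces in real data); at ld_rho = 0 this is plain iid uniform.
    """
    J = config.n_variants
    lo, hi = config.maf_range
    z = _hap_latent(rng, 1, J, config.ld_rho)[0]
    maf = lo + (hi - lo) * stats.norm.cdf(z)
    pal = rng.random(J) < config.palindromic_fraction
    pairs = [
        _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        if p
        else _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        for p in pal
    ]
    # effect allele may be the minor or the major allele
    minor_is_effect = rng.random(J) < 0.5
    eaf = np.where(minor_is_effect, maf, 1.0 - maf)
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{1000 + j}" for j in range(J)],
            "chrom": "1",
            "pos": 1_000_000 + 1_000 * np.arange(J),
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": eaf,
            "maf": maf,
        }
    )
    return attach_keys(df)


def _hap_latent(rng: np.random.Generator, n: int, J: int, rho: float) -> np.ndarray:
    """Lag-1 autoregressive latent Gaussians across variants."""
    z = rng.standard_normal((n, J))
    if rho > 0:
        out = np.empty_like(z)
        out[:, 0] = z[:, 0]
        c = np.sqrt(1.0 - rho**2)
        for j in range(1, J):
            out[:, j] = rho * out[:, j - 1] + c * z[:, j]
        return out
    return z


def simulate_panel(config: SimulationConfig) -> tuple[np.ndarray, LDMatrix]:
    """Reference-panel dosages (individuals × variants) plus empirical LD.

    Two latent AR(1) Gaussian haplotypes per individual are thresholded at
    each variant's effect-allele frequency quantile, giving Hardy-Weinberg
    dosage classes with the requested adjacent-variant correlation.
    """
    rng_meta, rng_panel = _rngs(config.seed, 4)[:2]
    variants = _variant_frame(config, rng_meta)
    return _panel_from_variants(config, variants, rng_panel)


def _panel_from_variants(
    config: SimulationConfig, variants: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, LDMatrix]:
    J = config.n_variants
    thresholds = stats.norm.ppf(1.0 - variants["eaf"].to_numpy())
    dosage = np.zeros((config.n_ref_panel, J))
    for _hap in range(2):
        z = _hap_latent(rng, config.n_ref_panel, J, config.ld_rho)
        dosage += (z > thresholds).astype(float)
    ld = ld_from_panel(dosage, list(variants["key"]))
    return dosage, ld


def _sumstats_frame(
    variants: pd.DataFrame,
    beta_hat: np.ndarray,
    se: np.ndarray,
    n: int,
    label: str,
) -> pd.DataFrame:
    z = np.abs(beta_hat) / se
    df = variants[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "key"]
    ].copy()
    df["beta"] = beta_hat
    df["se"] = se
    df["pvalue"] = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    df["n"] = n
    df["source_label"] = label
    return df


def _swap_presentation(df: pd.DataFrame, swap: np.ndarray) -> pd.DataFrame:
    """Report some variants for the opposite allele (beta negated, eaf
    complemented) so harmonization flips are exercised."""
    df = df.copy()
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    df.loc[swap, "effect_allele"] = oa[swap]
    df.loc[swap, "other_allele"] = ea[swap]
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    return df


def simulate_two_sample(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full two-sample study: 3 exposure sources, 2 outcome samples,
    reference panel, LD matrix and the generating truth."""
    (rng_meta, rng_panel, rng_truth, rng_exp, rng_out, rng_pres) = _rngs(
        config.seed, 6
    )
    variants = _variant_frame(config, rng_meta)
    J = config.n_variants
    maf = variants["maf"].to_numpy()

    gamma = np.abs(rng_truth.normal(0.0, config.gamma_sd, size=J))
    mode, scale = config.pleiotropy_mode, config.pleiotropy_scale
    if mode == "none":
        alpha = np.zeros(J)
    elif mode == "balanced":
        alpha = rng_truth.normal(0.0, scale, size=J)
    elif mode == "directional":
        alpha = rng_truth.normal(scale, scale / 2.0, size=J)
    else:  # invalid_fraction
        alpha = np.zeros(J)
        n_invalid = round(config.invalid_fraction * J)
        invalid = rng_truth.choice(J, size=n_invalid, replace=False)
        alpha[invalid] = scale
    Gamma = config.theta_true * gamma + alpha

    var_factor = 2.0 * maf * (1.0 - maf)

    exposure_sources = []
    for s, (n_frac, density) in enumerate(zip(SOURCE_N_FRACTIONS, SOURCE_DENSITIES)):
        n_s = max(2, round(n_frac * config.n_exposure))
        if density < 1.0:
            idx = np.sort(
                rng_exp.choice(J, size=max(1, round(density * J)), replace=False)
            )
        else:
            idx = np.arange(J)
        sub = variants.iloc[idx].reset_index(drop=True)
        se_x = 1.0 / np.sqrt(n_s * var_factor[idx])
        beta_hat = rng_exp.normal(gamma[idx], se_x)
        frame = _sumstats_frame(sub, beta_hat, se_x, n_s, f"exposure_src{s + 1}")
        exposure_sources.append(
            SummaryDataset(
                trait_name="exposure",
                trait_scale="sd_units",
                df=frame,
                provenance=[(f"exposure_src{s + 1}", n_s)],
            )
        )

    outcome_samples = []
    for s, (n_cases, n_controls) in enumerate(config.outcome_sizes):
        n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
        se_y = 1.0 / np.sqrt(n_eff * var_factor)
        Gamma_hat = rng_out.normal(Gamma, se_y)
        frame = _sumstats_frame(variants, Gamma_hat, se_y, n_cases + n_controls,
                                f"outcome_s{s + 1}")
        swap = rng_pres.random(J) < 0.3
        frame = _swap_presentation(frame, swap)
        outcome_samples.append(
            SummaryDataset(
                trait_name=f"outcome_s{s + 1}",
                trait_scale="log_odds",
                df=frame,
                provenance=[(f"outcome_s{s + 1}", n_cases + n_controls)],
            )
        )

    panel, ld = _panel_from_variants(config, variants, rng_panel)
    truth = pd.DataFrame(
        {
            "key": variants["key"],
            "gamma_true": gamma,
            "alpha_true": alpha,
            "maf": maf,
        }
    )
    return SyntheticStudy(
        exposure_sources=exposure_sources,
        outcome_samples=outcome_samples,
        truth=truth,
        theta_true=config.theta_true,
        ld=ld,
        panel=panel,
        config=config,
    )


def embed_pleiotropic_locus(
    study: SyntheticStudy, locus_size: int, outcome_effect: float
) -> SyntheticStudy:
    """Give a contiguous variant block a direct outcome effect (APOE analogue).

    Returns a new study whose outcome samples have ``outcome_effect`` added
    to the block's log-odds estimates (p-values recomputed); the block keys
    are recorded so exclusion-list efficacy can be verified.
    """
    J = study.config.n_variants
    if locus_size > J:
        raise ValueError("locus_size exceeds the number of variants")
    rng = np.random.default_rng(np.random.SeedSequence(study.config.seed).spawn(7)[6])
    start = int(rng.integers(0, J - locus_size + 1))
    block = study.truth["key"].iloc[start : start + locus_size].tolist()

    new_outcomes = []
    for ds in study.outcome_samples:
        df = ds.df.copy()
        in_block = df["key"].isin(block).to_numpy()
        df.loc[in_block, "beta"] += outcome_effect
        z = np.abs(df["beta"]) / df["se"]
        df["pvalue"] = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
        new_outcomes.append(
            SummaryDataset(
                trait_name=ds.trait_name,
                trait_scale=ds.trait_scale,
                df=df,
                provenance=list(ds.provenance),
            )
        )
    truth = study.truth.copy()
    truth["alpha_true"] = truth["alpha_true"] + np.where(
        truth["key"].isin(block), outcome_effect, 0.0
    )
    return SyntheticStudy(
        exposure_sources=study.exposure_sources,
        outcome_samples=new_outcomes,
        truth=truth,
        theta_true=study.theta_true,
        ld=study.ld,
        panel=study.panel,
        config=study.config,
        pleiotropic_block=block,
    )


def write_truth_table(study: SyntheticStudy, path) -> None:
    study.truth.to_csv(path, sep="\t", index=False, float_format="%.17g")
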