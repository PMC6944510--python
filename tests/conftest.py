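import numpy as np
import pandas as pd
import pytest

from cismr.harmonize import HarmonizedSet
from cismr.sumstats import SummaryDataset, attach_keys


def make_sumstats(
    rows,
    trait_name="exposure",
    trait_scale="sd_units",
):
    """Build a SummaryDataset from (variant_id, chrom, pos, ea, oa, eaf, beta, se, p, n) rows."""
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n",
        ],
    )
    df["source_label"] = trait_name
    return SummaryDataset(trait_name=trait_name, trait_scale=trait_scale, df=attach_keys(df))


def make_hset(gamma, Gamma, se_x=None, se_y=None, p_x=None, keys=None):
    """Build a HarmonizedSet directly from effect arrays."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    J = len(gamma)
    se_x = np.full(J, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(J, 0.01) if se_y is None else np.asarray(se_y, dtype=float)
    p_x = np.linspace(1e-8, 1e-4, J) if p_x is None else np.asarray(p_x, dtype=float)
    keys = [f"1:{1000 + j}:A_C" for j in range(J)] if keys is None else list(keys)
    df = pd.DataFrame(
        {
            "key": keys,
            "chrom": "1",
            "pos": 1000 + np.arange(J),
            "effect_allele": "A",
            "other_allele": "C",
            "gamma": gamma,
            "se_x": se_x,
            "p_x": p_x,
            "eaf_x": 0.3,
            "Gamma": Gamma,
            "se_y": se_y,
            "p_y": 0.5,
            "eaf_y": 0.3,
        }
    )
    return HarmonizedSet(df=df, exposure_scale="sd_units", outcome_scale="log_odds")


def random_hset(rng, J=20, sigma_y_range=(0.005, 0.05)):
    """A random harmonized instance for oracle-equivalence checks."""
    gamma = rng.normal(0, 0.05, J)
    gamma[gamma == 0] = 0.01
    se_y = rng.uniform(*sigma_y_range, J)
    se_x = rng.uniform(0.001, 0.01, J)
    Gamma = rng.normal(0.3 * gamma, se_y)
    return make_hset(gamma, Gamma, se_x=se_x, se_y=se_y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
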