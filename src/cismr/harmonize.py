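"""Alignment of exposure and outcome associations to a shared effect allele.

Consortium GWAS report effects for arbitrarily chosen alleles and strands.
Before combining a variant's exposure and outcome statistics, the outcome
record is oriented to the exposure's effect allele: swapped alleles flip the
sign of the outcome log-odds and complement its frequency; opposite-strand
records are resolved by complementing alleles.  Palindromic variants (A/T,
C/G) carry no strand information in their alleles, so they are aligned by
allele frequency when the minor-allele frequency is informative and dropped
as ambiguous when it lies in [0.4, 0.5] (or is missing) in either dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._alleles import is_palindromic
from .exceptions import NoOverlapError
from .sumstats import SummaryDataset

AMBIGUITY_BAND = (0.4, 0.5)  # closed band on minor-allele frequency


@dataclass
class HarmonizedSet:
    """Per-variant exposure (gamma, se_x) and outcome (Gamma, se_y) effects
    aligned to a common effect allele."""

    df: pd.DataFrame
    exposure_scale: str
    outcome_scale: str
    audit: dict = field(default_factory=dict)
    audit_table: pd.DataFrame | None = None

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy()

    @property
    def se_x(self) -> np.ndarray:
        return self.df["se_x"].to_numpy()

    @property
    def Gamma(self) -> np.ndarray:
        return self.df["Gamma"].to_numpy()

    @property
    def se_y(self) -> np.ndarray:
        return self.df["se_y"].to_numpy()

    @property
    def keys(self) -> list[str]:
        return list(self.df["key"])

    def subset(self, keys: Iterable[str]) -> "HarmonizedSet":
        keys = set(keys)
        return HarmonizedSet(
            df=self.df[self.df["key"].isin(keys)].reset_index(drop=True),
            exposure_scale=self.exposure_scale,
            outcome_scale=self.outcome_scale,
            audit=dict(self.audit),
            audit_table=self.audit_table,
        )

    def drop(self, key: str) -> "HarmonizedSet":
        return self.subset(k for k in self.df["key"] if k != key)

    def write_audit(self, path) -> None:
        """Harmonization audit table: variant_key, action."""
        if self.audit_table is not None:
            self.audit_table.to_csv(path, sep="\t", index=False)


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    strict_palindromic: bool = False,
) -> HarmonizedSet:
    """Intersect on variant key and orient outcome effects to exposure alleles.

    ``strict_palindromic=True`` drops every palindromic variant instead of
    frequency-aligning those with informative minor-allele frequency.
    """
    if exposure.df.empty or outcome.df.empty:
        raise NoOverlapError("empty exposure or outcome dataset")
    exp = exposure.df.drop_duplicates("key")
    out = outcome.df.drop_duplicates("key")
    merged = exp.merge(out, on="key", suffixes=("_x", "_y"))
    if merged.empty:
        raise NoOverlapError(
            f"no shared variants between {exposure.trait_name} and {outcome.trait_name}"
        )

    records = []
    actions = []
    n_flipped = n_pal_dropped = n_mismatch = 0
    lo, hi = AMBIGUITY_BAND
    for row in merged.itertuples(index=False):
        e1, e2 = row.effect_allele_x, row.other_allele_x
        o1, o2 = row.effect_allele_y, row.other_allele_y
        Gamma, eaf_y = row.beta_y, row.eaf_y
        flipped = False

        if is_palindromic(e1, e2):
            if strict_palindromic:
                n_pal_dropped += 1
                actions.append((row.key, "dropped_palindromic"))
                continue
            eafs = (row.eaf_x, row.eaf_y)
            if any(pd.isna(f) for f in eafs) or any(
                lo <= _maf(f) <= hi for f in eafs
            ):
                n_pal_dropped += 1
                actions.append((row.key, "dropped_palindromic"))
                continue
            # align by frequency: the exposure effect allele sits on a known
            # side of 0.5; orient the outcome so its effect allele agrees
            same_side = (row.eaf_x - 0.5) * (eaf_y - 0.5) > 0
            if not same_side:
                Gamma, eaf_y, flipped = -Gamma, 1.0 - eaf_y, True
        else:
            if {o1, o2} != {e1, e2}:
                # opposite strand: complement the outcome alleles
                from ._alleles import complement

                o1, o2 = complement(o1), complement(o2)
            if {o1, o2} != {e1, e2}:
                n_mismatch += 1
                actions.append((row.key, "dropped_mismatch"))
                continue
            if o1 != e1:
                Gamma = -Gamma
                eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
                flipped = True

        if flipped:
            n_flipped += 1
        actions.append((row.key, "flipped" if flipped else "kept"))
        records.append(
            {
                "key": row.key,
                "chrom": row.chrom_x,
                "pos": row.pos_x,
                "effect_allele": e1,
                "other_allele": e2,
                "gamma": row.beta_x,
                "se_x": row.se_x,
                "p_x": row.pvalue_x,
                "eaf_x": row.eaf_x,
                "Gamma": Gamma,
                "se_y": row.se_y,
                "p_y": row.pvalue_y,
                "eaf_y": eaf_y,
            }
        )

    df = pd.DataFrame(
        records,
        columns=[
            "key", "chrom", "pos", "effect_allele", "other_allele",
            "gamma", "se_x", "p_x", "eaf_x", "Gamma", "se_y", "p_y", "eaf_y",
        ],
    )
    if len(df):
        df = df.sort_values(["chrom", "pos", "key"]).reset_index(drop=True)
    audit = {
        "n_exposure": len(exp),
        "n_outcome": len(out),
        "n_intersection": len(merged),
        "kept": len(df),
        "flipped": n_flipped,
        "dropped_palindromic": n_pal_dropped,
        "dropped_mismatch": n_mismatch,
    }
    audit_table = pd.DataFrame(actions, columns=["variant_key", "action"])
    return HarmonizedSet(
        df=df,
        exposure_scale=exposure.trait_scale,
        outcome_scale=outcome.trait_scale,
        audit=audit,
        audit_table=audit_table,
    )


def harmonized_to_outcome_dataset(h: HarmonizedSet, trait_name: str = "outcome") -> SummaryDataset:
    """Re-express the harmonized outcome side as a SummaryDataset (already
    aligned to the exposure's effect alleles); useful for idempotence checks
    and for writing harmonized tables back out."""
    df = pd.DataFrame(
        {
            "variant_id": h.df["key"],
            "chrom": h.df["chrom"],
            "pos": h.df["pos"],
            "effect_allele": h.df["effect_allele"],
            "other_allele": h.df["other_allele"],
            "eaf": h.df["eaf_y"],
            "beta": h.df["Gamma"],
            "se": h.df["se_y"],
            "pvalue": h.df["p_y"],
            "n": np.nan,
            "source_label": "harmonized",
        }
    )
    return SummaryDataset(trait_name=trait_name, trait_scale=h.outcome_scale, df=df)
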