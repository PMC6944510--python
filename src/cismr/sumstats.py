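"""Reading, validating, merging and filtering GWAS summary statistics.

Exposure association statistics may come from several partially overlapping
consortium GWAS.  Following standard practice for combining such sources
without double counting, the tables are appended and, where the same variant
appears in more than one source, the record from the largest analysis sample
is retained — estimates are never averaged across sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._alleles import VALID_ALLELES, variant_key
from .exceptions import ConfigurationError, EmptyInputError, IncompatibleSourcesError

logger = logging.getLogger(__name__)

TRAIT_SCALES = ("sd_units", "ln_units", "log_odds")

#: canonical column order of the package's delimited summary-statistic format
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "source_label",
]

_MANDATORY = [c for c in COLUMNS if c not in ("eaf", "n", "source_label")]


@dataclass
class SummaryDataset:
    """One trait's per-variant association statistics.

    ``df`` holds one row per variant with the columns in :data:`COLUMNS`
    plus a computed ``key`` column (strand-insensitive variant key).
    """

    trait_name: str
    trait_scale: str
    df: pd.DataFrame
    ancestry_label: str = ""
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_scale not in TRAIT_SCALES:
            raise ConfigurationError(
                f"trait_scale must be one of {TRAIT_SCALES}, got {self.trait_scale!r}"
            )
        if "key" not in self.df.columns:
            self.df = attach_keys(self.df)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def subset(self, keys: Iterable[str]) -> "SummaryDataset":
        keys = set(keys)
        return SummaryDataset(
            trait_name=self.trait_name,
            trait_scale=self.trait_scale,
            df=self.df[self.df["key"].isin(keys)].reset_index(drop=True),
            ancestry_label=self.ancestry_label,
            provenance=list(self.provenance),
        )


def attach_keys(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["key"] = [
        variant_key(c, p, a1, a2)
        for c, p, a1, a2 in zip(
            df["chrom"], df["pos"], df["effect_allele"], df["other_allele"]
        )
    ]
    return df


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating per-variant invariants; return (valid rows, n dropped)."""
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (pos >= 1)
        & pos.notna()
        & (pd.to_numeric(df["se"], errors="coerce") > 0)
        & (pd.to_numeric(df["pvalue"], errors="coerce") > 0)
        & (pd.to_numeric(df["pvalue"], errors="coerce") <= 1)
        & np.isfinite(pd.to_numeric(df["beta"], errors="coerce"))
    )
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    ok &= eaf.isna() | ((eaf >= 0) & (eaf <= 1))
    dropped = int((~ok).sum())
    out = df[ok].copy()
    out["pos"] = pos[ok].astype(np.int64)
    for col in ("eaf", "beta", "se", "pvalue"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    out["n"] = pd.to_numeric(out["n"], errors="coerce")
    return out.reset_index(drop=True), dropped


def read_summary_stats(
    path: str | Path,
    trait_name: str = "",
    trait_scale: str = "sd_units",
    column_map: Mapping[str, str] | None = None,
    source_label: str | None = None,
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a validated dataset.

    ``column_map`` maps the package's canonical column names to the file's
    column names (e.g. ``{"pvalue": "p_value"}`` for GWAS-SSF-style headers).
    Rows violating the per-variant invariants are dropped with a logged count.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(
        path, sep=sep, comment="#", dtype={"chrom": str}, float_precision="round_trip"
    )
    colmap = dict(column_map or {})
    rename = {v: k for k, v in colmap.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")
    for opt in ("eaf", "n", "source_label"):
        if opt not in raw.columns:
            raw[opt] = np.nan
    df, dropped = validate_records(raw[COLUMNS])
    if dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, dropped)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    if source_label is not None:
        df["source_label"] = source_label
    elif df["source_label"].isna().all():
        df["source_label"] = path.stem
    label = str(df["source_label"].iloc[0])
    n_rep = df["n"].dropna()
    prov_n = int(n_rep.max()) if len(n_rep) else 0
    return SummaryDataset(
        trait_name=trait_name or path.stem,
        trait_scale=trait_scale,
        df=attach_keys(df),
        provenance=[(label, prov_n)],
    )


def write_summary_stats(dataset: SummaryDataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset back to delimited text (floats at full precision)."""
    out = dataset.df[COLUMNS]
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def merge_exposure_sources(sources: Sequence[SummaryDataset]) -> SummaryDataset:
    """Append exposure sources, keeping the largest-n record per variant key.

    Estimates are never averaged: appending with largest-n de-duplication
    avoids double counting across partially overlapping GWAS samples while
    retaining the most precise available estimate per variant.  Ties in n go
    to the earlier source in the supplied order; missing n counts as 0.
    """
    if not sources:
        raise EmptyInputError("no exposure sources supplied")
    first = sources[0]
    for s in sources[1:]:
        if s.trait_scale != first.trait_scale or s.trait_name != first.trait_name:
            raise IncompatibleSourcesError(
                f"cannot merge {s.trait_name}/{s.trait_scale} with "
                f"{first.trait_name}/{first.trait_scale}"
            )
    frames = []
    for order, s in enumerate(sources):
        f = s.df.copy()
        f["_order"] = order
        frames.append(f)
    allrec = pd.concat(frames, ignore_index=True)
    n_fill = allrec["n"].fillna(0.0)
    if allrec["n"].isna().any():
        logger.warning(
            "%d record(s) with missing n treated as n=0 for de-duplication",
            int(allrec["n"].isna().sum()),
        )
    allrec["_n_dedup"] = n_fill

    dup = allrec[allrec.duplicated("key", keep=False)]
    if len(dup):
        g = dup.groupby("key")
        ties = g["_n_dedup"].apply(lambda x: (x == x.max()).sum() > 1)
        if ties.any():
            logger.info(
                "%d variant key(s) tied on n across sources; keeping the "
                "earliest-listed source",
                int(ties.sum()),
            )
        eaf_rng = g["eaf"].apply(lambda x: float(x.max() - x.min()) if x.notna().all() else 0.0)
        conflicts = eaf_rng[eaf_rng > 0.2]
        for key in conflicts.index:
            logger.warning(
                "variant %s: effect-allele frequency differs by >0.2 across "
                "sources; keeping the largest-n record",
                key,
            )

    merged = (
        allrec.sort_values(["key", "_n_dedup", "_order"], ascending=[True, False, True])
        .drop_duplicates("key", keep="first")
        .sort_values(["chrom", "pos", "key"])
        .reset_index(drop=True)
    )
    retention = merged["_order"].value_counts().to_dict()
    provenance = []
    for order, s in enumerate(sources):
        label = s.provenance[0][0] if s.provenance else str(order)
        provenance.append((label, int(retention.get(order, 0))))
    merged = merged.drop(columns=["_order", "_n_dedup"])
    return SummaryDataset(
        trait_name=first.trait_name,
        trait_scale=first.trait_scale,
        df=merged,
        ancestry_label=first.ancestry_label,
        provenance=provenance,
    )


def read_exclusion_list(path: str | Path) -> list[str]:
    """One variant key (or verbatim variant_id) per line; '#' comments allowed."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                entries.append(line)
    return entries


def apply_exclusion_list(
    dataset: SummaryDataset, excluded: Iterable[str]
) -> SummaryDataset:
    """Remove variants whose key or variant_id appears in ``excluded``.

    Used e.g. to drop the APOE-region variants whose strong direct effect on
    Alzheimer-disease risk would violate the exclusion-restriction assumption.
    """
    excluded = set(excluded)
    if not excluded:
        return dataset
    hit = dataset.df["key"].isin(excluded) | dataset.df["variant_id"].isin(excluded)
    n_removed = int(hit.sum())
    if n_removed < len(excluded):
        logger.info(
            "%d exclusion-list entr(ies) matched no variant", len(excluded) - n_removed
        )
    logger.info("excluded %d variant(s)", n_removed)
    out = dataset.df[~hit].reset_index(drop=True)
    return SummaryDataset(
        trait_name=dataset.trait_name,
        trait_scale=dataset.trait_scale,
        df=out,
        ancestry_label=dataset.ancestry_label,
        provenance=list(dataset.provenance),
    )
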