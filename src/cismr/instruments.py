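"""Gene-region instrument selection, reference-panel LD and clumping.

Drug-target (cis) Mendelian randomization restricts instruments to variants
in or near the gene encoding the target protein, so the genetic effect
proxies pharmacological modulation of that target.  Nearby variants are
correlated (linkage disequilibrium); LD is estimated as the signed Pearson
correlation of effect-allele dosages in a reference panel, and an excess of
highly correlated variants is removed by p-value-ordered greedy clumping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingLDError, MonomorphicVariantError
from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)


@dataclass
class GeneRegion:
    """A gene's GRCh37 footprint plus a symmetric flank in base pairs."""

    gene_name: str
    chrom: str
    start: int
    stop: int
    flank_bp: int = 1_000

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"{self.gene_name}: stop < start")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")


@dataclass
class LDMatrix:
    """Signed correlation matrix over an ordered variant list.

    ``r[j, k]`` is the Pearson correlation between the effect-allele dosages
    of variants j and k; the diagonal is identically 1.
    """

    variant_keys: list[str]
    r: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.variant_keys), len(self.variant_keys)):
            raise ValueError("LD matrix dimension does not match variant list")

    @classmethod
    def identity(cls, variant_keys: Sequence[str], n_ref: int = 0) -> "LDMatrix":
        return cls(list(variant_keys), np.eye(len(variant_keys)), n_ref)

    def subset(self, keys: Sequence[str]) -> "LDMatrix":
        index = {k: i for i, k in enumerate(self.variant_keys)}
        missing = [k for k in keys if k not in index]
        if missing:
            raise MissingLDError(f"variant(s) missing from LD matrix: {missing[:5]}")
        idx = np.array([index[k] for k in keys], dtype=int)
        return LDMatrix(list(keys), self.r[np.ix_(idx, idx)], self.n_ref)


def select_region_variants(dataset: SummaryDataset, region: GeneRegion) -> SummaryDataset:
    """Variants with position in [start − flank, stop + flank], both ends inclusive."""
    lo = region.start - region.flank_bp
    hi = region.stop + region.flank_bp
    df = dataset.df
    keep = (df["chrom"] == region.chrom) & (df["pos"] >= lo) & (df["pos"] <= hi)
    if not keep.any():
        logger.warning(
            "region %s (%s:%d-%d ±%d bp) contains no dataset variants",
            region.gene_name, region.chrom, region.start, region.stop, region.flank_bp,
        )
    return dataset.subset(df.loc[keep, "key"])


def ld_from_panel(
    dosages: np.ndarray,
    variant_keys: Sequence[str],
    panel_effect_alleles: Sequence[str] | None = None,
    dataset_effect_alleles: Sequence[str] | None = None,
) -> LDMatrix:
    """Pearson LD from an individuals × variants dosage matrix in [0, 2].

    Columns whose panel counting allele differs from the dataset's effect
    allele are flipped (d → 2 − d) so the matrix is effect-allele oriented.
    Missing dosages (NaN) are mean-imputed per variant.
    """
    d = np.array(dosages, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need an individuals × variants matrix with ≥ 2 individuals")
    if d.shape[1] != len(variant_keys):
        raise ValueError("number of dosage columns does not match variant list")
    if panel_effect_alleles is not None and dataset_effect_alleles is not None:
        flip = np.array(
            [p != t for p, t in zip(panel_effect_alleles, dataset_effect_alleles)]
        )
        d[:, flip] = 2.0 - d[:, flip]
    col_mean = np.nanmean(d, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(d))
    d[nan_rows, nan_cols] = col_mean[nan_cols]
    var = d.var(axis=0)
    if np.any(var == 0):
        bad = [variant_keys[i] for i in np.flatnonzero(var == 0)]
        raise MonomorphicVariantError(f"zero dosage variance for variant(s): {bad[:5]}")
    r = np.corrcoef(d, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(list(variant_keys), r, n_ref=d.shape[0])


def _greedy_clump(
    keys: Sequence[str],
    pvalues: np.ndarray,
    betas: np.ndarray,
    ld: LDMatrix,
    r2_threshold: float,
) -> list[str]:
    """Retain variants in p-value order whose r² with all retained ≤ threshold.

    Ties in p break on larger |beta|, then lexicographic key, making the
    output independent of input record order.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    sub = ld.subset(keys)
    r2 = sub.r**2
    order = sorted(
        range(len(keys)), key=lambda i: (pvalues[i], -abs(betas[i]), keys[i])
    )
    retained: list[int] = []
    for i in order:
        if all(r2[i, j] <= r2_threshold for j in retained):
            retained.append(i)
    kept = set(retained)
    return [k for i, k in enumerate(keys) if i in kept]


def clump(
    dataset: SummaryDataset, ld: LDMatrix, r2_threshold: float
) -> SummaryDataset:
    """LD-clump a dataset on its exposure p-values at the given r² threshold."""
    df = dataset.df
    kept = _greedy_clump(
        list(df["key"]),
        df["pvalue"].to_numpy(),
        df["beta"].to_numpy(),
        ld,
        r2_threshold,
    )
    return dataset.subset(kept)


# ---------------------------------------------------------------------------
# external formats


def read_regions(path: str | Path, flank_bp: int = 1_000) -> list[GeneRegion]:
    """Read gene regions from BED3+name or a (gene, chrom, start, stop) table.

    BED input (detected by a ``.bed`` suffix or a headerless first line) is
    0-based half-open and converted to 1-based inclusive coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    is_bed = path.suffix.lower() == ".bed"
    header_tokens = first.replace(",", "\t").split("\t")
    has_header = any(t.lower() in ("gene", "gene_name", "chrom", "start") for t in header_tokens)
    sep = "\t" if "\t" in first else r"[,\s]+"
    regions = []
    if is_bed or not has_header:
        tbl = pd.read_csv(path, sep=sep, header=None, comment="#", engine="python")
        for _, row in tbl.iterrows():
            chrom, start0, stop, name = str(row[0]), int(row[1]), int(row[2]), str(row[3])
            regions.append(GeneRegion(name, chrom, start0 + 1, stop, flank_bp))
    else:
        tbl = pd.read_csv(path, sep=sep, comment="#", engine="python")
        tbl.columns = [c.lower() for c in tbl.columns]
        gene_col = "gene" if "gene" in tbl.columns else "gene_name"
        for _, row in tbl.iterrows():
            regions.append(
                GeneRegion(
                    str(row[gene_col]), str(row["chrom"]),
                    int(row["start"]), int(row["stop"]), flank_bp,
                )
            )
    return regions


def read_ld_matrix(path: str | Path, n_ref: int = 0) -> LDMatrix:
    """Square delimited text with a header row of variant keys."""
    tbl = pd.read_csv(path, sep=None, engine="python", index_col=None)
    keys = [str(c) for c in tbl.columns]
    return LDMatrix(keys, tbl.to_numpy(dtype=float), n_ref)


def write_ld_matrix(ld: LDMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, columns=ld.variant_keys).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def read_dosages(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Individuals × variants dosage table with a header row of variant keys."""
    tbl = pd.read_csv(path, sep=None, engine="python")
    return tbl.to_numpy(dtype=float), [str(c) for c in tbl.columns]


def vcf_to_dosages(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read biallelic SNP genotypes from an (uncompressed) VCF as ALT dosages.

    Returns (individuals × variants dosage matrix, variant keys, counted
    alleles).  Missing genotypes become NaN; multiallelic or non-SNP records
    are skipped.
    """
    from ._alleles import VALID_ALLELES, variant_key

    keys: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _vid, ref, alt = f[0], int(f[1]), f[2], f[3].upper(), f[4].upper()
            if "," in alt or ref not in VALID_ALLELES or alt not in VALID_ALLELES:
                continue
            gts = []
            for sample in f[9:]:
                gt = sample.split(":", 1)[0].replace("|", "/")
                if "." in gt:
                    gts.append(np.nan)
                else:
                    gts.append(sum(int(a) for a in gt.split("/")))
            keys.append(variant_key(chrom, pos, ref, alt))
            alts.append(alt)
            cols.append(np.array(gts, dtype=float))
    if not cols:
        return np.empty((0, 0)), [], []
    return np.column_stack(cols), keys, alts
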