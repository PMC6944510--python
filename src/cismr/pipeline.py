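"""End-to-end orchestration: merge → select → harmonize → clump → estimate → pool.

A run mirrors the canonical cis-MR workflow: exposure sources are appended
with largest-n de-duplication, restricted to a gene region (or used
genome-wide), harmonized separately against each outcome sample, LD-clumped
on the harmonized variant set, estimated with the requested methods, and
the per-outcome estimates pooled by fixed-effects meta-analysis before
conversion to presentation odds ratios.  All randomness (the weighted-median
bootstrap) derives from the run seed, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import estimators
from .estimators import EggerDiagnostics, MREstimate
from .exceptions import CisMRError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet, harmonize
from .instruments import (
    GeneRegion,
    LDMatrix,
    _greedy_clump,
    ld_from_panel,
    read_dosages,
    read_ld_matrix,
    select_region_variants,
)
from .meta import MetaResult, meta_fixed, present_or
from .sumstats import (
    SummaryDataset,
    apply_exclusion_list,
    merge_exposure_sources,
    read_exclusion_list,
    read_summary_stats,
)

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "pc_givw")


@dataclass
class RunConfig:
    """Parameters of one analysis run; defaults mirror the primary analysis
    (±1 kb flank, clumping at r² ≤ 0.6, κ = 0.99, OR per SD lower exposure)."""

    exposure_paths: list[str]
    outcome_paths: list[tuple[str, str]]  # (label, path)
    output_dir: str
    region: GeneRegion | str = "genome_wide"
    flank_bp: int = 1_000
    r2_threshold: float = 0.6
    kappa: float = 0.99
    methods: tuple[str, ...] = DEFAULT_METHODS
    direction: str = "per_sd_lower"
    exclusion_path: str | None = None
    ld_matrix_path: str | None = None
    ld_panel_path: str | None = None
    seed: int = 0
    n_boot: int = 1_000
    exposure_trait_scale: str = "sd_units"
    clump_stage: str = "after_harmonization"  # or "exposure"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be non-empty")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        region = raw.get("region", "genome_wide")
        if isinstance(region, dict):
            raw["region"] = GeneRegion(
                gene_name=region.get("gene_name", region.get("gene", "region")),
                chrom=str(region["chrom"]),
                start=int(region["start"]),
                stop=int(region["stop"]),
                flank_bp=int(region.get("flank_bp", raw.get("flank_bp", 1_000))),
            )
        raw["outcome_paths"] = [tuple(x) for x in raw["outcome_paths"]]
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


@dataclass
class RunResult:
    estimates: pd.DataFrame  # per outcome × method, with OR columns
    egger_diagnostics: pd.DataFrame
    meta: pd.DataFrame  # per method
    stage_counts: dict
    harmonized: dict[str, HarmonizedSet]
    output_dir: Path


def _stage(name: str):
    """Attach the failing stage's name to any pipeline error."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CisMRError):
                exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _ctx()


def clump_harmonized(
    h: HarmonizedSet, ld: LDMatrix, r2_threshold: float
) -> HarmonizedSet:
    """LD-clump a harmonized set on the exposure p-values."""
    kept = _greedy_clump(
        h.keys,
        h.df["p_x"].to_numpy(),
        h.df["gamma"].to_numpy(),
        ld,
        r2_threshold,
    )
    return h.subset(kept)


def _estimate_row(est: MREstimate, label: str, direction: str) -> dict:
    por = present_or(est.theta, est.se, direction)
    d = {"outcome": label, **est.as_dict()}
    d.update(
        {"or_point": por.or_point, "or_low": por.or_low, "or_high": por.or_high,
         "or_direction": direction}
    )
    return d


def run_region_analysis(config: RunConfig) -> RunResult:
    """Execute the full pipeline for one gene region (or genome-wide set)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    with _stage("merge"):
        sources = [
            read_summary_stats(
                p, trait_name="exposure", trait_scale=config.exposure_trait_scale
            )
            for p in config.exposure_paths
        ]
        exposure = merge_exposure_sources(sources)
    counts["merged"] = exposure.n_variants

    if config.exclusion_path:
        with _stage("exclusion"):
            exposure = apply_exclusion_list(
                exposure, read_exclusion_list(config.exclusion_path)
            )
    counts["after_exclusion"] = exposure.n_variants

    if isinstance(config.region, GeneRegion):
        with _stage("region_selection"):
            region = dataclasses.replace(config.region, flank_bp=config.flank_bp)
            exposure = select_region_variants(exposure, region)
    counts["region_selected"] = exposure.n_variants

    with _stage("ld"):
        if config.ld_matrix_path:
            ld = read_ld_matrix(config.ld_matrix_path)
        elif config.ld_panel_path:
            dosages, keys = read_dosages(config.ld_panel_path)
            ld = ld_from_panel(dosages, keys)
        else:
            logger.warning("no LD source given; assuming uncorrelated variants")
            ld = LDMatrix.identity(list(exposure.df["key"]))

    if config.clump_stage == "exposure":
        with _stage("clump"):
            from .instruments import clump as _clump

            exposure = _clump(exposure, ld, config.r2_threshold)
        counts["exposure_clumped"] = exposure.n_variants

    est_rows: list[dict] = []
    diag_rows: list[dict] = []
    per_method: dict[str, list[tuple[str, MREstimate]]] = {m: [] for m in config.methods}
    harmonized: dict[str, HarmonizedSet] = {}

    for label, path in config.outcome_paths:
        with _stage(f"harmonize[{label}]"):
            outcome = read_summary_stats(
                path, trait_name=label, trait_scale="log_odds"
            )
            h = harmonize(exposure, outcome)
            h.write_audit(outdir / f"audit_{label}.tsv")
        counts[f"harmonized_{label}"] = h.n_variants

        if config.clump_stage == "after_harmonization":
            with _stage(f"clump[{label}]"):
                h = clump_harmonized(h, ld, config.r2_threshold)
        counts[f"clumped_{label}"] = h.n_variants
        harmonized[label] = h

        with _stage(f"estimate[{label}]"):
            for method in config.methods:
                try:
                    if method in ("egger", "egger_slope"):
                        est, diag = estimators.egger(h)
                        diag_rows.append(
                            {
                                "outcome": label,
                                "intercept": diag.intercept,
                                "intercept_se": diag.intercept_se,
                                "intercept_p": diag.intercept_p,
                                "i2_gx_pct": 100.0 * diag.i2_gx,
                            }
                        )
                    else:
                        est = estimators.estimate(
                            h, method, ld=ld, kappa=config.kappa,
                            n_boot=config.n_boot, seed=config.seed,
                        )
                except InsufficientInstrumentsError as err:
                    logger.warning("%s/%s skipped: %s", label, method, err)
                    continue
                est_rows.append(_estimate_row(est, label, config.direction))
                per_method[method].append((label, est))

            try:
                estimators.funnel_data(h).to_csv(
                    outdir / f"funnel_{label}.tsv", sep="\t", index=False,
                    float_format="%.17g",
                )
                if h.n_variants >= 2:
                    estimators.leave_one_out(h, "ivw").to_csv(
                        outdir / f"leave_one_out_{label}.tsv", sep="\t", index=False,
                        float_format="%.17g",
                    )
            except (ZeroDivisionError, InsufficientInstrumentsError):
                pass
        counts[f"modeled_{label}"] = h.n_variants

    meta_rows = []
    for method, pairs in per_method.items():
        if not pairs:
            continue
        with _stage(f"meta[{method}]"):
            mr: MetaResult = meta_fixed(pairs)
            por = present_or(mr.theta_meta, mr.se_meta, config.direction)
        row = {"method": method, **mr.as_dict()}
        row.update(
            {"or_point": por.or_point, "or_low": por.or_low, "or_high": por.or_high,
             "or_direction": config.direction}
        )
        meta_rows.append(row)

    estimates = pd.DataFrame(est_rows)
    diagnostics = pd.DataFrame(diag_rows)
    meta_tbl = pd.DataFrame(meta_rows)
    estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False, float_format="%.17g")
    diagnostics.to_csv(
        outdir / "egger_diagnostics.tsv", sep="\t", index=False, float_format="%.17g"
    )
    meta_tbl.to_csv(outdir / "meta.tsv", sep="\t", index=False, float_format="%.17g")

    manifest = {
        "config": _config_dict(config),
        "stage_counts": counts,
        "provenance": exposure.provenance,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return RunResult(
        estimates=estimates,
        egger_diagnostics=diagnostics,
        meta=meta_tbl,
        stage_counts=counts,
        harmonized=harmonized,
        output_dir=outdir,
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(config.region, GeneRegion):
        d["region"] = dataclasses.asdict(config.region)
    return d
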