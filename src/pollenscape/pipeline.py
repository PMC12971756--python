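"""Top-level pipeline: landcover + field tables in, model comparison out.

Stages: classify habitat -> clip local landscapes -> label patches ->
connectivity metrics -> response variables (pollen-pool diversity,
pollinator composition, pass-through biparental inbreeding) -> AICc
model comparison with Akaike weights and summed factor weights.  A run
manifest (config digest, seed, library versions, per-stage record
counts) makes every run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    DEFAULT_ALPHA,
    DEFAULT_GAP_THRESHOLD,
    DEFAULT_LAMBDA,
    DEFAULT_RADIUS,
    compute_metric_suite,
)
from .genetics import infer_pollen_haplotype, pool_pollen, response_table
from .io import (
    SchemaError,
    metrics_to_frame,
    read_captures,
    read_genotypes,
    read_landcover,
    read_responses,
    read_sites,
    write_table,
)
from .models import FACTORS, compare_all, summed_factor_weights


@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run."""

    landcover: str
    sites: str
    genotypes: str
    captures: str | None = None
    responses: str | None = None
    outdir: str = "out"
    alpha: float = DEFAULT_ALPHA
    lam: float = DEFAULT_LAMBDA
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    radius: float = DEFAULT_RADIUS
    neighbourhood: int = 8
    merge_years: bool = True
    ambiguous_policy: str = "half"  # 'half' or 'exclude'
    on_incompatible: str = "error"  # or 'missing'
    rng_seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, log=print) -> dict:
    """Execute the full analysis; returns the paths of the written outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    log("reading landcover and sites")
    landcover = read_landcover(config.landcover)
    sites = read_sites(config.sites)
    counts["sites"] = len(sites)

    log("computing connectivity metrics")
    all_metrics = []
    for site in sites:
        all_metrics.extend(
            compute_metric_suite(
                landcover,
                site,
                alpha=config.alpha,
                lam=config.lam,
                gap_threshold=config.gap_threshold,
                radius=config.radius,
                neighbourhood=config.neighbourhood,
            )
        )
    metrics_df = metrics_to_frame(all_metrics)
    counts["metrics"] = len(metrics_df)
    write_table(metrics_df, outdir / "metrics.csv")

    log("inferring pollen haplotypes")
    records = read_genotypes(config.genotypes)
    counts["genotyped_individuals"] = len(records)
    mothers = {r.genotype.individual_id: r for r in records if r.mother_id is None}
    haps_by_site: dict[str, list] = {}
    for r in records:
        if r.mother_id is None:
            continue
        if r.mother_id not in mothers:
            raise SchemaError(f"seed {r.genotype.individual_id}: unknown mother {r.mother_id}")
        hap = infer_pollen_haplotype(
            mothers[r.mother_id].genotype, r.genotype, config.on_incompatible
        )
        # merge_years pools a site's years together; otherwise each
        # (site, year) forms its own pool keyed site@year
        key = r.site_id if config.merge_years else f"{r.site_id}@{r.year}"
        haps_by_site.setdefault(key, []).append(hap)
    pools = pool_pollen(haps_by_site, include_ambiguous=config.ambiguous_policy == "half")
    counts["pollen_haplotypes"] = sum(len(p.haplotypes) for p in pools.values())

    captures = read_captures(config.captures) if config.captures else None
    tm = read_responses(config.responses) if config.responses else None
    responses = response_table(pools, captures, tm)
    counts["response_sites"] = len(responses)
    write_table(responses, outdir / "responses.csv")

    log("comparing models")
    comparison = compare_all(responses, metrics_df)
    counts["models"] = len(comparison)
    write_table(comparison, outdir / "comparison.csv")

    factor_weights: dict[str, dict[str, dict[str, float]]] = {}
    local = comparison[comparison["scale"] == "local"]
    for response, grp in local.groupby("response"):
        factor_weights[response] = {
            f: summed_factor_weights(grp, f) for f in FACTORS
        }
    (outdir / "factor_weights.json").write_text(json.dumps(factor_weights, indent=1))

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "rng_seed": config.rng_seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "record_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log(f"wrote outputs to {outdir}")
    return {
        "metrics": outdir / "metrics.csv",
        "responses": outdir / "responses.csv",
        "comparison": outdir / "comparison.csv",
        "factor_weights": outdir / "factor_weights.json",
        "manifest": outdir / "manifest.json",
    }
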