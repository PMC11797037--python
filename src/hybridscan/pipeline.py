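"""End-to-end orchestration: VCF (or simulation) in, analysis tables out.

Stages: polarize -> genome/windowed D per triplet -> split windows ->
enriched regions -> folded profile -> per-bin ancestry (when hybrid roles
are configured).  Every output table carries the run-config hash in its
comment header; the machine-readable manifest records the config, seed,
versions and removal counters.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import scipy

from . import __version__, chromstruct, dstat, polarize, splits
from .config import DataError, RunConfig, config_hash
from .io import write_sites_table, write_table

__all__ = ["run_pipeline", "PipelineError"]

_GAMMA_FORMULA = (
    "gamma_hat = (c1 - c0) / ((c1 - c0) + (c2 - c0)); "
    "c1=#(hybrid,parent1) c2=#(hybrid,parent2) c0=#(parent1,parent2) splits per bin; "
    "count-ratio estimator, not a likelihood-based gamma"
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, vcf_path: str, out_dir: str) -> dict:
    """Run every analysis stage on ``vcf_path`` and write tables under
    ``out_dir``.  Returns the manifest dict (also written as manifest.json)."""
    os.makedirs(out_dir, exist_ok=True)
    cfg_text = json.dumps(_config_dict(config), indent=1, sort_keys=True)
    chash = config_hash(cfg_text)
    comments = [f"config_hash={chash}"]
    manifest: dict = {
        "config": _config_dict(config),
        "config_hash": chash,
        "seed": config.seed,
        "versions": {
            "hybridscan": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "counters": {},
        "outputs": [],
    }

    def emit(name: str) -> str:
        path = os.path.join(out_dir, name)
        manifest["outputs"].append(name)
        return path

    taxa_cfg = polarize.TaxaConfig(ingroup=config.ingroup, outgroups=config.outgroups)

    stage = "read_vcf"
    try:
        genotypes = polarize.read_vcf(vcf_path, taxa_cfg)
        contig_lengths = genotypes.attrs.get("contig_lengths", {})
        manifest["counters"]["read_vcf"] = genotypes.attrs.get("filter_counts", {})

        stage = "site_filters"
        if config.min_depth > 0 or config.snp_cluster_count > 0:
            genotypes, counters = polarize.apply_site_filters(
                genotypes,
                taxa_cfg.taxa,
                min_depth=config.min_depth,
                snp_cluster_window=config.snp_cluster_window,
                snp_cluster_count=config.snp_cluster_count,
            )
            manifest["counters"]["site_filters"] = counters

        stage = "polarize"
        result = polarize.polarize_sites(genotypes, config.ingroup, config.outgroups)
        sites = result.sites
        manifest["counters"]["polarize"] = result.removed
        write_sites_table(
            sites, emit("sites.tsv"), config.ingroup, contig_lengths, comments
        )
        if not len(sites):
            raise DataError("no polarized sites survive filtering")

        stage = "dstat"
        genome_rows = []
        for t in config.triplets:
            res = dstat.genome_d(sites, t)
            genome_rows.append(
                {
                    "p1": t.p1,
                    "p2": t.p2,
                    "p3": t.p3,
                    "n_bbaa": res.n_bbaa,
                    "n_abba": res.n_abba,
                    "n_baba": res.n_baba,
                    "d": res.d,
                }
            )
            wd = dstat.windowed_d(sites, t, window_n=config.d_window, level=config.level)
            write_table(
                wd,
                emit(f"dstat_windows.{t.p1}-{t.p2}-{t.p3}.tsv"),
                comments + [f"window_n={config.d_window} level={config.level}"],
            )
        if genome_rows:
            write_table(pd.DataFrame(genome_rows), emit("dstat_genome.tsv"), comments)

        stage = "splits"
        win = splits.split_windows(
            sites,
            config.ingroup,
            window_n=config.split_window,
            step=config.split_step,
            alpha=config.alpha,
            bonferroni=config.bonferroni,
        )
        write_table(
            win,
            emit("split_windows.tsv"),
            comments
            + [f"window_n={config.split_window} step={config.split_step} alpha={config.alpha}"
               f" bonferroni={config.bonferroni}"],
        )
        regions = splits.region_segmentation(win, config.ingroup, config.min_region_windows)
        write_table(
            regions, emit("split_regions.tsv"), comments + [f"min_windows={config.min_region_windows}"]
        )

        stage = "folded_profile"
        if contig_lengths:
            bins, smooth = chromstruct.folded_profile(
                sites, contig_lengths, config.ingroup, n_bins=config.n_bins
            )
            write_table(bins, emit("folded_bins.tsv"), comments)
            write_table(smooth, emit("folded_smooth.tsv"), comments)

        stage = "ancestry"
        if config.hybrid_roles is not None and contig_lengths:
            h, p1, p2 = config.hybrid_roles
            anc = chromstruct.ancestry_by_bin(
                sites, h, p1, p2, contig_lengths, config.ingroup, n_bins=config.n_bins
            )
            write_table(
                anc.table,
                emit("ancestry_bins.tsv"),
                comments + [f"hybrid={h} parent1={p1} parent2={p2}", _GAMMA_FORMULA],
            )
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, e) from e

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["triplets"] = [[t.p1, t.p2, t.p3] for t in config.triplets]
    return d
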