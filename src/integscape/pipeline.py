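"""End-to-end orchestration: filter -> controls -> enrichment -> gene context
-> motif -> flexibility, with a single master seed and a JSON run report.

Per-stage randomness is derived by stable hashing of (master seed, stage
name), so any stage can be rerun in isolation and reproduce the full-run
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from . import (
    feature_enrichment,
    gene_context,
    genomic_core,
    matched_controls,
    sequence_profile,
    site_filtering,
)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """All inputs, thresholds and sampling parameters for one full run.

    Threshold and sampling defaults: selected sets keep sites with > 50
    fragments, unselected sets >= 7 (>= 50
    when a restriction recognition site lies within 20 bp), 1000 control
    replicates drawn from a pool of one million 50-bp random locations, gene
    assignment 5 kb upstream of the TSS, and 1-kb TSS/TTS windows.
    """

    genome: str = ""
    sites: str = ""
    outdir: str = "integscape_out"
    genes: str | None = None
    tracks: list[str] = field(default_factory=list)
    expr: str | None = None
    mappability: str | None = None

    filter_mode: str = "selected"          # selected | unselected
    selected_gt: int = 50
    unselected_ge: int = 7
    re_ge: int = 50
    re_window: int = 20

    control_mode: str = "uniform"          # uniform | re_matched
    n_sets: int = 1000
    pool_size: int = 1_000_000
    site_len: int = 50

    upstream_bp: int = 5000
    window_bp: int = 1000
    bin_bp: int = 50
    zga_index: int = 2

    layout: str = "transposon_tsd"         # transposon_tsd | point_integration
    n_flex_sets: int = 100                 # control replicates for profiles
    seed: int = 0

    def validate(self) -> None:
        for name in ("selected_gt", "unselected_ge", "re_ge", "re_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.filter_mode not in ("selected", "unselected"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.control_mode not in ("uniform", "re_matched"):
            raise ValueError(f"unknown control_mode {self.control_mode!r}")
        if self.layout not in sequence_profile.LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.window_bp <= 0 or self.bin_bp <= 0:
            raise ValueError("window_bp and bin_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def write_controls(controls: matched_controls.ControlSetCollection, outdir) -> None:
    """One BED per replicate plus a JSON manifest (mode, seed, keys)."""
    os.makedirs(outdir, exist_ok=True)
    for i, s in enumerate(controls.sets):
        genomic_core.write_bed(
            genomic_core.FeatureTrack(f"control_{i:04d}", s),
            os.path.join(outdir, f"control_{i:04d}.bed"),
        )
    manifest = {
        "mode": controls.mode,
        "seed": controls.seed,
        "n_sets": controls.n_sets,
        "set_size": len(controls.sets[0]) if controls.sets else 0,
        "keys": (
            [[k.enzyme, k.distance] for k in controls.keys]
            if controls.keys else None
        ),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_controls(outdir) -> matched_controls.ControlSetCollection:
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    sets = []
    for i in range(manifest["n_sets"]):
        track = genomic_core.read_bed(
            os.path.join(outdir, f"control_{i:04d}.bed"))
        sets.append(track.intervals)
    keys = None
    if manifest.get("keys"):
        keys = [matched_controls.SiteMatchKey(e, d) for e, d in manifest["keys"]]
    return matched_controls.ControlSetCollection(
        sets=sets, seed=manifest["seed"], mode=manifest["mode"], keys=keys,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written to
    ``outdir/report.json``)."""
    config.validate()
    for path in [config.genome, config.sites] + list(config.tracks):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def out(name):
        return os.path.join(config.outdir, name)

    genome = genomic_core.read_fasta(config.genome)
    sites = genomic_core.read_sites(config.sites)

    # --- filter
    if config.filter_mode == "selected":
        kept, filt = site_filtering.filter_selected(sites, config.selected_gt)
    else:
        kept, filt = site_filtering.filter_unselected(
            sites, genome, window_bp=config.re_window,
            threshold_ge=config.unselected_ge, re_threshold_ge=config.re_ge,
        )
    genomic_core.write_sites(kept, out("kept.tsv"))
    report["stages"]["filter"] = dataclasses.asdict(filt)
    if not kept:
        raise RuntimeError("stage filter: no sites pass the fragment-count filter")

    # --- controls
    ctrl_seed = stage_seed(config.seed, "controls")
    if config.control_mode == "uniform":
        mappability = (
            genomic_core.read_bed(config.mappability, "mappability")
            if config.mappability else None
        )
        controls = matched_controls.uniform_controls(
            genome, mappability, set_size=len(kept), n_sets=config.n_sets,
            site_len=config.site_len, pool_size=config.pool_size,
            seed=ctrl_seed,
        )
    else:
        index = matched_controls.RestrictionIndex.build(genome)
        controls = matched_controls.re_matched_controls(
            kept, index, genome, n_sets=config.n_sets, seed=ctrl_seed,
        )
    write_controls(controls, out("controls"))
    report["stages"]["controls"] = {
        "mode": controls.mode, "n_sets": controls.n_sets, "seed": ctrl_seed,
    }

    # --- enrichment panel
    tracks = [genomic_core.read_bed(p) for p in config.tracks]
    if tracks:
        panel = feature_enrichment.enrichment_panel(kept, controls, tracks)
        panel.to_csv(out("enrichment.tsv"), sep="\t", index=False)
        report["stages"]["enrichment"] = {"n_features": len(tracks)}
    chrom_df = feature_enrichment.chromosome_distribution(kept, controls)
    chrom_df.to_csv(out("chromosome_distribution.tsv"), sep="\t", index=False)

    # --- gene context
    if config.genes:
        genes = genomic_core.read_genes_gff(config.genes)
        assignments = gene_context.assign_to_genes(
            kept, genes, upstream_bp=config.upstream_bp)
        import pandas as pd

        pd.DataFrame(
            [dataclasses.asdict(a) | {"regions": ",".join(a.regions)}
             for a in assignments]
        ).to_csv(out("assignments.tsv"), sep="\t", index=False)
        meta = [a.metagene_pct for a in assignments if a.metagene_pct is not None]
        import numpy as np

        hist, edges = np.histogram(meta, bins=20, range=(0, 100))
        pd.DataFrame({"pct_lo": edges[:-1], "pct_hi": edges[1:], "count": hist}
                     ).to_csv(out("metagene.tsv"), sep="\t", index=False)
        for anchor in ("TSS", "TTS"):
            prof = gene_context.anchor_profile(
                kept, genes, anchor, config.window_bp, config.bin_bp)
            prof.to_csv(out(f"{anchor.lower()}_profile.tsv"), sep="\t",
                        index=False)
        report["stages"]["gene_context"] = {
            "n_assignments": len(assignments),
            "n_intergenic": len(kept) - len({a.site_index for a in assignments}),
        }
        if config.expr:
            expr = gene_context.read_expression(config.expr, config.zga_index)
            ctrl_assign = [
                gene_context.assign_to_genes(
                    s, genes, upstream_bp=config.upstream_bp,
                    downstream_bp=config.upstream_bp)
                for s in controls.sets[: min(controls.n_sets, 50)]
            ]
            expr_assign = gene_context.assign_to_genes(
                kept, genes, upstream_bp=config.upstream_bp,
                downstream_bp=config.upstream_bp)
            assoc = gene_context.expression_association(
                expr_assign, expr, ctrl_assign)
            assoc.to_csv(out("expression_association.tsv"), sep="\t")

    # --- motif
    windows = sequence_profile.extract_flank_windows(kept, genome, config.layout)
    report["stages"]["motif"] = {
        "n_windows": len(windows.windows), "n_excluded": windows.n_excluded,
    }
    if windows.windows:
        pwm = sequence_profile.position_matrix(windows)
        df = pwm.probs.copy()
        df["bits"] = pwm.bits
        df.to_csv(out("pwm.tsv"), sep="\t")

        # --- flexibility profiles
        table = sequence_profile.step_table()
        ctrl_windows = sequence_profile.control_flank_windows(
            controls.sets[: min(config.n_flex_sets, controls.n_sets)],
            genome, config.layout,
        )
        for parameter in sequence_profile.PARAMETERS:
            prof = sequence_profile.flexibility_profile(
                windows, table, parameter, ctrl_windows)
            div = sequence_profile.profile_divergence(
                prof, min_replicates=min(30, len(ctrl_windows)))
            div.to_csv(out(f"flex_{parameter.lower()}.tsv"), sep="\t",
                       index=False)
        report["stages"]["flexibility"] = {
            "n_control_sets": len(ctrl_windows),
            "parameters": list(sequence_profile.PARAMETERS),
        }

    report["seeds"] = {
        stage: stage_seed(config.seed, stage) for stage in ("controls",)
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
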