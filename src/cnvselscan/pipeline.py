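"""End-to-end orchestration: merge -> QC -> windowed scan -> candidates ->
annotation -> cohort statistics -> PCA, with a reproducible run manifest.

Every stage writes its table into the output directory; the manifest
records parameters, input checksums and per-stage record counts, so two
runs on identical inputs and configuration produce identical artifacts
(the manifest timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as annot
from . import io as svio
from . import merge as svmerge
from . import popgen, qc, scan, stats

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    panel: str
    annotation: str
    out_dir: str
    merge: svmerge.MergeThresholds = field(default_factory=svmerge.MergeThresholds)
    qc: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    window_size: int = 100_000
    step: int = 10_000
    scan: scan.ScanConfig = field(default_factory=scan.ScanConfig)
    flank_bp: int = 1000
    yates: bool = True
    alpha: float = 0.05
    n_components: int = 2
    plots: bool = False
    skip_merge: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "merge" in kwargs:
            kwargs["merge"] = svmerge.MergeThresholds(**kwargs["merge"])
        if "qc" in kwargs:
            kwargs["qc"] = qc.QcThresholds(**kwargs["qc"])
        if "scan" in kwargs:
            kwargs["scan"] = scan.ScanConfig(**kwargs["scan"])
        try:
            return cls(**kwargs)
        except TypeError as e:
            raise ValueError(f"bad pipeline config: {e}") from e


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _chrom_lengths_from_records(records) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in records:
        out[r.chrom] = max(out.get(r.chrom, 0), r.end + 1)
    return out


def run_pipeline(
    config: PipelineConfig,
    chrom_lengths: dict[str, int] | None = None,
) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "tool": "cnvselscan",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "parameters": {
            "merge": asdict(config.merge),
            "qc": asdict(config.qc),
            "window_size": config.window_size,
            "step": config.step,
            "scan": asdict(config.scan),
            "flank_bp": config.flank_bp,
            "yates": config.yates,
            "alpha": config.alpha,
            "n_components": config.n_components,
            "seed": config.seed,
        },
        "inputs": {
            k: {"path": p, "sha256": _sha256(p)}
            for k, p in (
                ("vcf", config.vcf),
                ("panel", config.panel),
                ("annotation", config.annotation),
            )
        },
        "stages": {},
    }

    def _out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    panel = svio.read_panel(config.panel)
    records = svio.read_sv_vcf(config.vcf, panel)
    manifest["stages"]["input"] = {"records": len(records), "samples": panel.n}

    if config.skip_merge:
        merged_records = list(records)
    else:
        merged = svmerge.merge_population(records, config.merge)
        merged_records = [m.representative for m in merged]
        svmerge.merge_report_frame(merged).to_csv(
            _out("merge_report.tsv"), sep="\t", index=False
        )
        svio.write_sv_vcf(merged_records, panel, _out("merged.vcf"),
                          chrom_lengths)
    manifest["stages"]["merge"] = {"records": len(merged_records)}

    passing, report = qc.apply_filters(merged_records, config.qc)
    report.to_frame().to_csv(_out("qc_report.tsv"), sep="\t", index=False)
    svio.write_sv_vcf(passing, panel, _out("qc.vcf"), chrom_lengths)
    manifest["stages"]["qc"] = {
        "records": len(passing),
        "removed": report.removed_by_filter,
    }
    log.info("qc: %d -> %d records", report.input_count, report.output_count)

    grid = popgen.WindowGrid(
        config.window_size, config.step,
        chrom_lengths or _chrom_lengths_from_records(passing),
    )
    sites = popgen.site_table(passing, panel)
    sites.to_csv(_out("sites.tsv"), sep="\t", index=False)
    windows = popgen.window_table(passing, panel, grid, sites=sites)
    windows.to_csv(_out("windows.tsv"), sep="\t", index=False)
    manifest["stages"]["popgen"] = {
        "windows": len(windows),
        "windows_with_fst": int(windows["fst"].notna().sum()),
        "windows_with_ratio": int(windows["log2_ratio"].notna().sum()),
    }

    selected = scan.select_windows(windows, config.scan)
    selected.to_csv(_out("selected_windows.tsv"), sep="\t", index=False)
    genes = svio.read_annotation(config.annotation)
    loci = scan.windows_to_loci(selected, passing)
    candidates = scan.filter_candidates(loci, genes)
    scan.loci_frame(candidates).to_csv(
        _out("candidates.tsv"), sep="\t", index=False
    )
    manifest["stages"]["scan"] = {
        "selected_windows": len(selected),
        "loci_in_windows": len(loci),
        "candidates": len(candidates),
        "candidate_genes": sorted({g for l in candidates for g in l.genes}),
    }

    calls = annot.annotate_records(passing, genes, flank_bp=config.flank_bp)
    annot.calls_frame(calls).to_csv(_out("annotation.tsv"), sep="\t", index=False)
    if calls:
        annot.feature_summary(calls).rename("proportion").to_csv(
            _out("feature_summary.tsv"), sep="\t"
        )
    manifest["stages"]["annotate"] = {"calls": len(calls)}

    freqs = stats.group_frequencies(passing, panel)
    freqs.to_csv(_out("group_frequencies.tsv"), sep="\t", index=False)
    spectrum = stats.frequency_spectrum(freqs)
    spectrum.to_frame().to_csv(_out("spectrum.tsv"), sep="\t", index=False)
    stats.chrom_distribution_tests(
        passing, panel, alpha=config.alpha, yates=config.yates
    ).to_csv(_out("chrom_tests.tsv"), sep="\t", index=False)
    if passing:
        stats.bin_fisher_tests(spectrum).to_csv(
            _out("fisher_bins.tsv"), sep="\t", index=False
        )
    manifest["stages"]["stats"] = {"variants": len(passing)}

    if passing:
        coords, var_exp = stats.grm_pca(passing, panel, config.n_components)
        coords.to_csv(_out("pca.tsv"), sep="\t", index=False)
        manifest["stages"]["pca"] = {
            "variance_explained": [float(v) for v in var_exp]
        }

    if config.plots:
        manifest["plots"] = scan.manhattan_plots(
            windows, _out("manhattan")
        )

    with open(_out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
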