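"""One-command orchestration: filter -> map -> scan-del -> annotate.

The run directory receives filtered.tsv, profiles.tsv, interval.bed,
dels.bed, report.tsv, map.png and manifest.json; the manifest records the
config hash, seed, and per-stage record counts so a run is auditable and a
rerun with the same config and seed reproduces the machine outputs
byte-identically (the plot excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .af_map import (CandidateInterval, call_candidate_interval, homozygous_candidates,
                     loess_smooth, plot_profiles, window_means)
from .candidates import annotate_nearest_gene, candidate_gene_report
from .mm_filter import FilterConfig, filtered_to_rows, mutmap_filter
from .sv_scan import ScanConfig, scan_deletions
from .vcfio import (SampleRoles, read_bed, read_depth_tsv, read_gff, read_gff_exons,
                    read_vcf, write_bed)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    roles: SampleRoles
    out_dir: str = "mutmap_run"
    depth_tracks: dict[str, str] = field(default_factory=dict)  # role -> TSV path
    gff: str | None = None
    gene_list: list[str] = field(default_factory=list)
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    window_size: int = 1_000_000
    span: float = 0.2
    peak_min: float = 0.9
    edge: float = 0.75
    promoter_bp: int = 2000
    seed: int = 0
    make_plot: bool = True
    chrom_lengths: list[tuple[str, int]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["roles"] = SampleRoles(**raw["roles"])
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "scan" in raw:
            raw["scan"] = ScanConfig(**raw["scan"])
        if "chrom_lengths" in raw and raw["chrom_lengths"] is not None:
            raw["chrom_lengths"] = [tuple(x) for x in raw["chrom_lengths"]]
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = json.dumps(
            {k: str(v) for k, v in sorted(vars(self).items()) if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    out_dir: Path
    interval: CandidateInterval | None
    manifest: dict


def run_pipeline(cfg: RunConfig) -> RunResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mutmapkit",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    stage = "filter"
    try:
        variants = list(read_vcf(cfg.vcf, cfg.roles))
        result = mutmap_filter(variants, cfg.roles, cfg.filter)
        filtered = result.kept
        pd.DataFrame(filtered_to_rows(filtered)).to_csv(
            out / "filtered.tsv", sep="\t", index=False
        )
        manifest["stages"]["filter"] = {
            "n_input": len(variants),
            "n_kept": len(filtered),
            "rejections": result.tallies,
        }

        stage = "map"
        profiles = window_means(
            filtered, window_size=cfg.window_size, chrom_lengths=cfg.chrom_lengths
        )
        profiles = loess_smooth(profiles, span=cfg.span)
        pd.DataFrame(
            [
                {
                    "chrom": p.chrom, "window_start": p.window_start,
                    "window_end": p.window_end, "n_variants": p.n_variants,
                    "mean_af_f2mut": p.mean_af_f2mut, "mean_af_f2wt": p.mean_af_f2wt,
                    "smooth_af_f2mut": p.smooth_af_f2mut,
                    "smooth_af_f2wt": p.smooth_af_f2wt,
                }
                for p in profiles
            ]
        ).to_csv(out / "profiles.tsv", sep="\t", index=False)
        call = call_candidate_interval(profiles, peak_min=cfg.peak_min, edge=cfg.edge)
        interval = call.interval
        write_bed(
            [(interval.chrom, interval.start, interval.end)] if interval else [],
            out / "interval.bed",
        )
        hom = homozygous_candidates(filtered, interval)
        pd.DataFrame(filtered_to_rows(hom)).to_csv(
            out / "hom_candidates.tsv", sep="\t", index=False
        )
        manifest["stages"]["map"] = {
            "n_input": len(filtered),
            "n_windows": len(profiles),
            "diagnostic": call.diagnostic,
            "interval": (
                {"chrom": interval.chrom, "start": interval.start, "end": interval.end,
                 "peak_pos": interval.peak_pos, "peak_value": interval.peak_value}
                if interval else None
            ),
            "n_hom_candidates": len(hom),
        }
        if cfg.make_plot:
            plot_profiles(profiles, out / "map.png", interval=interval)

        stage = "scan-del"
        deletions = []
        if cfg.depth_tracks:
            tracks = {
                role: read_depth_tsv(path, sample=role)
                for role, path in cfg.depth_tracks.items()
            }
            region = None
            track0 = next(iter(tracks.values()))
            if interval and interval.chrom == track0.chrom:
                region = (
                    interval.chrom,
                    max(interval.start, track0.start),
                    min(interval.end, track0.end),
                )
            deletions = scan_deletions(tracks, cfg.scan, region=region)
        write_bed([(d.chrom, d.start, d.end) for d in deletions], out / "dels.bed")
        manifest["stages"]["scan_del"] = {
            "n_tracks": len(cfg.depth_tracks),
            "n_calls": len(deletions),
        }

        stage = "annotate"
        if cfg.gff:
            genes = read_gff(cfg.gff)
            exons = read_gff_exons(cfg.gff)
            targets = [g for g in genes if not cfg.gene_list or g.gene_id in cfg.gene_list]
            listed = [
                gid for gid in cfg.gene_list
                if gid not in {g.gene_id for g in genes}
            ]
            report = candidate_gene_report(
                filtered, deletions, targets, annotated_genes=genes,
                promoter_bp=cfg.promoter_bp, exons=exons,
            )
            if listed:
                report = pd.concat(
                    [report, pd.DataFrame(
                        [{"gene_id": gid, "coding": 0, "intron": 0, "promoter": 0,
                          "deletions": 0, "verdict": "not found"} for gid in listed]
                    )],
                    ignore_index=True,
                )
            report.to_csv(out / "report.tsv", sep="\t", index=False)
            annos = [
                annotate_nearest_gene((fv.chrom, fv.pos), genes,
                                      promoter_bp=cfg.promoter_bp, exons=exons)
                for fv in hom
            ]
            manifest["stages"]["annotate"] = {
                "n_genes": len(genes),
                "n_report_rows": len(report),
                "hom_candidate_annotations": [
                    {"pos": f"{a.target_chrom}:{a.target_start}", "gene": a.gene_id,
                     "distance": a.distance, "region": a.region}
                    for a in annos
                ],
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["candidate_found"] = interval is not None
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RunResult(out_dir=out, interval=interval, manifest=manifest)
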