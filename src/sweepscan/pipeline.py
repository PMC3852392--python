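"""End-to-end orchestration of the genome-scan analysis.

Binds the stages together for a two-lineage divergent-selection design:
QC -> allele counts -> windowed heterozygosity profiles -> between-lineage
difference profiles at two generations -> change profile -> empirical drift
threshold -> sweep regions -> timeline calls -> Fisher divergence scans and
the ordered -log p regression -> heterozygosity-loss table -> haplotype
blocks.  Panels are addressed by subgroup *role* (HWS40, ..., LWR9), which
is explicit configuration, never inferred from file names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import divergence as dv
from . import haploblocks as hb
from . import hetloss as hl
from . import io as pio
from . import sweep as sw
from .panel import GenotypeMatrix
from .sweep import SUBGROUPS, HetProfile, ScanConfig, SweepRegion

logger = logging.getLogger(__name__)

#: (earlier, later) ordered pairs of the heterozygosity-loss table
HETLOSS_PAIRS = (
    ("HWS40", "HWS53"),
    ("HWS40", "HWR9"),
    ("LWS40", "LWS53"),
    ("LWS40", "LWR9"),
)

#: divergence scans of each relaxed line against its ancestral selected line
DIVERGENCE_PAIRS = {"HW": ("HWS40", "HWR9"), "LW": ("LWS40", "LWR9")}


@dataclass
class SweepScanResult:
    profiles: dict[str, HetProfile]
    diff_t1: np.ndarray
    diff_t2: np.ndarray
    change: np.ndarray
    cuts: tuple[float, float]
    regions: list[SweepRegion]


def sweep_scan(
    panels: Mapping[str, GenotypeMatrix],
    cfg: ScanConfig | None = None,
    classify: bool = True,
) -> SweepScanResult:
    """Heterozygosity change scan between lineages at generations 40 and 53.

    ``panels`` maps subgroup roles to genotype panels; HWS40/LWS40 and
    HWS53/LWS53 are required, all eight roles are needed for timeline calls.
    """
    cfg = cfg or ScanConfig()
    needed = ("HWS40", "LWS40", "HWS53", "LWS53")
    missing = [r for r in needed if r not in panels]
    if missing:
        raise ValueError(f"missing required subgroup panels: {missing}")
    profiles = {role: sw.population_profile(p, cfg) for role, p in panels.items()}
    diff_t1 = sw.profile_difference(profiles["HWS40"], profiles["LWS40"])
    diff_t2 = sw.profile_difference(profiles["HWS53"], profiles["LWS53"])
    change = sw.profile_change(diff_t1, diff_t2)
    n_markers = next(iter(panels.values())).n_markers
    cuts = sw.empirical_threshold(change, cfg, n_markers)
    regions = sw.call_regions(change, cuts, profiles["HWS40"])
    if classify and all(r in profiles for r in SUBGROUPS):
        regions = [
            sw.SweepRegion(
                r.chromosome, r.start_bp, r.end_bp, r.direction, r.peak_value,
                r.window_indices, r.first_marker_index, r.last_marker_index,
                r.window_values, timeline=sw.classify_timeline(r, profiles, cfg),
            )
            for r in regions
        ]
    return SweepScanResult(profiles, diff_t1, diff_t2, change, cuts, regions)


def run_full_analysis(
    panels: Mapping[str, GenotypeMatrix],
    outdir: str | Path,
    scan_cfg: ScanConfig | None = None,
    alpha_fisher: float = 0.05,
    max_missing: int = 10,
    stages: Sequence[str] = ("qc", "scan", "divergence", "hetloss", "blocks"),
    block_min_span_bp: int = 5_000_000,
    block_max_pair_bp: int = 10_000_000,
) -> dict:
    """Run the selected stages and write all exports plus a summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan_cfg = scan_cfg or ScanConfig()
    summary: dict = {"stages": list(stages)}
    panels = dict(panels)

    if "qc" in stages:
        roles = list(panels)
        filtered, removed = pio.qc_filter_missing(list(panels.values()), max_missing)
        panels = dict(zip(roles, filtered))
        summary["qc"] = {
            "max_missing": max_missing,
            "n_removed": len(removed),
            "n_retained": filtered[0].n_markers if filtered else 0,
        }
        pio.write_frequency_table(list(panels.values()), outdir / "allele_freqs.tsv")

    if "scan" in stages:
        res = sweep_scan(panels, scan_cfg)
        sw.profiles_to_tsv(list(res.profiles.values()), outdir / "het_profiles.tsv")
        sw.regions_to_bed(res.regions, outdir / "sweep_regions.bed")
        sw.regions_to_tsv(res.regions, outdir / "sweep_regions.tsv")
        summary["scan"] = {
            "window_size": scan_cfg.window_size,
            "cuts": [round(c, 8) for c in res.cuts],
            "n_regions": len(res.regions),
            "regions": [
                {
                    "chrom": r.chromosome, "start_bp": r.start_bp, "end_bp": r.end_bp,
                    "direction": r.direction,
                    "rule": r.timeline.rule if r.timeline else None,
                    "lineage": r.timeline.lineage if r.timeline else None,
                    "onset": r.timeline.onset_interval if r.timeline else None,
                    "fixation": r.timeline.fixation_interval if r.timeline else None,
                }
                for r in res.regions
            ],
        }

    if "divergence" in stages:
        scans = {}
        for lineage, (sel, rel) in DIVERGENCE_PAIRS.items():
            if sel in panels and rel in panels:
                scans[lineage] = dv.scan_pair(panels[sel], panels[rel], alpha_fisher)
                dv.scan_to_tsv(scans[lineage], panels[sel], outdir / f"fisher_{lineage}.tsv")
        summary["divergence"] = {
            lineage: {
                "pair": s.pair, "n_tests": s.n_tests,
                "threshold": s.threshold, "n_significant": s.n_significant,
            }
            for lineage, s in scans.items()
        }
        if {"HW", "LW"} <= scans.keys():
            slope, se = dv.ordered_logp_regression(scans["HW"], scans["LW"])
            summary["divergence"]["ordered_logp_regression"] = {
                "x": scans["HW"].pair, "y": scans["LW"].pair,
                "slope": round(slope, 6), "stderr": round(se, 8),
            }

    if "hetloss" in stages:
        rows = []
        for earlier, later in HETLOSS_PAIRS:
            if earlier in panels and later in panels:
                rows.append(hl.mean_het_loss(panels[earlier], panels[later],
                                             unit="marker", cfg=scan_cfg))
        hl.hetloss_table(rows, outdir / "het_loss.tsv")
        summary["hetloss"] = [
            {"pair": s.pair, "mean_change": round(s.mean_change, 6),
             "se": round(s.uncertainty, 6)}
            for s in rows
        ]

    if "blocks" in stages:
        summary["blocks"] = {}
        for role in ("HWS40", "LWS40", "HWS50", "LWS50"):
            if role not in panels:
                continue
            blocks = hb.call_blocks(panels[role], max_pair_bp=block_max_pair_bp)
            large = hb.filter_large_blocks(blocks, min_span_bp=block_min_span_bp)
            hb.blocks_to_bed(blocks, outdir / f"blocks_{role}.bed")
            hb.blocks_to_tsv(large, role, outdir / f"blocks_large_{role}.tsv")
            summary["blocks"][role] = {
                "n_blocks": len(blocks), "n_large": len(large),
                "large": [
                    {"chrom": b.chromosome,
                     "start_Mb": round(b.start_bp / 1e6, 2),
                     "stop_Mb": round(b.end_bp / 1e6, 2)}
                    for b in large
                ],
            }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
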