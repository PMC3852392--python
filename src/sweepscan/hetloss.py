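"""Genome-wide mean heterozygosity change between two sampled generations.

The summary mirrors a loss-over-time table for selected and relaxed
sub-lines: mean over genome units of Hz(later) - Hz(earlier), negative when
variability was lost.  Because neighbouring markers are correlated through
linkage, the uncertainty is the standard error of the mean computed over
*non-overlapping* W-marker windows rather than over single markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import allele_counts
from .panel import GenotypeMatrix
from .sweep import ScanConfig, marker_het_from_m


@dataclass(frozen=True)
class HetLossSummary:
    pair: str
    mean_change: float      # later minus earlier; negative = loss
    uncertainty: float      # SE of the mean over non-overlapping windows
    n_units: int
    unit: str

    def __post_init__(self) -> None:
        if abs(self.mean_change) > 0.5 + 1e-12:
            raise ValueError("|mean_change| cannot exceed 0.5")


def mean_het_loss(
    earlier: GenotypeMatrix,
    later: GenotypeMatrix,
    unit: str = "marker",
    cfg: ScanConfig | None = None,
) -> HetLossSummary:
    """Mean per-unit Hz change between two panels on a shared marker map.

    ``unit`` is ``"marker"`` (mean over markers of the per-marker change) or
    ``"window"`` (mean over non-overlapping W-marker windows of the windowed
    change).  Markers undefined (uncalled) in either population are excluded
    pairwise.  Either way the SE is computed over non-overlapping windows to
    discount LD-induced correlation between markers.
    """
    cfg = cfg or ScanConfig()
    if earlier.n_markers != later.n_markers:
        raise ValueError("panels on different marker maps")
    hz_e = marker_het_from_m(allele_counts(earlier).m)
    hz_l = marker_het_from_m(allele_counts(later).m)
    change = hz_l - hz_e
    ok = ~np.isnan(change)
    if not np.any(ok):
        raise ValueError("no marker callable in both panels")

    W = cfg.window_size
    win_means = _window_means(change, W)
    if unit == "marker":
        mean_change = float(np.mean(change[ok]))
        n_units = int(np.count_nonzero(ok))
    elif unit == "window":
        if win_means.size == 0:
            raise ValueError(f"fewer than {W} markers: no complete window")
        mean_change = float(np.mean(win_means))
        n_units = int(win_means.size)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if win_means.size > 1:
        se = float(np.std(win_means, ddof=1) / np.sqrt(win_means.size))
    else:
        se = float("nan")
    return HetLossSummary(
        pair=f"{earlier.population_id} to {later.population_id}",
        mean_change=mean_change, uncertainty=se, n_units=n_units, unit=unit,
    )


def _window_means(change: np.ndarray, W: int) -> np.ndarray:
    """Means of non-overlapping W-marker windows, skipping NaN markers."""
    n_full = len(change) // W
    out = []
    for k in range(n_full):
        block = change[k * W:(k + 1) * W]
        block = block[~np.isnan(block)]
        if block.size:
            out.append(block.mean())
    return np.asarray(out)


def hetloss_table(summaries, path) -> None:
    """TSV with one row per ordered population pair."""
    import pandas as pd

    pd.DataFrame([
        {
            "pair": s.pair,
            "mean_change": round(s.mean_change, 6),
            "se": round(s.uncertainty, 6),
            "n_units": s.n_units,
            "unit": s.unit,
        }
        for s in summaries
    ]).to_csv(path, sep="\t", index=False)
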