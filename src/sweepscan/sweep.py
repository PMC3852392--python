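"""Sliding-window heterozygosity genome scan for selective sweeps.

The scan works on expected heterozygosity Hz = 2m(1-m), where m is the major
allele frequency of a biallelic marker, averaged in a sliding window of W
consecutive markers per chromosome.  Pairwise *differences* of two
populations' windowed profiles, and *changes* of those differences between
two sampling generations, are compared against an empirically calibrated
drift null: a normal distribution with the mean and SD of the observed
genome-wide change distribution, cut at a two-sided family-wise level that is
Bonferroni-corrected for the number of non-overlapping W-marker windows
needed to cover the genome (ceil(n_markers / W)).  Runs of significant
windows are merged into candidate sweep regions, and the pattern of fixation
across the eight sampled subgroups of a divergent-selection design (selected
high/low lines at three generations plus a relaxed line split off in
between) dates the onset and fixation of each sweep to an interval of the
sampling grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io import allele_counts
from .panel import GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

#: Subgroup roles of the two-lineage design, in sampling order.
SUBGROUPS = ("HWS40", "HWS50", "HWS53", "HWR9", "LWS40", "LWS50", "LWS53", "LWR9")


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the sweep scan.

    ``window_size`` is in markers (not bp).  ``alpha`` is the family-wise
    two-sided error rate of the empirical drift null.  ``fixation_threshold``
    is the windowed-Hz level below which a region counts as fixed in a
    subgroup; ``reduced_fraction`` sets the "reduced but not fixed" level as
    a fraction of that subgroup's genome-wide median windowed Hz.
    """

    window_size: int = 100
    step: int = 1
    alpha: float = 0.05
    fixation_threshold: float = 0.01
    reduced_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window_size):
            raise ValueError("need 1 <= step <= window_size")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class HetProfile:
    """Windowed expected-heterozygosity profile of one population."""

    population_id: str
    window_size: int
    step: int
    chromosome: np.ndarray      # per window
    first_index: np.ndarray     # global marker index of first marker in window
    last_index: np.ndarray      # global marker index of last marker (inclusive)
    start_bp: np.ndarray
    end_bp: np.ndarray
    hz: np.ndarray              # windowed mean Hz, NaN if no defined marker

    @property
    def n_windows(self) -> int:
        return len(self.hz)

    @property
    def mid_bp(self) -> np.ndarray:
        return (self.start_bp + self.end_bp) // 2

    def same_grid(self, other: "HetProfile") -> bool:
        return (
            self.window_size == other.window_size
            and self.step == other.step
            and self.n_windows == other.n_windows
            and np.array_equal(self.first_index, other.first_index)
            and np.array_equal(self.chromosome, other.chromosome)
        )


@dataclass(frozen=True)
class TimelineCall:
    """Dating of a sweep on the sampling grid of the selection design."""

    rule: str                       # 'a'..'e'
    lineage: str                    # 'HW', 'LW', 'both', 'pre-divergence', 'none'
    onset_interval: str             # e.g. '(40,45]', '<=40', 'none'
    fixation_interval: str          # e.g. '(45,50]', 'not fixed'
    states: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class SweepRegion:
    """A merged run of significant windows."""

    chromosome: str
    start_bp: int
    end_bp: int
    direction: str                  # 'loss' or 'gain' of heterozygosity
    peak_value: float
    window_indices: tuple[int, ...]
    first_marker_index: int
    last_marker_index: int
    window_values: tuple[float, ...] = ()
    timeline: TimelineCall | None = None


def marker_het(m) -> np.ndarray | float:
    """Expected heterozygosity Hz = 1 - (m^2 + (1-m)^2) = 2m(1-m).

    ``m`` is the major allele frequency; the formula is symmetric so any
    allele frequency in [0, 1] is accepted.  NaN propagates (undefined
    markers).  Values outside [0, 1] are a hard error.
    """
    arr = np.asarray(m, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if np.any(bad):
        raise ValueError(f"allele frequency outside [0, 1]: {arr[bad].flat[0]}")
    hz = 1.0 - (arr**2 + (1.0 - arr) ** 2)
    return float(hz) if np.isscalar(m) else hz


def panel_marker_het(panel: GenotypeMatrix) -> np.ndarray:
    """Per-marker Hz of one population (NaN where no calls)."""
    return marker_het_from_m(allele_counts(panel).m)


def marker_het_from_m(m: np.ndarray) -> np.ndarray:
    hz = np.full(len(m), np.nan)
    ok = ~np.isnan(m)
    hz[ok] = marker_het(m[ok])
    return hz


def window_profile(
    het: np.ndarray,
    markers: MarkerMap,
    cfg: ScanConfig,
    population_id: str = "",
) -> HetProfile:
    """Sliding mean of per-marker Hz, per chromosome, window of W markers.

    Markers with undefined Hz (NaN) are excluded from a window's mean and the
    divisor reduced accordingly; a window with no defined marker is NaN.
    Chromosomes with fewer than W markers are skipped with a warning.
    Windows never span a chromosome boundary.
    """
    het = np.asarray(het, dtype=float)
    if len(het) != markers.n_markers:
        raise ValueError("het vector length does not match marker map")
    W, step = cfg.window_size, cfg.step
    chroms, firsts, lasts, starts, ends, means = [], [], [], [], [], []
    for chrom, sl in markers.chrom_slices().items():
        n = sl.stop - sl.start
        if n < W:
            logger.warning("chromosome %s has %d < %d markers; skipped", chrom, n, W)
            continue
        h = het[sl]
        valid = ~np.isnan(h)
        vals = np.where(valid, h, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        ccnt = np.concatenate([[0], np.cumsum(valid)])
        starts_local = np.arange(0, n - W + 1, step)
        s = csum[starts_local + W] - csum[starts_local]
        c = ccnt[starts_local + W] - ccnt[starts_local]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        chroms.append(np.full(len(starts_local), chrom, dtype=object))
        firsts.append(starts_local + sl.start)
        lasts.append(starts_local + sl.start + W - 1)
        starts.append(markers.position_bp[sl][starts_local])
        ends.append(markers.position_bp[sl][starts_local + W - 1])
        means.append(mean)
    if not chroms:
        empty_i = np.zeros(0, dtype=np.int64)
        return HetProfile(population_id, W, step, np.zeros(0, dtype=object),
                          empty_i, empty_i, empty_i, empty_i, np.zeros(0))
    return HetProfile(
        population_id, W, step,
        np.concatenate(chroms), np.concatenate(firsts), np.concatenate(lasts),
        np.concatenate(starts), np.concatenate(ends), np.concatenate(means),
    )


def population_profile(panel: GenotypeMatrix, cfg: ScanConfig) -> HetProfile:
    """Windowed Hz profile straight from a genotype panel."""
    return window_profile(panel_marker_het(panel), panel.markers, cfg, panel.population_id)


def profile_difference(a: HetProfile, b: HetProfile) -> np.ndarray:
    """Per-window Hz(a) - Hz(b); the two profiles must share the window grid."""
    if not a.same_grid(b):
        raise ValueError("profiles computed on different window grids")
    return a.hz - b.hz


def profile_change(diff_t1: np.ndarray, diff_t2: np.ndarray) -> np.ndarray:
    """Change of a windowed difference between two generations: diff_t2 - diff_t1."""
    diff_t1, diff_t2 = np.asarray(diff_t1, float), np.asarray(diff_t2, float)
    if diff_t1.shape != diff_t2.shape:
        raise ValueError("difference vectors on mismatched window grids")
    return diff_t2 - diff_t1


def n_independent_windows(n_markers: int, window_size: int) -> int:
    """Number of non-overlapping W-marker windows needed to cover the genome."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return -(-n_markers // window_size)  # ceil


def empirical_threshold(
    change: np.ndarray, cfg: ScanConfig, n_markers: int
) -> tuple[float, float]:
    """Two-sided significance cuts from the empirical drift null.

    Fits a normal to the genome-wide window-change distribution (its observed
    mean and SD) and returns the quantiles at per-tail probability
    (alpha/2) / n_indep, where n_indep = ceil(n_markers / W) counts
    non-overlapping windows.  The pooled fit assumes most of the genome
    drifts neutrally, which makes the null slightly conservative wherever
    true sweeps inflate the SD.
    """
    change = np.asarray(change, dtype=float)
    change = change[~np.isnan(change)]
    if change.size == 0:
        raise ValueError("empty change vector")
    n_indep = n_independent_windows(n_markers, cfg.window_size)
    q = (cfg.alpha / 2.0) / n_indep
    mu = float(np.mean(change))
    sigma = float(np.std(change, ddof=1)) if change.size > 1 else 0.0
    if sigma == 0.0:
        raise ValueError("degenerate null: zero variance in change vector")
    z = norm.ppf(q)
    return (mu + sigma * z, mu - sigma * z)


def call_regions(
    change: np.ndarray,
    cuts: tuple[float, float],
    grid: HetProfile,
) -> list[SweepRegion]:
    """Merge consecutive significant windows into sweep regions.

    Windows strictly below the lower cut (heterozygosity loss) or strictly
    above the upper cut (gain) are flagged; adjacent flagged windows of the
    same sign on one chromosome merge into a region spanning the first
    window's first marker to the last window's last marker.  Ties at exactly
    the cut value are not flagged.
    """
    lower, upper = cuts
    change = np.asarray(change, dtype=float)
    if len(change) != grid.n_windows:
        raise ValueError("change vector does not match window grid")
    with np.errstate(invalid="ignore"):
        sign = np.where(change < lower, -1, np.where(change > upper, 1, 0))
    sign[np.isnan(change)] = 0
    regions: list[SweepRegion] = []
    i = 0
    n = len(sign)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and sign[j + 1] == sign[i]
            and grid.chromosome[j + 1] == grid.chromosome[i]
        ):
            j += 1
        block = slice(i, j + 1)
        vals = change[block]
        peak = float(vals.min() if sign[i] < 0 else vals.max())
        regions.append(
            SweepRegion(
                chromosome=str(grid.chromosome[i]),
                start_bp=int(grid.start_bp[i]),
                end_bp=int(grid.end_bp[j]),
                direction="loss" if sign[i] < 0 else "gain",
                peak_value=peak,
                window_indices=tuple(range(i, j + 1)),
                first_marker_index=int(grid.first_index[i]),
                last_marker_index=int(grid.last_index[j]),
                window_values=tuple(float(v) for v in vals),
            )
        )
        i = j + 1
    return _merge_overlapping(regions)


def _merge_overlapping(regions: list[SweepRegion]) -> list[SweepRegion]:
    """Merge flagged runs of the same sign whose marker spans overlap (sliding
    windows can produce bp-overlapping runs separated by unflagged windows)."""
    out: list[SweepRegion] = []
    for r in regions:
        if (
            out
            and out[-1].chromosome == r.chromosome
            and out[-1].direction == r.direction
            and r.first_marker_index <= out[-1].last_marker_index
        ):
            prev = out[-1]
            peak = (min(prev.peak_value, r.peak_value) if r.direction == "loss"
                    else max(prev.peak_value, r.peak_value))
            out[-1] = SweepRegion(
                prev.chromosome, prev.start_bp, max(prev.end_bp, r.end_bp),
                prev.direction, peak,
                prev.window_indices + r.window_indices,
                prev.first_marker_index,
                max(prev.last_marker_index, r.last_marker_index),
                prev.window_values + r.window_values,
            )
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Timeline classification
# ---------------------------------------------------------------------------

def _region_state(region: SweepRegion, profile: HetProfile, cfg: ScanConfig) -> str:
    """Classify one subgroup's state over a sweep region.

    The statistic is the *minimum* windowed Hz across the region's windows —
    the depth of the profile dip.  A merged significant region includes
    partially swept flank windows whose higher Hz would dilute a mean, while
    the fixation pattern that dates a sweep is carried by the deepest part of
    the dip (a region is "fixed" in a subgroup when its profile touches zero
    there).
    """
    idx = np.asarray(region.window_indices, dtype=int)
    if idx.max(initial=0) >= profile.n_windows:
        raise ValueError(
            f"region windows absent from profile of {profile.population_id!r}"
        )
    vals = profile.hz[idx]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(
            f"region has no defined windows in profile of {profile.population_id!r}"
        )
    dip_hz = float(np.min(vals))
    reduced_cut = cfg.reduced_fraction * float(np.nanmedian(profile.hz))
    if dip_hz < cfg.fixation_threshold:
        return "fixed"
    if dip_hz < reduced_cut:
        return "reduced"
    return "polymorphic"


def _lineage_rule(s40: str, s50: str, s53: str, sR9: str) -> tuple[str, str, str] | None:
    """Timeline rule for one lineage given its four subgroup states.

    Returns (rule, onset_interval, fixation_interval) or None if the lineage
    shows no dateable fixation.
    """
    if s40 == "polymorphic" and s50 == "fixed" and s53 == "fixed":
        if sR9 == "fixed":
            # fixation may predate the relaxed-line split: only onset is datable
            return ("b", "(40,45]", "(40,50]")
        if sR9 == "reduced":
            return ("c", "(40,45]", "(45,50]")
    if s40 == "polymorphic" and s50 == "polymorphic" and s53 == "fixed":
        return ("d", "(45,53]", "(50,53]")
    return None


def classify_timeline(
    region: SweepRegion,
    profiles: Mapping[str, HetProfile],
    cfg: ScanConfig,
) -> TimelineCall:
    """Date a sweep region from the fixation pattern across the 8 subgroups.

    The rule table follows the sampling design: selected lines sampled at
    generations 40, 50 and 53, and relaxed lines split off at generation 45
    and sampled 9 generations later.  A fixation present in all subgroups of
    both lineages predates generation 40 (rule a); present in X50/X53 and the
    relaxed line but not X40 places onset in (40,45] with fixation possibly
    predating the split (rule b); the same but with the relaxed line only
    *reduced* bounds fixation to (45,50] (rule c); fixation appearing only in
    X53 places it in (50,53] (rule d); anything else is "not fixed" (rule e).
    """
    missing = [g for g in SUBGROUPS if g not in profiles]
    if missing:
        raise ValueError(f"missing subgroup profiles: {missing}")
    states = {g: _region_state(region, profiles[g], cfg) for g in SUBGROUPS}

    hw = tuple(states[g] for g in ("HWS40", "HWS50", "HWS53", "HWR9"))
    lw = tuple(states[g] for g in ("LWS40", "LWS50", "LWS53", "LWR9"))

    if all(s == "fixed" for s in (hw[0], lw[0])):
        return TimelineCall("a", "both", "<=40", "<=40", states)

    hw_call = _lineage_rule(*hw)
    lw_call = _lineage_rule(*lw)
    if hw_call and lw_call:
        rule = hw_call[0] if hw_call[0] == lw_call[0] else "e"
        if rule != "e":
            return TimelineCall(rule, "both", hw_call[1], hw_call[2], states)
        return TimelineCall("e", "both", "none", "not fixed", states)
    if hw_call:
        return TimelineCall(hw_call[0], "HW", hw_call[1], hw_call[2], states)
    if lw_call:
        return TimelineCall(lw_call[0], "LW", lw_call[1], lw_call[2], states)
    return TimelineCall("e", "none", "none", "not fixed", states)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def profiles_to_tsv(profiles: Sequence[HetProfile], path) -> None:
    """TSV export: chrom, window start/end bp, one Hz column per population."""
    import pandas as pd

    base = profiles[0]
    data = {
        "chrom": base.chromosome,
        "win_start_bp": base.start_bp,
        "win_end_bp": base.end_bp,
    }
    for p in profiles:
        if not p.same_grid(base):
            raise ValueError("profiles on different window grids")
        data[f"Hz_{p.population_id}"] = np.round(p.hz, 6)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def regions_to_bed(regions: Sequence[SweepRegion], path) -> None:
    """BED export (0-based half-open) of sweep regions."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.direction}"
            if r.timeline is not None:
                name += f";rule={r.timeline.rule};lineage={r.timeline.lineage}"
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")


def regions_to_tsv(regions: Sequence[SweepRegion], path) -> None:
    """TSV export of regions with timeline calls."""
    import pandas as pd

    rows = []
    for r in regions:
        t = r.timeline
        rows.append({
            "chrom": r.chromosome,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "direction": r.direction,
            "peak_change": round(r.peak_value, 6),
            "n_windows": len(r.window_indices),
            "rule": t.rule if t else "",
            "lineage": t.lineage if t else "",
            "onset": t.onset_interval if t else "",
            "fixation": t.fixation_interval if t else "",
        })
    pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "direction",
                                "peak_change", "n_windows", "rule", "lineage",
                                "onset", "fixation"]).to_csv(path, sep="\t", index=False)
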