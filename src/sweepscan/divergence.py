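"""Per-marker Fisher exact tests of allele-frequency divergence.

Each marker contributes a 2x2 table of allele counts (rows = populations,
columns = alt/ref allele copies).  Two-sided p-values follow the standard
Fisher convention — the sum of hypergeometric probabilities of all tables
with the observed margins that are at most as probable as the observed one —
and are thresholded at a Bonferroni-corrected family-wise level alpha
divided by the number of markers actually tested.  A rank-ordered regression
of the two scans' -log10 p-values compares the *global* amount of divergence
accumulated by two population pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import statsmodels.api as sm
from scipy.stats import fisher_exact as _scipy_fisher

from .io import allele_counts
from .panel import GenotypeMatrix


@dataclass(frozen=True)
class DivergenceScan:
    """Genome-wide Fisher-exact scan between two populations."""

    pair: str
    p_values: np.ndarray          # NaN where untestable (no calls in a population)
    tested: np.ndarray            # boolean mask of tested markers
    threshold: float
    n_tests: int

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.tested & (self.p_values < self.threshold)

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.significant))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 count table.

    A table with a zero margin carries no information about association and
    returns p = 1 (see :func:`is_degenerate`).
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    return _fisher_cached(int(a), int(b), int(c), int(d))


def is_degenerate(table) -> bool:
    """True when a row or column margin is zero (test carries no information)."""
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    return 0 in (a + b, c + d, a + c, b + d)


@lru_cache(maxsize=1 << 20)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    if 0 in (a + b, c + d, a + c, b + d):
        return 1.0
    # p is invariant to swapping rows and to swapping columns: canonicalise to
    # boost the cache hit rate on genome scans, where tables repeat heavily.
    rows = sorted([(a, b), (c, d)])
    (a, b), (c, d) = rows
    if a + c > b + d:
        a, b, c, d = b, a, d, c
    return float(_scipy_fisher(np.array([[a, b], [c, d]]), alternative="two-sided")[1])


def bonferroni_cut(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def scan_pair(
    pop_a: GenotypeMatrix, pop_b: GenotypeMatrix, alpha: float = 0.05
) -> DivergenceScan:
    """Fisher exact test at every marker callable in both populations.

    The Bonferroni threshold uses the number of markers actually tested.
    Markers monomorphic for the same allele in both populations give p = 1
    and count toward n_tests.
    """
    ac_a, ac_b = allele_counts(pop_a), allele_counts(pop_b)
    tested = ac_a.defined & ac_b.defined
    n_tests = int(np.count_nonzero(tested))
    if n_tests == 0:
        raise ValueError("no testable markers (no marker called in both populations)")
    p = np.full(pop_a.n_markers, np.nan)
    idx = np.flatnonzero(tested)
    for j in idx:
        p[j] = _fisher_cached(
            int(ac_a.n_alt[j]), int(ac_a.n_total[j] - ac_a.n_alt[j]),
            int(ac_b.n_alt[j]), int(ac_b.n_total[j] - ac_b.n_alt[j]),
        )
    return DivergenceScan(
        pair=f"{pop_a.population_id}/{pop_b.population_id}",
        p_values=p, tested=tested,
        threshold=bonferroni_cut(alpha, n_tests), n_tests=n_tests,
    )


def ordered_logp_regression(
    scan_x: DivergenceScan,
    scan_y: DivergenceScan,
    log_base: float = 10.0,
    intercept: bool = True,
) -> tuple[float, float]:
    """Rank-for-rank OLS of sorted -log p-values: does pair y diverge more?

    Both scans' -log p-values are sorted descending and paired by rank; the
    slope of the OLS fit of y on x measures the global excess of divergence
    in pair y relative to pair x (slope > 1: y globally more diverged).
    Returns (slope, standard error of the slope).
    """
    x = np.sort(_neglogp(scan_x, log_base))[::-1]
    y = np.sort(_neglogp(scan_y, log_base))[::-1]
    if len(x) != len(y):
        raise ValueError(f"scans test different marker counts: {len(x)} vs {len(y)}")
    X = sm.add_constant(x) if intercept else x[:, None]
    fit = sm.OLS(y, X).fit()
    slope_idx = 1 if intercept else 0
    return float(fit.params[slope_idx]), float(fit.bse[slope_idx])


def _neglogp(scan: DivergenceScan, log_base: float) -> np.ndarray:
    p = scan.p_values[scan.tested]
    return -np.log(p) / np.log(log_base)


def scan_to_tsv(scan: DivergenceScan, panel: GenotypeMatrix, path) -> None:
    """TSV export: marker, position, p-value, significance flag."""
    import pandas as pd

    m = panel.markers
    pd.DataFrame({
        "marker_id": m.marker_id,
        "chrom": m.chromosome,
        "pos_bp": m.position_bp,
        "p_value": scan.p_values,
        "significant": scan.significant.astype(int),
    }).to_csv(path, sep="\t", index=False)
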