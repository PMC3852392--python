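"""Haplotype-block calling from unphased genotypes (Gabriel-style definition).

Pairwise linkage disequilibrium is summarised by |D'| with a confidence
interval obtained from the likelihood of the unphased genotype data profiled
over a |D'| grid (allele frequencies held at their sample estimates).  A
marker pair is in *strong LD* when the CI is (ci_low >= 0.70, ci_high >=
0.98), shows *strong evidence of historical recombination* when ci_high <
0.90, and is *uninformative* otherwise.  A block is a marker interval whose
outermost pair is strong-LD and in which at least 95% of informative pairs
are strong-LD; overlapping candidate blocks are resolved longest-first.
Pairs separated by more than a configurable physical distance (default
10 Mb) are never evaluated.

Two-locus haplotype frequencies come from an expectation-maximisation over
the double-heterozygote phase ambiguity; no genome-wide phasing is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import MISSING, GenotypeMatrix, MarkerMap

STRONG_LD_LOW = 0.70
STRONG_LD_HIGH = 0.98
RECOMB_HIGH = 0.90
INFORMATIVE_FRACTION = 0.95
MAF_FLOOR = 0.05
_DGRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class PairLD:
    i: int
    j: int
    d_prime: float
    ci_low: float
    ci_high: float
    klass: str        # 'strong_LD' | 'recombination' | 'uninformative'


@dataclass(frozen=True)
class HaploBlock:
    chromosome: str
    start_bp: int
    end_bp: int
    first_index: int
    last_index: int
    n_markers: int

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray | None:
    """3x3 genotype-pair count table over double-called individuals."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok].astype(np.int64), g2[ok].astype(np.int64)
    if len(g1) < 2:
        return None
    return np.bincount(g1 * 3 + g2, minlength=9).reshape(3, 3)


def _em_from_counts(counts: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    n = int(counts.sum())
    # fixed haplotype counts from unambiguous genotype pairs: when at most
    # one locus is heterozygous, the het alleles pair with the hom allele
    base = [0.0, 0.0, 0.0, 0.0]  # f00 f01 f10 f11
    for a in range(3):
        for b in range(3):
            c = int(counts[a, b])
            if c == 0 or (a == 1 and b == 1):
                continue
            alleles1 = (0, 1) if a == 1 else (a // 2, a // 2)
            alleles2 = (0, 1) if b == 1 else (b // 2, b // 2)
            for x, y in zip(alleles1, alleles2):
                base[2 * x + y] += c
    n_dh = int(counts[1, 1])
    two_n = 2.0 * n
    f0 = f1 = f2 = f3 = 0.25
    for _ in range(max_iter):
        cis = f0 * f3
        trans = f1 * f2
        tot = cis + trans
        p_cis = 0.5 if tot == 0.0 else cis / tot
        n0 = (base[0] + n_dh * p_cis) / two_n
        n1 = (base[1] + n_dh * (1.0 - p_cis)) / two_n
        n2 = (base[2] + n_dh * (1.0 - p_cis)) / two_n
        n3 = (base[3] + n_dh * p_cis) / two_n
        delta = max(abs(n0 - f0), abs(n1 - f1), abs(n2 - f2), abs(n3 - f3))
        f0, f1, f2, f3 = n0, n1, n2, n3
        if delta < tol:
            break
    return np.array([f0, f1, f2, f3])


def two_locus_em(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray | None:
    """ML haplotype frequencies [f00, f01, f10, f11] of two unphased markers.

    Index order: allele (0=ref, 1=alt) at locus 1, then locus 2.  Only the
    double-heterozygote phase is latent; all other genotype pairs resolve
    deterministically.  Returns None when fewer than two individuals are
    called at both markers.
    """
    counts = _pair_counts(g1, g2)
    if counts is None:
        return None
    return _em_from_counts(counts, tol, max_iter)


def d_prime(f: np.ndarray) -> float:
    """|D'| from haplotype frequencies [f00, f01, f10, f11]."""
    p1 = f[2] + f[3]
    p2 = f[1] + f[3]
    D = f[3] - p1 * p2
    if D >= 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    if dmax <= 0:
        return 0.0
    return abs(D) / dmax


def dprime_ci(
    g1: np.ndarray, g2: np.ndarray, i: int = 0, j: int = 1
) -> PairLD:
    """|D'| point estimate and likelihood-profile CI for one marker pair.

    The likelihood of the unphased genotype counts is evaluated on a 101-point
    |D'| grid with allele frequencies held at their sample values, normalised
    to a distribution, and the CI read off at the 5th and 95th percentiles.
    Pairs with minor allele frequency below the floor, or too few
    double-called individuals, are uninformative.
    """
    counts = _pair_counts(g1, g2)
    if counts is None:
        return PairLD(i, j, np.nan, np.nan, np.nan, "uninformative")
    f_hat = _em_from_counts(counts, 1e-8, 1000)
    p1 = f_hat[2] + f_hat[3]
    p2 = f_hat[1] + f_hat[3]
    if min(p1, 1 - p1) < MAF_FLOOR or min(p2, 1 - p2) < MAF_FLOOR:
        return PairLD(i, j, np.nan, np.nan, np.nan, "uninformative")
    dp_hat = d_prime(f_hat)
    sign = 1.0 if (f_hat[3] - p1 * p2) >= 0 else -1.0
    dmax = (min(p1 * (1 - p2), (1 - p1) * p2) if sign > 0
            else min(p1 * p2, (1 - p1) * (1 - p2)))

    D = sign * dmax * _DGRID
    f = np.clip(np.stack([
        (1 - p1) * (1 - p2) + D,
        (1 - p1) * p2 - D,
        p1 * (1 - p2) - D,
        p1 * p2 + D,
    ], axis=1), 1e-12, None)
    f /= f.sum(axis=1, keepdims=True)
    loglik = _genotype_loglik_grid(counts, f)
    w = np.exp(loglik - loglik.max())
    cdf = np.cumsum(w) / w.sum()
    ci_low = float(_DGRID[np.searchsorted(cdf, 0.05)])
    ci_high = float(_DGRID[np.searchsorted(cdf, 0.95)])
    if ci_low >= STRONG_LD_LOW and ci_high >= STRONG_LD_HIGH:
        klass = "strong_LD"
    elif ci_high < RECOMB_HIGH:
        klass = "recombination"
    else:
        klass = "uninformative"
    return PairLD(i, j, dp_hat, ci_low, ci_high, klass)


def _genotype_loglik_grid(counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Log-likelihood of a 3x3 genotype-pair count table under random union,
    for each row of haplotype-frequency matrix ``f`` (n_grid, 4)."""
    f00, f01, f10, f11 = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    p = {
        (0, 0): f00**2, (0, 2): f01**2, (2, 0): f10**2, (2, 2): f11**2,
        (0, 1): 2 * f00 * f01, (1, 0): 2 * f00 * f10,
        (2, 1): 2 * f10 * f11, (1, 2): 2 * f01 * f11,
        (1, 1): 2 * f00 * f11 + 2 * f01 * f10,
    }
    ll = np.zeros(f.shape[0])
    for (a, b), pab in p.items():
        c = counts[a, b]
        if c:
            ll += c * np.log(np.maximum(pab, 1e-300))
    return ll


def pairwise_ld(
    panel: GenotypeMatrix, max_pair_bp: int = 10_000_000
) -> list[PairLD]:
    """All within-chromosome PairLD for marker pairs closer than max_pair_bp."""
    out: list[PairLD] = []
    m = panel.markers
    for chrom, sl in m.chrom_slices().items():
        idx = range(sl.start, sl.stop)
        for i in idx:
            for j in range(i + 1, sl.stop):
                if m.position_bp[j] - m.position_bp[i] > max_pair_bp:
                    break
                out.append(dprime_ci(panel.calls[:, i], panel.calls[:, j], i, j))
    return out


def call_blocks(
    panel: GenotypeMatrix,
    max_pair_bp: int = 10_000_000,
    informative_fraction: float = INFORMATIVE_FRACTION,
) -> list[HaploBlock]:
    """Gabriel spanning rule: outermost pair strong-LD, >=95% of informative
    pairs inside strong-LD; overlapping candidates resolved longest-first."""
    m = panel.markers
    pairs = pairwise_ld(panel, max_pair_bp)

    # integral images over the (i, j) pair plane make the strong/informative
    # counts of any candidate interval O(1)
    M = m.n_markers
    strong = np.zeros((M, M), dtype=np.int32)
    info = np.zeros((M, M), dtype=np.int32)
    for p in pairs:
        if p.klass == "strong_LD":
            strong[p.i, p.j] = 1
            info[p.i, p.j] = 1
        elif p.klass == "recombination":
            info[p.i, p.j] = 1
    strong_c = strong.cumsum(axis=0).cumsum(axis=1)
    info_c = info.cumsum(axis=0).cumsum(axis=1)

    def rect(c, i, j):
        # pairs (a, b) with i <= a < b <= j (matrix is upper-triangular)
        total = c[j, j] - (c[i - 1, j] if i else 0)
        return int(total - (c[j, i - 1] - (c[i - 1, i - 1] if i else 0) if i else 0))

    candidates: list[tuple[int, int, int]] = []  # (span_bp, i, j)
    for p in pairs:
        i, j = p.i, p.j
        if p.klass != "strong_LD" or m.chromosome[i] != m.chromosome[j]:
            continue
        n_strong = rect(strong_c, i, j)
        n_info = rect(info_c, i, j)
        if n_info and n_strong / n_info >= informative_fraction:
            span = int(m.position_bp[j] - m.position_bp[i])
            candidates.append((span, i, j))

    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m.n_markers, dtype=bool)
    blocks: list[HaploBlock] = []
    for span, i, j in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        blocks.append(HaploBlock(
            chromosome=str(m.chromosome[i]),
            start_bp=int(m.position_bp[i]), end_bp=int(m.position_bp[j]),
            first_index=i, last_index=j, n_markers=j - i + 1,
        ))
    blocks.sort(key=lambda b: (b.chromosome, b.start_bp))
    return blocks


def filter_large_blocks(
    blocks: Sequence[HaploBlock], min_span_bp: int = 5_000_000
) -> list[HaploBlock]:
    """Blocks strictly larger than min_span_bp, sorted by chromosome then start."""
    return sorted(
        (b for b in blocks if b.span_bp > min_span_bp),
        key=lambda b: (b.chromosome, b.start_bp),
    )


def blocks_to_bed(blocks: Sequence[HaploBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start_bp - 1}\t{b.end_bp}\tn={b.n_markers}\n")


def blocks_to_tsv(blocks: Sequence[HaploBlock], population_id: str, path) -> None:
    """Table export: population, chromosome, start/stop in Mb."""
    import pandas as pd

    pd.DataFrame([
        {
            "population": population_id,
            "chrom": b.chromosome,
            "start_Mb": round(b.start_bp / 1e6, 2),
            "stop_Mb": round(b.end_bp / 1e6, 2),
            "n_markers": b.n_markers,
        }
        for b in blocks
    ]).to_csv(path, sep="\t", index=False)
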