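"""Core in-memory containers for genotype panels.

A *panel* is one population sample genotyped on a shared marker map.
Genotypes are stored as alt-allele dosage (0, 1, 2); a missing call is the
sentinel :data:`MISSING` (-1) and is never conflated with homozygous
reference.  All panels in one analysis share a single :class:`MarkerMap`
sorted by genome coordinate, so marker index `j` means the same site in
every population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Sentinel for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker metadata: id, chromosome, physical position, alleles.

    Positions are 1-based physical bp (MAP/VCF convention).  Markers must be
    strictly sorted by position within each chromosome, chromosomes must form
    contiguous runs, and no two markers may share a (chromosome, bp) pair.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_ref: np.ndarray
    allele_alt: np.ndarray
    position_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=object))
        object.__setattr__(self, "position_bp", np.asarray(self.position_bp, dtype=np.int64))
        object.__setattr__(self, "allele_ref", np.asarray(self.allele_ref, dtype=object))
        object.__setattr__(self, "allele_alt", np.asarray(self.allele_alt, dtype=object))
        if self.position_cM is not None:
            object.__setattr__(self, "position_cM", np.asarray(self.position_cM, dtype=float))
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "allele_ref", "allele_alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} has wrong length")
        if np.any(self.position_bp < 1):
            raise ValueError("position_bp must be >= 1 (1-based)")
        # chromosomes must be contiguous runs, positions strictly increasing within
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for i in range(n):
            chrom = self.chromosome[i]
            pos = int(self.position_bp[i])
            if chrom != prev_chrom:
                if chrom in seen:
                    raise ValueError(
                        f"markers not sorted: chromosome {chrom!r} appears in "
                        f"non-contiguous runs (marker {self.marker_id[i]!r})"
                    )
                seen.add(chrom)
                prev_chrom, prev_pos = chrom, -1
            if pos <= prev_pos:
                raise ValueError(
                    f"markers not sorted or duplicated at {chrom}:{pos} "
                    f"(marker {self.marker_id[i]!r})"
                )
            prev_pos = pos
        bad = self.allele_ref == self.allele_alt
        if np.any(bad):
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(f"allele_ref == allele_alt at marker {self.marker_id[j]!r}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome label -> contiguous index slice, in map order."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.chromosome[i] != self.chromosome[start]:
                out[self.chromosome[start]] = slice(start, i)
                start = i
        return out

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        mask = np.asarray(mask, dtype=bool)
        cm = self.position_cM[mask] if self.position_cM is not None else None
        return MarkerMap(
            self.marker_id[mask],
            self.chromosome[mask],
            self.position_bp[mask],
            self.allele_ref[mask],
            self.allele_alt[mask],
            cm,
        )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_markers


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid genotype calls for one population on a shared marker map.

    ``calls[i, j]`` is the alt-allele dosage of individual *i* at marker *j*
    in {0, 1, 2}, or :data:`MISSING`.
    """

    population_id: str
    individuals: tuple[str, ...]
    calls: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals", tuple(self.individuals))
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        if calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x markers)")
        if calls.shape != (len(self.individuals), self.markers.n_markers):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {self.markers.n_markers} markers"
            )
        valid = (calls == MISSING) | ((calls >= 0) & (calls <= 2))
        if not np.all(valid):
            raise ValueError("genotype calls must be in {0,1,2} or MISSING")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def missing_per_marker(self) -> np.ndarray:
        return np.count_nonzero(self.calls == MISSING, axis=0)

    def subset_markers(self, mask: np.ndarray, markers: MarkerMap | None = None) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        if markers is None:
            markers = self.markers.subset(mask)
        return GenotypeMatrix(self.population_id, self.individuals, self.calls[:, mask], markers)


@dataclass(frozen=True)
class AlleleCounts:
    """Per-marker allele counts for one population.

    ``n_total`` counts successfully called allele copies (2 per called
    individual); ``m`` is the major allele frequency in [0.5, 1], NaN where no
    calls exist.
    """

    n_alt: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_alt", np.asarray(self.n_alt, dtype=np.int64))
        object.__setattr__(self, "n_total", np.asarray(self.n_total, dtype=np.int64))
        if np.any(self.n_alt > self.n_total) or np.any(self.n_alt < 0):
            raise ValueError("need 0 <= n_alt <= n_total")

    @property
    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.n_alt / self.n_total
        return np.where(self.n_total > 0, f, np.nan)

    @property
    def m(self) -> np.ndarray:
        """Major allele frequency, NaN where undefined (no calls)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.maximum(self.n_alt, self.n_total - self.n_alt) / self.n_total
        return np.where(self.n_total > 0, m, np.nan)

    @property
    def defined(self) -> np.ndarray:
        return self.n_total > 0
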