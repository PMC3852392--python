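"""Reading, writing and QC of genotype panels.

Supported formats:

* PLINK ``.ped``/``.map`` (whitespace-delimited; the family id column is the
  population id).  The 4-column ``.map`` file carries no ref/alt designation,
  so :func:`write_panel` also writes a ``<prefix>.alleles`` sidecar
  (marker_id, ref, alt) which :func:`read_panel` picks up automatically; this
  makes PED round trips allele-exact.  Without a sidecar or an explicit
  :class:`~sweepscan.panel.MarkerMap`, the alt allele is taken to be the
  lexicographically greater of the two observed allele codes.
* VCF (plain text, biallelic SNPs only), read through :mod:`pysam`.  Sample to
  population assignment comes from a ``sample_populations`` mapping (or a
  two-column TSV path).

The QC filter reproduces a combined-dataset missingness screen: a marker is
dropped when its missing-call count, pooled over every individual of every
population, reaches ``max_missing``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import MISSING, AlleleCounts, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

_PED_MISSING = "0"


def allele_counts(panel: GenotypeMatrix) -> AlleleCounts:
    """Per-marker alt-allele counts and called-copy totals for one panel.

    Missing calls contribute nothing to either count, so ``n_total`` is twice
    the number of successfully called individuals at each marker.
    """
    calls = panel.calls
    called = calls != MISSING
    n_alt = np.where(called, calls, 0).sum(axis=0).astype(np.int64)
    n_total = 2 * np.count_nonzero(called, axis=0).astype(np.int64)
    return AlleleCounts(n_alt=n_alt, n_total=n_total)


def qc_filter_missing(
    panels: Sequence[GenotypeMatrix], max_missing: int = 10
) -> tuple[list[GenotypeMatrix], list[str]]:
    """Drop markers with >= ``max_missing`` missing genotypes pooled over all panels.

    Returns the filtered panels (sharing one new MarkerMap) and the removed
    marker ids.  Idempotent: a second pass removes nothing.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    if not panels:
        return [], []
    markers = panels[0].markers
    for p in panels[1:]:
        if p.markers is not markers and not _same_map(p.markers, markers):
            raise ValueError("all panels must share one MarkerMap")
    total_missing = np.zeros(markers.n_markers, dtype=np.int64)
    for p in panels:
        total_missing += p.missing_per_marker()
    keep = total_missing < max_missing
    removed = [str(mid) for mid in markers.marker_id[~keep]]
    new_map = markers.subset(keep)
    out = [p.subset_markers(keep, markers=new_map) for p in panels]
    logger.info(
        "qc_filter_missing: removed %d markers, retained %d (max_missing=%d)",
        len(removed), new_map.n_markers, max_missing,
    )
    return out, removed


def _same_map(a: MarkerMap, b: MarkerMap) -> bool:
    return (
        a.n_markers == b.n_markers
        and np.array_equal(a.marker_id, b.marker_id)
        and np.array_equal(a.position_bp, b.position_bp)
        and np.array_equal(a.chromosome, b.chromosome)
    )


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def _resolve_prefix(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in {".ped", ".map", ".vcf"}:
        return path.with_suffix("")
    return path


def read_panel(
    path: str | Path,
    format: str | None = None,
    sample_populations: Mapping[str, str] | str | Path | None = None,
    markers: MarkerMap | None = None,
) -> tuple[MarkerMap, list[GenotypeMatrix]]:
    """Read a genotype panel, returning one GenotypeMatrix per population.

    Parameters
    ----------
    path:
        PED/MAP prefix (or either file), or a ``.vcf`` path.
    format:
        ``"plink-pedmap"`` or ``"vcf"``; inferred from the extension if None.
    sample_populations:
        Required for VCF (mapping or two-column TSV ``sample<TAB>population``);
        ignored for PED where the family id column assigns populations.
    markers:
        Optional existing MarkerMap whose ref/alt codes are used to orient
        dosages (hard error on an allele code absent from it).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "plink-pedmap"
    if format == "plink-pedmap":
        return _read_pedmap(path, markers=markers)
    if format == "vcf":
        return _read_vcf(path, sample_populations)
    raise ValueError(f"unknown format {format!r}")


def _read_pedmap(path: Path, markers: MarkerMap | None) -> tuple[MarkerMap, list[GenotypeMatrix]]:
    prefix = _resolve_prefix(path)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cM", "bp"], dtype={"chrom": str, "marker_id": str},
    )
    n_markers = len(mp)

    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    if ped.shape[1] != 6 + 2 * n_markers:
        raise ValueError(
            f"{ped_path}: expected {6 + 2 * n_markers} columns for {n_markers} markers, "
            f"found {ped.shape[1]}"
        )
    fam = ped.iloc[:, 0].to_numpy()
    iid = ped.iloc[:, 1].to_numpy()
    if np.any(fam == _PED_MISSING) or np.any(pd.isna(fam)):
        bad = iid[(fam == _PED_MISSING) | pd.isna(fam)][0]
        raise ValueError(f"sample {bad!r} has no population label (family id)")
    a1 = ped.iloc[:, 6::2].to_numpy(dtype=object)
    a2 = ped.iloc[:, 7::2].to_numpy(dtype=object)

    ref, alt = _resolve_alleles(mp["marker_id"].to_numpy(), a1, a2, prefix, markers)
    calls = _dosage_from_letters(a1, a2, ref, alt, mp["marker_id"].to_numpy())

    cm = mp["cM"].to_numpy(dtype=float)
    marker_map = MarkerMap(
        mp["marker_id"].to_numpy(), mp["chrom"].to_numpy(), mp["bp"].to_numpy(),
        ref, alt, cm if np.any(cm != 0) else None,
    )
    return marker_map, _split_populations(fam, iid, calls, marker_map)


def _resolve_alleles(
    marker_ids: np.ndarray,
    a1: np.ndarray,
    a2: np.ndarray,
    prefix: Path,
    markers: MarkerMap | None,
) -> tuple[np.ndarray, np.ndarray]:
    if markers is not None:
        return markers.allele_ref.copy(), markers.allele_alt.copy()
    sidecar = prefix.with_suffix(".alleles")
    if sidecar.exists():
        tab = pd.read_csv(sidecar, sep="\t", header=None,
                          names=["marker_id", "ref", "alt"], dtype=str)
        tab = tab.set_index("marker_id").reindex(marker_ids)
        if tab["ref"].isna().any():
            missing = marker_ids[tab["ref"].isna().to_numpy()][0]
            raise ValueError(f"{sidecar}: no allele entry for marker {missing!r}")
        return tab["ref"].to_numpy(dtype=object), tab["alt"].to_numpy(dtype=object)
    # infer from data: alt = lexicographically greater observed allele
    ref = np.empty(len(marker_ids), dtype=object)
    alt = np.empty(len(marker_ids), dtype=object)
    for j in range(len(marker_ids)):
        obs = sorted({*a1[:, j], *a2[:, j]} - {_PED_MISSING})
        if len(obs) > 2:
            raise ValueError(f"marker {marker_ids[j]!r} has >2 alleles: {obs}")
        if len(obs) == 2:
            ref[j], alt[j] = obs[0], obs[1]
        elif len(obs) == 1:
            ref[j] = obs[0]
            alt[j] = next(c for c in "ACGT" if c != obs[0])
        else:  # fully missing marker
            ref[j], alt[j] = "A", "C"
    return ref, alt


def _dosage_from_letters(a1, a2, ref, alt, marker_ids) -> np.ndarray:
    n_ind, n_markers = a1.shape
    calls = np.full((n_ind, n_markers), MISSING, dtype=np.int8)
    for j in range(n_markers):
        for i in range(n_ind):
            x, y = a1[i, j], a2[i, j]
            if x == _PED_MISSING or y == _PED_MISSING:
                continue
            dose = 0
            for z in (x, y):
                if z == alt[j]:
                    dose += 1
                elif z != ref[j]:
                    raise ValueError(
                        f"unknown allele code {z!r} at marker {marker_ids[j]!r} "
                        f"(expected {ref[j]!r}/{alt[j]!r})"
                    )
            calls[i, j] = dose
    return calls


def _split_populations(fam, iid, calls, marker_map) -> list[GenotypeMatrix]:
    panels = []
    for pop in pd.unique(fam):
        sel = fam == pop
        panels.append(GenotypeMatrix(str(pop), tuple(iid[sel]), calls[sel], marker_map))
    return panels


def write_panel(
    panels: Sequence[GenotypeMatrix],
    path: str | Path,
    format: str = "plink-pedmap",
) -> None:
    """Write panels (sharing one MarkerMap) as PED/MAP (+.alleles sidecar) or VCF."""
    if not panels:
        raise ValueError("nothing to write")
    markers = panels[0].markers
    path = Path(path)
    if format == "plink-pedmap":
        _write_pedmap(panels, markers, _resolve_prefix(path))
    elif format == "vcf":
        _write_vcf(panels, markers, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_pedmap(panels, markers: MarkerMap, prefix: Path) -> None:
    cm = markers.position_cM if markers.position_cM is not None else np.zeros(markers.n_markers)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(markers.n_markers):
            fh.write(f"{markers.chromosome[j]}\t{markers.marker_id[j]}\t{cm[j]:g}\t{markers.position_bp[j]}\n")
    with open(prefix.with_suffix(".alleles"), "w") as fh:
        for j in range(markers.n_markers):
            fh.write(f"{markers.marker_id[j]}\t{markers.allele_ref[j]}\t{markers.allele_alt[j]}\n")
    code = np.stack([markers.allele_ref, markers.allele_alt], axis=0)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for panel in panels:
            for i, ind in enumerate(panel.individuals):
                fields = [panel.population_id, ind, "0", "0", "0", "-9"]
                row = panel.calls[i]
                for j in range(markers.n_markers):
                    d = row[j]
                    if d == MISSING:
                        fields += [_PED_MISSING, _PED_MISSING]
                    else:
                        fields += [code[min(d, 1), j], code[1 if d == 2 else 0, j]]
                fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _load_pop_mapping(spec) -> Mapping[str, str]:
    if isinstance(spec, (str, Path)):
        tab = pd.read_csv(spec, sep="\t", header=None, names=["sample", "population"], dtype=str)
        return dict(zip(tab["sample"], tab["population"]))
    return dict(spec)


def _read_vcf(path: Path, sample_populations) -> tuple[MarkerMap, list[GenotypeMatrix]]:
    if sample_populations is None:
        raise ValueError("VCF input requires a sample->population mapping")
    pop_of = _load_pop_mapping(sample_populations)
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    for s in samples:
        if s not in pop_of:
            raise ValueError(f"sample {s!r} has no population label")
    ids, chroms, pos, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"site {rec.chrom}:{rec.pos} ({rec.id or '.'}) is not biallelic"
            )
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            raise ValueError(f"site {rec.chrom}:{rec.pos} is not a SNP")
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        pos.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alts[0])
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for k, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                continue
            row[k] = sum(gt)
        rows.append(row)
    vcf.close()
    calls = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    marker_map = MarkerMap(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64), np.array(refs, dtype=object),
        np.array(alts, dtype=object),
    )
    fam = np.array([pop_of[s] for s in samples], dtype=object)
    return marker_map, _split_populations(fam, np.array(samples, dtype=object), calls, marker_map)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(panels, markers: MarkerMap, path: Path) -> None:
    samples, pops, cols = [], [], []
    for p in panels:
        for i, ind in enumerate(p.individuals):
            samples.append(ind)
            pops.append(p.population_id)
            cols.append(p.calls[i])
    calls = np.stack(cols, axis=0)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in dict.fromkeys(markers.chromosome):
            sl = markers.chrom_slices()[chrom]
            fh.write(f"##contig=<ID={chrom},length={int(markers.position_bp[sl][-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(markers.n_markers):
            gts = "\t".join(_GT_CODE[int(calls[i, j])] for i in range(len(samples)))
            fh.write(
                f"{markers.chromosome[j]}\t{markers.position_bp[j]}\t{markers.marker_id[j]}\t"
                f"{markers.allele_ref[j]}\t{markers.allele_alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    # population table alongside, so the VCF round-trips without extra state
    with open(path.with_suffix(path.suffix + ".pops"), "w") as fh:
        for s, p in zip(samples, pops):
            fh.write(f"{s}\t{p}\n")


def write_frequency_table(panels: Sequence[GenotypeMatrix], path: str | Path) -> None:
    """TSV of per-population alt-allele frequencies and major allele frequency."""
    markers = panels[0].markers
    data = {
        "marker_id": markers.marker_id,
        "chrom": markers.chromosome,
        "pos_bp": markers.position_bp,
    }
    for p in panels:
        ac = allele_counts(p)
        data[f"{p.population_id}_alt_freq"] = np.round(ac.alt_freq, 6)
        data[f"{p.population_id}_major_freq"] = np.round(ac.m, 6)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
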