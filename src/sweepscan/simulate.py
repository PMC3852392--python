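"""Individual-based forward Wright-Fisher simulator of a divergent
truncation-selection experiment.

The simulator emulates the design of a long-term bidirectional selection
experiment on a polygenic trait: a structured founder pool (a mixture of
partially differentiated founder sub-lines supplying standing variation)
seeds a high line and a low line; every generation the top (or bottom)
fraction of individuals by phenotype is kept as parents and mated at random
(no selfing); relaxed derivative lines split off at a scheduled generation
and thereafter pick parents at random, optionally with a weak fitness cost
on the previously selected alleles (purging).  A single strongly beneficial
novel mutation can be injected into a chosen line and generation.  Meioses
follow a Haldane crossover model: switch events between adjacent markers are
independent with probability given by the inverse Haldane map function of
the cM spacing (equivalent to a Poisson crossover process with no
interference).

Individuals are hermaphroditic (sex is ignored); the trait is strictly
additive over causal loci plus Gaussian environmental noise.  Everything is
reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .panel import GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class SplitEvent:
    generation: int
    source_line: str
    new_line: str
    mode: str                   # 'high' | 'low' | 'random'
    purging_cost: float = 0.0   # soft selection against the source direction
    size: int = 0               # flock size of the new line; 0 = same as source


@dataclass(frozen=True)
class SamplingEvent:
    line: str
    generation: int
    n_individuals: int
    label: str = ""


@dataclass(frozen=True)
class Injection:
    line: str
    generation: int
    chromosome: int             # 0-based chromosome index
    marker: int                 # marker index within the chromosome
    effect: float               # additive effect on the trait per allele copy


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one forward-simulation experiment."""

    n_chromosomes: int = 5
    markers_per_chromosome: int = 2000
    chromosome_length_cM: float = 100.0
    chromosome_length_bp: int = 50_000_000
    n_founder_sublines: int = 7
    founder_concentration: float = 8.0   # Beta concentration of sub-line freqs
    # chip-style ascertainment: arrays target common SNPs, so founder-pool
    # frequencies are drawn away from the extremes
    founder_freq_range: tuple[float, float] = (0.2, 0.8)
    N: int = 50                          # breeding individuals per line per generation
    n_causal: int = 50
    effect_sd: float = 1.0
    env_sd: float = 3.0
    lines: Mapping[str, str] = field(default_factory=lambda: {"HW": "high", "LW": "low"})
    truncation: float = 0.2              # fraction kept as parents under selection
    # mating scheme among selected parents: 'random_union' pairs any two
    # distinct parents; 'sire_dam' mirrors hierarchical poultry breeding —
    # the n_sires most extreme selected individuals each contribute one
    # gamete per offspring, the remaining selected ("dams") the other
    mating: str = "random_union"
    n_sires: int = 0
    n_generations: int = 54
    splits: tuple[SplitEvent, ...] = ()
    sampling: tuple[SamplingEvent, ...] = ()
    injection: Injection | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.truncation <= 1.0):
            raise ValueError("truncation must be in (0, 1]")
        gens = [s.generation for s in self.splits] + [s.generation for s in self.sampling]
        if any(g < 0 or g > self.n_generations for g in gens):
            raise ValueError("scheduled generations must lie within the run")
        if self.injection is not None:
            inj = self.injection
            if not (0 <= inj.chromosome < self.n_chromosomes):
                raise ValueError("injected locus chromosome off the simulated map")
            if not (0 <= inj.marker < self.markers_per_chromosome):
                raise ValueError("injected locus marker off the simulated map")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["lines"] = dict(d.get("lines", {}))
        d["splits"] = tuple(SplitEvent(**s) for s in d.get("splits", ()))
        d["sampling"] = tuple(SamplingEvent(**s) for s in d.get("sampling", ()))
        if d.get("injection"):
            d["injection"] = Injection(**d["injection"])
        else:
            d["injection"] = None
        return cls(**d)


def _config_dict(cfg: SimConfig) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    d["lines"] = dict(cfg.lines)
    d["splits"] = [asdict(s) for s in cfg.splits]
    d["sampling"] = [asdict(s) for s in cfg.sampling]
    d["injection"] = asdict(cfg.injection) if cfg.injection else None
    return d


@dataclass
class SimResult:
    markers: MarkerMap
    panels: dict[str, GenotypeMatrix]          # label -> sampled panel
    causal_indices: np.ndarray
    causal_effects: np.ndarray
    injected_index: int | None                  # global marker index, if injected
    final_freqs: dict[str, np.ndarray]          # line -> final alt-allele frequency


class _Line:
    __slots__ = ("name", "mode", "haps", "purging_cost", "direction")

    def __init__(self, name: str, mode: str, haps: np.ndarray,
                 purging_cost: float = 0.0, direction: float = 0.0) -> None:
        self.name = name
        self.mode = mode          # 'high' | 'low' | 'random'
        self.haps = haps          # (2N, M) uint8; rows 2i, 2i+1 are individual i
        self.purging_cost = purging_cost
        self.direction = direction  # +1 high-selected ancestry, -1 low

    @property
    def N(self) -> int:
        return self.haps.shape[0] // 2


def _marker_map(cfg: SimConfig) -> MarkerMap:
    per = cfg.markers_per_chromosome
    spacing_bp = cfg.chromosome_length_bp // (per + 1)
    ids, chroms, pos, cm = [], [], [], []
    for c in range(cfg.n_chromosomes):
        label = f"chr{c + 1}"
        for j in range(per):
            ids.append(f"{label}_m{j + 1}")
            chroms.append(label)
            pos.append((j + 1) * spacing_bp)
            cm.append((j + 1) * cfg.chromosome_length_cM / (per + 1))
    n = len(ids)
    return MarkerMap(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(["A"] * n, dtype=object), np.array(["C"] * n, dtype=object),
        np.array(cm),
    )


def _recomb_probs(cfg: SimConfig, markers: MarkerMap) -> np.ndarray:
    """Per-interval switch probability; chromosome starts get 0.5 (free phase)."""
    cm = markers.position_cM
    r = np.empty(markers.n_markers)
    for chrom, sl in markers.chrom_slices().items():
        r[sl.start] = 0.5
        d_morgan = np.diff(cm[sl]) / 100.0
        r[sl.start + 1:sl.stop] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    return r


def _gametes(haps: np.ndarray, parent_idx: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per entry of parent_idx, vectorised."""
    switches = rng.random((len(parent_idx), len(r)), dtype=np.float32) < r
    chooser = np.bitwise_xor.accumulate(switches.astype(np.uint8), axis=1) & 1
    h0 = haps[2 * parent_idx]
    h1 = haps[2 * parent_idx + 1]
    return np.where(chooser == 0, h0, h1)


def _select_parents(line: _Line, trait: np.ndarray, cfg: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    N = line.N
    if line.mode == "random":
        if line.purging_cost > 0.0:
            # soft viability selection against previously favoured alleles
            w = np.exp(-line.purging_cost * line.direction * trait)
            w /= w.sum()
            k = max(2, N // 2)
            return rng.choice(N, size=k, replace=False, p=w)
        return np.arange(N)
    k = max(2, int(round(N * cfg.truncation)))
    order = np.argsort(trait, kind="stable")
    if line.mode == "high":
        return order[-k:]
    if line.mode == "low":
        return order[:k]
    raise ValueError(f"unknown selection mode {line.mode!r}")


def simulate(cfg: SimConfig) -> SimResult:
    """Run the forward simulation and return the scheduled genotype samples.

    Raises if a line's selected-parent count would fall below 2.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg)
    M = markers.n_markers
    r = _recomb_probs(cfg, markers)

    # structured founder pool: per-marker base frequency, sub-line frequencies
    # drawn around it (Beta with fixed concentration), founder haplotypes
    # drawn marker-independently within a sub-line
    base_p = rng.uniform(*cfg.founder_freq_range, size=M)
    conc = cfg.founder_concentration
    subline_p = rng.beta(base_p * conc, (1 - base_p) * conc,
                         size=(cfg.n_founder_sublines, M))

    inj = cfg.injection
    inj_index = (inj.chromosome * cfg.markers_per_chromosome + inj.marker
                 if inj is not None else None)
    if inj_index is not None:
        # a *novel* mutation: founders are monomorphic reference at the site
        subline_p[:, inj_index] = 0.0

    eligible = np.setdiff1d(np.arange(M), [] if inj_index is None else [inj_index])
    causal = rng.choice(eligible, size=cfg.n_causal, replace=False)
    causal.sort()
    effects = rng.normal(0.0, cfg.effect_sd, size=cfg.n_causal)

    effect_vec = np.zeros(M)
    effect_vec[causal] = effects

    lines: dict[str, _Line] = {}
    for name, mode in cfg.lines.items():
        assign = rng.integers(0, cfg.n_founder_sublines, size=2 * cfg.N)
        haps = (rng.random((2 * cfg.N, M)) < subline_p[assign]).astype(np.uint8)
        direction = 1.0 if mode == "high" else (-1.0 if mode == "low" else 0.0)
        lines[name] = _Line(name, mode, haps, direction=direction)

    splits_by_gen: dict[int, list[SplitEvent]] = {}
    for s in cfg.splits:
        splits_by_gen.setdefault(s.generation, []).append(s)
    samples_by_gen: dict[int, list[SamplingEvent]] = {}
    for s in cfg.sampling:
        samples_by_gen.setdefault(s.generation, []).append(s)

    panels: dict[str, GenotypeMatrix] = {}

    def take_samples(gen: int) -> None:
        for ev in samples_by_gen.get(gen, []):
            if ev.line not in lines:
                raise ValueError(f"sampling event for unknown line {ev.line!r} at gen {gen}")
            line = lines[ev.line]
            pick = rng.choice(line.N, size=ev.n_individuals, replace=False)
            dose = (line.haps[2 * pick] + line.haps[2 * pick + 1]).astype(np.int8)
            if cfg.missing_rate > 0:
                mask = rng.random(dose.shape) < cfg.missing_rate
                dose[mask] = -1
            label = ev.label or f"{ev.line}{gen}"
            panels[label] = GenotypeMatrix(
                label, tuple(f"{label}_i{k + 1}" for k in range(ev.n_individuals)),
                dose, markers,
            )

    take_samples(0)
    for gen in range(1, cfg.n_generations + 1):
        for s in splits_by_gen.get(gen, []):
            src = lines[s.source_line]
            founders = src.haps
            if s.size and s.size != src.N:
                pick = rng.choice(src.N, size=s.size, replace=False)
                rows = np.empty(2 * s.size, dtype=np.int64)
                rows[0::2], rows[1::2] = 2 * pick, 2 * pick + 1
                founders = src.haps[rows]
            lines[s.new_line] = _Line(
                s.new_line, s.mode, founders.copy(),
                purging_cost=s.purging_cost, direction=src.direction,
            )
        for line in list(lines.values()):
            N = line.N
            dose = line.haps[0::2] + line.haps[1::2]
            genetic = dose @ effect_vec
            trait = genetic + rng.normal(0.0, cfg.env_sd, size=N)
            trait_sorted = _select_parents(line, trait, cfg, rng)  # ascending trait
            parents = np.sort(trait_sorted)
            if len(parents) < 2:
                raise ValueError(f"line {line.name}: fewer than 2 selected parents")
            if (inj is not None and line.name == inj.line and gen == inj.generation):
                carrier = parents[rng.integers(len(parents))]
                line.haps[2 * carrier, inj_index] = 1
                effect_vec[inj_index] = inj.effect
            if (cfg.mating == "sire_dam" and line.mode in ("high", "low")
                    and 0 < cfg.n_sires < len(parents)):
                # parents are trait-sorted by _select_parents: the most extreme
                # end of the selected group serves as sires
                if line.mode == "high":
                    sires, dams = trait_sorted[-cfg.n_sires:], trait_sorted[:-cfg.n_sires]
                else:
                    sires, dams = trait_sorted[:cfg.n_sires], trait_sorted[cfg.n_sires:]
                p1 = rng.choice(sires, size=N)
                p2 = rng.choice(dams, size=N)
            else:
                p1 = rng.choice(parents, size=N)
                shift = 1 + rng.integers(0, len(parents) - 1, size=N)
                pos1 = np.searchsorted(parents, p1)
                p2 = parents[(pos1 + shift) % len(parents)]  # avoids selfing
            g1 = _gametes(line.haps, p1, r, rng)
            g2 = _gametes(line.haps, p2, r, rng)
            new = np.empty_like(line.haps)
            new[0::2] = g1
            new[1::2] = g2
            line.haps = new
        take_samples(gen)

    final = {name: line.haps.mean(axis=0) for name, line in lines.items()}
    return SimResult(markers, panels, causal, effects, inj_index, final)


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

def _base_schedule(relaxed_size: int = 25, purging_cost: float = 0.0):
    """Two-lineage design: relaxed lines split at generation 45 into small
    maintenance flocks and sampled 9 generations later; selected lines
    sampled at generations 40, 50 and 53; 20 individuals per sample."""
    splits = (
        SplitEvent(45, "HW", "HWR", "random", purging_cost, relaxed_size),
        SplitEvent(45, "LW", "LWR", "random", purging_cost, relaxed_size),
    )
    sampling = tuple(
        SamplingEvent(line, gen, 20, label=f"{line}S{gen}")
        for line in ("HW", "LW") for gen in (40, 50, 53)
    ) + (
        SamplingEvent("HWR", 54, 20, label="HWR9"),
        SamplingEvent("LWR", 54, 20, label="LWR9"),
    )
    return splits, sampling


SCENARIOS = ("A_drift_only", "B_novel_mutation", "C_standing_sweeps", "D_purging_relaxed")

# shared founder/trait architecture of the canned scenarios: chip-ascertained
# founder frequencies, 7 founder sub-lines, polygenic trait with h^2 ~ 0.2
_SCENARIO_GENOME = dict(
    n_chromosomes=5, chromosome_length_cM=200.0, chromosome_length_bp=50_000_000,
    n_causal=40, effect_sd=1.0, env_sd=8.0, n_generations=54,
)

# selected-line scale emulating the study system: large hatches, hierarchical
# sire/dam matings among the selected group (Ne = 4SD/(S+D) ~ 100), giving the
# per-generation heterozygosity-loss rate the real lines show
_SELECTED_SCALE = dict(
    N=1000, truncation=0.15, mating="sire_dam", n_sires=30,
)


def scenario_library(name: str, seed: int = 0) -> SimConfig:
    """Canned experiment configurations.

    * ``A_drift_only`` — the full sampling design with selection switched off
      everywhere (N = 50 flocks, 10^4 markers): a pure drift null for
      calibrating scan thresholds.
    * ``B_novel_mutation`` — bidirectional truncation selection plus a single
      strongly beneficial mutation injected into the high line at generation
      42, between the last shared sample (40) and the relaxed split (45).
    * ``C_standing_sweeps`` — bidirectional truncation selection on standing
      variation only (polygenic sweeps, no novel mutation).
    * ``D_purging_relaxed`` — selection as in C at a reduced census, with the
      relaxed lines suffering a fitness cost on previously favoured alleles,
      so heterozygosity is purged faster after the split.
    """
    if name == "A_drift_only":
        splits, sampling = _base_schedule(relaxed_size=50)
        # a second, independent generation-40 sample of the high line: a
        # true-null pair for calibrating the marker-wise Fisher scan
        sampling = sampling + (SamplingEvent("HW", 40, 20, label="HWS40b"),)
        return SimConfig(
            lines={"HW": "random", "LW": "random"}, splits=splits,
            sampling=sampling, seed=seed, N=50,
            markers_per_chromosome=2000, **_SCENARIO_GENOME,
        )
    if name == "B_novel_mutation":
        splits, sampling = _base_schedule()
        return SimConfig(
            lines={"HW": "high", "LW": "low"}, splits=splits, sampling=sampling,
            injection=Injection(line="HW", generation=42, chromosome=0,
                                marker=500, effect=30.0),
            seed=seed, markers_per_chromosome=1000,
            **_SELECTED_SCALE, **_SCENARIO_GENOME,
        )
    if name == "C_standing_sweeps":
        splits, sampling = _base_schedule()
        return SimConfig(
            lines={"HW": "high", "LW": "low"}, splits=splits, sampling=sampling,
            seed=seed, markers_per_chromosome=1000,
            **_SELECTED_SCALE, **_SCENARIO_GENOME,
        )
    if name == "D_purging_relaxed":
        splits, sampling = _base_schedule(relaxed_size=50, purging_cost=1.0)
        return SimConfig(
            lines={"HW": "high", "LW": "low"}, splits=splits, sampling=sampling,
            seed=seed, N=200, truncation=0.25,
            markers_per_chromosome=1000, **_SCENARIO_GENOME,
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
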