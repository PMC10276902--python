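"""Forward Wright-Fisher simulation of a hybrid population.

A single admixture pulse founds a population from two sources: a fraction
``alpha`` of haplotypes are fully introgressed (ancestry 1) and the rest
fully recipient (ancestry 0).  Each generation, diploid parents are sampled
in proportion to fitness, and gametes are formed with a Poisson number of
crossovers (mean = map length in Morgans, no interference) placed uniformly
on the genetic map, with independent assortment across chromosomes.
Population size follows an arbitrary trajectory 2N(t), so bottlenecks and
expansions can be simulated directly.

Genome-wide selection against one ancestry follows a linear additive model:
the fitness of individual i is w_i = 1 - p_i * S * m(t), where p_i is the
fraction of introgressed alleles that i carries across a set of selected
loci (diploid dosage averaged over the two haplotypes), S is the total
selection strength, and m(t) in [-1, 1] is a per-generation schedule
multiplier (0 = neutral, -1 = selection favouring the introgressed
ancestry).  With S = 1 an F1 hybrid (p = 1/2) has relative fitness 0.5.

Ancestry along each chromosome is stored at the evenly spaced grid loci of
the output resolution; crossover positions are drawn continuously on the
genetic map and take effect at the first grid locus to their right, so
ancestry tracts and junction counts are exact up to grid quantisation.

The module also provides the closed-form neutral expectation of the
per-scale wavelet variance of the ancestry proportion (see
:func:`expected_neutral_wavelet_variance`), derived from the backward
two-locus lineage process, for direct comparison with simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .modwt import haar_filter
from .signal_prep import GridSignal, RecombinationMap

__all__ = [
    "SelectionRegime",
    "SimConfig",
    "PopulationState",
    "HaplotypeAncestry",
    "simulate",
    "linear_fitness",
    "individual_fitness",
    "ancestry_proportion_signal",
    "tract_length_summary",
    "haplotype_ancestry",
    "recombination_rate_signal",
    "expected_neutral_wavelet_variance",
    "run_selection_scenarios",
]


def linear_fitness(p: np.ndarray | float, S: float, multiplier: float = 1.0):
    """w = 1 - p*S*m, clamped at zero.

    ``p`` is the individual's introgressed-allele fraction at the selected
    loci.  The clamp only matters for S*m > 1; within the standard S = 1
    regime fitness stays in [0, 1].
    """
    return np.clip(1.0 - np.asarray(p, dtype=float) * S * multiplier, 0.0, None)


@dataclass
class SelectionRegime:
    """Time-varying genome-wide selection against introgressed alleles.

    ``schedule(g)`` gives the multiplier applied when the parents of
    generation g+1 are sampled (g is the parents' generation index).
    Founders (g = 0) always reproduce neutrally: they are pure-ancestry
    individuals and the selection model targets recombinant hybrids.
    """

    S: float = 1.0
    n_loci: int = 10_000
    schedule: Callable[[int], float] | None = None
    positions: dict[str, np.ndarray] | None = None
    placement: str = "physical"  # where loci are placed uniformly, if drawn

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be >= 0")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")

    def multiplier(self, g: int) -> float:
        if g == 0:
            return 0.0
        m = 1.0 if self.schedule is None else float(self.schedule(g))
        if abs(m) > 1:
            raise ValueError("schedule multiplier must lie in [-1, 1]")
        return m

    # -- common schedules -------------------------------------------------
    @classmethod
    def continuous(cls, S: float = 1.0, **kw) -> "SelectionRegime":
        return cls(S=S, schedule=None, **kw)

    @classmethod
    def early_only(cls, S: float = 1.0, n_generations: int = 10, **kw) -> "SelectionRegime":
        """Selection on the first ``n_generations`` of recombinant hybrids."""
        return cls(S=S, schedule=lambda g: 1.0 if g <= n_generations else 0.0, **kw)

    @classmethod
    def late_onset(cls, S: float = 1.0, neutral_generations: int = 500, **kw) -> "SelectionRegime":
        return cls(S=S, schedule=lambda g: 1.0 if g > neutral_generations else 0.0, **kw)

    @classmethod
    def reversal(cls, S: float = 1.0, flip_generation: int = 100, **kw) -> "SelectionRegime":
        """Favour the alternate ancestry after ``flip_generation``."""
        return cls(S=S, schedule=lambda g: 1.0 if g <= flip_generation else -1.0, **kw)


@dataclass
class SimConfig:
    """Configuration of one simulation run.

    ``chrom_lengths`` gives per-chromosome genetic lengths in Morgans; a
    ``rec_maps`` entry (physical-coordinate recombination map) may be
    supplied per chromosome to define a physical map, in which case the
    genetic length is taken from the map and selected loci are placed
    uniformly on the physical map (as befits loci that are features of the
    physical sequence).  ``twoN`` is either a constant or a trajectory:
    an array of 2N for generations 0..T, or a {generation: size} dict of
    stepwise changes.
    """

    chrom_lengths: dict[str, float] | None = None
    rec_maps: dict[str, RecombinationMap] | None = None
    alpha: float = 0.5
    twoN: int | Sequence[int] | dict[int, int] = 2000
    generations: int = 100
    selection: SelectionRegime | None = None
    resolution: float = 2.0**-12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            if self.rec_maps is None:
                raise ValueError("supply chrom_lengths or rec_maps")
            self.chrom_lengths = {
                c: m.total_length for c, m in self.rec_maps.items()
            }
            for c, m in self.rec_maps.items():
                if m.units not in ("Morgan_per_bp", "cM_per_Mb"):
                    raise ValueError("rec_maps must be in Morgan/bp or cM/Mb units")
                if m.units == "cM_per_Mb":
                    self.chrom_lengths[c] = m.total_length * 1e-8
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for chrom, length in self.chrom_lengths.items():
            if int(round(length / self.resolution)) < 2:
                raise ValueError(
                    f"resolution {self.resolution:g} too coarse for chromosome "
                    f"{chrom!r} of length {length:g} M"
                )

    def trajectory(self) -> np.ndarray:
        """2N at generations 0..T as an integer array."""
        T = self.generations
        if isinstance(self.twoN, dict):
            sizes = np.empty(T + 1, dtype=int)
            current = None
            changes = dict(sorted(self.twoN.items()))
            if 0 not in changes:
                raise ValueError("trajectory dict must define a size at generation 0")
            for g in range(T + 1):
                current = changes.get(g, current)
                sizes[g] = current
        elif np.isscalar(self.twoN):
            sizes = np.full(T + 1, int(self.twoN))
        else:
            sizes = np.asarray(self.twoN, dtype=int)
            if len(sizes) != T + 1:
                raise ValueError("twoN trajectory must have length generations+1")
        if np.any(sizes < 2) or np.any(sizes % 2):
            raise ValueError("2N must be even and >= 2 at every generation")
        return sizes

    def grid(self, chrom: str) -> np.ndarray:
        L = int(round(self.chrom_lengths[chrom] / self.resolution))
        return np.arange(L) * self.resolution


@dataclass
class PopulationState:
    """Snapshot of all haplotypes at one generation.

    ``haplotypes[chrom]`` is a (2N, L) uint8 ancestry matrix at the grid
    loci (0 = recipient, 1 = introgressed); row 2i and 2i+1 are the two
    haplotypes of diploid i.
    """

    generation: int
    haplotypes: dict[str, np.ndarray]
    resolution: float
    chrom_lengths: dict[str, float]
    selected_loci: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def twoN(self) -> int:
        return next(iter(self.haplotypes.values())).shape[0]

    def selected_fraction(self) -> np.ndarray:
        """Per-diploid fraction of introgressed alleles at the selected loci."""
        n_loci = sum(len(idx) for idx in self.selected_loci.values())
        if n_loci == 0:
            raise ValueError("state carries no selected loci")
        counts = np.zeros(self.twoN)
        for chrom, idx in self.selected_loci.items():
            if len(idx):
                counts += self.haplotypes[chrom][:, idx].sum(axis=1)
        return (counts[0::2] + counts[1::2]) / (2.0 * n_loci)


@dataclass
class HaplotypeAncestry:
    """Tract representation of one haploid chromosome.

    ``junctions`` are ancestry switch points in Morgans, strictly
    increasing within (0, length); ancestry alternates across junctions
    starting from ``left_ancestry``.
    """

    chromosome: str
    length: float
    junctions: np.ndarray
    left_ancestry: int

    def __post_init__(self) -> None:
        self.junctions = np.asarray(self.junctions, dtype=float)
        if len(self.junctions) and (
            np.any(np.diff(self.junctions) <= 0)
            or self.junctions[0] <= 0
            or self.junctions[-1] >= self.length
        ):
            raise ValueError("junctions must be strictly increasing within (0, length)")

    def tract_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, ancestries) of the tracts, left to right."""
        bounds = np.concatenate([[0.0], self.junctions, [self.length]])
        lengths = np.diff(bounds)
        ancestries = (self.left_ancestry + np.arange(len(lengths))) % 2
        return lengths, ancestries


# ---------------------------------------------------------------------------
# core engine


def _place_selected_loci(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Grid indices of the selected loci on each chromosome.

    With a physical recombination map, loci are dropped uniformly on the
    physical sequence and mapped to genetic coordinates (so their density
    per Morgan is inversely proportional to the local recombination rate,
    the feature that couples selection strength to recombination);
    otherwise they are uniform on the genetic map.
    """
    regime = config.selection
    chroms = list(config.chrom_lengths)
    out: dict[str, np.ndarray] = {c: np.empty(0, dtype=int) for c in chroms}
    if regime is None:
        return out
    if regime.positions is not None:
        for chrom, pos in regime.positions.items():
            grid = config.grid(chrom)
            out[chrom] = np.searchsorted(grid + config.resolution / 2, pos)
            out[chrom] = np.clip(out[chrom], 0, len(grid) - 1)
        return out
    if regime.n_loci == 0:
        return out
    use_physical = config.rec_maps is not None and regime.placement == "physical"
    if use_physical:
        sizes = np.array([config.rec_maps[c].ends[-1] - config.rec_maps[c].starts[0] for c in chroms])
    else:
        sizes = np.array([config.chrom_lengths[c] for c in chroms])
    counts = rng.multinomial(regime.n_loci, sizes / sizes.sum())
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        grid = config.grid(chrom)
        if use_physical:
            rmap = config.rec_maps[chrom]
            phys = rng.uniform(rmap.starts[0], rmap.ends[-1], size=k)
            factor = 1e-8 if rmap.units == "cM_per_Mb" else 1.0
            gen_pos = rmap.cumulative_at(phys) * factor
        else:
            gen_pos = rng.uniform(0.0, config.chrom_lengths[chrom], size=k)
        idx = np.clip(np.searchsorted(grid + config.resolution / 2, gen_pos), 0, len(grid) - 1)
        out[chrom] = np.sort(idx)
    return out


def individual_fitness(
    state: PopulationState, regime: SelectionRegime, multiplier: float | None = None
) -> np.ndarray:
    """Fitness of every diploid in a state under the linear selection model."""
    if multiplier is None:
        multiplier = regime.multiplier(max(state.generation, 1))
    return linear_fitness(state.selected_fraction(), regime.S, multiplier)


def _make_children(
    pop: dict[str, np.ndarray],
    parent_idx: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Form one gamete per entry of ``parent_idx`` on every chromosome."""
    n_gametes = len(parent_idx)
    children: dict[str, np.ndarray] = {}
    for chrom, haps in pop.items():
        L = haps.shape[1]
        length = config.chrom_lengths[chrom]
        start_hap = rng.integers(0, 2, size=n_gametes, dtype=np.int64)
        n_cross = rng.poisson(length, size=n_gametes)
        total = int(n_cross.sum())
        if total:
            pos = rng.uniform(0.0, length, size=total)
            gamete_of = np.repeat(np.arange(n_gametes), n_cross)
            flip_at = np.ceil(pos / config.resolution).astype(np.int64)
            inside = flip_at < L
            flat = gamete_of[inside] * L + flip_at[inside]
            counts = np.bincount(flat, minlength=n_gametes * L)
            bits = (counts.astype(np.uint8) & 1).view(np.bool_).reshape(n_gametes, L)
            phase = np.bitwise_xor.accumulate(bits, axis=1)
            phase ^= start_hap[:, None].astype(np.bool_)
            phase = phase.view(np.uint8)
        else:
            phase = np.broadcast_to(
                (start_hap[:, None] & 1).astype(np.uint8), (n_gametes, L)
            )
        hap_a = haps[2 * parent_idx]
        hap_b = haps[2 * parent_idx + 1]
        # phase selects hap_a (0) or hap_b (1) per locus without a full gather
        children[chrom] = hap_a ^ (phase & (hap_a ^ hap_b))
    return children


def simulate(
    config: SimConfig, record_generations: Iterable[int] | None = None
) -> dict[int, PopulationState]:
    """Run the forward simulation, returning snapshots at the requested
    generations (default: the final generation only).

    Identical configurations and seeds reproduce snapshots exactly.
    """
    sizes = config.trajectory()
    T = config.generations
    record = sorted(set(record_generations)) if record_generations is not None else [T]
    if record and (record[0] < 0 or record[-1] > T):
        raise ValueError("record_generations outside [0, generations]")
    rng = np.random.default_rng(config.seed)
    # locus placement uses its own stream so that matched-seed runs with and
    # without selection share founders and crossover draws
    loci_rng = np.random.default_rng(
        None if config.seed is None else [1, int(config.seed)]
    )
    sel_idx = _place_selected_loci(config, loci_rng)
    regime = config.selection

    twoN0 = int(sizes[0])
    n_intro = int(round(config.alpha * twoN0))
    order = rng.permutation(twoN0)
    pop: dict[str, np.ndarray] = {}
    for chrom in config.chrom_lengths:
        L = len(config.grid(chrom))
        haps = np.zeros((twoN0, L), dtype=np.uint8)
        haps[order[:n_intro]] = 1
        pop[chrom] = haps

    def snap(g: int) -> PopulationState:
        return PopulationState(
            generation=g,
            haplotypes={c: h.copy() for c, h in pop.items()},
            resolution=config.resolution,
            chrom_lengths=dict(config.chrom_lengths),
            selected_loci={c: i.copy() for c, i in sel_idx.items()},
        )

    snapshots: dict[int, PopulationState] = {}
    if record and record[0] == 0:
        snapshots[0] = snap(0)
    for g in range(T):
        n_parents = int(sizes[g]) // 2
        n_gametes = int(sizes[g + 1])
        m = regime.multiplier(g) if regime is not None else 0.0
        if regime is not None and regime.S > 0 and m != 0.0:
            state = PopulationState(g, pop, config.resolution, config.chrom_lengths, sel_idx)
            w = linear_fitness(state.selected_fraction(), regime.S, m)
            total_w = w.sum()
            if total_w <= 0:
                raise RuntimeError(
                    f"no viable parents at generation {g}: all fitnesses are zero"
                )
            parent_idx = rng.choice(n_parents, size=n_gametes, p=w / total_w)
        else:
            parent_idx = rng.integers(0, n_parents, size=n_gametes)
        pop = _make_children(pop, parent_idx, config, rng)
        if (g + 1) in record:
            snapshots[g + 1] = snap(g + 1)
    return snapshots


# ---------------------------------------------------------------------------
# summaries of a population state


def ancestry_proportion_signal(
    state: PopulationState,
    resolution: float | None = None,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, GridSignal]:
    """Per-chromosome introgressed ancestry proportion on the genetic grid.

    By default every haplotype in the population contributes; pass
    ``sample_size`` to emulate a finite study sample (drawn without
    replacement).  A coarser output ``resolution`` (an integer multiple of
    the simulation grid) averages blocks of grid loci.
    """
    signals: dict[str, GridSignal] = {}
    rows = None
    if sample_size is not None:
        if rng is None:
            rng = np.random.default_rng()
        rows = rng.choice(state.twoN, size=sample_size, replace=False)
    for chrom, haps in state.haplotypes.items():
        if resolution is not None and resolution > state.chrom_lengths[chrom]:
            raise ValueError(
                f"resolution {resolution:g} exceeds length of chromosome {chrom!r}"
            )
        values = (haps if rows is None else haps[rows]).mean(axis=0)
        res = state.resolution
        if resolution is not None and resolution != res:
            factor = resolution / res
            k = int(round(factor))
            if k < 1 or abs(factor - k) > 1e-9:
                raise ValueError(
                    "output resolution must be an integer multiple of the grid"
                )
            n_blocks = len(values) // k
            values = values[: n_blocks * k].reshape(n_blocks, k).mean(axis=1)
            res = resolution
        signals[chrom] = GridSignal(chrom, res, values, map_kind="genetic", start=0.0)
    return signals


def haplotype_ancestry(state: PopulationState, chrom: str, index: int) -> HaplotypeAncestry:
    """Tract representation of one haplotype; junction positions are placed
    midway between the grid loci flanking each ancestry switch."""
    values = state.haplotypes[chrom][index]
    res = state.resolution
    switches = np.flatnonzero(np.diff(values.astype(np.int8)) != 0)
    junctions = (switches + 0.5) * res
    return HaplotypeAncestry(
        chromosome=chrom,
        length=len(values) * res,
        junctions=junctions,
        left_ancestry=int(values[0]),
    )


def tract_length_summary(state: PopulationState) -> pd.DataFrame:
    """Tract table (haplotype, chromosome, start, end, ancestry, length in
    Morgans) for every haplotype in the state."""
    frames = []
    res = state.resolution
    for chrom, haps in state.haplotypes.items():
        n, L = haps.shape
        length = L * res
        change = np.diff(haps.astype(np.int8), axis=1) != 0
        hap_id, switch = np.nonzero(change)
        junctions = (switch + 0.5) * res
        n_j = np.bincount(hap_id, minlength=n)
        starts, ends, owners = [], [], []
        offset = 0
        for i in range(n):
            j = junctions[offset : offset + n_j[i]]
            offset += n_j[i]
            bounds = np.concatenate([[0.0], j, [length]])
            starts.append(bounds[:-1])
            ends.append(bounds[1:])
            owners.append(np.full(len(bounds) - 1, i))
        start = np.concatenate(starts)
        end = np.concatenate(ends)
        owner = np.concatenate(owners)
        first_idx = np.clip((start / res + 0.5).astype(int), 0, L - 1)
        ancestry = haps[owner, first_idx]
        frames.append(
            pd.DataFrame(
                {
                    "haplotype": owner,
                    "chromosome": chrom,
                    "start_M": start,
                    "end_M": end,
                    "ancestry": ancestry.astype(int),
                    "length_M": end - start,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def recombination_rate_signal(
    rmap: RecombinationMap, resolution: float, log: bool = False
) -> GridSignal:
    """Local recombination rate (cM/Mb) at evenly spaced genetic positions.

    Each genetic grid point is located in its physical map interval and
    assigned that interval's rate; this is the predictor signal for
    ancestry-recombination correlation analyses on the genetic map.
    """
    rate_m_per_bp = rmap.rates_morgan_per_bp()
    cum_m = np.concatenate([[0.0], np.cumsum(rate_m_per_bp * rmap.widths)])
    total = cum_m[-1]
    L = int(round(total / resolution))
    if L < 2:
        raise ValueError("resolution too coarse for this map's genetic length")
    grid = np.arange(L) * resolution
    idx = np.clip(np.searchsorted(cum_m[1:], grid, side="right"), 0, len(rate_m_per_bp) - 1)
    values = rate_m_per_bp[idx] / 1e-8  # cM/Mb
    sig = GridSignal(rmap.chromosome, resolution, values, map_kind="genetic", start=0.0)
    if log:
        from .signal_prep import log_transform_rates

        sig = log_transform_rates(sig)
    return sig


# ---------------------------------------------------------------------------
# neutral theory


def _same_haplotype_probability(
    distances: np.ndarray, sizes: np.ndarray, t: int
) -> np.ndarray:
    """P(two locus-lineages at the given map separations trace to the same
    founder haplotype), by the backward together/apart two-state chain.

    Per backward step the pair separates with the Haldane probability of an
    odd crossover count, r(d) = (1 - exp(-2d))/2, and re-joins by
    coalescence with probability 1/2N of the parental generation.
    """
    r = 0.5 * (1.0 - np.exp(-2.0 * distances))
    u = np.full_like(r, 1.0 / sizes[t])
    for g in range(t, 0, -1):
        u = u * (1.0 - r) + (1.0 - u) / sizes[g - 1]
    return u


def expected_neutral_wavelet_variance(
    twoN: int | Sequence[int],
    t: int,
    scales: Sequence[float],
    resolution: float,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Expected wavelet variance of the ancestry proportion under drift.

    The ancestry-frequency covariance between loci at map distance d is
    C(d) = a(1-a) * [u - (1-u)/(2N0 - 1)], where u is the probability the
    two lineages sit on the same founder haplotype and the second term is
    the hypergeometric correction for a founding pool of fixed composition
    (a = alpha rounded to a whole number of founder haplotypes).  The
    expected wavelet variance at a scale is then the quadratic form of the
    level's Haar filter autocorrelation with C; it applies to non-boundary
    (unbiased-estimator) coefficients of the full-population signal.

    ``twoN`` may be a scalar or a trajectory over generations 0..t;
    ``scales`` are in map units (Morgans) and must be dyadic multiples
    (>= 2x) of ``resolution``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if np.isscalar(twoN):
        sizes = np.full(t + 1, int(twoN))
    else:
        sizes = np.asarray(twoN, dtype=int)
        if len(sizes) != t + 1:
            raise ValueError("twoN trajectory must have length t+1")
    if np.any(sizes < 2):
        raise ValueError("2N must be >= 2")
    levels = []
    for s in scales:
        ratio = s / resolution
        j = int(round(np.log2(ratio)))
        if s < 2 * resolution or abs(ratio - 2**j) > 1e-6 * ratio:
            raise ValueError(
                f"scale {s:g} is not a dyadic multiple (>= 2x) of resolution "
                f"{resolution:g}"
            )
        levels.append(j)
    n_taps = 2 ** max(levels)
    d = np.arange(n_taps) * resolution
    u = _same_haplotype_probability(d, sizes, t)
    a = round(alpha * sizes[0]) / sizes[0]
    cov = a * (1.0 - a) * (u - (1.0 - u) / (sizes[0] - 1.0))
    variances = []
    for j in levels:
        f = haar_filter(j)
        acf = np.correlate(f, f, mode="full")
        center = len(f) - 1
        v = acf[center] * cov[0] + 2.0 * np.dot(acf[center + 1 : center + len(f)], cov[1 : len(f)])
        variances.append(v)
    return pd.DataFrame(
        {
            "level": levels,
            "scale_map": [2.0**j * resolution for j in levels],
            "variance": variances,
        }
    )


# ---------------------------------------------------------------------------
# scenario driver


_SCENARIOS: dict[str, Callable[[float, SelectionRegime], SelectionRegime]] = {
    "continuous": lambda S, base: replace(base, S=S, schedule=None),
    "early": lambda S, base: replace(
        base, S=S, schedule=SelectionRegime.early_only(S).schedule
    ),
    "late": lambda S, base: replace(
        base, S=S, schedule=SelectionRegime.late_onset(S).schedule
    ),
    "reversal": lambda S, base: replace(
        base, S=S, schedule=SelectionRegime.reversal(S).schedule
    ),
}


def run_selection_scenarios(
    config: SimConfig,
    scenarios: Sequence[str] = ("continuous", "early", "late", "reversal"),
    record_generations: Iterable[int] | None = None,
) -> dict[str, dict]:
    """Matched-seed runs of the canonical selection timing scenarios.

    For each scenario (continuous; selection on the first 10 hybrid
    generations only; onset after 500 neutral generations; direction
    reversal after 100 generations) the configured simulation is run with
    the scenario's schedule and, under the same seed, with S = 0 as a
    neutral control.  Results carry ancestry-proportion signals per
    recorded generation plus the recombination-rate signal when a physical
    map was supplied.
    """
    if config.selection is None or config.selection.S <= 0:
        raise ValueError("config must carry a selection regime with S > 0")
    base_regime = config.selection
    rec_signals = None
    if config.rec_maps is not None:
        rec_signals = {
            c: recombination_rate_signal(m, config.resolution)
            for c, m in config.rec_maps.items()
        }
    out: dict[str, dict] = {}
    for name in scenarios:
        if name not in _SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
        regime = _SCENARIOS[name](base_regime.S, base_regime)
        cfg = replace(config, selection=regime)
        snaps = simulate(cfg, record_generations)
        control_cfg = replace(config, selection=None)
        control = simulate(control_cfg, record_generations)
        out[name] = {
            "config": cfg,
            "snapshots": snaps,
            "signals": {g: ancestry_proportion_signal(s) for g, s in snaps.items()},
            "control_snapshots": control,
            "control_signals": {
                g: ancestry_proportion_signal(s) for g, s in control.items()
            },
            "recombination": rec_signals,
        }
    return out
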