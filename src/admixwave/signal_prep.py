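"""Preparation of evenly spaced per-chromosome signals.

Wavelet analysis requires a signal sampled at evenly spaced locations along a
chromosome, on either a physical (bp) or genetic (Morgan) map.  Raw genomic
observations -- ancestry-informative SNPs, recombination-map intervals,
genotype posteriors -- are irregular, so this module converts them:
computing diploid ancestry dosage from genotype posteriors, interpolating
irregular tracks to a fixed-step grid, moving tracks from physical to
genetic coordinates, and rescaling population-scaled (rho = 2*Ne*r)
recombination maps into Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "RawTrack",
    "GridSignal",
    "RecombinationMap",
    "GenotypePosteriorTrack",
    "diploid_dosage",
    "interpolate_to_grid",
    "physical_to_genetic",
    "rho_map_to_morgans",
    "log_transform_rates",
]

MapKind = Literal["physical", "genetic"]

#: conversion factor: 1 cM/Mb = 1e-8 Morgan/bp
_CM_PER_MB_TO_M_PER_BP = 1e-8


@dataclass
class RawTrack:
    """Irregularly spaced observations of a signal along one chromosome.

    Positions must be non-decreasing (ties can legitimately arise from
    degenerate genetic-map conversion; downstream gridding rejects
    zero-span tracks).
    """

    chromosome: str
    positions: np.ndarray
    values: np.ndarray
    map_kind: MapKind = "physical"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be 1-D and equal length")
        if len(self.positions) < 2:
            raise ValueError(
                f"track for {self.chromosome!r} needs >= 2 observations"
            )
        if np.any(np.diff(self.positions) < 0):
            raise ValueError(f"positions not sorted on {self.chromosome!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values on {self.chromosome!r}")

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class GridSignal:
    """An evenly spaced signal x(l), l = 1..L, along one chromosome.

    ``start`` records the map coordinate of the first grid point so that
    round-tripping through interpolation is lossless.
    """

    chromosome: str
    resolution: float
    values: np.ndarray
    map_kind: MapKind = "genetic"
    start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.values) < 2:
            raise ValueError(
                f"grid signal for {self.chromosome!r} needs >= 2 points"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values on {self.chromosome!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) * self.resolution


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rates over contiguous bp intervals.

    ``units`` is one of ``Morgan_per_bp``, ``cM_per_Mb`` or ``rho``
    (population-scaled, rho = 2*Ne*r per bp).  Intervals are half-open
    [start, end), contiguous and non-overlapping.
    """

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    rates: np.ndarray
    units: Literal["Morgan_per_bp", "cM_per_Mb", "rho"] = "Morgan_per_bp"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.rates)):
            raise ValueError("starts, ends, rates must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted interval in recombination map")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError(
                f"recombination map for {self.chromosome!r} has gaps/overlaps"
            )
        if np.any(self.rates < 0):
            raise ValueError("negative recombination rate")

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def rates_morgan_per_bp(self) -> np.ndarray:
        if self.units == "Morgan_per_bp":
            return self.rates
        if self.units == "cM_per_Mb":
            return self.rates * _CM_PER_MB_TO_M_PER_BP
        raise ValueError(
            "rho-scaled map: convert with rho_map_to_morgans() first"
        )

    def cumulative_at(self, positions: np.ndarray) -> np.ndarray:
        """Cumulative map length (in the map's own rate units x bp) from the
        chromosome start to each physical position."""
        positions = np.asarray(positions, dtype=float)
        if np.any(positions < self.starts[0]) or np.any(positions > self.ends[-1]):
            raise ValueError(
                f"position outside recombination map coverage on {self.chromosome!r}"
            )
        cum = np.concatenate([[0.0], np.cumsum(self.rates * self.widths)])
        idx = np.clip(
            np.searchsorted(self.ends, positions, side="left"), 0, len(self.rates) - 1
        )
        return cum[idx] + self.rates[idx] * (positions - self.starts[idx])

    @property
    def total_length(self) -> float:
        """Total map length in rate-units x bp (Morgans if Morgan_per_bp)."""
        return float(np.sum(self.rates * self.widths))


@dataclass
class GenotypePosteriorTrack:
    """Per-site posterior probabilities of the three diploid genotypes."""

    chromosome: str
    positions: np.ndarray
    pAA: np.ndarray
    pAa: np.ndarray
    paa: np.ndarray
    tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.pAA = np.asarray(self.pAA, dtype=float)
        self.pAa = np.asarray(self.pAa, dtype=float)
        self.paa = np.asarray(self.paa, dtype=float)
        for arr in (self.pAA, self.pAa, self.paa):
            if arr.shape != self.positions.shape:
                raise ValueError("posterior arrays must match positions")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("posterior probabilities must lie in [0, 1]")
        total = self.pAA + self.pAa + self.paa
        bad = np.flatnonzero(np.abs(total - 1.0) > self.tol)
        if bad.size:
            pos = self.positions[bad[0]]
            raise ValueError(
                f"posteriors do not sum to 1 at {self.chromosome}:{pos:g} "
                f"(sum={total[bad[0]]:.8f})"
            )


def diploid_dosage(track: GenotypePosteriorTrack) -> RawTrack:
    """Expected frequency of the A-type allele in a diploid.

    The dosage is the posterior-weighted average p_hat = P(AA) + P(Aa)/2,
    i.e. homozygotes contribute a full copy and heterozygotes half.
    """
    values = track.pAA + 0.5 * track.pAa
    return RawTrack(track.chromosome, track.positions, values, map_kind="physical")


def interpolate_to_grid(
    track: RawTrack,
    resolution: float,
    method: Literal["linear", "step"] = "linear",
) -> GridSignal:
    """Resample an irregular track onto an even grid.

    The grid is anchored at the first observed position and extends in
    steps of ``resolution`` up to the last observation; no extrapolation
    is performed.  ``linear`` interpolates between flanking observations;
    ``step`` carries the nearest preceding observation forward (appropriate
    for piecewise-constant signals such as haploid ancestry state).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if track.span < resolution:
        raise ValueError(
            f"resolution {resolution:g} exceeds the span ({track.span:g}) of "
            f"chromosome {track.chromosome!r}"
        )
    n = int(np.floor(track.span / resolution + 1e-9)) + 1
    grid = track.positions[0] + np.arange(n) * resolution
    if method == "linear":
        values = np.interp(grid, track.positions, track.values)
    elif method == "step":
        idx = np.searchsorted(track.positions, grid + 1e-12 * resolution, side="right") - 1
        values = track.values[np.clip(idx, 0, len(track.values) - 1)]
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return GridSignal(
        track.chromosome,
        resolution,
        values,
        map_kind=track.map_kind,
        start=float(grid[0]),
    )


def physical_to_genetic(track: RawTrack, rmap: RecombinationMap) -> RawTrack:
    """Replace bp positions with cumulative genetic distance (Morgans)."""
    if track.map_kind != "physical":
        raise ValueError("track is already on a genetic map")
    if rmap.units == "rho":
        raise ValueError("convert the rho-scaled map to Morgans first")
    morgan_map = RecombinationMap(
        rmap.chromosome,
        rmap.starts,
        rmap.ends,
        rmap.rates_morgan_per_bp(),
        units="Morgan_per_bp",
    )
    genetic = morgan_map.cumulative_at(track.positions)
    return RawTrack(track.chromosome, genetic, track.values, map_kind="genetic")


def rho_map_to_morgans(
    rmaps: dict[str, RecombinationMap],
    chrom_genetic_lengths: dict[str, float],
    truncation: float | None = None,
) -> tuple[dict[str, RecombinationMap], float]:
    """Convert population-scaled (rho = 2*Ne*r) maps to Morgans.

    2*Ne is estimated as the slope of a through-the-origin regression of
    per-chromosome cumulative rho lengths on external crossover-map genetic
    lengths (a chromosome of zero crossover length must have zero rho
    length, hence no intercept).  Before the regression, per-interval rho
    values above ``truncation`` are capped at it (winsorised): LD-based
    maps show extreme local outliers that would otherwise dominate the
    slope.  Rates are then divided by the estimated 2*Ne.

    Returns the converted maps and the 2*Ne estimate.
    """
    if len(rmaps) < 2:
        raise ValueError("need >= 2 chromosomes to regress rho on Morgans")
    missing = set(rmaps) - set(chrom_genetic_lengths)
    if missing:
        raise ValueError(f"no crossover-map length for chromosomes {sorted(missing)}")
    capped: dict[str, np.ndarray] = {}
    rho_lengths = {}
    for chrom, rmap in rmaps.items():
        if rmap.units != "rho":
            raise ValueError(f"map for {chrom!r} is not in rho units")
        rates = rmap.rates
        if truncation is not None:
            rates = np.minimum(rates, truncation)
        capped[chrom] = rates
        rho_lengths[chrom] = float(np.sum(rates * rmap.widths))
    x = np.array([chrom_genetic_lengths[c] for c in rmaps])  # Morgans
    y = np.array([rho_lengths[c] for c in rmaps])
    two_ne = float(np.sum(x * y) / np.sum(x * x))
    if two_ne <= 0:
        raise ValueError("estimated 2Ne is non-positive; check input maps")
    converted = {
        chrom: RecombinationMap(
            rmap.chromosome,
            rmap.starts,
            rmap.ends,
            capped[chrom] / two_ne,
            units="Morgan_per_bp",
        )
        for chrom, rmap in rmaps.items()
    }
    return converted, two_ne


def log_transform_rates(signal: GridSignal, offset: float | None = None) -> GridSignal:
    """log(value + offset), for recombination-rate signals whose variance is
    dominated by a long right tail.

    With ``offset=None`` the offset defaults to half the smallest positive
    value, which keeps zero rates finite while perturbing positive rates
    by less than one doubling.
    """
    values = signal.values
    if np.any(values < 0):
        raise ValueError("negative rates cannot be log-transformed")
    if offset is None:
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("all rates are zero; cannot choose a log offset")
        offset = float(positive.min()) / 2.0
    if offset == 0 and np.any(values == 0):
        raise ValueError("zero rate with zero offset: log undefined")
    return GridSignal(
        signal.chromosome,
        signal.resolution,
        np.log(values + offset),
        map_kind=signal.map_kind,
        start=signal.start,
    )
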