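"""Readers and writers for the tab-delimited interchange formats.

Signal tracks:        chrom  pos  value
Recombination maps:   chrom  start  end  rate      (units declared by caller)
Posterior tracks:     chrom  pos  pAA  pAa  paa
Decomposition tables: scale  scale_map  level  statistic  value  ...

Every run driver also writes a JSON provenance record (configuration,
seed, package version) so that results can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeDecomposition
from .signal_prep import (
    GenotypePosteriorTrack,
    GridSignal,
    RawTrack,
    RecombinationMap,
)

__all__ = [
    "read_signal_tracks",
    "write_signal_tracks",
    "read_recombination_maps",
    "read_posterior_tracks",
    "write_decomposition",
    "write_provenance",
]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_signal_tracks(
    path: str | Path, map_kind: Literal["physical", "genetic"] = "physical"
) -> dict[str, RawTrack]:
    """Read `chrom pos value` tracks, grouped by chromosome in first-seen
    order.  Unsorted or duplicated positions are rejected with their line
    numbers (1-based, counting the header)."""
    df = _read_table(path, ["chrom", "pos", "value"])
    tracks: dict[str, RawTrack] = {}
    for chrom in df["chrom"].drop_duplicates():
        sub = df[df["chrom"] == chrom]
        pos = sub["pos"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(pos) <= 0)
        if bad.size:
            lines = sub.index[bad + 1] + 2
            raise ValueError(
                f"{path}: unsorted or duplicate positions on {chrom!r} "
                f"at line(s) {list(lines[:5])}"
            )
        tracks[str(chrom)] = RawTrack(
            str(chrom), pos, sub["value"].to_numpy(dtype=float), map_kind=map_kind
        )
    return tracks


def write_signal_tracks(
    signals: dict[str, GridSignal] | dict[str, RawTrack], path: str | Path
) -> None:
    frames = []
    for chrom, sig in signals.items():
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": sig.positions, "value": sig.values}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_recombination_maps(
    path: str | Path,
    units: Literal["Morgan_per_bp", "cM_per_Mb", "rho"] = "cM_per_Mb",
) -> dict[str, RecombinationMap]:
    df = _read_table(path, ["chrom", "start", "end", "rate"])
    return {
        str(chrom): RecombinationMap(
            str(chrom),
            sub["start"].to_numpy(dtype=float),
            sub["end"].to_numpy(dtype=float),
            sub["rate"].to_numpy(dtype=float),
            units=units,
        )
        for chrom, sub in df.groupby("chrom", sort=False)
    }


def read_posterior_tracks(path: str | Path) -> dict[str, GenotypePosteriorTrack]:
    df = _read_table(path, ["chrom", "pos", "pAA", "pAa", "paa"])
    return {
        str(chrom): GenotypePosteriorTrack(
            str(chrom),
            sub["pos"].to_numpy(dtype=float),
            sub["pAA"].to_numpy(dtype=float),
            sub["pAa"].to_numpy(dtype=float),
            sub["paa"].to_numpy(dtype=float),
        )
        for chrom, sub in df.groupby("chrom", sort=False)
    }


def write_decomposition(decomp: GenomeDecomposition, path: str | Path) -> None:
    decomp.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_provenance(path: str | Path, config: dict, seed: int | None) -> None:
    record = {
        "package": "admixwave",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
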