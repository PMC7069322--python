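"""Binned coverage tracks: construction from alignments or bedGraph, and IO.

A :class:`CoverageTrack` holds per-scaffold vectors of binned coverage for
one sample, where each bin value is the per-base depth summed over the bin
(robust to read-length differences between libraries).  Bins are 0-based
half-open; a trailing partial bin keeps its true width.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = ["CoverageTrack", "bin_coverage", "bin_bedgraph", "read_fai", "write_bedgraph"]


@dataclass
class CoverageTrack:
    """Per-bin coverage of one sample over a set of scaffolds."""

    sample_id: str
    bin_size: int
    bins: dict[str, np.ndarray]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for scaf, v in self.bins.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any():
                raise ValueError(f"negative bin counts on {scaf}")
            self.bins[scaf] = v
            if scaf not in self.lengths:
                self.lengths[scaf] = len(v) * self.bin_size

    @property
    def total(self) -> float:
        """Sum of all bin values over all scaffolds."""
        return float(sum(v.sum() for v in self.bins.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.bins.values()))

    def bin_bounds(self, scaffold: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays in bp for one scaffold's bins."""
        n = len(self.bins[scaffold])
        starts = np.arange(n, dtype=np.int64) * self.bin_size
        ends = np.minimum(starts + self.bin_size, self.lengths[scaffold])
        return starts, ends

    def same_grid_as(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.bins) == set(other.bins)
            and all(len(self.bins[s]) == len(other.bins[s]) for s in self.bins)
        )


def read_fai(path: str | os.PathLike) -> dict[str, int]:
    """Scaffold lengths from a samtools .fai index."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["name", "length"])
    return dict(zip(df["name"], df["length"].astype(int)))


def _n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def _add_interval(vec: np.ndarray, start: int, end: int, value: float, bin_size: int) -> None:
    """Add value*overlap_bp to every bin overlapped by [start, end)."""
    first = start // bin_size
    last = (end - 1) // bin_size
    if first == last:
        vec[first] += value * (end - start)
        return
    vec[first] += value * ((first + 1) * bin_size - start)
    vec[last] += value * (end - last * bin_size)
    if last - first > 1:
        vec[first + 1 : last] += value * bin_size


def bin_coverage(
    path: str | os.PathLike,
    bin_size: int = 1000,
    min_mapq: int = 0,
    sample_id: str | None = None,
    lengths: dict[str, int] | None = None,
) -> CoverageTrack:
    """Bin per-base depth from a SAM/BAM/CRAM alignment file.

    Each aligned reference block of each read passing the MAPQ filter
    contributes its overlap length (in bp) to the bins it spans, i.e. bins
    hold summed per-base depth.  Scaffold lengths come from the header
    unless ``lengths`` overrides them; reads on scaffolds absent from
    ``lengths`` raise an error naming the offenders.
    """
    path = Path(path)
    with pysam.AlignmentFile(str(path)) as af:
        header_lengths = dict(zip(af.references, af.lengths))
        use = lengths if lengths is not None else header_lengths
        if lengths is not None:
            missing = sorted(set(header_lengths) - set(lengths))
            if missing:
                raise ValueError(
                    f"alignment scaffolds absent from provided lengths: {missing}"
                )
        bins = {
            scaf: np.zeros(_n_bins(length, bin_size))
            for scaf, length in use.items()
        }
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            vec = bins[read.reference_name]
            for s, e in read.get_blocks():
                _add_interval(vec, s, e, 1.0, bin_size)
    return CoverageTrack(
        sample_id=sample_id or path.stem,
        bin_size=bin_size,
        bins=bins,
        lengths=dict(use),
    )


def bin_bedgraph(
    path: str | os.PathLike,
    lengths: dict[str, int] | str | os.PathLike,
    bin_size: int = 1000,
    sample_id: str | None = None,
) -> CoverageTrack:
    """Bin a bedGraph depth track by overlap-weighted summation.

    A bedGraph interval ``[start, end) = d`` contributes ``d`` per bp, so a
    bin's value is the summed per-base depth exactly as on the alignment
    path.  ``lengths`` is a scaffold→length mapping or a .fai path.
    """
    path = Path(path)
    if not isinstance(lengths, dict):
        lengths = read_fai(lengths)
    bins = {
        scaf: np.zeros(_n_bins(length, bin_size)) for scaf, length in lengths.items()
    }
    offenders: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            scaf, start, end, value = line.split()[:4]
            if scaf not in bins:
                offenders.add(scaf)
                continue
            _add_interval(bins[scaf], int(start), int(end), float(value), bin_size)
    if offenders:
        raise ValueError(
            f"bedGraph scaffolds absent from FASTA index: {sorted(offenders)}"
        )
    return CoverageTrack(
        sample_id=sample_id or path.stem,
        bin_size=bin_size,
        bins=bins,
        lengths=dict(lengths),
    )


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Emit a track as bedGraph (one line per bin, value = binned depth sum)."""
    with open(path, "w") as fh:
        for scaf in sorted(track.bins):
            starts, ends = track.bin_bounds(scaf)
            for s, e, v in zip(starts, ends, track.bins[scaf]):
                fh.write(f"{scaf}\t{s}\t{e}\t{v:g}\n")
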