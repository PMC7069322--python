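"""Assembly contiguity and composition metrics.

N50 is the length of the scaffold at which the descending cumulative
length first reaches half the assembly total; L50 counts the scaffolds up
to and including it (first-crossing rule at exact boundaries).  NG50 uses
an externally supplied genome size — for instance one derived from a
C-value — in place of the assembly total.  GC% excludes N bases from the
denominator; N% is relative to total length.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = [
    "Scaffold",
    "AssemblyMetrics",
    "read_fasta",
    "compute_metrics",
    "cumulative_curve",
    "cvalue_to_gbp",
    "GBP_PER_PG",
]

#: genomic DNA mass-to-length conversion, Gbp per pg (0.978e9 bp/pg)
GBP_PER_PG = 0.978


@dataclass(frozen=True)
class Scaffold:
    """One assembly sequence record reduced to length and base composition."""

    id: str
    length: int
    gc_count: int
    n_count: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"scaffold {self.id!r} has non-positive length")
        if self.gc_count + self.n_count > self.length:
            raise ValueError(f"scaffold {self.id!r}: base counts exceed length")


@dataclass(frozen=True)
class AssemblyMetrics:
    n_scaffolds: int
    n_ge_1000: int
    total_length: int
    largest: int
    n50: int
    n75: int
    l50: int
    l75: int
    ng50: int | None
    gc_pct: float
    n_pct: float


def scaffold_from_sequence(name: str, seq: str) -> Scaffold:
    """Count composition case-insensitively; ambiguity codes other than N
    count toward length but neither GC nor N."""
    s = seq.upper()
    return Scaffold(
        id=name,
        length=len(s),
        gc_count=s.count("G") + s.count("C"),
        n_count=s.count("N"),
    )


def read_fasta(path: str | os.PathLike) -> list[Scaffold]:
    """Read a (possibly gzipped) FASTA into per-record composition summaries."""
    opener = gzip.open if str(path).endswith(".gz") else open
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate scaffold id {rec.id!r}")
            seen.add(rec.id)
            scaffolds.append(scaffold_from_sequence(rec.id, str(rec.seq)))
    if not scaffolds:
        raise ValueError(f"no FASTA records in {path}")
    return scaffolds


def _nx_lx(lengths_desc: np.ndarray, target: float) -> tuple[int, int]:
    """(Nx, Lx): first scaffold whose cumulative length reaches target."""
    cum = np.cumsum(lengths_desc)
    i = int(np.searchsorted(cum, target, side="left"))
    return int(lengths_desc[i]), i + 1


def compute_metrics(
    scaffolds: list[Scaffold],
    min_len: int = 500,
    genome_size: int | None = None,
    inclusive: bool = True,
) -> AssemblyMetrics:
    """Contiguity/composition metrics over scaffolds passing the length filter.

    ``inclusive`` keeps scaffolds of exactly ``min_len``.  When
    ``genome_size`` is given, NG50 is computed against it (undefined — and
    reported as None — if the assembly never reaches half the genome size).
    """
    kept = [s for s in scaffolds if (s.length >= min_len if inclusive else s.length > min_len)]
    if not kept:
        raise ValueError(f"no scaffolds pass the {min_len} bp filter")
    lengths = np.sort(np.array([s.length for s in kept], dtype=np.int64))[::-1]
    total = int(lengths.sum())
    n50, l50 = _nx_lx(lengths, 0.5 * total)
    n75, l75 = _nx_lx(lengths, 0.75 * total)
    ng50: int | None = None
    if genome_size is not None:
        if genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if total >= 0.5 * genome_size:
            ng50, _ = _nx_lx(lengths, 0.5 * genome_size)
    gc = sum(s.gc_count for s in kept)
    nn = sum(s.n_count for s in kept)
    return AssemblyMetrics(
        n_scaffolds=len(kept),
        n_ge_1000=int((lengths >= 1000).sum()),
        total_length=total,
        largest=int(lengths[0]),
        n50=n50,
        n75=n75,
        l50=l50,
        l75=l75,
        ng50=ng50,
        gc_pct=100.0 * gc / (total - nn) if total > nn else float("nan"),
        n_pct=100.0 * nn / total,
    )


def cumulative_curve(scaffolds: list[Scaffold]) -> np.ndarray:
    """Points (k, % of assembly covered by the k largest scaffolds).

    Returns an (n, 2) array; the curve is monotone non-decreasing and ends
    at 100%.
    """
    if not scaffolds:
        raise ValueError("no scaffolds")
    lengths = np.sort(np.array([s.length for s in scaffolds], dtype=np.int64))[::-1]
    pct = 100.0 * np.cumsum(lengths) / lengths.sum()
    k = np.arange(1, len(lengths) + 1)
    return np.column_stack([k, pct])


def scaffolds_to_cover(scaffolds: list[Scaffold], pct: float = 95.0) -> int:
    """Smallest k such that the k largest scaffolds cover >= pct of the assembly."""
    curve = cumulative_curve(scaffolds)
    return int(curve[np.searchsorted(curve[:, 1], pct, side="left"), 0])


def cvalue_to_gbp(c_value_pg: float) -> float:
    """Convert a haploid C-value in pg of DNA to genome size in Gbp.

    Uses 0.978 Gbp per pg; round only at reporting (e.g. 1.73 pg -> 1.69
    Gbp at two decimals).
    """
    if c_value_pg <= 0:
        raise ValueError("C-value must be positive")
    return c_value_pg * GBP_PER_PG
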