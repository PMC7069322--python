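"""Two-sample binned coverage-ratio statistic and CNV segmentation.

For each bin the statistic is ``r = e / (e + s*a)`` where ``e`` is the
focal sample's binned coverage, ``a`` the comparison sample's, and ``s`` a
library-size correction.  With equal copy number and corrected libraries
``r`` is expected at 0.5; a region duplicated in the comparison sample
pulls ``r`` down (0.33 for a twofold comparison excess), a deletion pushes
it up.  Deviant runs of bins are merged into CNV segments with an
estimated comparison:focal copy fold ``(1 - r) / r``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

__all__ = [
    "CNVSegment",
    "library_scale",
    "ratio_scan",
    "call_cnv",
    "write_ratios_tsv",
    "write_cnv_bed",
]

#: columns of the per-bin ratio table returned by :func:`ratio_scan`
RATIO_COLUMNS = ("scaffold", "start", "end", "e", "a_corrected", "r", "masked")


@dataclass(frozen=True)
class CNVSegment:
    """A merged run of deviant bins."""

    scaffold: str
    start: int
    end: int
    mean_r: float
    n_bins: int
    direction: str  # comparison_gain | comparison_loss

    @property
    def fold(self) -> float:
        """Estimated comparison:focal copy fold, (1 - mean_r) / mean_r."""
        return (1.0 - self.mean_r) / self.mean_r


def _check_grids(track_focal: CoverageTrack, track_comparison: CoverageTrack) -> None:
    if not track_focal.same_grid_as(track_comparison):
        raise ValueError("tracks differ in bin size or scaffold set")


def library_scale(
    track_focal: CoverageTrack,
    track_comparison: CoverageTrack,
    mode: str = "median-recenter",
) -> float:
    """Library-size correction factor ``s`` applied to the comparison track.

    ``totals`` divides the two library totals, the literal correction for
    library size.  ``median-recenter`` (default) picks ``s`` so the
    genome-wide median ratio lands on 0.5, which is robust when CNVs or
    sex-linked scaffolds bias the totals.
    """
    _check_grids(track_focal, track_comparison)
    if mode == "totals":
        te, ta = track_focal.total, track_comparison.total
        if te == 0 or ta == 0:
            raise ValueError("zero library total")
        return te / ta
    if mode == "median-recenter":
        e = np.concatenate([track_focal.bins[s] for s in sorted(track_focal.bins)])
        a = np.concatenate([track_comparison.bins[s] for s in sorted(track_focal.bins)])
        ok = (e > 0) & (a > 0)
        if not ok.any():
            raise ValueError("no informative bins for median recentering")
        # median r = 0.5  <=>  s = median(e/a)
        return float(np.median(e[ok] / a[ok]))
    raise ValueError(f"unknown scale mode {mode!r}")


def ratio_scan(
    track_focal: CoverageTrack,
    track_comparison: CoverageTrack,
    s: float = 1.0,
    min_combined: float = 10.0,
) -> pd.DataFrame:
    """Per-bin ratio table.

    Returns a DataFrame with columns ``scaffold, start, end, e,
    a_corrected, r, masked``; bins with combined corrected coverage below
    ``min_combined`` (in particular empty bins, where ``r`` is undefined)
    are masked with ``r = NaN`` and never imputed.
    """
    if s <= 0:
        raise ValueError("scale factor s must be positive")
    _check_grids(track_focal, track_comparison)
    frames = []
    for scaf in sorted(track_focal.bins):
        e = track_focal.bins[scaf]
        a_corr = s * track_comparison.bins[scaf]
        combined = e + a_corr
        masked = combined < min_combined
        r = np.full(len(e), np.nan)
        ok = combined > 0
        r[ok] = e[ok] / combined[ok]
        r[masked] = np.nan
        starts, ends = track_focal.bin_bounds(scaf)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "start": starts,
                    "end": ends,
                    "e": e,
                    "a_corrected": a_corr,
                    "r": r,
                    "masked": masked,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _runs_with_gaps(hit: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal [first, last] index runs of True, bridging gaps <= max_gap."""
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return []
    runs = []
    lo = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((int(lo), int(prev)))
            lo = prev = i
    runs.append((int(lo), int(prev)))
    return runs


def call_cnv(
    ratios: pd.DataFrame,
    low_thr: float = 0.40,
    high_thr: float = 0.60,
    min_bins: int = 5,
    max_gap_bins: int = 2,
) -> list[CNVSegment]:
    """Merge deviant bins into CNV segments.

    Unmasked bins with ``r <= low_thr`` seed comparison_gain segments
    (coverage excess in the comparison sample) and ``r >= high_thr``
    comparison_loss segments; runs may bridge up to ``max_gap_bins``
    non-deviant bins and must contain at least ``min_bins`` deviant bins.
    ``mean_r`` averages all unmasked bins the merged segment spans.
    """
    if not (0.0 < low_thr < 0.5 < high_thr < 1.0):
        raise ValueError("thresholds must satisfy 0 < low < 0.5 < high < 1")
    out: list[CNVSegment] = []
    for scaf, sub in ratios.groupby("scaffold", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        r = sub["r"].to_numpy()
        unmasked = ~sub["masked"].to_numpy()
        for direction, hit in (
            ("comparison_gain", unmasked & (r <= low_thr)),
            ("comparison_loss", unmasked & (r >= high_thr)),
        ):
            for lo, hi in _runs_with_gaps(hit, max_gap_bins):
                n_dev = int(hit[lo : hi + 1].sum())
                if n_dev < min_bins:
                    continue
                span_ok = unmasked[lo : hi + 1]
                mean_r = float(r[lo : hi + 1][span_ok].mean())
                out.append(
                    CNVSegment(
                        scaffold=str(scaf),
                        start=int(sub.loc[lo, "start"]),
                        end=int(sub.loc[hi, "end"]),
                        mean_r=mean_r,
                        n_bins=n_dev,
                        direction=direction,
                    )
                )
    out.sort(key=lambda seg: (seg.scaffold, seg.start))
    return out


def write_ratios_tsv(ratios: pd.DataFrame, path: str | os.PathLike) -> None:
    """Per-bin ratios as bedGraph-like TSV."""
    ratios.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cnv_bed(segments: list[CNVSegment], path: str | os.PathLike) -> None:
    """CNV calls as BED: name=direction, score=round(1000*mean_r), plus
    mean_r, fold and n_bins columns."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.scaffold}\t{seg.start}\t{seg.end}\t{seg.direction}\t"
                f"{round(1000 * seg.mean_r)}\t{seg.mean_r:.4f}\t{seg.fold:.3f}\t"
                f"{seg.n_bins}\n"
            )
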