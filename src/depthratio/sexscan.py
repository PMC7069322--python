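"""Z-chromosome scaffold assignment from male:female coverage folds.

In birds males are ZZ and females ZW, so Z-linked scaffolds show a
male:female coverage fold near 2 after library correction while autosomes
sit near 1.  Per scaffold the fold is the median over informative bins of
``e / (s*a)`` — the median is robust to CNV segments embedded in a
scaffold — and scaffolds are classified by disjoint fold bands, with an
explicit ambiguous class rather than forced binary calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

__all__ = ["ScaffoldSexCall", "scaffold_fold", "classify", "write_calls"]


@dataclass(frozen=True)
class ScaffoldSexCall:
    scaffold: str
    length: int
    median_fold: float
    n_informative_bins: int
    call: str  # Z | autosome | ambiguous


def scaffold_fold(
    track_male: CoverageTrack,
    track_female: CoverageTrack,
    s: float = 1.0,
    min_bins: int = 10,
    min_combined: float = 10.0,
) -> pd.DataFrame:
    """Median male:female library-corrected coverage fold per scaffold.

    Informative bins have female coverage > 0 and combined corrected
    coverage >= ``min_combined``.  Scaffolds with fewer than ``min_bins``
    informative bins are excluded from the result.
    """
    if s <= 0:
        raise ValueError("scale factor s must be positive")
    if not track_male.same_grid_as(track_female):
        missing = set(track_male.bins) ^ set(track_female.bins)
        if missing:
            raise ValueError(f"scaffolds absent from one track: {sorted(missing)}")
        raise ValueError("tracks differ in bin size or bin counts")
    rows = []
    for scaf in sorted(track_male.bins):
        e = track_male.bins[scaf]
        a_corr = s * track_female.bins[scaf]
        ok = (a_corr > 0) & (e + a_corr >= min_combined)
        n_inf = int(ok.sum())
        if n_inf < min_bins:
            continue
        fold = float(np.median(e[ok] / a_corr[ok]))
        rows.append(
            {
                "scaffold": scaf,
                "length": track_male.lengths[scaf],
                "median_fold": fold,
                "n_informative_bins": n_inf,
            }
        )
    return pd.DataFrame(rows, columns=["scaffold", "length", "median_fold", "n_informative_bins"])


def classify(
    folds: pd.DataFrame,
    z_band: tuple[float, float] = (1.6, 2.6),
    auto_band: tuple[float, float] = (0.8, 1.25),
    min_len: int = 10_000,
) -> tuple[list[ScaffoldSexCall], dict]:
    """Classify scaffolds into Z / autosome / ambiguous and summarize.

    The summary reports the number of Z scaffolds, their total length and
    the percentage of the filtered assembly they cover.
    """
    if not (auto_band[0] < auto_band[1] and z_band[0] < z_band[1]):
        raise ValueError("bands must be non-empty intervals")
    if max(auto_band[0], z_band[0]) < min(auto_band[1], z_band[1]):
        raise ValueError("z_band and auto_band overlap")
    calls: list[ScaffoldSexCall] = []
    kept = folds[folds["length"] >= min_len]
    for row in kept.itertuples(index=False):
        fold = float(row.median_fold)
        if z_band[0] <= fold <= z_band[1]:
            call = "Z"
        elif auto_band[0] <= fold <= auto_band[1]:
            call = "autosome"
        else:
            call = "ambiguous"
        calls.append(
            ScaffoldSexCall(
                scaffold=row.scaffold,
                length=int(row.length),
                median_fold=fold,
                n_informative_bins=int(row.n_informative_bins),
                call=call,
            )
        )
    total_len = int(kept["length"].sum())
    z_calls = [c for c in calls if c.call == "Z"]
    z_bp = sum(c.length for c in z_calls)
    summary = {
        "n_scaffolds": len(calls),
        "n_z": len(z_calls),
        "z_bp": z_bp,
        "z_pct_of_assembly": 100.0 * z_bp / total_len if total_len else float("nan"),
    }
    return calls, summary


def write_calls(
    calls: list[ScaffoldSexCall],
    tsv_path: str | os.PathLike,
    bed_path: str | os.PathLike | None = None,
) -> None:
    """TSV of all calls; optional BED of Z scaffolds."""
    df = pd.DataFrame(
        [
            {
                "scaffold": c.scaffold,
                "length": c.length,
                "median_fold": round(c.median_fold, 4),
                "n_informative_bins": c.n_informative_bins,
                "call": c.call,
            }
            for c in calls
        ]
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in calls:
                if c.call == "Z":
                    fh.write(f"{c.scaffold}\t0\t{c.length}\tZ\n")
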