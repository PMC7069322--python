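"""qPCR relative copy-number quantification with standard curves.

A standard curve is the ordinary least-squares fit of Ct on log10 starting
copies over a dilution series; its slope m gives the amplification
efficiency E = 10^(-1/m) - 1 (m = -3.3219 cycles/decade is a perfect
doubling, E = 100%).  Unknown samples are quantified on their assay's
curve and the target:control copy ratio is reported per sample, with
mean ± sd per group.  Replicate QC follows the duplicate rule: a sample is
discarded when any two replicate Ct values differ by more than 0.3 cycles
(exactly 0.3 passes).
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "SampleQuant",
    "fit_standard_curve",
    "duplicate_qc",
    "quantify_sample",
    "relative_copy_number",
    "analyze_table",
]

MAX_DELTA_CT = 0.3


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares calibration Ct = slope * log10(copies) + intercept."""

    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification gain, E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, log10_copies: float) -> float:
        return self.slope * log10_copies + self.intercept

    def copies_from_ct(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass(frozen=True)
class SampleQuant:
    sample_id: str
    assay_id: str
    ct_replicates: tuple[float, ...]
    qc_pass: bool
    mean_ct: float  # NaN when QC fails
    copies: float  # NaN when QC fails or no curve


def fit_standard_curve(points, assay_id: str = "assay") -> StandardCurve:
    """Fit a dilution series of (log10_copies, Ct) pairs; needs >= 3 levels."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (log10_copies, Ct) pairs")
    levels = np.unique(pts[:, 0])
    if len(levels) < 3:
        raise ValueError("standard curve needs >= 3 distinct dilution levels")
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    if not np.isfinite(fit.slope) or fit.slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    return StandardCurve(
        assay_id=assay_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(pts),
    )


def duplicate_qc(
    ct_replicates,
    max_delta: float = MAX_DELTA_CT,
    accept_single: bool = False,
) -> tuple[bool, float]:
    """(qc_pass, mean_ct) under the max-pairwise replicate rule.

    Fails when any two replicates differ by more than ``max_delta`` cycles
    (the boundary passes).  A single replicate is rejected unless
    ``accept_single``.
    """
    cts = [float(c) for c in ct_replicates]
    if len(cts) == 0:
        raise ValueError("no replicates")
    if len(cts) == 1:
        return (True, cts[0]) if accept_single else (False, math.nan)
    for a, b in itertools.combinations(cts, 2):
        # small epsilon so the exact boundary passes despite float rounding
        if abs(a - b) > max_delta + 1e-9:
            return False, math.nan
    return True, float(np.mean(cts))


def quantify_sample(
    sample_id: str,
    assay_id: str,
    ct_replicates,
    curve: StandardCurve | None = None,
    max_delta: float = MAX_DELTA_CT,
    accept_single: bool = False,
) -> SampleQuant:
    """QC replicates and, when a curve is given, convert mean Ct to copies."""
    qc_pass, mean_ct = duplicate_qc(ct_replicates, max_delta, accept_single)
    copies = math.nan
    if qc_pass and curve is not None:
        copies = curve.copies_from_ct(mean_ct)
    return SampleQuant(
        sample_id=sample_id,
        assay_id=assay_id,
        ct_replicates=tuple(float(c) for c in ct_replicates),
        qc_pass=qc_pass,
        mean_ct=mean_ct,
        copies=copies,
    )


def relative_copy_number(target: SampleQuant, control: SampleQuant) -> float:
    """Target:control copy ratio for one sample; both assays must pass QC."""
    if not target.qc_pass:
        raise ValueError(f"target assay failed replicate QC for {target.sample_id!r}")
    if not control.qc_pass:
        raise ValueError(f"control assay failed replicate QC for {control.sample_id!r}")
    if not (target.copies > 0 and control.copies > 0):
        raise ValueError("copies undefined; quantify on a standard curve first")
    return target.copies / control.copies


def analyze_table(
    table: pd.DataFrame,
    target_assay: str = "target",
    control_assay: str = "control",
    max_delta: float = MAX_DELTA_CT,
    mode: str = "curve",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full analysis of a long-format Ct table.

    Expected columns: ``sample_id, group, assay_id, role, log10_copies,
    ct`` with ``role`` in {standard, unknown}.  Mode ``curve`` (default)
    fits one standard curve per assay from the standard rows and quantifies
    absolutely; mode ``ddct`` uses the perfect-efficiency shortcut
    ratio = 2^-(mean Ct_target - mean Ct_control) and needs no standards.
    Returns (per-sample table, per-group mean ± sd summary); QC-failed
    samples are retained in the per-sample table with reason but excluded
    from summaries.
    """
    required = {"sample_id", "assay_id", "role", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    curves: dict[str, StandardCurve] = {}
    if mode == "curve":
        std = table[table["role"] == "standard"]
        for assay in (target_assay, control_assay):
            sub = std[std["assay_id"] == assay]
            if sub.empty:
                raise ValueError(f"no standard-curve rows for assay {assay!r}")
            curves[assay] = fit_standard_curve(
                sub[["log10_copies", "ct"]].to_numpy(), assay_id=assay
            )
    elif mode != "ddct":
        raise ValueError(f"unknown mode {mode!r}")

    unknowns = table[table["role"] == "unknown"]
    rows = []
    for sample, sub in unknowns.groupby("sample_id", sort=True):
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        quants: dict[str, SampleQuant] = {}
        for assay in (target_assay, control_assay):
            cts = sub.loc[sub["assay_id"] == assay, "ct"].tolist()
            if not cts:
                quants[assay] = None  # type: ignore[assignment]
                continue
            quants[assay] = quantify_sample(
                sample, assay, cts, curves.get(assay), max_delta=max_delta
            )
        tq, cq = quants.get(target_assay), quants.get(control_assay)
        reason = ""
        ratio = math.nan
        if tq is None or cq is None:
            reason = "missing assay"
        elif not (tq.qc_pass and cq.qc_pass):
            failed = [a for a, q in quants.items() if q is not None and not q.qc_pass]
            reason = f"replicate QC failed ({', '.join(failed)})"
        elif mode == "curve":
            ratio = relative_copy_number(tq, cq)
        else:
            ratio = 2.0 ** (-(tq.mean_ct - cq.mean_ct))
        rows.append(
            {
                "sample_id": sample,
                "group": group,
                "target_mean_ct": tq.mean_ct if tq else math.nan,
                "control_mean_ct": cq.mean_ct if cq else math.nan,
                "qc_pass": reason == "",
                "exclusion_reason": reason,
                "relative_ratio": ratio,
            }
        )
    per_sample = pd.DataFrame(rows)
    ok = per_sample[per_sample["qc_pass"]]
    summary = (
        ok.groupby("group")["relative_ratio"]
        .agg(n="count", mean_ratio="mean", sd_ratio=lambda x: x.std(ddof=1))
        .reset_index()
        if not ok.empty
        else pd.DataFrame(columns=["group", "n", "mean_ratio", "sd_ratio"])
    )
    return per_sample, summary


def write_results(
    per_sample: pd.DataFrame,
    summary: pd.DataFrame,
    sample_path: str | os.PathLike,
    summary_path: str | os.PathLike,
) -> None:
    per_sample.to_csv(sample_path, sep="\t", index=False, float_format="%.5g")
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.5g")
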