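"""Synthetic genomes, two-sample coverage tracks, GC-stratified exons and qPCR tables.

The generator emulates the data layout of a two-individual comparative
read-depth study: a focal male (ZZ) genome against a comparison female (ZW)
genome mapped to the same assembly.  Coverage is simulated directly as
per-bin depth sums (not reads), because the downstream ratio statistic
consumes binned coverage only.

Per-bin counts are drawn with mean ``mu = phi * c * w`` where ``phi`` is the
mean per-base depth contributed by one haploid copy, ``c`` the local copy
number (autosomes: 2; Z: 2 in the male, 1 in the female; planted CNV
segments: as specified) and ``w`` the bin width in bp.  ``dispersion = 0``
gives Poisson counts; ``dispersion > 0`` gives negative-binomial counts with
variance ``mu * (1 + dispersion * mu)``.  The comparison sample's drawn
counts are then multiplied by its library-scale factor, emulating unequal
library sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

__all__ = [
    "SimParams",
    "CNVSpec",
    "TruthSet",
    "GC_CLASSES",
    "simulate_genome",
    "make_truth",
    "simulate_coverage",
    "simulate_exons",
    "simulate_qpcr",
    "gc_class_of",
]

MALE = "male"
FEMALE = "female"


@dataclass(frozen=True)
class CNVSpec:
    """A planted copy-number segment: absolute copies per sample."""

    scaffold: str
    start: int
    end: int
    focal_copies: int
    comparison_copies: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")
        if self.focal_copies < 0 or self.comparison_copies < 0:
            raise ValueError("copy numbers must be non-negative")

    @property
    def expected_ratio(self) -> float:
        """Focal/(focal+comparison) copy ratio after library correction."""
        tot = self.focal_copies + self.comparison_copies
        if tot == 0:
            return math.nan
        return self.focal_copies / tot


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-sample coverage simulation.

    ``depth_per_copy`` is phi, the mean per-base depth of one haploid copy;
    the default 15 puts the diploid focal sample at ~30x, the order of a
    typical short-read genome project.
    """

    n_autosomes: int = 8
    n_z_scaffolds: int = 2
    scaffold_length: int = 1_000_000
    bin_size: int = 1000
    depth_per_copy: float = 15.0
    dispersion: float = 0.0
    library_scale_comparison: float = 1.0
    gc_content: float = 0.42
    cnv_segments: tuple[CNVSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autosomes < 0 or self.n_z_scaffolds < 0:
            raise ValueError("scaffold counts must be non-negative")
        if self.n_autosomes + self.n_z_scaffolds == 0:
            raise ValueError("need at least one scaffold")
        if self.scaffold_length <= 0 or self.bin_size <= 0:
            raise ValueError("lengths must be positive")
        if self.scaffold_length % self.bin_size != 0:
            raise ValueError("scaffold_length must be a multiple of bin_size")
        if self.depth_per_copy <= 0:
            raise ValueError("depth_per_copy must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.library_scale_comparison <= 0:
            raise ValueError("library_scale_comparison must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        segs = tuple(
            s if isinstance(s, CNVSpec) else CNVSpec(*s) for s in self.cnv_segments
        )
        object.__setattr__(self, "cnv_segments", segs)
        names = set(self.scaffold_ids)
        by_scaffold: dict[str, list[CNVSpec]] = {}
        for s in segs:
            if s.scaffold not in names:
                raise ValueError(f"CNV segment on unknown scaffold {s.scaffold!r}")
            if s.end > self.scaffold_length:
                raise ValueError(f"CNV segment {s} exceeds scaffold length")
            by_scaffold.setdefault(s.scaffold, []).append(s)
        for scaf, lst in by_scaffold.items():
            lst = sorted(lst, key=lambda s: s.start)
            for a, b in zip(lst, lst[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping CNV segments on {scaf}: {a} and {b}"
                    )

    @property
    def autosome_ids(self) -> tuple[str, ...]:
        return tuple(f"autosome_{i + 1}" for i in range(self.n_autosomes))

    @property
    def z_ids(self) -> tuple[str, ...]:
        return tuple(f"z_scaffold_{i + 1}" for i in range(self.n_z_scaffolds))

    @property
    def scaffold_ids(self) -> tuple[str, ...]:
        return self.autosome_ids + self.z_ids

    @property
    def n_bins_per_scaffold(self) -> int:
        return self.scaffold_length // self.bin_size

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for a simulated genome: sex linkage and planted CNVs."""

    z_scaffold_ids: frozenset[str]
    cnv_segments: tuple[CNVSpec, ...]
    bin_size: int
    lengths: dict[str, int] = field(default_factory=dict)

    def copy_number(self, scaffold: str, sex: str) -> np.ndarray:
        """Length-weighted mean copy number per bin for one sample.

        Bins straddling a CNV boundary get the bp-weighted mean of the two
        copy numbers, mirroring a gene that sits across a duplication edge.
        """
        if sex not in (MALE, FEMALE):
            raise ValueError(f"unknown sex label {sex!r}")
        length = self.lengths[scaffold]
        n_bins = -(-length // self.bin_size)
        if scaffold in self.z_scaffold_ids:
            base = 2.0 if sex == MALE else 1.0
        else:
            base = 2.0
        per_bp = np.full(length, base)
        for seg in self.cnv_segments:
            if seg.scaffold != scaffold:
                continue
            c = seg.focal_copies if sex == MALE else seg.comparison_copies
            per_bp[seg.start : seg.end] = float(c)
        full = length // self.bin_size
        out = np.empty(n_bins)
        if full:
            out[:full] = per_bp[: full * self.bin_size].reshape(
                full, self.bin_size
            ).mean(axis=1)
        if n_bins > full:  # trailing partial bin keeps its true width
            out[full] = per_bp[full * self.bin_size :].mean()
        return out

    def expected_ratio(self, scaffold: str) -> np.ndarray:
        """Expected per-bin focal/(focal+comparison) ratio after library correction."""
        cf = self.copy_number(scaffold, MALE)
        cc = self.copy_number(scaffold, FEMALE)
        with np.errstate(invalid="ignore", divide="ignore"):
            return cf / (cf + cc)

    def neutral_mask(self, scaffold: str) -> np.ndarray:
        """True for bins untouched by any planted CNV segment."""
        length = self.lengths[scaffold]
        n_bins = -(-length // self.bin_size)
        mask = np.ones(n_bins, dtype=bool)
        for seg in self.cnv_segments:
            if seg.scaffold != scaffold:
                continue
            first = seg.start // self.bin_size
            last = -(-seg.end // self.bin_size)
            mask[first:last] = False
        return mask


def make_truth(params: SimParams) -> TruthSet:
    """Truth annotations only (no sequences); cheap for coverage-only studies."""
    lengths = {name: params.scaffold_length for name in params.scaffold_ids}
    return TruthSet(
        z_scaffold_ids=frozenset(params.z_ids),
        cnv_segments=params.cnv_segments,
        bin_size=params.bin_size,
        lengths=lengths,
    )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"AGCT", dtype="S1"), size=length, p=probs)
    return bases.tobytes().decode("ascii")


def simulate_genome(
    params: SimParams, with_sequences: bool = True
) -> tuple[dict[str, str], TruthSet]:
    """Generate scaffold sequences and the matching truth annotations.

    Returns a ``{scaffold_id: sequence}`` mapping (empty strings when
    ``with_sequences`` is False) and a :class:`TruthSet` labelling every
    scaffold as autosome or Z and recording the planted CNV segments.
    """
    truth = make_truth(params)
    seqs: dict[str, str] = {}
    if with_sequences:
        ss = np.random.SeedSequence([params.seed, 101])
        rngs = [np.random.default_rng(s) for s in ss.spawn(len(params.scaffold_ids))]
        for name, rng in zip(params.scaffold_ids, rngs):
            seqs[name] = _random_sequence(rng, params.scaffold_length, params.gc_content)
    else:
        seqs = {name: "" for name in params.scaffold_ids}
    return seqs, truth


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    # NB with var = mu (1 + dispersion * mu): shape n = 1/dispersion
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def simulate_coverage(params: SimParams, truth: TruthSet, sex: str) -> CoverageTrack:
    """Draw one sample's per-bin coverage track.

    ``sex`` doubles as the sample role: the male is the focal sample, the
    female the comparison sample whose counts carry the library-scale
    factor.  Fixed ``params.seed`` gives bit-identical output.
    """
    if sex not in (MALE, FEMALE):
        raise ValueError(f"unknown sex label {sex!r}; expected 'male' or 'female'")
    role = 0 if sex == MALE else 1
    ss = np.random.SeedSequence([params.seed, 202, role])
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(truth.lengths))]
    scale = 1.0 if sex == MALE else params.library_scale_comparison
    bins: dict[str, np.ndarray] = {}
    for (scaffold, length), rng in zip(sorted(truth.lengths.items()), rngs):
        copies = truth.copy_number(scaffold, sex)
        widths = np.full(copies.shape, params.bin_size, dtype=float)
        rem = length % params.bin_size
        if rem:
            widths[-1] = rem
        mu = params.depth_per_copy * copies * widths
        bins[scaffold] = _draw_counts(rng, mu, params.dispersion) * scale
    return CoverageTrack(
        sample_id=f"sim_{sex}",
        bin_size=params.bin_size,
        bins=bins,
        lengths=dict(truth.lengths),
    )


# --- GC-stratified exon sets -------------------------------------------------

#: GC classes as (label, lower bound %, upper bound %), inclusive lower bound.
GC_CLASSES: tuple[tuple[str, float, float], ...] = (
    (">=70", 70.0, 100.0000001),
    ("60-69", 60.0, 70.0),
    ("50-59", 50.0, 60.0),
    ("40-49", 40.0, 50.0),
    ("<40", 0.0, 40.0),
)

_CLASS_BOUNDS = {label: (lo, hi) for label, lo, hi in GC_CLASSES}


def gc_class_of(gc_pct: float) -> str:
    """Assign a GC percentage to its class (inclusive lower bounds)."""
    for label, lo, hi in GC_CLASSES:
        if lo <= gc_pct < hi:
            return label
    raise ValueError(f"GC percentage out of range: {gc_pct}")


def _target_gc_count(label: str, length: int) -> int:
    lo, hi = _CLASS_BOUNDS[label]
    mid = min(max((lo + min(hi, 100.0)) / 2.0, lo), 99.9)
    k = round(mid / 100.0 * length)
    # nudge onto the class interval if rounding fell off it
    while k <= length and 100.0 * k / length < lo:
        k += 1
    while k >= 0 and 100.0 * k / length >= hi:
        k -= 1
    if not (0 <= k <= length and lo <= 100.0 * k / length < hi):
        raise ValueError(
            f"no achievable GC count for class {label!r} at length {length}"
        )
    return k


def simulate_exons(
    n_per_class: dict[str, int],
    exon_length: int = 120,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate exon sequences whose realized GC falls inside assigned classes.

    ``n_per_class`` maps class labels (see :data:`GC_CLASSES`) to exon
    counts.  Returns a DataFrame with columns ``exon_id, gc_class, length,
    gc_pct, sequence``.
    """
    if exon_length < 1:
        raise ValueError("exon_length must be positive")
    unknown = set(n_per_class) - set(_CLASS_BOUNDS)
    if unknown:
        raise ValueError(f"unknown GC class labels: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    strong = np.frombuffer(b"GC", dtype="S1")
    weak = np.frombuffer(b"AT", dtype="S1")
    rows = []
    for label, _, _ in GC_CLASSES:
        n = n_per_class.get(label, 0)
        if n < 0:
            raise ValueError("exon counts must be non-negative")
        k = _target_gc_count(label, exon_length) if n else 0
        for j in range(n):
            arr = np.concatenate(
                [
                    rng.choice(strong, size=k),
                    rng.choice(weak, size=exon_length - k),
                ]
            )
            rng.shuffle(arr)
            seq = arr.tobytes().decode("ascii")
            gc_pct = 100.0 * k / exon_length
            rows.append(
                {
                    "exon_id": f"exon_{label}_{j + 1}",
                    "gc_class": label,
                    "length": exon_length,
                    "gc_pct": gc_pct,
                    "sequence": seq,
                }
            )
    return pd.DataFrame(rows)


# --- qPCR Ct tables ----------------------------------------------------------


def simulate_qpcr(
    true_ratio: float,
    curve,
    noise_sd: float = 0.0,
    replicates: int = 2,
    control_copies: float = 1e4,
    n_samples: int = 1,
    group: str = "simulated",
    include_standards: bool = False,
    standard_levels: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table for a target/control relative-quantification assay.

    Ct values are produced by evaluating the standard curve at the implied
    copy numbers (control at ``control_copies``, target at ``true_ratio``
    times that) and adding Gaussian noise of sd ``noise_sd`` cycles.  Both
    assays share the supplied curve.  Output columns follow the analysis
    table contract: ``sample_id, group, assay_id, role, log10_copies, ct``.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    rows = []
    for i in range(n_samples):
        sample = f"{group}_{i + 1}"
        for assay, copies in (
            ("control", control_copies),
            ("target", true_ratio * control_copies),
        ):
            base_ct = curve.predict_ct(math.log10(copies))
            for _ in range(replicates):
                ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "assay_id": assay,
                        "role": "unknown",
                        "log10_copies": math.nan,
                        "ct": ct,
                    }
                )
    if include_standards:
        for assay in ("control", "target"):
            for lvl in standard_levels:
                base_ct = curve.predict_ct(lvl)
                for _ in range(replicates):
                    ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                    rows.append(
                        {
                            "sample_id": f"std_1e{lvl:g}",
                            "group": "standard",
                            "assay_id": assay,
                            "role": "standard",
                            "log10_copies": lvl,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)
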