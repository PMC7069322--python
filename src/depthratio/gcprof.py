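"""GC content by gene region and GC-stratified exon recovery.

Gene models are split into 5'UTR, CDS and 3'UTR; per gene the regions of a
kind are concatenated and their GC% computed (N bases excluded from the
denominator), then mean and sd are taken across genes.  Exon recovery asks
whether each first exon can be found in an assembly by local alignment —
recovered when an alignment covers at least ``min_cov`` of the exon at
``min_ident`` identity — and tallies recovery per GC class.  High-GC first
exons are the classic casualty of PCR-biased short-read libraries, which
is what the class-stratified recovery quantifies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement

from .simulate import GC_CLASSES, gc_class_of

__all__ = [
    "GeneModel",
    "read_gff3",
    "gc_percent",
    "gc_by_region",
    "exon1_recovery",
]

REGION_KINDS = ("five_prime_utr", "cds", "three_prime_utr")

_GFF_KIND = {
    "five_prime_UTR": "five_prime_utr",
    "CDS": "cds",
    "three_prime_UTR": "three_prime_utr",
}


@dataclass(frozen=True)
class GeneModel:
    """A gene's region layout: (kind, start, end) in 0-based half-open bp."""

    gene_id: str
    scaffold: str
    strand: str
    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for kind, start, end in self.regions:
            if kind not in REGION_KINDS:
                raise ValueError(f"unknown region kind {kind!r}")
            if not 0 <= start < end:
                raise ValueError(f"bad region bounds [{start}, {end})")
        spans = sorted((s, e) for _, s, e in self.regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping regions in gene {self.gene_id!r}")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models (5'UTR / CDS / 3'UTR features) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        regions: list[tuple[str, int, int]] = []
        for feat in db.children(gene, featuretype=tuple(_GFF_KIND)):
            # GFF3 is 1-based closed; convert to 0-based half-open
            regions.append((_GFF_KIND[feat.featuretype], feat.start - 1, feat.end))
        if regions:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    scaffold=gene.seqid,
                    strand=gene.strand or "+",
                    regions=tuple(sorted(regions, key=lambda r: r[1])),
                )
            )
    if not genes:
        raise ValueError(f"no gene models with annotated regions in {path}")
    return genes


def gc_percent(seq: str) -> float:
    """GC% of a sequence, N bases excluded from the denominator."""
    s = seq.upper()
    n = s.count("N")
    denom = len(s) - n
    if denom == 0:
        return float("nan")
    return 100.0 * (s.count("G") + s.count("C")) / denom


def _fetch(sequences, scaffold: str, start: int, end: int) -> str:
    seq = sequences[scaffold]
    s = str(seq[start:end]) if not isinstance(seq, str) else seq[start:end]
    if len(s) != end - start:
        raise ValueError(
            f"region [{start}, {end}) outside sequence {scaffold!r} (len {len(seq)})"
        )
    return s


def gc_by_region(genes: list[GeneModel], sequences) -> pd.DataFrame:
    """Mean ± sd GC% per region kind across genes.

    ``sequences`` is any mapping from scaffold id to sequence (dict of str,
    ``pyfaidx.Fasta``, ...).  Per gene, all regions of one kind are
    concatenated before computing GC%; minus-strand regions are
    reverse-complemented first (irrelevant to GC, kept for sequence-export
    consistency).  The sd is the sample standard deviation across genes.
    """
    per_gene: dict[str, list[float]] = {k: [] for k in REGION_KINDS}
    for gene in genes:
        parts: dict[str, list[str]] = {k: [] for k in REGION_KINDS}
        for kind, start, end in gene.regions:
            s = _fetch(sequences, gene.scaffold, start, end)
            if gene.strand == "-":
                s = reverse_complement(s)
            parts[kind].append(s)
        for kind, chunks in parts.items():
            if chunks:
                per_gene[kind].append(gc_percent("".join(chunks)))
    rows = []
    for kind in REGION_KINDS:
        vals = np.array(per_gene[kind])
        rows.append(
            {
                "region": kind,
                "n_genes": len(vals),
                "mean_gc_pct": float(vals.mean()) if len(vals) else float("nan"),
                "sd_gc_pct": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _local_alignment_stats(query: str, target: str) -> tuple[float, float]:
    """Best local alignment (coverage of query, identity) vs one target."""
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1.0,
        mismatch_score=-2.0,
        open_gap_score=-2.5,
        extend_gap_score=-0.5,
    )
    try:
        aln = aligner.align(target, query)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    counts = aln.counts()
    gaps, identities, mismatches = counts.gaps, counts.identities, counts.mismatches
    cols = gaps + identities + mismatches
    if cols == 0:
        return 0.0, 0.0
    qblocks = aln.aligned[1]
    span = int(qblocks[-1][1] - qblocks[0][0])
    return span / len(query), identities / cols


def _is_recovered(query: str, targets: list[str], min_cov: float, min_ident: float) -> bool:
    q = query.upper()
    candidates = [q, reverse_complement(q)]
    for t in targets:
        for qq in candidates:
            # fast path: full-length infix hit (coverage 1) via edit distance
            res = edlib.align(qq, t, mode="HW", task="distance")
            ed = res["editDistance"]
            if ed >= 0 and (len(qq) - ed) / len(qq) >= min_ident and min_cov <= 1.0:
                return True
        for qq in candidates:
            cov, ident = _local_alignment_stats(qq, t)
            if cov >= min_cov and ident >= min_ident:
                return True
    return False


def exon1_recovery(
    exons: pd.DataFrame,
    assembly,
    min_cov: float = 0.8,
    min_ident: float = 0.9,
) -> pd.DataFrame:
    """Per-GC-class recovery of first exons in an assembly.

    ``exons`` needs columns ``sequence`` and either ``gc_class`` or enough
    to derive it (GC is recomputed when the column is absent).
    ``assembly`` is a mapping from scaffold id to sequence or a FASTA
    accessor.  Returns per-class n, n_recovered and recovered percentage;
    an empty class reports NaN, not 0.
    """
    if not 0 < min_cov <= 1 or not 0 < min_ident <= 1:
        raise ValueError("min_cov and min_ident must be in (0, 1]")
    targets = [str(assembly[k]).upper() for k in assembly.keys()]
    df = exons.copy()
    if "gc_class" not in df.columns:
        df["gc_class"] = [gc_class_of(gc_percent(s)) for s in df["sequence"]]
    recovered = [
        _is_recovered(seq, targets, min_cov, min_ident) for seq in df["sequence"]
    ]
    df["recovered"] = recovered
    rows = []
    for label, _, _ in GC_CLASSES:
        sub = df[df["gc_class"] == label]
        n = len(sub)
        n_rec = int(sub["recovered"].sum())
        rows.append(
            {
                "gc_class": label,
                "n": n,
                "n_recovered": n_rec,
                "recovered_pct": 100.0 * n_rec / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
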