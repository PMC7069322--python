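"""Writers for simulated datasets: FASTA, truth BEDs, Ct TSVs."""

from __future__ import annotations

import os
import textwrap

from .simulate import TruthSet

__all__ = ["write_fasta", "write_truth_beds"]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for line in textwrap.wrap(seq, width, drop_whitespace=False):
                fh.write(line + "\n")


def write_truth_beds(
    truth: TruthSet,
    cnv_path: str | os.PathLike,
    z_path: str | os.PathLike,
) -> None:
    """Planted CNV segments and Z scaffolds as BED (0-based half-open)."""
    with open(cnv_path, "w") as fh:
        for seg in truth.cnv_segments:
            fh.write(
                f"{seg.scaffold}\t{seg.start}\t{seg.end}\t"
                f"cnv_{seg.focal_copies}v{seg.comparison_copies}\n"
            )
    with open(z_path, "w") as fh:
        for scaf in sorted(truth.z_scaffold_ids):
            fh.write(f"{scaf}\t0\t{truth.lengths[scaf]}\tZ\n")
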