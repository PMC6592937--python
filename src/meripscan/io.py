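"""Readers and writers for the plain-text formats the pipeline exchanges.

Aligned reads travel as BED6 (name = ``sample:condition``), peaks as
BED6+4 in transcript space (chrom column = gene_id), window statistics as
TSV, and transcript sequences as FASTA. All writers emit tab-separated
text without headers unless noted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import AlignedRead


def read_bed6(
    path: str | Path, sample: str | None = None, condition: str | None = None
) -> list[AlignedRead]:
    """Read aligned reads from BED6.

    When ``sample``/``condition`` are not given, the name field is parsed
    as ``sample:condition``.
    """
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >=6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            smp, cond = sample, condition
            if smp is None or cond is None:
                parts = name.split(":")
                smp = smp or (parts[0] if parts else "IP")
                cond = cond or (parts[1] if len(parts) > 1 else "")
            reads.append(
                AlignedRead(
                    chrom=chrom, start=int(start), length=int(end) - int(start),
                    strand=strand, sample=smp, condition=cond,
                )
            )
    return reads


def write_bed6(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            name = f"{r.sample}:{r.condition}" if r.condition else r.sample
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def peaks_to_frame(peaks) -> pd.DataFrame:
    """Tabulate peaks as a BED6+4 frame (chrom = gene_id, transcript space)."""
    import math

    rows = []
    counts: dict[str, int] = {}
    for p in peaks:
        n = counts.get(p.gene_id, 0) + 1
        counts[p.gene_id] = n
        rows.append(
            {
                "chrom": p.gene_id,
                "start": p.start,
                "end": p.end,
                "name": f"{p.gene_id}:peak_{n}",
                "score": int(round(100 * math.log2(p.peak_es))) if p.peak_es > 0 else 0,
                "strand": "+",
                "p": p.min_p,
                "q": p.min_q,
                "es": p.peak_es,
                "summit": p.summit,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "p", "q", "es", "summit"],
    )


def write_peaks_bed(peaks, path: str | Path) -> None:
    frame = peaks_to_frame(peaks)
    frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_peaks_bed(path: str | Path) -> list:
    """Read peaks back from the BED6+4 written by :func:`write_peaks_bed`."""
    from .peakcalling import Peak

    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}: line {lineno}: expected 10 BED6+4 fields")
            peaks.append(
                Peak(
                    gene_id=f[0], start=int(f[1]), end=int(f[2]),
                    n_windows=0, peak_es=float(f[8]), summit=int(f[9]),
                    min_q=float(f[7]), min_p=float(f[6]),
                )
            )
    return peaks


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
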