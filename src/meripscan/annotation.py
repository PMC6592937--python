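"""Transcript models and genome <-> transcript coordinate mapping.

MeRIP-seq peak calling operates in the coordinate system of each gene's
longest spliced isoform: aligned reads are extended to the library's mean
fragment size in genomic space and then projected onto the exon structure,
so that the windows and peaks downstream live on the mRNA rather than on
the genome. This module provides the transcript model, the longest-isoform
selection rule, strand-aware read extension, and the projection of genomic
intervals into transcript coordinates.

Conventions: all coordinates are 0-based, half-open. On the minus strand,
transcript coordinate 0 corresponds to the highest genomic coordinate of
the exon set (the 5' end of the mRNA).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence


class AnnotationError(ValueError):
    """Raised for malformed annotation records (message names the line)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's isoform: exon structure, strand and CDS offsets.

    ``exons`` are genomic intervals, 0-based half-open, sorted by genomic
    start and non-overlapping. ``cds_start``/``cds_end`` are *transcript*
    offsets delimiting the CDS; a non-coding model has cds_start == cds_end.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int = 0
    cds_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(
                f"transcript {self.transcript_id} has no exons"
            )
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: bad exon ({s}, {e})"
                )
            if s < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = e
        if not (0 <= self.cds_start <= self.cds_end <= self.length):
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS offsets out of range"
            )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_end

    # -- coordinate mapping ------------------------------------------------

    def _plus_offset(self, pos: int) -> Optional[int]:
        """Transcript offset of genomic ``pos`` in 5'->3' *genomic* order."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to a transcript position (None if intronic)."""
        t = self._plus_offset(pos)
        if t is None:
            return None
        return t if self.strand == "+" else self.length - 1 - t

    def transcript_to_genomic(self, pos: int) -> int:
        """Map a transcript position back to its genomic position."""
        if not (0 <= pos < self.length):
            raise ValueError(f"transcript position {pos} out of [0, {self.length})")
        t = pos if self.strand == "+" else self.length - 1 - pos
        off = 0
        for s, e in self.exons:
            if t < off + (e - s):
                return s + (t - off)
            off += e - s
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped aligned read (or extended fragment) in genomic coordinates."""

    chrom: str
    start: int
    length: int
    strand: str
    sample: str = "IP"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("read start must be >= 0")
        if self.length <= 0:
            raise ValueError("read length must be > 0")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TranscriptInterval:
    """A half-open interval in the transcript coordinates of one gene."""

    gene_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad transcript interval [{self.start}, {self.end})")


def extend_read(read: AlignedRead, fragment_length: int = 150) -> AlignedRead:
    """Extend a read to the mean fragment size, keeping its 5' end fixed.

    On the plus strand the start stays put; on the minus strand the genomic
    end (the read's 5' end) stays put and the start moves upstream. If the
    extension would run past genomic coordinate 0 the fragment is truncated
    there.
    """
    if fragment_length < read.length:
        raise ValueError(
            f"fragment_length {fragment_length} < read length {read.length}"
        )
    if read.strand == "+":
        return dataclasses.replace(read, length=fragment_length)
    new_start = max(0, read.end - fragment_length)
    return dataclasses.replace(read, start=new_start, length=read.end - new_start)


def genome_to_transcript(
    read: AlignedRead, model: TranscriptModel
) -> Optional[TranscriptInterval]:
    """Project a (typically extended) read onto a transcript.

    The genomic extent is intersected with the exon set; the exonic bases
    are mapped to transcript coordinates and the single spanning interval
    [min, max+1) is returned. Returns None when the read is on a different
    chromosome or entirely intronic/intergenic.
    """
    if read.chrom != model.chrom:
        return None
    g0, g1 = read.start, read.end
    tmin: Optional[int] = None
    tmax: Optional[int] = None
    off = 0
    for s, e in model.exons:
        lo, hi = max(g0, s), min(g1, e)
        if lo < hi:
            for g in (lo, hi - 1):
                t_plus = off + (g - s)
                t = t_plus if model.strand == "+" else model.length - 1 - t_plus
                tmin = t if tmin is None else min(tmin, t)
                tmax = t if tmax is None else max(tmax, t)
        off += e - s
    if tmin is None:
        return None
    return TranscriptInterval(model.gene_id, tmin, tmax + 1)


def select_longest_isoform(
    models: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick one isoform per gene, maximizing spliced length.

    Ties are broken by lexicographically smallest transcript_id so the
    choice is deterministic.
    """
    best: dict[str, TranscriptModel] = {}
    for m in sorted(models, key=lambda m: (m.gene_id, -m.length, m.transcript_id)):
        best.setdefault(m.gene_id, m)
    return best


# -- annotation readers ----------------------------------------------------


def _thick_to_cds(
    model_exons: Sequence[tuple[int, int]],
    strand: str,
    thick_start: int,
    thick_end: int,
) -> tuple[int, int]:
    """Convert a genomic thick (CDS) region into transcript CDS offsets."""
    probe = TranscriptModel(
        gene_id="_", transcript_id="_", chrom="_", strand=strand,
        exons=tuple(model_exons),
    )
    if thick_start >= thick_end:
        return 0, 0
    # snap the thick boundaries onto exonic bases
    first = None
    for s, e in model_exons:
        if e > thick_start:
            first = max(s, thick_start)
            break
    last = None
    for s, e in reversed(model_exons):
        if s < thick_end:
            last = min(e, thick_end) - 1
            break
    if first is None or last is None or first > last:
        return 0, 0
    ta = probe.genomic_to_transcript(first)
    tb = probe.genomic_to_transcript(last)
    assert ta is not None and tb is not None
    return min(ta, tb), max(ta, tb) + 1


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: BED12 record has {len(fields)} fields")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        thick_start = int(fields[6])
        thick_end = int(fields[7])
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(f"line {lineno}: blockCount does not match block lists")
    exons = tuple(
        (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
    )
    if "|" in name:
        gene_id, transcript_id = name.split("|", 1)
    else:
        gene_id = transcript_id = name
    try:
        cds_start, cds_end = _thick_to_cds(exons, strand, thick_start, thick_end)
        return TranscriptModel(
            gene_id=gene_id, transcript_id=transcript_id, chrom=chrom,
            strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end,
        )
    except AnnotationError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from exc


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            models.append(_parse_bed12_line(line, lineno))
    return models


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from a GTF file (Ensembl/UCSC dialects)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        if tid is None:
            raise AnnotationError(
                f"{feat.featuretype} record without transcript_id near "
                f"{feat.seqid}:{feat.start}"
            )
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        # GTF is 1-based inclusive; convert to 0-based half-open
        iv = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        ex = tuple(sorted(ex))
        if tid in cds:
            thick_start = min(s for s, _ in cds[tid])
            thick_end = max(e for _, e in cds[tid])
        else:
            thick_start = thick_end = 0
        cds_start, cds_end = _thick_to_cds(ex, strand, thick_start, thick_end)
        models.append(
            TranscriptModel(
                gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                exons=ex, cds_start=cds_start, cds_end=cds_end,
            )
        )
    return models


def load_annotation(path: str | Path) -> list[TranscriptModel]:
    """Load a GTF or BED12 annotation, dispatching on the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return read_gtf(path)
    if suffix in (".bed", ".bed12"):
        return read_bed12(path)
    raise AnnotationError(f"unrecognized annotation format: {path.name}")
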