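"""Peak-set comparison across conditions, metagene profiling and motif check.

Two peak sets called on the same annotation are compared by >= 1 nt
overlap within each gene: overlapping peaks are "common", the rest are
condition-unique. A gene is a common m6A gene if it carries at least one
common peak; genes whose peaks never overlap the other condition's peaks
are unique m6A genes of their condition.

The metagene profile places each peak's summit on a standardized mRNA
model of 100 bins - 10 for the 5'UTR, 50 for the CDS, 40 for the 3'UTR -
and reports the percentage of peaks per bin. Region proportions aggregate
the same assignment at the 5'UTR/CDS/3'UTR level. The motif check scans
peak and non-peak transcript sequence for a fixed consensus (GGACU,
U == T) and reports the per-nucleotide rate ratio with a one-sided Fisher
exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation import TranscriptModel
from .peakcalling import Peak, fisher_window_test

UTR5_BINS = 10
CDS_BINS = 50
UTR3_BINS = 40
N_BINS = UTR5_BINS + CDS_BINS + UTR3_BINS


@dataclass
class PeakSetComparison:
    common_pairs: list[tuple[Peak, Peak]]
    unique_a: list[Peak]
    unique_b: list[Peak]
    common_genes: set[str]
    unique_genes_a: set[str]
    unique_genes_b: set[str]


def compare_peak_sets(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    lengths_a: Optional[Mapping[str, int]] = None,
    lengths_b: Optional[Mapping[str, int]] = None,
) -> PeakSetComparison:
    """Classify peaks as common (>= 1 nt overlap, same gene) or unique.

    When per-gene transcript lengths are supplied for both sets they must
    agree on shared genes (both sets must come from the same annotation).
    """
    if lengths_a is not None and lengths_b is not None:
        for g in set(lengths_a) & set(lengths_b):
            if lengths_a[g] != lengths_b[g]:
                raise ValueError(
                    f"annotation mismatch for gene {g}: "
                    f"lengths {lengths_a[g]} != {lengths_b[g]}"
                )
    by_gene_b: dict[str, list[Peak]] = {}
    for p in peaks_b:
        by_gene_b.setdefault(p.gene_id, []).append(p)

    common_pairs: list[tuple[Peak, Peak]] = []
    common_a_ids: set[int] = set()
    common_b_ids: set[int] = set()
    for pa in peaks_a:
        for pb in by_gene_b.get(pa.gene_id, []):
            if pa.start < pb.end and pb.start < pa.end:
                common_pairs.append((pa, pb))
                common_a_ids.add(id(pa))
                common_b_ids.add(id(pb))
    unique_a = [p for p in peaks_a if id(p) not in common_a_ids]
    unique_b = [p for p in peaks_b if id(p) not in common_b_ids]
    common_genes = {pa.gene_id for pa, _ in common_pairs}
    genes_a = {p.gene_id for p in peaks_a}
    genes_b = {p.gene_id for p in peaks_b}
    return PeakSetComparison(
        common_pairs=common_pairs,
        unique_a=unique_a,
        unique_b=unique_b,
        common_genes=common_genes,
        unique_genes_a=genes_a - common_genes,
        unique_genes_b=genes_b - common_genes,
    )


def metagene_bin(peak: Peak, model: TranscriptModel) -> Optional[int]:
    """Bin index (0..99) of a peak's summit on the standardized mRNA.

    Returns None (peak skipped) for models lacking any of the three
    regions. Within a region, bin = offset + floor(fraction * bins),
    clamped to the region's last bin.
    """
    u5, cds, u3 = model.utr5_len, model.cds_len, model.utr3_len
    if u5 == 0 or cds == 0 or u3 == 0:
        return None
    s = peak.summit
    if s < model.cds_start:
        return min(UTR5_BINS - 1, s * UTR5_BINS // u5)
    if s < model.cds_end:
        return UTR5_BINS + min(CDS_BINS - 1, (s - model.cds_start) * CDS_BINS // cds)
    return (UTR5_BINS + CDS_BINS
            + min(UTR3_BINS - 1, (s - model.cds_end) * UTR3_BINS // u3))


@dataclass
class MetageneProfile:
    bins: np.ndarray  # 100 percentages, 5' -> 3'
    n_peaks: int
    n_skipped: int = 0


def metagene_profile(
    peaks: Iterable[Peak], models: Mapping[str, TranscriptModel]
) -> MetageneProfile:
    counts = np.zeros(N_BINS, dtype=np.int64)
    skipped = 0
    for p in peaks:
        model = models.get(p.gene_id)
        b = metagene_bin(p, model) if model is not None else None
        if b is None:
            skipped += 1
        else:
            counts[b] += 1
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no usable peaks for metagene profile")
    return MetageneProfile(bins=100.0 * counts / n, n_peaks=n, n_skipped=skipped)


@dataclass
class RegionProportions:
    utr5: float
    cds: float
    utr3: float
    n_peaks: int
    n_skipped: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"5'UTR": self.utr5, "CDS": self.cds, "3'UTR": self.utr3}


def region_proportions(
    peaks: Iterable[Peak], models: Mapping[str, TranscriptModel]
) -> RegionProportions:
    """Fractions of peaks whose summit falls in the 5'UTR, CDS and 3'UTR."""
    counts = {"utr5": 0, "cds": 0, "utr3": 0}
    skipped = 0
    for p in peaks:
        model = models.get(p.gene_id)
        b = metagene_bin(p, model) if model is not None else None
        if b is None:
            skipped += 1
        elif b < UTR5_BINS:
            counts["utr5"] += 1
        elif b < UTR5_BINS + CDS_BINS:
            counts["cds"] += 1
        else:
            counts["utr3"] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no usable peaks for region proportions")
    return RegionProportions(
        utr5=counts["utr5"] / n, cds=counts["cds"] / n, utr3=counts["utr3"] / n,
        n_peaks=n, n_skipped=skipped,
    )


@dataclass
class MotifReport:
    motif: str
    fold: float
    p_value: float
    peak_hits: int
    background_hits: int
    peak_length: int
    background_length: int
    n_genes: int
    n_genes_skipped: int = 0

    @property
    def peak_rate(self) -> float:
        return self.peak_hits / self.peak_length if self.peak_length else 0.0

    @property
    def background_rate(self) -> float:
        return self.background_hits / self.background_length if self.background_length else 0.0


def _find_motif_positions(seq: str, motif: str) -> list[int]:
    positions = []
    pos = seq.find(motif)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(motif, pos + 1)
    return positions


def motif_enrichment(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    motif: str = "GGACU",
) -> MotifReport:
    """Fold enrichment of a fixed motif under peaks vs the rest of the
    same transcripts (U and T treated as equivalent).

    An occurrence belongs to the peak class when its start position lies
    inside a peak interval; rates are per covered nucleotide, and the
    p-value is a one-sided Fisher exact test of occurrence counts against
    covered lengths. Genes with peaks but no sequence are skipped.
    """
    motif_dna = motif.upper().replace("U", "T")
    by_gene: dict[str, list[Peak]] = {}
    for p in peaks:
        by_gene.setdefault(p.gene_id, []).append(p)
    peak_hits = bg_hits = 0
    peak_len = bg_len = 0
    n_genes = n_skipped = 0
    for gene_id, gpeaks in sorted(by_gene.items()):
        seq = sequences.get(gene_id)
        if seq is None:
            n_skipped += 1
            continue
        n_genes += 1
        seq = seq.upper().replace("U", "T")
        intervals = sorted((p.start, min(p.end, len(seq))) for p in gpeaks)
        covered = sum(max(0, e - s) for s, e in intervals)
        peak_len += covered
        bg_len += len(seq) - covered
        for pos in _find_motif_positions(seq, motif_dna):
            if any(s <= pos < e for s, e in intervals):
                peak_hits += 1
            else:
                bg_hits += 1
    if peak_hits == 0:
        fold = 0.0
    elif bg_hits == 0 or bg_len == 0:
        fold = float("inf")
    else:
        fold = (peak_hits / peak_len) / (bg_hits / bg_len)
    if peak_len == 0 and bg_len == 0:
        p_value = 1.0
    else:
        p_value = fisher_window_test(
            peak_hits, bg_hits,
            max(0, peak_len - peak_hits), max(0, bg_len - bg_hits),
        )
    return MotifReport(
        motif=motif, fold=fold, p_value=p_value,
        peak_hits=peak_hits, background_hits=bg_hits,
        peak_length=peak_len, background_length=bg_len,
        n_genes=n_genes, n_genes_skipped=n_skipped,
    )
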