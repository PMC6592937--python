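"""Sliding-window IP-vs-input peak calling on transcript coordinates.

Each gene's longest isoform is scanned with 100-nt windows at a 10-nt
step. Per window, the fragment counts of the immunoprecipitated (IP)
library are contrasted with the input library by a one-sided Fisher exact
test (toward IP enrichment), with the rest of the gene's fragments as the
second row of the 2x2 table. Windows whose raw count is below 1/20 of the
gene's top window in *both* libraries are excluded before testing, to
blunt the effect of inaccurate gene structure annotation. P-values are
adjusted by Benjamini-Hochberg across all tested windows of the dataset.
A window is positive when FDR < 0.01 and log2 of its enrichment score

    ES = (a * d) / (b * c)

is >= 1, where a and c are the window's IP and input fragment counts and
b and d the gene's median window counts (the medians are computed over
ALL windows, before any exclusion, and act as per-gene library-size
normalizers). Overlapping positive windows are merged into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import (
    AlignedRead,
    TranscriptInterval,
    TranscriptModel,
    extend_read,
    genome_to_transcript,
)

DEFAULT_WINDOW = 100
DEFAULT_STEP = 10
DEFAULT_MIN_FRACTION = 1.0 / 20.0
DEFAULT_FDR = 0.01
DEFAULT_MIN_LOG2_ES = 1.0
DEFAULT_FRAGMENT_LENGTH = 150


@dataclass
class GeneWindowTable:
    """Per-gene sliding-window fragment counts plus gene-level summaries."""

    gene_id: str
    length: int
    window: int
    step: int
    starts: np.ndarray
    ip_counts: np.ndarray
    input_counts: np.ndarray
    n_ip_fragments: int
    n_input_fragments: int

    # gene-level summaries, computed over ALL windows (before exclusion)
    ip_median: float = field(init=False)
    input_median: float = field(init=False)
    ip_top: int = field(init=False)
    input_top: int = field(init=False)

    def __post_init__(self) -> None:
        self.ip_median = float(np.median(self.ip_counts))
        self.input_median = float(np.median(self.input_counts))
        self.ip_top = int(self.ip_counts.max(initial=0))
        self.input_top = int(self.input_counts.max(initial=0))

    @property
    def effective_window(self) -> int:
        """Window width actually used (full length for short transcripts)."""
        return min(self.window, self.length)


def window_starts(length: int, window: int = DEFAULT_WINDOW,
                  step: int = DEFAULT_STEP) -> np.ndarray:
    """Window start positions: 0, step, 2*step, ...

    For length >= window there are floor((L - window)/step) + 1 windows;
    shorter transcripts get a single full-length window.
    """
    if length <= 0:
        raise ValueError("transcript length must be positive")
    if length < window:
        return np.array([0], dtype=np.int64)
    n = (length - window) // step + 1
    return np.arange(n, dtype=np.int64) * step


def _as_interval_arrays(
    intervals: Sequence[TranscriptInterval] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(intervals, tuple) and len(intervals) == 2:
        s, e = intervals
        return np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64)
    s = np.array([iv.start for iv in intervals], dtype=np.int64)
    e = np.array([iv.end for iv in intervals], dtype=np.int64)
    return s, e


def _overlap_counts(
    frag_start: np.ndarray, frag_end: np.ndarray, n_windows: int,
    window: int, step: int,
) -> np.ndarray:
    """Count, per window, the fragments overlapping it by >= 1 nt."""
    counts = np.zeros(n_windows, dtype=np.int64)
    if frag_start.size == 0:
        return counts
    # smallest k with k*step + window > start  /  largest k with k*step < end
    k_min = np.maximum(0, (frag_start - window) // step + 1)
    k_max = np.minimum(n_windows - 1, (frag_end - 1) // step)
    valid = k_min <= k_max
    k_min, k_max = k_min[valid], k_max[valid]
    diff = np.zeros(n_windows + 1, dtype=np.int64)
    np.add.at(diff, k_min, 1)
    np.add.at(diff, k_max + 1, -1)
    return np.cumsum(diff)[:n_windows]


def count_windows(
    model: TranscriptModel,
    ip_intervals,
    input_intervals,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> GeneWindowTable:
    """Build the sliding-window count table for one gene.

    A fragment contributes 1 to every window its transcript interval
    overlaps by at least one nucleotide.
    """
    starts = window_starts(model.length, window, step)
    eff_window = min(window, model.length)
    ip_s, ip_e = _as_interval_arrays(ip_intervals)
    in_s, in_e = _as_interval_arrays(input_intervals)
    ip_counts = _overlap_counts(ip_s, ip_e, len(starts), eff_window, step)
    input_counts = _overlap_counts(in_s, in_e, len(starts), eff_window, step)
    return GeneWindowTable(
        gene_id=model.gene_id, length=model.length, window=window, step=step,
        starts=starts, ip_counts=ip_counts, input_counts=input_counts,
        n_ip_fragments=int(ip_s.size), n_input_fragments=int(in_s.size),
    )


def filter_low_windows(
    table: GeneWindowTable, fraction: float = DEFAULT_MIN_FRACTION
) -> np.ndarray:
    """Boolean mask of retained windows.

    A window is excluded iff its raw count is below ``fraction`` of the
    gene's top window in BOTH the IP and the input library. Genes whose
    top is 0 in either library are skipped upstream.
    """
    low_ip = table.ip_counts < fraction * table.ip_top
    low_input = table.input_counts < fraction * table.input_top
    return ~(low_ip & low_input)


def normalize_counts(table: GeneWindowTable) -> tuple[np.ndarray, np.ndarray]:
    """Median-normalized per-window counts (a/b, c/d), for reporting/ES."""
    if table.ip_median <= 0 or table.input_median <= 0:
        raise ValueError(
            f"gene {table.gene_id}: insufficient coverage (zero median)"
        )
    return (table.ip_counts / table.ip_median,
            table.input_counts / table.input_median)


def fisher_pvalues(
    ip_in, input_in, ip_rest, input_rest
) -> np.ndarray:
    """Vectorized one-sided (IP-enrichment) Fisher exact p-values.

    For the 2x2 table [ip_in, input_in; ip_rest, input_rest], the p-value
    is the hypergeometric tail P(X >= ip_in) with population size the
    grand total, ip_in + ip_rest IP fragments in the population, and
    ip_in + input_in fragments drawn into the window.
    """
    a = np.asarray(ip_in, dtype=np.int64)
    c = np.asarray(input_in, dtype=np.int64)
    ar = np.asarray(ip_rest, dtype=np.int64)
    cr = np.asarray(input_rest, dtype=np.int64)
    if np.any(a < 0) or np.any(c < 0) or np.any(ar < 0) or np.any(cr < 0):
        raise ValueError("Fisher table entries must be non-negative")
    total = a + c + ar + cr
    with np.errstate(all="ignore"):
        p = hypergeom.sf(a - 1, total, a + ar, a + c)
    p = np.where(a == 0, 1.0, p)  # P(X >= 0) = 1, covers all-zero tables
    return np.clip(p, 0.0, 1.0)


def fisher_window_test(
    ip_in: int, input_in: int, ip_rest: int, input_rest: int
) -> float:
    """Scalar one-sided Fisher exact p for a single window's 2x2 table."""
    return float(fisher_pvalues([ip_in], [input_in], [ip_rest], [input_rest])[0])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over the whole tested family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def enrichment_score(a, b, c, d):
    """ES = (a*d)/(b*c) with a pseudocount of 1/2 on a and c when c = 0.

    a, c are a window's IP/input fragment counts; b, d the gene's median
    window counts. The score is invariant under rescaling all IP counts
    by one constant and all input counts by another. Accepts scalars or
    arrays (b, d broadcast).
    """
    a_arr = np.asarray(a, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    d_arr = np.asarray(d, dtype=float)
    if np.any(b_arr <= 0) or np.any(d_arr <= 0):
        raise ValueError("gene medians must be positive (gene should be skipped)")
    zero_c = c_arr == 0
    a_adj = np.where(zero_c, a_arr + 0.5, a_arr)
    c_adj = np.where(zero_c, 0.5, c_arr)
    es = (a_adj * d_arr) / (b_arr * c_adj)
    if np.isscalar(a) and np.isscalar(c):
        return float(es)
    return es


def call_positive_windows(
    q_values, es_values,
    q_max: float = DEFAULT_FDR, min_log2_es: float = DEFAULT_MIN_LOG2_ES,
) -> np.ndarray:
    """Positive <=> q < q_max (strict) and log2(ES) >= min_log2_es (inclusive)."""
    q = np.asarray(q_values, dtype=float)
    es = np.asarray(es_values, dtype=float)
    with np.errstate(divide="ignore"):
        log2es = np.where(es > 0, np.log2(np.where(es > 0, es, 1.0)), -np.inf)
    return (q < q_max) & (log2es >= min_log2_es)


@dataclass(frozen=True)
class Peak:
    """A merged run of overlapping positive windows, in transcript space."""

    gene_id: str
    start: int
    end: int
    n_windows: int
    peak_es: float
    summit: int
    min_q: float
    min_p: float = float("nan")


def merge_windows(
    gene_id: str,
    starts: Sequence[int],
    es: Sequence[float],
    q: Sequence[float],
    p: Sequence[float] | None = None,
    window: int = DEFAULT_WINDOW,
    length: Optional[int] = None,
    recount_es=None,
) -> list[Peak]:
    """Merge overlapping positive windows of one gene into peaks.

    ``starts`` must be the sorted start positions of the positive windows.
    The peak's ES is recomputed over the merged interval via the
    ``recount_es(start, end)`` callback when given (fragment counts a, c
    recounted over [start, end) with b, d unchanged); otherwise the
    maximum constituent-window ES is used. The summit is the midpoint of
    the constituent window with the highest ES.
    """
    if len(starts) == 0:
        return []
    starts = np.asarray(starts, dtype=np.int64)
    es = np.asarray(es, dtype=float)
    q = np.asarray(q, dtype=float)
    p_arr = np.asarray(p, dtype=float) if p is not None else np.full(len(starts), np.nan)
    order = np.argsort(starts, kind="stable")
    starts, es, q, p_arr = starts[order], es[order], q[order], p_arr[order]

    def win_end(s: int) -> int:
        e = s + window
        return min(e, length) if length is not None else e

    peaks: list[Peak] = []
    run_start = 0
    run_end_pos = win_end(int(starts[0]))
    for i in range(1, len(starts) + 1):
        if i < len(starts) and starts[i] < run_end_pos:
            run_end_pos = max(run_end_pos, win_end(int(starts[i])))
            continue
        lo, hi = run_start, i
        best = lo + int(np.argmax(es[lo:hi]))
        peak_start = int(starts[lo])
        peak_end = run_end_pos
        if recount_es is not None:
            peak_es = float(recount_es(peak_start, peak_end))
        else:
            peak_es = float(es[best])
        summit = min(int(starts[best]) + (win_end(int(starts[best])) - int(starts[best])) // 2,
                     peak_end - 1)
        peaks.append(
            Peak(
                gene_id=gene_id, start=peak_start, end=peak_end,
                n_windows=hi - lo, peak_es=peak_es, summit=summit,
                min_q=float(np.min(q[lo:hi])),
                min_p=float(np.min(p_arr[lo:hi])),
            )
        )
        if i < len(starts):
            run_start = i
            run_end_pos = win_end(int(starts[i]))
    return peaks


# -- whole-dataset driver ----------------------------------------------------


@dataclass
class PeakCallParams:
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    min_fraction: float = DEFAULT_MIN_FRACTION
    fdr: float = DEFAULT_FDR
    min_log2_es: float = DEFAULT_MIN_LOG2_ES
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH

    def validate(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.fragment_length <= 0:
            raise ValueError("window, step and fragment_length must be positive")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not (0 <= self.min_fraction < 1):
            raise ValueError("min_fraction must lie in [0, 1)")


@dataclass
class PeakCallResult:
    peaks: list[Peak]
    window_stats: pd.DataFrame
    skipped: dict[str, str]
    n_windows_tested: int


def _reads_to_arrays(reads: Iterable[AlignedRead]):
    """Group reads per chromosome as (start, length, is_minus) arrays."""
    by_chrom: dict[str, list[tuple[int, int, bool]]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.length, r.strand == "-"))
    out = {}
    for chrom, rows in by_chrom.items():
        arr = np.asarray(rows, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2].astype(bool))
    return out


def _map_fragments(
    model: TranscriptModel, arrays, fragment_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend reads to fragments and project onto the transcript.

    Fast vectorized path for single-exon models; exact per-read fallback
    (extend_read + genome_to_transcript) for spliced models.
    """
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    if arrays is None:
        return empty
    starts, lengths, is_minus = arrays
    F = fragment_length
    frag_start = np.where(is_minus,
                          np.maximum(0, starts + lengths - F),
                          starts)
    frag_end = np.where(is_minus, starts + lengths, starts + F)
    if len(model.exons) == 1:
        es, ee = model.exons[0]
        lo = np.maximum(frag_start, es)
        hi = np.minimum(frag_end, ee)
        keep = lo < hi
        lo, hi = lo[keep], hi[keep]
        if model.strand == "+":
            return lo - es, hi - es
        L = model.length
        return L - (hi - es), L - (lo - es)
    t0, t1 = [], []
    for fs, fe in zip(frag_start, frag_end):
        read = AlignedRead(chrom=model.chrom, start=int(fs), length=int(fe - fs),
                           strand="+")
        iv = genome_to_transcript(read, model)
        if iv is not None:
            t0.append(iv.start)
            t1.append(iv.end)
    return np.asarray(t0, dtype=np.int64), np.asarray(t1, dtype=np.int64)


def call_peaks(
    models: Mapping[str, TranscriptModel],
    ip_reads: Iterable[AlignedRead],
    input_reads: Iterable[AlignedRead],
    params: PeakCallParams | None = None,
) -> PeakCallResult:
    """Run the full sliding-window peak caller for one IP/input pair.

    Deterministic given its inputs. Genes with zero median or zero top
    window count in either library are skipped and recorded in
    ``result.skipped``; the Benjamini-Hochberg family is the set of all
    tested (retained) windows across all genes.
    """
    params = params or PeakCallParams()
    params.validate()
    if not models:
        raise ValueError("empty annotation")
    ip_arrays = _reads_to_arrays(ip_reads)
    input_arrays = _reads_to_arrays(input_reads)

    skipped: dict[str, str] = {}
    per_gene: dict[str, dict] = {}
    rows_gene, rows_start, rows_a, rows_c = [], [], [], []
    rows_es = []
    for gene_id in sorted(models):
        model = models[gene_id]
        ip_iv = _map_fragments(model, ip_arrays.get(model.chrom),
                               params.fragment_length)
        in_iv = _map_fragments(model, input_arrays.get(model.chrom),
                               params.fragment_length)
        table = count_windows(model, ip_iv, in_iv, params.window, params.step)
        if table.ip_top == 0 or table.input_top == 0:
            skipped[gene_id] = "zero top window count"
            continue
        if table.ip_median <= 0 or table.input_median <= 0:
            skipped[gene_id] = "zero median window count"
            continue
        retained = filter_low_windows(table, params.min_fraction)
        if not retained.any():
            skipped[gene_id] = "no windows retained"
            continue
        per_gene[gene_id] = {"table": table, "intervals": (ip_iv, in_iv)}
        a = table.ip_counts[retained]
        c = table.input_counts[retained]
        es = enrichment_score(a, table.ip_median, c, table.input_median)
        rows_gene.extend([gene_id] * int(retained.sum()))
        rows_start.append(table.starts[retained])
        rows_a.append(a)
        rows_c.append(c)
        rows_es.append(np.atleast_1d(es))

    if rows_start:
        starts_all = np.concatenate(rows_start)
        a_all = np.concatenate(rows_a)
        c_all = np.concatenate(rows_c)
        es_all = np.concatenate(rows_es)
        ip_tot = np.array([per_gene[g]["table"].n_ip_fragments for g in rows_gene])
        in_tot = np.array([per_gene[g]["table"].n_input_fragments for g in rows_gene])
        p_all = fisher_pvalues(a_all, c_all, ip_tot - a_all, in_tot - c_all)
        q_all = bh_fdr(p_all)
        positive = call_positive_windows(q_all, es_all, params.fdr,
                                         params.min_log2_es)
    else:
        starts_all = a_all = c_all = es_all = np.empty(0, dtype=np.int64)
        p_all = q_all = np.empty(0, dtype=float)
        positive = np.empty(0, dtype=bool)

    stats = pd.DataFrame(
        {
            "gene_id": rows_gene,
            "start": starts_all,
            "ip_count": a_all,
            "input_count": c_all,
            "p_value": p_all,
            "q_value": q_all,
            "enrichment_score": es_all,
            "positive": positive,
        }
    )

    peaks: list[Peak] = []
    for gene_id, sub in stats[stats["positive"]].groupby("gene_id", sort=True):
        info = per_gene[gene_id]
        table: GeneWindowTable = info["table"]
        ip_iv, in_iv = info["intervals"]
        b, d = table.ip_median, table.input_median

        def recount_es(start: int, end: int,
                       ip_iv=ip_iv, in_iv=in_iv, b=b, d=d) -> float:
            a_peak = int(np.count_nonzero((ip_iv[0] < end) & (ip_iv[1] > start)))
            c_peak = int(np.count_nonzero((in_iv[0] < end) & (in_iv[1] > start)))
            return enrichment_score(a_peak, b, c_peak, d)

        peaks.extend(
            merge_windows(
                gene_id,
                sub["start"].to_numpy(),
                sub["enrichment_score"].to_numpy(),
                sub["q_value"].to_numpy(),
                p=sub["p_value"].to_numpy(),
                window=table.effective_window,
                length=table.length,
                recount_es=recount_es,
            )
        )
    peaks.sort(key=lambda p: (p.gene_id, p.start))
    return PeakCallResult(
        peaks=peaks, window_stats=stats, skipped=skipped,
        n_windows_tested=int(len(stats)),
    )
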