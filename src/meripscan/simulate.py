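"""Ground-truth simulator for a two-condition MeRIP-seq experiment.

The generator emulates the statistical structure of an shRNA-knockdown
m6A-seq design: a control and a demethylase-knockdown condition, each
with one IP and one input library of single-end 80-nt reads derived from
~150-nt fragments. Input fragments fall uniformly over each transcript at
a target coverage; IP fragments are a mixture of the same uniform
background and site-proximal fragments whose rate is background times the
site's enrichment factor. Planted methylation sites carry a GGACU motif,
favor the stop-codon vicinity and the 5'UTR, and a configurable fraction
of them respond to knockdown by a multiplicative increase in enrichment -
the direction expected when an m6A eraser is depleted.

Everything is deterministic given the seed, and the planted truth is kept
so called peaks can be scored for sensitivity and precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AlignedRead, TranscriptModel
from .peakcalling import Peak

BASES = np.array(list("ACGT"))
MOTIF = "GGACT"  # GGACU in DNA space


@dataclass
class SimulationParams:
    """Knobs of the synthetic two-condition MeRIP-seq experiment.

    Read length (80 nt) and fragment length (150 nt) match a single-end
    sequencing run of ~150-nt RNA fragments. Region length means are
    typical of human mRNAs. ``site_enrichment`` is the IP fold increase at
    a methylation site, ``knockdown_effect`` the extra multiplicative
    methylation gain at responder sites in the knockdown condition, and
    ``fto_target_fraction`` the share of sites that respond.
    """

    n_genes: int = 200
    utr5_mean: float = 150.0
    cds_mean: float = 1200.0
    utr3_mean: float = 500.0
    length_sigma: float = 0.25  # lognormal sigma on each region length
    sites_per_gene: int = 1
    site_enrichment: float = 8.0
    knockdown_effect: float = 4.0
    fto_target_fraction: float = 0.5
    coverage: float = 30.0
    fragment_length: int = 150
    read_length: int = 80
    nb_dispersion: Optional[float] = None  # None => Poisson fragment counts
    multi_exon: bool = False
    intron_length: int = 200
    seed: int = 1
    conditions: tuple[str, str] = ("control", "knockdown")

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if min(self.utr5_mean, self.cds_mean, self.utr3_mean) <= 0:
            raise ValueError("region length means must be positive")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if not (0 <= self.fto_target_fraction <= 1):
            raise ValueError("fto_target_fraction must lie in [0, 1]")
        if self.coverage <= 0 or self.site_enrichment <= 0:
            raise ValueError("coverage and site_enrichment must be positive")
        if self.knockdown_effect <= 0:
            raise ValueError("knockdown_effect must be positive")


@dataclass(frozen=True)
class PlantedSite:
    """A planted methylation site with its ground-truth enrichment."""

    gene_id: str
    position: int  # transcript coordinate
    region: str  # utr5 | cds | utr3
    base_enrichment: float
    responds_to_knockdown: bool
    motif_written: bool = True

    def enrichment(self, condition: str, params: SimulationParams) -> float:
        """Expected IP fold at the site under a given condition."""
        f = self.base_enrichment
        if condition == params.conditions[1] and self.responds_to_knockdown:
            f *= params.knockdown_effect
        return f


def _region_length(rng: np.random.Generator, mean: float, sigma: float,
                   minimum: int) -> int:
    mu = math.log(mean) - sigma**2 / 2.0
    return max(minimum, int(round(rng.lognormal(mu, sigma))))


def generate_transcriptome(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Synthesize one coding transcript per gene on its own chromosome.

    Region lengths are lognormal around the configured means. By default
    each gene is a single exon (genome <-> transcript mapping trivially
    auditable); ``multi_exon`` splits the transcript over 2-4 exons with
    fixed-size introns to exercise the coordinate mapping. Strands
    alternate. Sequences are uniform random; motifs are written at planted
    sites afterwards.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    models: dict[str, TranscriptModel] = {}
    seqs: dict[str, str] = {}
    offset = 200  # upstream buffer so minus-strand extension never hits 0
    for i in range(params.n_genes):
        gene_id = f"G{i + 1:04d}"
        u5 = _region_length(rng, params.utr5_mean, params.length_sigma, 60)
        cds = _region_length(rng, params.cds_mean, params.length_sigma, 300)
        u3 = _region_length(rng, params.utr3_mean, params.length_sigma, 120)
        length = u5 + cds + u3
        strand = "+" if i % 2 == 0 else "-"
        if params.multi_exon:
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(1, length), n_exons - 1,
                                      replace=False))
            sizes = np.diff(np.concatenate([[0], cuts, [length]]))
        else:
            sizes = np.array([length])
        exons = []
        pos = offset
        for sz in sizes:
            exons.append((pos, pos + int(sz)))
            pos += int(sz) + params.intron_length
        models[gene_id] = TranscriptModel(
            gene_id=gene_id, transcript_id=f"{gene_id}.1",
            chrom=f"chr_{gene_id}", strand=strand, exons=tuple(exons),
            cds_start=u5, cds_end=u5 + cds,
        )
        seqs[gene_id] = "".join(rng.choice(BASES, size=length))
    return models, seqs


def plant_sites(
    models: Mapping[str, TranscriptModel],
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> list[PlantedSite]:
    """Plant methylation sites, skewed toward the stop codon and the 5'UTR.

    Positions are drawn from a mixture: half near the stop codon
    ([cds_end - 50, cds_end + 150)), a quarter in the 5'UTR, a quarter
    uniform in the CDS; sites of one gene are kept >= 100 nt apart.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed + 1)
    sites: list[PlantedSite] = []
    for gene_id in sorted(models):
        model = models[gene_id]
        L = model.length
        placed: list[int] = []
        for _ in range(params.sites_per_gene):
            pos = None
            for _attempt in range(50):
                u = rng.random()
                if u < 0.5:
                    lo = max(0, model.cds_end - 50)
                    hi = min(L - len(MOTIF), model.cds_end + 150)
                elif u < 0.75:
                    lo, hi = 0, max(1, model.cds_start - len(MOTIF))
                else:
                    lo, hi = model.cds_start, max(model.cds_start + 1,
                                                  model.cds_end - len(MOTIF))
                if hi <= lo:
                    continue
                cand = int(rng.integers(lo, hi))
                if all(abs(cand - p) >= 100 for p in placed):
                    pos = cand
                    break
            if pos is None:
                continue  # transcript too crowded/short for another site
            placed.append(pos)
            if pos < model.cds_start:
                region = "utr5"
            elif pos < model.cds_end:
                region = "cds"
            else:
                region = "utr3"
            sites.append(
                PlantedSite(
                    gene_id=gene_id, position=pos, region=region,
                    base_enrichment=params.site_enrichment,
                    responds_to_knockdown=bool(
                        rng.random() < params.fto_target_fraction
                    ),
                )
            )
    return sites


def write_motifs(
    seqs: Mapping[str, str], sites: Iterable[PlantedSite]
) -> dict[str, str]:
    """Return sequences with the consensus motif written at each site."""
    out = dict(seqs)
    for site in sites:
        if not site.motif_written:
            continue
        seq = out[site.gene_id]
        p = site.position
        out[site.gene_id] = seq[:p] + MOTIF + seq[p + len(MOTIF):]
    return out


def _draw_count(rng: np.random.Generator, mean: float,
                dispersion: Optional[float]) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # gamma-Poisson mixture: NB with Var = mean + dispersion * mean^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return int(rng.poisson(lam))


def simulate_reads(
    models: Mapping[str, TranscriptModel],
    sites: Sequence[PlantedSite],
    params: SimulationParams,
    condition: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Simulate one condition's IP and input libraries.

    Reads are the 5'-most ``read_length`` nt of each fragment, emitted as
    ungapped genomic intervals on the gene's strand.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed + 2)
    by_gene: dict[str, list[PlantedSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    ip_reads: list[AlignedRead] = []
    input_reads: list[AlignedRead] = []
    for gene_id in sorted(models):
        model = models[gene_id]
        L = model.length
        F = min(params.fragment_length, L)
        R = min(params.read_length, F)
        mean_frags = params.coverage * L / params.fragment_length
        if mean_frags < 1:
            import warnings

            warnings.warn(
                f"gene {gene_id}: expected fragment count below 1 at this coverage"
            )

        def frag_starts(n: int) -> np.ndarray:
            return rng.integers(0, L - F + 1, size=n)

        n_input = _draw_count(rng, mean_frags, params.nb_dispersion)
        input_starts = frag_starts(n_input)
        n_bg = _draw_count(rng, mean_frags, params.nb_dispersion)
        parts = [frag_starts(n_bg)]
        for site in by_gene.get(gene_id, []):
            f = site.enrichment(condition, params)
            extra_mean = params.coverage * max(0.0, f - 1.0)
            n_extra = _draw_count(rng, extra_mean, params.nb_dispersion)
            if n_extra:
                lo = max(0, site.position - F + 1)
                hi = max(lo, min(site.position, L - F))
                parts.append(rng.integers(lo, hi + 1, size=n_extra))
        ip_starts = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

        for sample, starts, bucket in (
            ("IP", ip_starts, ip_reads),
            ("input", input_starts, input_reads),
        ):
            if starts.size == 0:
                continue
            if len(model.exons) == 1:
                es, _ = model.exons[0]
                if model.strand == "+":
                    g_start = es + starts
                else:
                    g_start = es + L - starts - R
            else:
                g_start = np.array(
                    [
                        model.transcript_to_genomic(int(t))
                        if model.strand == "+"
                        else max(0, model.transcript_to_genomic(int(t)) - R + 1)
                        for t in starts
                    ]
                )
            for gs in g_start:
                bucket.append(
                    AlignedRead(
                        chrom=model.chrom, start=int(gs), length=R,
                        strand=model.strand, sample=sample, condition=condition,
                    )
                )
    return ip_reads, input_reads


# -- companion generators for the qPCR/decay module --------------------------


def simulate_qpcr(
    fold_changes: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "HPRT1",
    samples: tuple[str, str] = ("control", "knockdown"),
    base_cq: float = 20.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Long Cq table for ddCq analysis with planted fold changes.

    Cq = base_cq - log2(quantity) + Normal(0, sd), in replicates; the
    reference gene has quantity 1 in every sample, targets have quantity 1
    in the control sample and the planted fold in the treated sample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        quantities = {reference_gene: ("reference", 1.0)}
        for gene, fold in fold_changes.items():
            quantities[gene] = ("target", fold if sample == samples[1] else 1.0)
        for gene, (role, q) in quantities.items():
            for rep in range(1, n_replicates + 1):
                cq = base_cq - math.log2(q) + rng.normal(0.0, noise_sd)
                rows.append(
                    {"sample": sample, "gene": gene, "role": role,
                     "replicate": rep, "cq": cq}
                )
    return pd.DataFrame(rows)


def simulate_m6a_qpcr(
    levels: Mapping[str, Mapping[str, float]],
    input_fraction: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_cq: float = 20.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Cq table for gene-specific m6A qPCR with planted relative levels.

    ``levels`` maps gene -> sample -> true relative m6A level; the IP Cq
    is offset from the input Cq by log2(level * input_fraction).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(levels):
        for sample in sorted(levels[gene]):
            level = levels[gene][sample]
            for role, cq0 in (
                ("input", base_cq),
                ("IP", base_cq - math.log2(level * input_fraction)),
            ):
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {"sample": sample, "gene": gene, "role": role,
                         "replicate": rep,
                         "cq": cq0 + rng.normal(0.0, noise_sd)}
                    )
    return pd.DataFrame(rows)


def simulate_decay(
    half_lives: Mapping[tuple[str, str], float],
    timepoints: Sequence[float] = (0.0, 3.0, 6.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Decay time-course table with planted half-lives (gene, condition)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for (gene, condition), hl in sorted(half_lives.items()):
        k = math.log(2) / hl
        values = np.array(
            [math.exp(-k * t) * math.exp(rng.normal(0.0, noise_sd))
             for t in timepoints]
        )
        values = values / values[0]  # t0-normalize
        for t, v in zip(timepoints, values):
            rows.append({"gene": gene, "condition": condition,
                         "hours": t, "value": v})
    return pd.DataFrame(rows)


# -- recovery scoring --------------------------------------------------------


@dataclass
class RecoveryReport:
    sensitivity: float
    precision: float
    per_region_sensitivity: dict[str, float]
    n_sites: int
    n_peaks: int
    n_sites_recovered: int
    n_true_peaks: int
    mean_es_responders: float = float("nan")


def evaluate_recovery(
    peaks: Sequence[Peak],
    sites: Sequence[PlantedSite],
    tolerance: int = 50,
) -> RecoveryReport:
    """Score called peaks against the planted truth.

    A site is recovered iff some called peak on its gene satisfies
    start - tolerance <= position < end + tolerance; a peak is true iff it
    recovers some site by the same rule.
    """
    if not sites:
        raise ValueError("empty truth")
    peaks_by_gene: dict[str, list[Peak]] = {}
    for p in peaks:
        peaks_by_gene.setdefault(p.gene_id, []).append(p)

    def hits(site: PlantedSite, peak: Peak) -> bool:
        return peak.start - tolerance <= site.position < peak.end + tolerance

    region_tot: dict[str, int] = {}
    region_hit: dict[str, int] = {}
    n_rec = 0
    for site in sites:
        region_tot[site.region] = region_tot.get(site.region, 0) + 1
        if any(hits(site, p) for p in peaks_by_gene.get(site.gene_id, [])):
            n_rec += 1
            region_hit[site.region] = region_hit.get(site.region, 0) + 1
    sites_by_gene: dict[str, list[PlantedSite]] = {}
    for s in sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)
    n_true = sum(
        1
        for p in peaks
        if any(hits(s, p) for s in sites_by_gene.get(p.gene_id, []))
    )
    return RecoveryReport(
        sensitivity=n_rec / len(sites),
        precision=n_true / len(peaks) if peaks else 0.0,
        per_region_sensitivity={
            r: region_hit.get(r, 0) / n for r, n in sorted(region_tot.items())
        },
        n_sites=len(sites),
        n_peaks=len(peaks),
        n_sites_recovered=n_rec,
        n_true_peaks=n_true,
    )


# -- file emission -----------------------------------------------------------


def models_to_bed12(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            chrom_start = m.exons[0][0]
            chrom_end = m.exons[-1][1]
            if m.is_coding:
                g1 = m.transcript_to_genomic(m.cds_start)
                g2 = m.transcript_to_genomic(m.cds_end - 1)
                thick_start, thick_end = min(g1, g2), max(g1, g2) + 1
            else:
                thick_start = thick_end = chrom_start
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - chrom_start) for s, e in m.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, chrom_start, chrom_end,
                        f"{m.gene_id}|{m.transcript_id}", 0, m.strand,
                        thick_start, thick_end, "0", len(m.exons), sizes, starts,
                    )
                )
                + "\n"
            )


def models_to_gtf(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                g1 = m.transcript_to_genomic(m.cds_start)
                g2 = m.transcript_to_genomic(m.cds_end - 1)
                lo, hi = min(g1, g2), max(g1, g2) + 1
                for s, e in m.exons:
                    cs, ce = max(s, lo), min(e, hi)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}"
                            f"\t.\t{attrs}\n"
                        )


def truth_to_frame(sites: Sequence[PlantedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id, "start": s.position,
                "end": s.position + 1, "region": s.region,
                "base_enrichment": s.base_enrichment,
                "responds": int(s.responds_to_knockdown),
            }
            for s in sites
        ]
    )


def truth_to_bed(sites: Sequence[PlantedSite], path: str | Path) -> None:
    truth_to_frame(sites).to_csv(path, sep="\t", header=False, index=False)


def truth_from_bed(path: str | Path) -> list[PlantedSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene_id, start, _end, region, enr, resp = line.split("\t")[:6]
            sites.append(
                PlantedSite(
                    gene_id=gene_id, position=int(start), region=region,
                    base_enrichment=float(enr),
                    responds_to_knockdown=bool(int(resp)),
                )
            )
    return sites


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def build_genome(
    models: Mapping[str, TranscriptModel],
    seqs: Mapping[str, str],
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Per-chromosome genomic sequence with transcript sequence placed on
    the exons (reverse-complemented for minus-strand genes) and random
    filler elsewhere."""
    rng = rng or np.random.default_rng(0)
    genome: dict[str, str] = {}
    for gene_id in sorted(models):
        m = models[gene_id]
        tseq = seqs[gene_id]
        chrom_len = m.exons[-1][1] + 100
        arr = rng.choice(BASES, size=chrom_len)
        off = 0
        L = m.length
        for s, e in m.exons:
            n = e - s
            if m.strand == "+":
                chunk = tseq[off : off + n]
            else:
                chunk = _revcomp(tseq[L - off - n : L - off])
            arr[s:e] = list(chunk)
            off += n
        genome[m.chrom] = "".join(arr)
    return genome


@dataclass
class SimulatedDataset:
    params: SimulationParams
    models: dict[str, TranscriptModel]
    seqs: dict[str, str]
    sites: list[PlantedSite]
    reads: dict[str, tuple[list[AlignedRead], list[AlignedRead]]]  # condition -> (IP, input)


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate a full two-condition dataset from a single seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    models, seqs = generate_transcriptome(params, rng)
    sites = plant_sites(models, params, rng)
    seqs = write_motifs(seqs, sites)
    reads = {}
    for condition in params.conditions:
        reads[condition] = simulate_reads(models, sites, params, condition, rng)
    return SimulatedDataset(
        params=params, models=models, seqs=seqs, sites=sites, reads=reads
    )
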