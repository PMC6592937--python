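"""qPCR fold change, gene-specific m6A enrichment, mRNA decay and tumor volume.

Relative expression follows the ddCq convention with amplification
efficiency fixed at 2: fold = 2^-ddCq, where dCq = Cq(target) -
Cq(reference gene) within a sample and ddCq contrasts sample against
control. Gene-specific m6A enrichment follows a percent-of-input
convention: 2^(Cq_input - Cq_IP) / input_fraction, the fraction being the
share of fragmented mRNA saved as input (default 5%). mRNA stability is
quantified from an actinomycin-D chase (0/3/6 h by default) by a
log-linear decay fit forced through the t0-normalized origin, giving the
decay rate k and half-life ln(2)/k. The tumor-volume utility implements
the caliper formula volume = d^2 * D / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CqRecord:
    """Replicate threshold-cycle (Cq) values for one gene in one sample."""

    sample: str
    gene: str
    role: str  # target | reference | IP | input
    cq_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cq_values:
            raise ValueError("CqRecord needs at least one replicate")
        if any(not math.isfinite(v) for v in self.cq_values):
            raise ValueError("Cq values must be finite")

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq_values))


def relative_expression(
    target: CqRecord,
    reference: CqRecord,
    target_ctrl: CqRecord,
    reference_ctrl: CqRecord,
) -> float:
    """Fold change 2^-ddCq of a target gene, sample vs control."""
    if reference.gene != reference_ctrl.gene:
        raise ValueError("reference gene differs between sample and control")
    d_sample = target.mean_cq - reference.mean_cq
    d_ctrl = target_ctrl.mean_cq - reference_ctrl.mean_cq
    return float(2.0 ** -(d_sample - d_ctrl))


def m6a_enrichment(
    ip: CqRecord, input_: CqRecord, input_fraction: float = 0.05
) -> float:
    """Relative m6A level of a gene: IP signal normalized by its input.

    Percent-of-input convention: 2^(Cq_input - Cq_IP) / input_fraction,
    where input_fraction is the share of material saved as input.
    Typically rescaled downstream so a control sample equals 1.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must lie in (0, 1]")
    if ip.gene != input_.gene:
        raise ValueError("IP and input records are for different genes")
    return float(2.0 ** (input_.mean_cq - ip.mean_cq) / input_fraction)


@dataclass(frozen=True)
class DecaySeries:
    """Reference- and t0-normalized transcript abundance over a chase."""

    gene: str
    condition: str
    timepoints: tuple[float, ...]
    rel_abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.rel_abundance):
            raise ValueError("timepoints and abundances differ in length")
        if len(self.timepoints) < 3 or self.timepoints[0] != 0:
            raise ValueError("need >= 3 timepoints starting at 0")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(v <= 0 for v in self.rel_abundance):
            raise ValueError("abundances must be positive (log undefined)")


@dataclass(frozen=True)
class DecayFit:
    k: float  # decay rate, 1/h
    half_life: float  # h; inf when the transcript appears stable
    r_squared: float

    @property
    def stable(self) -> bool:
        return not (self.k > 0)


def fit_decay(series: DecaySeries) -> DecayFit:
    """Least-squares line through ln(abundance) vs time, intercept fixed at 0.

    The t0 normalization makes the intercept exact by construction, so the
    slope is fit through the origin: k = -sum(t * ln y) / sum(t^2).
    A non-positive k is reported as stable with infinite half-life.
    """
    t = np.asarray(series.timepoints, dtype=float)
    y = np.asarray(series.rel_abundance, dtype=float)
    y = y / y[0]  # enforce t0 == 1
    ln_y = np.log(y)
    slope = float(np.sum(t * ln_y) / np.sum(t * t))
    k = -slope
    half_life = math.log(2) / k if k > 0 else math.inf
    resid = ln_y - slope * t
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ln_y - ln_y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return DecayFit(k=k, half_life=half_life, r_squared=min(1.0, max(0.0, r2)))


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement: shortest (d) and longest (D) diameters in mm."""

    d: float
    D: float

    def __post_init__(self) -> None:
        if not (0 < self.d <= self.D):
            raise ValueError("need 0 < d <= D")


def tumor_volume(m: TumorMeasurement) -> float:
    """Tumor volume in mm^3 from caliper diameters: d^2 * D / 2."""
    return m.d**2 * m.D / 2.0


# -- table-level helpers (CSV/TSV schemas: sample, gene, role, replicate, cq
#    and gene, condition, hours, value) --------------------------------------


def records_from_table(df: pd.DataFrame) -> dict[tuple[str, str, str], CqRecord]:
    """Collapse a long Cq table into CqRecords keyed by (sample, gene, role)."""
    required = {"sample", "gene", "role", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    out = {}
    for (sample, gene, role), sub in df.groupby(["sample", "gene", "role"], sort=True):
        out[(sample, gene, role)] = CqRecord(
            sample=sample, gene=gene, role=role,
            cq_values=tuple(float(v) for v in sub["cq"]),
        )
    return out


def expression_table(
    df: pd.DataFrame, reference_gene: str, control_sample: str
) -> pd.DataFrame:
    """Per-sample, per-gene ddCq fold changes relative to a control sample."""
    recs = records_from_table(df)
    samples = sorted({k[0] for k in recs})
    genes = sorted({k[1] for k in recs if k[1] != reference_gene and k[2] == "target"})
    rows = []
    for sample in samples:
        ref = recs.get((sample, reference_gene, "reference"))
        ref_ctrl = recs.get((control_sample, reference_gene, "reference"))
        if ref is None or ref_ctrl is None:
            raise ValueError(f"missing reference gene {reference_gene}")
        for gene in genes:
            tgt = recs.get((sample, gene, "target"))
            tgt_ctrl = recs.get((control_sample, gene, "target"))
            if tgt is None or tgt_ctrl is None:
                continue
            rows.append(
                {
                    "sample": sample, "gene": gene,
                    "fold_change": relative_expression(tgt, ref, tgt_ctrl, ref_ctrl),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "fold_change"])


def m6a_table(
    df: pd.DataFrame,
    input_fraction: float = 0.05,
    control_sample: str | None = None,
) -> pd.DataFrame:
    """Per-sample, per-gene m6A enrichment (optionally rescaled to a control)."""
    recs = records_from_table(df)
    keys = sorted({(k[0], k[1]) for k in recs})
    rows = []
    for sample, gene in keys:
        ip = recs.get((sample, gene, "IP"))
        inp = recs.get((sample, gene, "input"))
        if ip is None or inp is None:
            continue
        rows.append(
            {
                "sample": sample, "gene": gene,
                "enrichment": m6a_enrichment(ip, inp, input_fraction),
            }
        )
    out = pd.DataFrame(rows, columns=["sample", "gene", "enrichment"])
    if control_sample is not None and not out.empty:
        ctrl = out[out["sample"] == control_sample].set_index("gene")["enrichment"]
        out["relative_to_control"] = [
            row.enrichment / ctrl[row.gene] if row.gene in ctrl.index else np.nan
            for row in out.itertuples()
        ]
    return out


def decay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit a decay rate and half-life per (gene, condition) series."""
    required = {"gene", "condition", "hours", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"decay table must have columns {sorted(required)}")
    rows = []
    for (gene, cond), sub in df.groupby(["gene", "condition"], sort=True):
        sub = sub.sort_values("hours")
        series = DecaySeries(
            gene=gene, condition=cond,
            timepoints=tuple(float(t) for t in sub["hours"]),
            rel_abundance=tuple(float(v) for v in sub["value"]),
        )
        fit = fit_decay(series)
        rows.append(
            {
                "gene": gene, "condition": cond, "k_per_hour": fit.k,
                "half_life_hours": fit.half_life, "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "condition", "k_per_hour",
                       "half_life_hours", "r_squared"],
    )
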