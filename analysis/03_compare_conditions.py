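#!/usr/bin/env python
"""Compare the two conditions' peak sets and profile them along the mRNA.

Classifies peaks as common/unique and genes as common or condition-unique
m6A genes, computes the 100-bin metagene profile and 5'UTR/CDS/3'UTR
summit proportions per condition, checks GGACU motif enrichment under
peaks, and scores both peak sets against the planted truth. Tables land
under results/comparison/.
"""

import argparse
from pathlib import Path

import pandas as pd

from meripscan import io as mio
from meripscan.annotation import load_annotation, select_longest_isoform
from meripscan.compare import (
    compare_peak_sets,
    metagene_profile,
    motif_enrichment,
    region_proportions,
)
from meripscan.simulate import evaluate_recovery, truth_from_bed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--peaks", type=Path, default=Path("results/peaks"))
    ap.add_argument("--out", type=Path, default=Path("results/comparison"))
    args = ap.parse_args()

    models = select_longest_isoform(load_annotation(args.sim / "annotation.gtf"))
    seqs = mio.read_fasta(args.sim / "transcripts.fa")
    sites = truth_from_bed(args.sim / "truth.bed")
    peaks = {c: mio.read_peaks_bed(args.peaks / f"peaks_{c}.bed")
             for c in ("control", "knockdown")}
    args.out.mkdir(parents=True, exist_ok=True)

    cmp_ = compare_peak_sets(peaks["control"], peaks["knockdown"])
    print(f"common pairs: {len(cmp_.common_pairs)}, "
          f"unique control: {len(cmp_.unique_a)}, "
          f"unique knockdown: {len(cmp_.unique_b)}, "
          f"common m6A genes: {len(cmp_.common_genes)}")
    pd.DataFrame(
        [{"gene_id": g, "class": "common"} for g in sorted(cmp_.common_genes)]
        + [{"gene_id": g, "class": "unique_control"}
           for g in sorted(cmp_.unique_genes_a)]
        + [{"gene_id": g, "class": "unique_knockdown"}
           for g in sorted(cmp_.unique_genes_b)]
    ).to_csv(args.out / "gene_classes.tsv", sep="\t", index=False)

    region_rows, motif_rows, recovery_rows = [], [], []
    for cond, pk in peaks.items():
        prof = metagene_profile(pk, models)
        pd.DataFrame({"bin": range(100), "percent": prof.bins}).to_csv(
            args.out / f"metagene_{cond}.tsv", sep="\t", index=False,
            float_format="%.6g")
        props = region_proportions(pk, models)
        region_rows.append({"condition": cond, "utr5": props.utr5,
                            "cds": props.cds, "utr3": props.utr3})
        rep = motif_enrichment(pk, seqs)
        motif_rows.append({"condition": cond, "fold": rep.fold,
                           "p_value": rep.p_value})
        rec = evaluate_recovery(pk, sites)
        recovery_rows.append({"condition": cond,
                              "sensitivity": rec.sensitivity,
                              "precision": rec.precision})
        print(f"{cond}: 5'UTR {props.utr5:.3f} / CDS {props.cds:.3f} / "
              f"3'UTR {props.utr3:.3f}; motif fold {rep.fold:.2f}; "
              f"sensitivity {rec.sensitivity:.3f}, precision {rec.precision:.3f}")
    for name, rows in (("region_proportions", region_rows),
                       ("motif", motif_rows), ("recovery", recovery_rows)):
        pd.DataFrame(rows).to_csv(args.out / f"{name}.tsv", sep="\t",
                                  index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
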