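#!/usr/bin/env python
"""Generate the benchmark MeRIP-seq dataset with known ground truth.

Writes a 300-gene two-condition experiment (control vs demethylase
knockdown) to results/sim/: annotation (GTF + BED12), transcript and
genome FASTA, IP/input read BEDs per condition, the planted-site truth
BED, and the echoed simulation parameters. Downstream scripts read these
files, so the whole analysis also exercises the plain-text interchange
formats.
"""

import argparse
import dataclasses
from pathlib import Path

from meripscan.pipeline import PRESETS
from meripscan.simulate import (
    build_genome,
    models_to_bed12,
    models_to_gtf,
    simulate_dataset,
    truth_to_bed,
)
from meripscan import io as mio

import numpy as np
import yaml


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    params = dataclasses.replace(PRESETS["benchmark"], seed=args.seed)
    ds = simulate_dataset(params)
    args.out.mkdir(parents=True, exist_ok=True)
    models_to_gtf(ds.models, args.out / "annotation.gtf")
    models_to_bed12(ds.models, args.out / "annotation.bed12.bed")
    mio.write_fasta(ds.seqs, args.out / "transcripts.fa")
    mio.write_fasta(build_genome(ds.models, ds.seqs), args.out / "genome.fa")
    truth_to_bed(ds.sites, args.out / "truth.bed")
    with open(args.out / "params.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)
    for cond, (ip, inp) in ds.reads.items():
        mio.write_bed6(ip, args.out / f"reads_{cond}_IP.bed")
        mio.write_bed6(inp, args.out / f"reads_{cond}_input.bed")
        print(f"{cond}: {len(ip)} IP reads, {len(inp)} input reads")
    n_resp = sum(s.responds_to_knockdown for s in ds.sites)
    print(f"{len(ds.models)} genes, {len(ds.sites)} planted sites "
          f"({n_resp} respond to knockdown); wrote {args.out}/")


if __name__ == "__main__":
    main()
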