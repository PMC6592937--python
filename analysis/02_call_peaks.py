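#!/usr/bin/env python
"""Call m6A peaks per condition from the simulated libraries.

Reads the dataset written by 01_simulate.py, runs the sliding-window
Fisher/FDR/enrichment-score caller for each condition, and writes
peaks_<condition>.bed plus the full per-window statistics table under
results/peaks/.
"""

import argparse
from pathlib import Path

from meripscan import io as mio
from meripscan.annotation import load_annotation, select_longest_isoform
from meripscan.peakcalling import call_peaks


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/peaks"))
    args = ap.parse_args()

    models = select_longest_isoform(load_annotation(args.sim / "annotation.gtf"))
    args.out.mkdir(parents=True, exist_ok=True)
    for cond in ("control", "knockdown"):
        ip = mio.read_bed6(args.sim / f"reads_{cond}_IP.bed")
        inp = mio.read_bed6(args.sim / f"reads_{cond}_input.bed")
        result = call_peaks(models, ip, inp)
        mio.write_peaks_bed(result.peaks, args.out / f"peaks_{cond}.bed")
        result.window_stats.to_csv(args.out / f"windows_{cond}.tsv", sep="\t",
                                   index=False, float_format="%.6g")
        print(f"{cond}: {result.n_windows_tested} windows tested, "
              f"{len(result.peaks)} peaks, {len(result.skipped)} genes skipped")


if __name__ == "__main__":
    main()
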