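# meripscan

Sliding-window peak calling for MeRIP-seq / m⁶A-seq (methylated-RNA
immunoprecipitation sequencing), with cross-condition peak comparison,
metagene profiling, a fixed-motif (GGACU) enrichment check, qPCR-based
quantification (ΔΔCq expression, gene-specific m⁶A enrichment,
actinomycin-D mRNA decay), and a ground-truth simulator for benchmarking
the whole pipeline.

The package is aimed at epitranscriptomics analyses of the kind used to
study m⁶A writers and erasers: an anti-m⁶A IP library is contrasted with a
non-enriched input library in two conditions (e.g. a control and an m⁶A
demethylase knockdown), peaks mark methylated regions of each gene's
longest isoform, and downstream comparisons ask where methylation changed
along the mRNA.

## Method

All peak calling happens in **transcript coordinates**: reads are extended
to the mean fragment size (150 nt) from their strand-aware 5′ end in
genomic space and projected onto each gene's longest spliced isoform.
Each isoform is scanned with 100-nt windows at a 10-nt step. For a window
with IP count *a* and input count *c*, with *b* and *d* the gene's median
window counts in the IP and input libraries (computed over **all** windows
of the gene), the enrichment score is

```
ES = (a × d) / (b × c)
```

Windows below 1/20 of the gene's top window in **both** libraries are
excluded (robustness to annotation errors); remaining windows are tested
with a one-sided Fisher exact test of `[a, c; gene IP total − a, gene
input total − c]`, and p-values are Benjamini–Hochberg adjusted across all
tested windows of the dataset. A window is **positive** when FDR < 0.01
and log₂(ES) ≥ 1; overlapping positive windows merge into peaks, whose ES
is recomputed over the merged interval.

Companion analyses:

- **Metagene profile** — each peak's summit lands in one of 100 bins
  (10 for the 5′UTR, 50 for the CDS, 40 for the 3′UTR); region
  proportions aggregate the same assignment.
- **Peak-set comparison** — peaks of two conditions are *common* when they
  share ≥ 1 nt on the same gene; a *common m⁶A gene* carries at least one
  common peak, a condition-unique m⁶A gene carries none.
- **Motif check** — GGACU (U ≡ T) occurrence rate under peaks vs the rest
  of the same transcripts, with a one-sided Fisher p.
- **qPCR / decay** — fold change 2^(−ΔΔCq); gene-specific m⁶A level
  2^(Cq_input − Cq_IP) / input_fraction (percent-of-input, default 5%);
  mRNA half-life ln 2 / k from a log-linear fit of a 0/3/6 h
  actinomycin-D chase forced through the t₀-normalized origin; and the
  caliper tumor-volume utility d² × D / 2.
- **Simulator** — generates annotation, sequences, planted GGACU-bearing
  sites (skewed toward the stop codon and 5′UTR), and IP/input reads for
  both conditions with known per-site enrichment, so sensitivity and
  precision are measurable.

## Worked example

```
$ python analysis/01_simulate.py --seed 1 --out results/sim
control: 173047 IP reads, 110385 input reads
knockdown: 294603 IP reads, 110341 input reads
300 genes, 300 planted sites (169 respond to knockdown); wrote results/sim/

$ python analysis/02_call_peaks.py --sim results/sim --out results/peaks
control: 52301 windows tested, 300 peaks, 0 genes skipped
knockdown: 52301 windows tested, 300 peaks, 0 genes skipped

$ python analysis/03_compare_conditions.py
common pairs: 300, unique control: 0, unique knockdown: 0, common m6A genes: 300
control: 5'UTR 0.230 / CDS 0.363 / 3'UTR 0.407; motif fold 3.75; sensitivity 1.000, precision 1.000
knockdown: 5'UTR 0.227 / CDS 0.353 / 3'UTR 0.420; motif fold 3.57; sensitivity 1.000, precision 1.000
```

Each of the 300 genes carries one planted 8-fold site, and the caller
recovers every one of them with no false peaks (sensitivity and precision
1.000 at ±50 nt). The knockdown IP library is visibly deeper at responder
sites (294,603 vs 173,047 IP reads), peak summits sit mostly in the 3′UTR
near the stop codon, and GGACU is ~3.6–3.8-fold enriched under peaks.
`analysis/04_qpcr_decay.py` then recovers planted 2-fold m⁶A gains and the
3 h → 1.5 h half-life drop from simulated Cq and chase tables.

The same pipeline is available as a CLI (`meripscan simulate | callpeaks |
compare | metagene | motif | qpcr-expression | qpcr-m6a | decay | run`)
and as a single YAML-driven run (`meripscan run --config run.yaml`), whose
defaults are exactly the thresholds above.

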