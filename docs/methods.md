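# Methods

## Coordinate model

Every statistic is computed on each gene's **longest spliced isoform**
(ties broken by lexicographically smallest transcript id, for
determinism). Coordinates are 0-based half-open everywhere internally; BED
input/output is native, GTF is converted on read. On the minus strand,
transcript position 0 is the highest genomic coordinate of the exon set.

Reads are extended to the mean fragment size (default 150 nt) in genomic
space from the strand-aware 5′ end, *then* intersected with the exon set
and mapped to transcript coordinates; a junction-spanning extension keeps
only its exonic overlap, returned as one transcript interval. Counting is
strand-agnostic: reads from either genomic strand count toward a
transcript, since window-level IP/input contrasts cancel any antisense
background that is shared between the libraries. A minus-strand extension
that would cross genomic coordinate 0 is truncated there rather than
producing a negative start.

## Window statistics

Windows are 100 nt at a 10-nt step (`floor((L−100)/10)+1` windows; a
transcript shorter than 100 nt gets one full-length window). A fragment
increments every window it overlaps by ≥ 1 nt.

Per gene and library, the **median** window count (over all windows,
before any exclusion) is the normalizer *b* (IP) / *d* (input); the
**top** window count drives the low-coverage exclusion: a window is
dropped only when its raw count is below 1/20 of the top in *both*
libraries. Genes with a zero top or zero median in either library are
skipped entirely and logged — there is no usable contrast on them.

The Fisher 2×2 table for a window is
`[a, c; gene IP total − a, gene input total − c]` with gene totals the
fragment counts of the gene, tested one-sided toward IP enrichment (the
enrichment-score filter already fixes the direction of interest, so a
two-sided test would only spend power on depletion we never call). Raw
integer counts enter the test; the median normalization feeds only the
enrichment score and reporting. The p-value is the hypergeometric tail
P(X ≥ a), computed vectorized; the test suite pins it against both an
exact integer-combinatorics enumeration and an independent library
implementation. FDR control is Benjamini–Hochberg over **all tested
windows of the dataset jointly**; excluded windows never enter the family.

ES = (a·d)/(b·c). When c = 0, a pseudocount of ½ is added to a and c only,
keeping the score finite while preserving the ordering of zero-input
windows. Positivity is `q < 0.01` (strict) and `log2(ES) ≥ 1` (inclusive).
Runs of chain-overlapping positive windows merge into one peak; the peak's
ES is recomputed from fragment counts over the merged interval (b, d
unchanged), its summit is the midpoint of the constituent window with the
highest ES, and the smallest constituent p and q are reported alongside.
Whether the original convention recomputed the score over the merged
interval or kept the max-window score is not decidable from the published
description; recomputation was chosen because it makes the reported score
a property of the reported interval, and the per-window table is always
written in full so either convention can be recovered.

## Comparison, metagene, motif

Peaks from two conditions are *common* when they share ≥ 1 nt on the same
gene (no reciprocal-fraction requirement — the published rule names no
threshold, and 100-nt-scale peaks make fractional criteria brittle). Gene
classes follow from the peaks: a gene with at least one common peak is a
common m⁶A gene; genes with peaks but no common peak are unique to their
condition.

Metagene bins: 10/50/40 for 5′UTR/CDS/3′UTR. Each peak contributes one
count at its **summit** (the published phrasing counts peaks per bin, so a
point assignment, not fractional spreading); within a region, bin =
offset + floor(fraction × bins), clamped to the region's last bin.
Non-coding models, or models missing any region, skip their peaks (the
skip count is reported). Percentages are over usable peaks and sum to 100.

The motif check is a fixed-string scan (GGACU with U ≡ T), not de-novo
discovery: occurrence rate per nucleotide under peak intervals vs the
complement of the same transcripts, fold = rate ratio, p from a one-sided
Fisher test of counts against covered lengths.

## qPCR, decay, tumor volume

ΔΔCq uses replicate means and an amplification efficiency fixed at 2 (no
dilution-series calibration). Gene-specific m⁶A enrichment uses the
percent-of-input convention, `2^(Cq_input − Cq_IP) / input_fraction`, with
the input fraction defaulting to 5% — the share of fragmented mRNA
typically saved as input; since the exact published normalization
arithmetic is not printed, results are best interpreted **relative to a
control sample**, in which the input-fraction constant cancels. The decay
fit regresses ln(abundance) on time with the intercept fixed at 0 (the t₀
normalization makes it exact by construction): k = −Σt·ln y / Σt²,
half-life = ln 2 / k, with k ≤ 0 reported as stable (infinite half-life).
R² is computed on the log scale and clamped to [0, 1]. Tumor volume is the
caliper formula d²·D/2 with 0 < d ≤ D enforced.

## Simulator

The generator emulates the statistical structure of a two-condition
(control vs m⁶A-demethylase-knockdown) MeRIP-seq design:

- One coding transcript per gene on its own chromosome (auditable
  mapping); an optional multi-exon mode (2–4 exons, fixed 200-nt introns)
  exists solely to exercise the coordinate code. Region lengths are
  lognormal with means 150/1200/500 nt (5′UTR/CDS/3′UTR), typical of human
  mRNAs.
- Sites are planted from a mixture favoring the stop-codon vicinity
  ([cds_end−50, cds_end+150), weight ½) and the 5′UTR (¼), with the
  remainder uniform in the CDS, ≥ 100 nt apart within a gene, each
  carrying a written GGACU.
- Input fragments are uniform over the transcript at the target coverage
  (default 30×, i.e. `coverage·L/150` expected fragments); IP fragments
  are the same uniform background plus site-covering fragments at rate
  `coverage × (enrichment − 1)`, so the local IP rate at a site is
  background × enrichment. Fragment counts are Poisson by default
  (keeping the null calibration interpretable); a negative-binomial
  dispersion is available. Reads are the 5′-most 80 nt of each fragment.
- In the knockdown condition, a configurable fraction of sites
  (default 50%) multiplies its enrichment by the knockdown effect
  (default 4) — the direction expected when an eraser is depleted.
- Everything derives from one seed; identical parameters reproduce
  identical bytes.

The **benchmark** preset is 300 genes, one site per gene at 8-fold
enrichment, 30× coverage; the **null** preset is 200 genes with enrichment
1 everywhere (no site effect), used to check that the positive-window rate
stays within the nominal FDR level. Recovery uses a ±50 nt tolerance —
half a window, a benchmark convention, not a published value.

What the simulator does **not** model: sequencing error and base
qualities, PCR duplicates, multimapping, non-uniform (GC- or
fragmentation-biased) coverage, isoform mixtures, antibody off-target
binding, or replicate-level biological variability. Passing the benchmark
therefore shows the windowing/testing/merging machinery is correct and
well calibrated under the stated noise model — not that real libraries
with structured bias would be called with the same sensitivity.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at 300 genes
and the null calibration at 200 genes × 10 seeds (5 seeds in the script),
sizes at which every per-gene quantity is estimated from tens of thousands
of windows while a full run stays in the tens of seconds. The Fisher
enumeration check covers every 2×2 table with grand total ≤ 60 at
|Δp| ≤ 1e−9. Degenerate inputs are defined, not special-cased: all-zero
tables give p = 1, empty p-vectors give empty q-vectors, zero-read genes
are skipped with a logged reason, an empty truth set or an empty usable
peak set is an error rather than a silent zero.
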