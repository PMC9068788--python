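# Methods

## Differential methylation calling

The unit of analysis is the array probe, anchored to a 1-based CpG
coordinate by a manifest. M-values (`log2` methylated/unmethylated
intensity ratio) are compared between two time points per probe:
`ΔM = M(t_later) − M(t_earlier)`, methylated if `ΔM > τ`, demethylated if
`ΔM < −τ`, with `τ = 2` M-units by default and strict inequalities — a
probe sitting exactly at the threshold is not called. Replicates are
expected to be averaged into one value per time point before calling;
there is no replicate-level test. Probes with a missing value at either
time point are excluded from that interval's calls and counted. Beta
values may be supplied instead and converted via
`M = log2(β / (1 − β))` with clipping to `[1e−6, 1 − 1e−6]`.

With the default six-point course and a demethylation effect spread over
several intervals, adjacent-interval ΔM steps may stay below τ even
though the cumulative change is large; the informative comparisons are
then cumulative intervals against the first time point. The screen
accepts any interval list for exactly this reason.

## Uninherited demethylated regions (UDRs)

Cumulative demethylated sets versus time 0 overlap heavily because a
demethylated CpG usually stays demethylated. UDR sets partition them by
first crossing time: `UDR(t_k) = Demeth(t0→t_k) \ ∪_{j<k} Demeth(t0→t_j)`.
They are pairwise disjoint by construction and their union up to `t_k`
equals the union of the cumulative sets up to `t_k`; both properties are
enforced by tests on random inputs.

## Motif scanning

PWMs are per-position probability matrices (columns A, C, G, T), with a
0.01 pseudocount per cell and row renormalization; MEME-minimal and
JASPAR text files are accepted (counts are normalized). Scoring is
log-odds against a background composition (uniform by default):
`s(i) = Σ_j log2(p_j(base_{i+j}) / q(base_{i+j}))`, both strands, with
positions covering N scoring −∞. A position is a hit when
`s ≥ f · s_max`, where `s_max` is the maximum attainable score and
`f = 0.85` by default — common scanning practice. Overlapping hits are
all counted (no greedy masking). A hit's position is the motif center,
rounded toward the motif start for even lengths; offsets are reported
relative to the window's CpG. The vectorized scanner is checked against
an explicit per-position brute-force oracle, exhaustively for all short
sequences and on seeded 12-mers including Ns.

## Over-representation statistic

Target windows are ±5 kb (truncated at contig ends) around the
differential CpGs of one interval × direction; background windows
surround an equal number of probes sampled (seeded) from the
non-differential remainder, optionally averaged over several draws. The
expected count is `λ = (background total + 1) · n_target / n_background`;
the add-one pseudo-hit keeps λ positive when a motif is absent from the
background sample and makes the test conservative at small counts. The
p-value is the exact Poisson upper tail `P(X ≥ observed)` via the
survival function (regularized incomplete gamma), never a normal
approximation; tests require agreement with term-by-term summation to
1e−12. Cells with an empty differential set are reported as not testable
(NaN), not as p = 1.

Across the motif library within each interval × direction the screen
applies Benjamini–Hochberg correction and passes TFs at FDR ≤ 0.05 (raw-p
mode available via `use_fdr=False`); the final gate requires expression
≥ 50 TPM at either flanking time point (inclusive). Rows of the resulting
matrix can be ordered by complete-linkage clustering of −log10 p
profiles.

The positional enrichment profile bins hit offsets into 100-bp bins over
±5 kb and reports `log2((d_t + c_t)/(d_b + c_b))` where `d` are
per-window-per-base hit densities and `c = 1/(n_windows · bin)` is a
pseudo-density; a centered 5-bin moving average is applied by default.
The log-ratio definition of this score is this package's choice and is
documented as such.

## Region operations

All intervals are 0-based half-open. A CpG at 1-based `pos` extends to
`[pos − 1 − w, pos + w)` (width `2w + 1`), `w = 200` bp for overlap
tests and `w = 100` bp for functional annotation in the original
workflow; both are parameters. Overlap counting marks a query interval
once if it shares ≥ 1 base with any subject interval (pyranges
underneath). The permutation test relocates every query interval
independently: chromosome chosen with probability proportional to its
number of valid start positions, start uniform, lengths preserved,
placed regions free to overlap each other (no mappability masking —
a known simplification). Inside the loop the subject set is pre-merged
and queried with a numpy interval sweep; tests verify this fast path
against pyranges and against exhaustive placement enumeration on a toy
genome, plus super-uniformity of the p-value under the null. The
empirical tail is `(#{permuted ≥ observed} + 1)/(n + 1)`, so 1000
permutations floor at p ≈ 0.001.

Annotation is by CpG-point containment: promoters are strand-aware
`[TSS − 1000, TSS + 200]` spans of gene models, promoter takes
precedence over enhancer, the rest is unannotated; class counts sum to
the number of regions.

## Coverage and kinetics

Coverage tracks (bedGraph or BED reads expanded per base; alignment
files are out of scope) are normalized so the wigsum (total per-base
coverage) equals 1e9, i.e. the depth of ten million 100-nt reads.
Meta-region matrices average normalized coverage in 100-bp bins over
±5 kb around each CpG; bases beyond contig ends contribute zero while
the denominator stays the full bin width (the w0 convention), so edge
bins are honestly deflated rather than renormalized. Region expression
is CAGE-style: tags within a closed ±250 bp window × 1e6 / library
size; across-region means are reported relative to the first time point
with an ε = 0.01 TPM pseudocount on both sides of the ratio. The
kinetics table reports, per UDR set, the mean −ΔM versus time 0 and
per-assay `log2((cov_t + c)/(cov_t0 + c))` with pseudo-coverage c = 1
normalized unit (zero-handling in the source figures is unstated; these
pseudocounts are this package's choice), using region *means* rather
than sums, plus the driver's TPM series.

## Synthetic study generator

The generator emulates the structure the analysis assumes, not array
chemistry: i.i.d. genome at 41% GC (human-like); 25 planted consensus
instances of a 10-bp driver motif (reverse complement on minus strand,
about half of sites) on a 1-Mb contig; 120 probes, half within 500 bp of
a planted site and half resampled until > 500 bp from every site, so
clean target and background populations exist; driver-adjacent probes
start at M = +3 (keeping a > 2 drop inside a realistic M range) and
decline linearly by 4 M-units from the onset time point (index 2 of 6)
to the course end, background probes keep a constant per-probe
N(0, 2) mean; i.i.d. N(0, 0.3²) noise per probe per time point (no
autocorrelation); driver TPM steps 0 → 300 at onset while decoys sit
constant below 50. All outputs are deterministic under the seed.

Sizing rationale: windows are ±5 kb, so the planted-site density (25 per
Mb) keeps a background window's chance of containing a site at ~0.25
while every target window contains one — the regime in which motif
over-representation is detectable. Motif consensi are 10 bp with mixed
composition, the realistic length scale for TF PWM libraries; much
shorter AT-rich consensi occur so frequently by chance that target and
background windows become equally motif-rich and no method could
separate them. Because the 4-M-unit effect is spread over three
intervals, adjacent-interval steps (~1.3 M-units) stay below the
threshold and the screen is validated on cumulative intervals versus
time 0 — mirroring how slow continuous demethylation is genuinely
invisible to adjacent-time-point calling.

What passing synthetic tests does **not** show about real data: array
normalization artifacts, probe cross-reactivity, correlated noise,
non-consensus (degenerate) binding sites, CpG-density biases and real
genome repeat structure are all absent; the generator demonstrates that
the statistics recover a planted signal under their own assumptions, not
that those assumptions hold on arrays.

## Problem sizes and numerical choices

Default test and validation scale: 1-Mb genome, 120 probes, 4 PWMs, 10
seeds for the recovery check; permutation tests at 1000 permutations
(tests use fewer where only calibration, not resolution, is at stake).
Ties at the scan threshold count as hits (`≥`); the Poisson tail at
observed = 0 is exactly 1; zero-variance samples yield NaN correlations
with a warning rather than an error; empty differential sets and empty
UDR sets are flagged and skipped rather than silently propagated.

## Known limitations

Single-contig synthetic genomes by default (the region machinery is
multi-chromosome); no mappability/blacklist masking in the permutation
test; no dinucleotide or methylation-aware background models in
scanning; no IDAT ingestion or normalization (inputs are normalized M or
beta values); plain heatmap-ready tables rather than rendered figures.
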