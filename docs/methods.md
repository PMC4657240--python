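# Methods

## Coordinate and binning conventions

All internal coordinates are 0-based, half-open; GFF3 input is converted at
the I/O boundary. Signal tracks are rasterized onto a uniform bin grid
(default 10 bp): a bin takes the value of the bedGraph interval covering
its midpoint, uncovered bins are 0, and the partial last bin of a
chromosome is kept and weighted as a full bin in genomic statistics. The
10 bp default resolves the 100 bp smoothing window and the 200 bp minimum
peak length in integer bins. Strand is ignored for tracks and respected
only for TSS definitions and promoter windows.

## Peak calling

The input track is first scaled so that its genome-wide total equals the IP
total; the per-bin statistic is log2((IP + α)/(input·s + α)) with
pseudocount α = 0.5 reads/bin. Without the library-size scaling a ratio of
read densities from libraries of unequal depth is not interpretable, so the
scaling is applied before the ratio; a `normalize=False`-style comparison
is possible by pre-scaling inputs externally. Median smoothing replaces
each bin by the median of the bins whose centres lie within ±window/2
(100 bp default) of its centre, truncating at chromosome ends. The calling
threshold is the genome-wide 95th percentile of the smoothed track over
*all* bins, zeros included; peaks are maximal runs of bins *strictly*
above threshold spanning ≥ 200 bp. The summit is the midpoint of the run's
maximal bin, ties resolved leftmost, which makes downstream windows
deterministic. A constant track yields no peaks (nothing exceeds its own
percentile) and triggers a warning rather than an error.

## Binding summaries and the classification matrix

The per-peak, per-dataset statistic is the maximum mean over
`n_consecutive = 3` adjacent bins lying fully inside
[centre − w, centre + w). Window half-widths default to w = 150 bp for
protein datasets and w = 250 bp for histone modifications; the
corresponding full widths (300 and 500 bp) match the window sizes quoted
for protein and histone comparisons, and both are configurable because the
half- versus full-width reading is genuinely ambiguous. If fewer than three
bins fit the window the dataset's genomic mean stands in, and any computed
value below the genomic mean is floored to it — a site where a factor is
absent is "background", never "depleted". Flooring is applied uniformly to
the classification matrix as well as to display values (toggleable), which
keeps one contract for both uses. Raw-density tracks are log2-transformed
with the same pseudocount before summarization; genomic mean and maximum
are computed on that same log2 track.

Mean/max scaling, used for display and for cross-dataset averaging, is the
affine map (x − mean)/(max − mean): 0 is the genomic mean, 1 the genomic
maximum. It is order-preserving, deliberately unclipped, and undefined for
constant tracks (error).

## Classification

Columns are centred and scaled to unit variance (ddof = 1), so the PCA
diagonalizes the correlation structure; scores and loadings come from the
SVD of the standardized matrix, with each component's sign fixed so its
largest-magnitude loading is positive. Component retention is either
`fixed(k)` (k = 4 in the published parameterization) or `broken_stick`
(leading components whose variance fraction exceeds the broken-stick
expectation, stopping at the first failure) — the data-driven default for
synthetic runs; a Kaiser rule is also available. Clustering is Ward on
Euclidean distances of the retained scores via scipy's linkage (the Ward.D2
convention; no alternative convention is offered), cut with `maxclust`,
and classes are numbered by dendrogram leaf order so that the leftmost
leaf block is class 1. Determinism comes from scipy's nearest-neighbor
chain algorithm: the same matrix always yields the same tree.

## Class characterization

* **Gene features.** A peak is classified by its centre with precedence
  promoter > exon > intron > intergenic. The promoter is the strand-aware
  window (−500, +100) around the TSS; "promoter" is otherwise undefined in
  the source analysis, so the window is configurable. Classifying by centre
  makes per-class fractions sum to 1.
* **Expression.** Genes are ranked and cut into three equally sized bins
  (low/mid/high), lower bins absorbing the remainder and ties broken by
  gene id. Expression values are treated as opaque ranked quantities.
* **Overlaps.** "Associated with" a reference set means ≥ 1 bp interval
  intersection (optional slop widens both sides). The RGR control redraws
  count- and length-matched regions uniformly over the genome (no
  mappability mask), seeded, reporting the mean fraction and a percentile
  interval over the draws.
* **Correlations.** Within each class with ≥ 4 members, Spearman ρ between
  the anchor dataset and every other column with the asymptotic p-value;
  Benjamini–Hochberg adjustment optional. Constant columns yield NaN with
  a warning.
* **Developmental profiles.** Per gene, the change between consecutive
  log2 timepoints; the gene-set average is mean-centred so profiles sum to
  zero by construction.
* **Distances.** Distance from peak centre to the nearest domain edge
  (0 inside); two peak sets are compared with a two-sided Mann–Whitney U
  test, chosen as a robust rank test where no test is prescribed.

## Insulator boundary analysis

Candidate regions are optionally restricted to intergenic elements and to
those whose centre lies within 10 kb of an H3K27me3 domain (overlap counts
as distance 0); the within-10 kb rule subsumes strict overlap and is the
default. Signal is extracted in [centre − 10 kb, centre + 10 kb) from the
mean/max-scaled H3K27me3 track, aggregated into 100 bp output bins, and
each region is flipped so the flank with the larger *summed* signal lies to
the right — "higher methylation level" is unquantified, and the sum is
robust to bin width; exact ties are not flipped, and re-orienting an
oriented set is a no-op. Windows truncated by a chromosome end are
excluded and reported in the eligibility counts. Because scaled background
sits near (slightly below) zero, a blocking insulator's left/right flank
mean ratio is near zero or negative, while a non-blocking insulator's is
near one.

Acetylation subclassing runs the same PCA + Ward machinery on the histone
columns only (k = 2), flagging as "high-acetylation" the subclass with the
larger mean scaled value across acetylation-named columns (pattern
`K<digit>ac`, methylation names excluded).

## ChIP-qPCR arithmetic

Per replicate and antibody, enrichment over input is E = 2^(Cq_input −
Cq_IP) at fixed amplification efficiency 2.0 (none is given by the assay
design). E is divided by the geometric mean of E at the two intergenic
control sites — geometric because Cq space is logarithmic — and the target
value is divided by the matching total-H3 value. The treated/control fold
of these final values is tested with a two-sided Welch t-test across
replicates. Because every Cq of a replicate shifts together under a machine
offset, and the input Cq of a sample is shared by its target and H3
measurements, the normalization cancels both offsets exactly.

## Word enrichment

Controls are filtered to the foreground's per-sequence A/T range (ambiguous
bases excluded from both numerator and denominator). Overlapping k-mers are
counted per valid window; with reverse-complement pooling (default — ChIP
regions are unstranded) each word is reported as the lexicographically
smaller of its pair. Enrichment is log2((fg_rate + ε)/(bg_rate + ε)) with
ε = 1/(positions of the smaller set), a scale-free smoothing. The one-sided
binomial p-value treats the background rate as known, so it is conservative
only when the control set is much deeper than the foreground; the null
calibration checks run in that regime. Bonferroni correction over the 4^k
word space is reported alongside raw p, and 2-periodic words are flagged as
dinucleotide repeats. Multivariate word modeling is deliberately out of
scope; the module substitutes transparent count-based ranking.

## Synthetic data: what it emulates and what it does not

The default configuration is one 5 Mb chromosome at 10 bp bins, Poisson
background λ = 20 reads/bin, and 40 elements of 500 bp per archetype
(promoter, active enhancer, inactive enhancer, PRE, blocking insulator,
non-blocking insulator), placed on an even grid with ±500 bp jitter so
that 10 kb flanks never collide with a neighbour's domain. Element signal
is λ·(1 + (fold − 1)·k(x)) with a Gaussian kernel (σ = width/4, truncated
at the element boundary) producing realistic summits for the
top-3-consecutive statistic; a flat kernel is available for calibration
checks. Each element carries a log-normal intensity factor (σ = 0.2,
clipped to [0.8, 1.5]) shared across factors, so co-bound factors co-vary
within an archetype — the minimum effective IP amplitude stays ≥ 4. A
negative-binomial option (gamma-mixed Poisson) stress-tests overdispersion.
H3K27me3 domains are laid down per archetype: ±8 kb around PREs, a 9 kb
domain ending exactly at a blocking insulator's edge, and a domain crossing
a non-blocking insulator by 9 kb on both sides. Promoter elements straddle
a TSS (alternating strands), enhancers sit in introns of host genes, and
intergenic archetypes receive a dedicated nearby gene, so nearest-TSS
assignment and feature fractions have known answers. Expression classes
are drawn at 2/5/8 (log2 units, σ = 0.4) and inactive-enhancer genes ramp
up late in a 12-point timecourse.

Not emulated: mappability and read-level artefacts, copy-number and GC
biases, fragment-size effects, overlapping or nested genes, inter-element
correlation beyond the shared intensity factor, and realistic genome-scale
element density. Passing tests therefore demonstrate correctness of the
arithmetic and the recoverability of well-separated archetypes, not
performance on real chromatin.

The sequence simulator draws iid letters at a configured A/T fraction,
plants words at fixed per-sequence rates at non-overlapping positions, and
scrubs planted words (and their reverse complements) from controls; a
configurable fraction of controls is drawn at an outlying A/T fraction to
exercise the control filter. The qPCR simulator draws every measured Cq
with independent N(0, σ) noise around its true value, sharing one input
quantity per sample.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on the 5 Mb /
240-element dataset (seconds), oracle comparisons on fifty 10⁵-bin random
tracks, 10⁴ random summarizer cases, 200 seeded qPCR replicates and 1000
Spearman null replicates — sizes chosen so the whole suite completes in
well under a minute per analysis while keeping every statistical check
adequately powered. Floating-point specifics: PCA reconstruction is checked
to 1e-8; zero-variance columns are detected with a relative 1e-12
tolerance; exact ties in peak summits and flank sums resolve deterministically
(leftmost bin, no flip). Percentiles use numpy's default linear
interpolation.

## Known limitations

* The classification is as good as the track compendium: archetypes
  distinguishable only by a dataset that is absent will merge.
* The RGR control has no mappability or blacklist masking.
* The binomial word test underestimates tail probabilities for shallow
  control sets and for highly self-overlapping words.
* Ward is offered in the D2 convention only.
* bigWig output, BAM-level processing and liftover are out of scope.
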