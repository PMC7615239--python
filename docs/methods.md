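# Methods

## Scope and model

chipmeta starts where a peak caller ends. Its inputs are per-replicate
narrowPeak files (ENCODE BED6+4, with −log₁₀ p/Q and a summit offset), a
gene-level GFF3 annotation and bedGraph coverage; read mapping and peak
calling are upstream concerns. All internal coordinates are 0-based,
half-open (BED convention); GFF3's 1-based inclusive spans are converted
on read and back on write. The declared chromosome order of the genome
assembly is authoritative for every sorted output.

## Peak filtering

Peak callers are typically run permissively (e.g. q = 0.05); the analysis
then keeps only highly significant peaks. The post-filter retains peaks
with −log₁₀ Q ≥ 10 (Q ≤ 10⁻¹⁰), *inclusive* at the threshold. Peaks with
missing Q (−1 per narrowPeak convention) are rejected with an instructive
error rather than silently dropped: the filter is meaningless without
called Q-values. Filtering is applied to replicate peak sets *before*
consensus building, so a weakly supported peak cannot ride into a
consensus cluster on a strong neighbour's significance.

## Consensus peaks

"Present in at least two replicates" is interpreted cluster-wise: a
factor/condition's filtered replicate peaks are pooled and clustered by
transitive overlap, and a cluster is emitted when its members span ≥ 2
distinct replicates (two peaks from one replicate count once). Clustering
uses merge semantics — touching intervals ([a,b), [b,c)) join one
cluster — so that with `min_support=1` the emitted regions reduce exactly
to a plain interval merge of the pooled peaks; for real peak data the
touching case is measure-zero. The consensus *extent* is the cluster's
union span and its *summit* is taken from the member peak with the
highest −log₁₀ Q (leftmost summit on ties) — the union keeps clusters
maximal and the best-supported summit anchors gene assignment. Support is
configurable down to 1 (with a logged warning) for designs with a single
replicate, such as single-replicate control IPs.

## Gene assignment

A consensus peak is assigned by its summit. Candidate genes are those
whose assignment window — gene body extended by 1 kb on each side, so
1 kb upstream of the TSS through 1 kb downstream of the TTS, clipped at
chromosome ends — contains the summit; the window boundary is inclusive
(a summit exactly 1 kb upstream is inside). Because the two flanks are
equal the window is strand-independent. Among candidates, distance is
measured from the summit to the gene *body* (0 inside; otherwise to the
nearer of the first and last body base): the candidate window is
body ± 1 kb, so body distance is the natural metric. Exact distance ties
break to the lexicographically smallest gene ID — an arbitrary but
deterministic rule. Only the winner is emitted; the number of candidates
is recorded for audit. The target table counts distinct assigned genes,
so a gene hit by several peaks counts once.

## Co-occupancy

Overlap between factors is peak-level with a ≥ 1 bp criterion and no
reciprocal-fraction requirement (default intersection semantics of the
standard interval tools). `pct[i][j]` is the percentage of set *i*'s
peaks overlapped by ≥ 1 peak of set *j*, reported to one decimal; empty
sets yield NA rows/columns, never 0. Multi-way counts partition a
reference factor's peaks by the exact combination of other factors
co-occupying them (2^(k−1) rows summing to the reference set size).
Gene-set overlap is exact set arithmetic on normalized IDs (case-folded,
version suffixes stripped on request); the hypergeometric upper-tail
p-value is computed only when a gene universe is supplied and is an
extra beyond the raw percentages.

## Coverage and metagene profiles

Coverage is a piecewise-constant step function per chromosome with
implicit zeros. Replicates are merged by step-wise summation of raw
tracks *before* normalization, so merging k identical tracks leaves the
normalized profile unchanged. RPGC normalization multiplies every value
by G / Σ(value · step length), with G the effective genome size
(default: total assembly length, configurable because published analyses
rarely state the value used); the genome-wide mean is then exactly 1.

The metagene axis is a 1 kb upstream flank in 20 fixed-width bins, the
gene body scaled into 100 equal-fraction bins, and a 1 kb downstream
flank in 20 bins (all configurable; the flank must divide evenly by its
bin count). Bin values are length-weighted mean coverage, computed as
exact integrals of the step function between bin boundaries via
cumulative step sums. Body-bin boundaries are placed at real-valued equal
fractions of the gene length rather than rounded to whole bases: integer
binning is not mirror-symmetric when the length is not divisible by the
bin count, and symmetry is what guarantees that a minus-strand gene over
mirrored coverage yields an identical row. Minus-strand rows are
reversed so bin 0 is always 5′-most. Flank bins extending past a
chromosome end are reported NA (not truncated means) and ignored,
column-wise, when averaging; genes shorter than a minimum length
(default: one body-bin's worth, 100 bp) are excluded and logged. Input
controls are profiled identically and plotted as separate curves — no
subtraction or log-ratio.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not sequencing reads. Genes (default 300, lengths 800–2500 bp) are placed
non-overlapping with ≥ 4 kb spacing on a 2 × 1 Mb genome — spacing at
least twice the assignment flank plus room for intergenic sites, which
makes summit-to-gene assignment unambiguous by construction. Latent
binding sites are drawn per factor and condition from a positional
mixture (default 60% TSS, 25% slightly downstream of the TTS — 200 bp in
the direction of transcription — 15% intergenic, with 100 bp Gaussian
jitter), reflecting the empirical pattern of PRC2-accessory binding:
strong TSS preference with a minor mode past the TTS. Genic sites of one
factor occupy distinct genes; intergenic sites keep > 1 kb + peak-width
clearance from every gene so they are planted non-targets.

Conditions differ only in site count (default 120 NV vs 250 post-cold),
a deliberately simple stand-in for the biology that after prolonged cold
the factors occupy many more genes. Inter-factor sharing π copies a
Bernoulli(π) fraction of a dependent factor's sites from the reference
factor (50 bp copy jitter); the complement is drawn from anchors the
reference does not use, so the planted overlap fraction is exactly π and
a measured co-occupancy percentage deviates from 100π by binomial noise
only. Each replicate realizes each site independently with probability
r (default 0.8), giving the Binomial(R, r) consensus-recovery law; peak
−log₁₀ Q values are strong (uniform 10.5–40) except for a configurable
weak fraction (default 20%, uniform 2–10) that fails the significance
filter. Coverage is a uniform background (1.0) plus Gaussian bumps
(amplitude 8, σ 200 bp) at realized summits, written at 10 bp step
resolution; input controls carry background only, noiseless by design —
stochasticity enters through site placement and replicate realization,
not read noise. A single seeded random stream drives everything; the
same seed reproduces every file byte for byte.

What passing these tests shows — and does not. Recovery of planted
parameters validates the interval algebra, the consensus/assignment
rules and the normalization arithmetic under the generator's idealized
conditions: well-separated genes, symmetric peaks, no duplicated or
GC-biased reads, no copy-number variation, no overlapping gene models.
Real genomes violate several of these (nested and overlapping genes
above all), where the closest-gene tie-break and the unambiguity
guarantees matter more and planted-truth accuracy cannot be asserted.

## Numerical and design choices

* Interval merge joins intervals separated by at most `min_gap` bp
  (touching merges at the default 0); any-overlap requires ≥ 1 shared bp.
* Closest-feature distance to an interval uses its first and last *base*
  (end − 1), consistent with the assignment metric; ties break on the
  feature identifier.
* Metagene bin integrals are exact for step functions; the test suite
  checks them against a dense per-base oracle at 1e-9.
* Default simulation sizes (genome, site counts) are chosen so every
  statistical check has hundreds of Bernoulli trials while a full test
  run stays in seconds; measured fractions are compared within 3
  standard errors of their planted expectation.
* Pipeline outputs use fixed decimal formatting, "NA" for missing, TSV
  with headers; the run manifest records a config hash and per-stage
  counts only, so identical inputs reproduce identical bytes.

## Limitations

Transcript isoforms, UTRs and exon structure are out of scope — peaks are
assigned to gene spans. No IDR or statistical reproducibility model
stands behind the consensus rule; it is the deterministic ≥2-replicate
cluster criterion. BAM/bigWig are not read or written; coverage comes in
as bedGraph. The hypergeometric gene-set p-value assumes a well-defined
universe and exchangeable genes, which real target lists rarely satisfy
exactly.
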