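# Methods

## The problem

ChAP-Seq (chromatin affinity purification and sequencing) maps the genomic
binding sites of a tagged DNA-binding protein — here, bacterial
transcription regulators such as the iron-responsive repressor DtxR or the
heme-responsive response regulator HrrA of *Corynebacterium glutamicum* —
by sequencing the DNA fragments co-purified with the protein. Analytically
the data are equivalent to ChIP-Seq: a per-base coverage track over a
(circular) chromosome in which binding sites appear as roughly
Gaussian-shaped enrichments over a noisy background. chapkit implements a
complete desk-scale analysis: duplicate collapsing and coverage
computation, a kernel-convolution peak caller with data-driven bandwidth,
replicate/condition consolidation, TSS annotation, regulon comparison,
PWM scanning with exact p-values, and the associated correlation analyses
— all exercisable against synthetic data with planted ground truth.

## Peak-calling model

The caller treats a binding site as a bump of unknown but roughly
consistent width `w` on a locally flat background, and detects bumps by
matched second-derivative filtering.

**Width estimation.** Provisional peaks are maximal runs of coverage
strictly above 3x the genome-wide mean coverage μ (μ is computed over the
whole genome, peak regions included). For each run the apex is its
maximum; the peak's FWHM is the distance between the outermost positions,
walking left and right from the apex, whose coverage is still ≥ half the
apex height. On a discrete triangular peak rising and falling over 100 bp
this yields exactly 100, matching the continuous half-maximum crossing;
the first-position-strictly-below convention would be 2 bp wider. The
expected width `w` is the median FWHM; for an even count of provisional
peaks the lower middle element is taken, so `w` is always an observed
integer width.

**Kernel.** The detection kernel is the negated second derivative of a
Gaussian density (a Mexican hat with positive center), truncated at 4σ
with σ = w/8, so the ±4σ support spans exactly the expected width. The
sign convention makes coverage maxima produce convolution maxima, which is
the only reading consistent with detecting summits where the profile's
first derivative changes from positive to negative. Truncation breaks the
analytic identity ∫g″ = 0, so the discrete weights are mean-shifted to sum
to zero exactly; a constant track then maps to an identically zero
profile, and the convolution score is invariant to uniform background
offsets. σ = w/8 is one reading of "kernel expanded to the expected peak
width"; the ratio is exposed as `sigma_ratio` (default 0.125) because
other mappings (e.g. σ = w/4) are defensible.

**Convolution** is circular (wrap-around) on circular chromosomes and
zero-padded on linear ones, computed by direct FIR filtering
(`scipy.ndimage.convolve1d`); tests pin it to the naive
O(L·R) direct sum at 1e−9 relative error.

**Summit detection.** The discrete first difference of the profile is
scanned for sign changes from positive to negative; a flat top (zero-run)
reports its center position rounded down. Candidates with non-positive
profile value are discarded.

**Filtering.** A candidate is kept if its raw summit coverage is ≥
`min_fold`·μ (default 3, reusing the detection threshold — the only
coverage threshold the procedure defines) and its convolution score is
positive. Each peak's extent is summit ± w/2; where extents overlap, only
the higher-scoring summit survives (greedy, score-descending, ties to the
smaller coordinate), which resolves shoulder artifacts deterministically.

**Normalization.** The normalization coefficient B is the total genomic
coverage minus the coverage inside all detected peak extents — the
background mass of the library. Each peak's normalized intensity is
`score / B × 1e6`; the 1e6 factor only keeps numbers readable.
Dividing the score *by* B (rather than B by the score) is chosen so that
stronger binding gives larger intensity, consistent with every downstream
use of "peak intensity"; intensities are exactly invariant under uniform
rescaling of the track, which is the property that makes samples of
different sequencing depth comparable.

## Consolidation and statistics

Summits from several replicate/condition peak sets are clustered by
single-linkage with threshold `merge_distance` (default w/2) on circular
distance — in one dimension this reduces to splitting the sorted summits
at gaps exceeding the threshold, with a wrap-around join at the origin.
Each cluster becomes one consolidated target: its locus is the
intensity-weighted mean summit; its support n is the number of distinct
samples (replicates) contributing a significant peak, where significance
means presence in that replicate's filtered peak set (no per-replicate
test is defined beyond the caller's own filter). Replicate
reproducibility is the Pearson correlation of intensity vectors over the
union loci, with 0 for absent peaks — dropping loci absent anywhere would
discard exactly the condition-specific signal of interest. Samples with
zero-variance vectors get NaN entries rather than an exception.

Regulon comparison partitions two target lists into shared / A-only /
B-only either by assigned gene id or by locus proximity (greedy
nearest-pair matching under a distance threshold). Correlations between
binding and expression pair each target's maximum per-sample intensity
with the **absolute** log2 expression ratio of its assigned gene
(activation and repression both count as regulation). All correlation
p-values are two-sided permutation p-values (default 10⁴ label
permutations, seeded, with the +1 small-sample correction); no normality
is assumed at these sample sizes. The qPCR helper implements the standard
2^−ΔΔCt relative quantification.

## Annotation

A summit inside exactly one gene body is intragenic, with positive
oriented distance from the TSS (TSS = gene start on +, end−1 on −). An
intergenic summit is assigned to the gene whose TSS lies downstream of it
in that gene's orientation within the upstream window (default 500 bp,
class "upstream", negative distance); for divergent promoters the nearer
TSS wins, ties break lexicographically. Summits matching neither rule
fall back to the overall nearest TSS. The upstream window is the one
genuinely free parameter: upstream-vs-intragenic counts depend on it
directly, and it should be reported with any such counts.

## Motif scanning

PWMs are built from aligned sites with a pseudocount (default 0.5 spread
by background frequency), or from an IUPAC consensus with `match_prob`
(default 0.9) shared equally among allowed bases. The p-value of a
log-odds score is the exact tail probability under a 0-order background
model, computed by dynamic programming over integer-binned per-position
scores (bin width `granularity` = 0.001); binning displaces the score
threshold by at most `length·granularity/2`, verified against exhaustive
4⁵ enumeration. The scan background defaults to the scanned sequence's
own mononucleotide frequencies (the common FIMO-style choice, which also
makes forward/reverse-complement scans exactly symmetric); both strands
are scanned, circular sequences are scanned across the origin, all
overlapping hits above threshold are reported, and hits are filtered at
p < 1e−5 by default. No FDR/q-values are computed and no de novo
discovery is attempted.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
circular chromosome (default 100 kb, GC 0.54 as in *C. glutamicum*),
40 non-overlapping genes on both strands, 20–60 Gaussian binding peaks
parameterized by FWHM (default 40–120 bp — the empirical width
distribution of real ChAP-Seq peaks is not well characterized, so this
range is configurable), heights 30–300 over a Poisson background of mean
10, three replicates per condition, condition-specific peak subsets
(optionally with exact per-pattern counts), planted IUPAC-consensus motif
instances centered on summits, and expression tables that are either null
or anti-proportional to peak height (magnitude decreasing with binding
strength, sign negative; when several peaks share a nearest gene the
strongest wins). PCR duplicates are emulated at the alignment-record
level for the collapsing stage. All generators are pure functions of
their seed, and the planted truth serializes to a JSON sidecar.

What the generator does **not** emulate: read-level sequencing error,
fragment-size distributions, mappability artifacts, GC bias, copy-number
variation, or correlated (non-Poisson) background structure. Passing the
recovery tests therefore demonstrates correctness of the algorithmic
chain under the model's own assumptions, not performance on real
libraries, where background inhomogeneity typically dominates.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  and bedGraph conversions happen only at the I/O boundary.
- bedGraph is written with one line per maximal constant run, zeros
  included, so write∘read is the identity and interval counts are
  predictable.
- Duplicate collapsing keys on (chrom, start, end, strand), keeping the
  first record; SAM input uses primary mapped records only, and by
  default one fragment interval per properly paired read pair.
- Constant tracks raise a "no peaks detectable" error carrying μ; a peak
  set covering the whole genome raises a normalization error (B ≤ 0);
  empty peak sets are valid results, not errors.
- Problem sizes in the test and acceptance harnesses (100 kb genomes,
  30 peaks, 10 simulation seeds, 200 oracle instances, 10⁴ permutations,
  50 calibration seeds) are desk-scale choices that keep the full suite
  under a minute while leaving every estimate's Monte-Carlo error well
  inside the asserted tolerances.

## Known limitations

- Single chromosome per run; no joint multi-chromosome calling.
- No input/control-sample subtraction and no peak-level FDR — the filter
  is the 3×μ coverage rule.
- The σ↔width mapping, the filter rule, and the upstream window are
  under-determined by the procedure the caller mirrors; all three are
  configurable and documented above.
- Greedy overlap resolution can suppress a genuine secondary summit
  closer than w to a stronger one.
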