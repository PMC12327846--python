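# chapkit

Kernel-convolution peak calling and regulon analysis for bacterial
ChAP-Seq / ChIP-Seq.

ChAP-Seq maps the genome-wide binding sites of a tagged DNA-binding
protein — e.g. the iron-responsive repressor DtxR or the heme-responsive
regulator HrrA of *Corynebacterium glutamicum* — as enrichments in a
per-base coverage track over a circular chromosome. chapkit turns aligned
reads into consolidated, annotated regulon maps:

1. **Coverage** — PCR-duplicate collapsing and interval-stabbing depth
   (BED/SAM in, bedGraph out), with circular-chromosome wrap-around.
2. **Peak calling** — the core algorithm. The expected peak width *w* is
   the median FWHM of all coverage runs above 3×mean; the track is
   convolved with a negated second-derivative-of-Gaussian kernel
   (σ = *w*/8, truncated at 4σ, zero-sum corrected); summits are the
   points where the first derivative of the convolution profile flips
   from + to −; peaks below 3×mean raw coverage are filtered; each peak's
   intensity is its convolution score divided by the background mass
   B = Σcoverage − Σcoverage(peak extents), ×10⁶.
3. **Consolidation** — single-linkage merging of summits across
   replicates/conditions, replicate support counts *n*, Pearson
   reproducibility matrices, condition-specific target partitions,
   regulon overlap between two regulators.
4. **Annotation** — nearest-TSS assignment with an upstream window
   (default 500 bp), upstream vs intragenic classification, oriented
   distance to the TSS, and the distance–intensity trend.
5. **Motifs** — PWMs from aligned sites or IUPAC consensus (e.g. the
   DtxR box `TAGGTTAGSCTAACCTAA`), scanned on both strands with *exact*
   tail p-values computed by dynamic programming (default p < 1e−5).
6. **Correlations** — permutation-tested Spearman/Pearson between peak
   intensity and |log2 expression ratio|, plus the 2^−ΔΔCt qPCR helper.

A first-class synthetic-data module generates genomes, gene models,
planted Gaussian peaks with condition-specific presence, motif instances,
replicate Poisson coverage and expression tables — the planted truth is
the oracle for the whole test suite. See `docs/methods.md` for the model
in detail.

## Worked example

The built-in demo plants 30 peaks (two conditions × three replicates,
Poisson noise, half the peaks carrying the DtxR-box consensus) on a
100 kb circular genome, runs the full pipeline, and prints the summary:

```bash
chapkit demo --outdir demo_out --seed 1
```

```json
{
 "expression_correlation": {
  "regA": {"n_pairs": 30, "p_permutation": 0.0049, "spearman": -0.502}
 },
 "n_motif_hits": 39,
 "n_planted_peaks": 30,
 "n_samples": 6,
 "per_regulator": {
  "regA": {
   "condition_classes": {"all": 11, "only_heme": 8, "only_iron": 11},
   "distance_intensity": {"p_permutation": 0.090, "spearman": -0.312},
   "n_intragenic": 6,
   "n_targets": 30,
   "n_upstream": 24
  }
 }
}
```

Reading it: all 30 planted sites were recovered as consolidated targets
(`n_targets` = `n_planted_peaks`); 11 bind in both conditions, 11 only
under iron, 8 only under heme; 24 summits lie in upstream (promoter)
regions and 6 inside ORFs; the planted motif yields 39 hits at p < 1e−5
(each near-palindromic site matches on both strands); and the
anti-proportional synthetic expression model shows up as a significant
negative Spearman correlation between binding intensity and expression
magnitude (r = −0.50, permutation p = 0.005). Per-sample peak tables,
target TSVs, the Pearson matrix, motif hits, a manifest and this summary
are written to `demo_out/results/`.

Every stage is also a subcommand (`simulate`, `coverage`, `callpeaks`,
`consolidate`, `annotate`, `scan`, `correlate`, `run`) and a plain
library call (`chapkit.call_peaks(track)` etc.).

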