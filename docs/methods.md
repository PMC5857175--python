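# Methods

## The quantification model

`absquant` treats a microbiome sample as two coupled measurements of the
same DNA extract:

1. amplicon sequencing, which multinomially samples `depth` reads from the
   community's 16S gene pool and yields relative abundances
   `p_i = reads_i / depth`;
2. qPCR of the same 16S variable region, which yields the total gene load
   `T` (copies per gram dry soil) via a standard curve.

The per-taxon absolute abundance is the product `A_i = p_i × T`. The model
assumes (a) sequencing reads are drawn proportionally to 16S gene copies —
no amplification bias differing between taxa and qPCR, which is why the
same variable region should be used for both measurements; (b) the qPCR
total reflects the same template pool the sequencing library was built
from. Under these assumptions `Σ_i A_i = T` holds exactly, and the package
enforces it as an invariant.

Units are 16S gene copies per gram throughout. Genomes carry between 1 and
~15 rRNA operons, so gene copies overcount cells for multi-operon taxa;
`to_genome_equivalents` divides by a per-taxon operon count `c_i`
(`G_i = A_i / c_i`) where one is known. Community-wide operon-count
inference from reference databases is out of scope; unmatched taxa default
to `c = 1`, i.e. their numbers stay on the gene-copy scale, with a logged
warning.

## qPCR calibration and QC

A standard curve is fitted by ordinary least squares of Ct on
log10(copies) over a ≥3-point dilution series spanning at least two
decades. Efficiency is `E = 10^(−1/slope) − 1`; a perfect doubling per
cycle gives slope −3.3219 and E = 1. Unknowns are quantified from the
*mean* of replicate Cts (quantifying the mean Ct, not averaging
per-replicate copy numbers, matches standard practice and keeps the
estimator monotone in Ct). Three flags:

- `high_replicate_sd` — replicate SD above `sd_limit` (default 0.5 Ct,
  a common acceptance threshold for triplicate assays);
- `below_loq` — mean Ct beyond the most dilute standard's mean Ct. This is
  a non-detect call: a signal weaker than the weakest calibrator cannot be
  distinguished from off-target amplification;
- `out_of_range` — implied copies above the calibrated range (the low side
  is already expressed by `below_loq`, so the two flags never both fire
  for the same cause).

Single replicates get SD 0 (no SD flag): a degenerate input, not an error.

Scaling to soil units is
`copies/g = copies/rxn ÷ template_µL × elution_µL ÷ soil_g`; defaults
(1 µL template, 100 µL elution, 0.21 g extractions) mirror a typical soil
DNA-extraction kit protocol. When triplicate extracts are pooled into one
sequencing library, `mean_total` averages the triplicate qPCR totals to
produce the matching `T`.

## Spike-in validation

A reference strain of known addition carrying a single-copy marker gene
gives two independent handles on the same quantity: the marker qPCR value
times the 16S:marker copy ratio (`expected_marker_copies`), and the
sequencing-derived `A_i` of the strain's genus. `validate_spikein` fits,
on log10 scales:

- the calibration fit (with intercept) of marker qPCR on nominal
  additions — the pass/fail verdict uses this fit, with default
  thresholds slope ∈ [0.9, 1.1] and centered R² ≥ 0.99 (package policy,
  parameterised);
- through-origin agreement fits of the integrated estimate on the
  16S-equivalent expectation, with and without the lowest addition level,
  which sits closest to the sequencing detection limit and is the first
  point to degrade.

For through-origin fits the centered and uncentered R² differ and no
single convention is universal, so `RegressionResult` always reports both,
labelled. Nominal additions are converted as CFU/mL × volume ÷ soil mass,
treating one CFU as one genome.

Method agreement across quantification routes uses Levene's test
(mean-centered) for variance homogeneity at α = 0.05; homogeneous groups
go to one-way ANOVA with Tukey's HSD (scipy), heterogeneous ones to
Tamhane's T2, implemented as Welch-type pairwise t statistics with
Satterthwaite degrees of freedom and a Šidák multiplicity adjustment
(no installed library provides it). Results are summarised as a compact
letter display (insert-and-absorb); the letter *partition* is invariant
under group reordering, the letter names themselves follow input order.
When every observation is identical the chain short-circuits to "no
differences" rather than evaluating degenerate test statistics.

## Dynamics and discordance

Relative changes are reported in percentage points (difference of shares);
absolute changes in percent of the baseline quantity — mixing the two
conventions is deliberate, since shares and quantities are on different
scales. A taxon between two time points is *discordant* when the two
deltas have opposite nonzero signs, *concordant* when signs agree, and
*unchanged* when either |delta| ≤ eps. The default eps = 0 is a strict
sign test; it is exposed because read-count noise makes tiny deltas
meaningless in practice. A taxon absent at baseline with nonzero copies
later has an undefined percent change (reported as missing, not infinity)
and its absolute delta treated as positive.

Sample clustering for heatmaps is agglomerative hierarchical clustering
(scipy) with euclidean distance and complete linkage on log10(x+1)
values — the defaults of the widely used R heatmap tooling — all
parameterised. Ties break deterministically by input order; the dendrogram
exports to newick.

## The synthetic generator

`synth.generate` emulates a soil spike-in study: a fixed background
community (explicit proportions or a symmetric Dirichlet, default
concentration 0.5 across 50 taxa, giving the long-tailed profile typical
of soil), a lognormal total load (default median 5.82×10⁹ copies/g with
log10-SD 0.025, i.e. ~6% CV, matching triplicate qPCR scatter on a soil
background), and a reference strain added at six levels from 7.0×10⁹ to
7.0×10⁴ CFU/g (1 mL of 10-fold suspension dilutions into 30 g of soil)
with 7 rRNA operons and a single-copy marker. Sequencing is an ideal
multinomial draw of 66,460 reads per sample; qPCR is the exact standard
curve plus Gaussian Ct noise (default SD 0.1, triplicate). All randomness
derives from one seed through per-component substreams, so enlarging the
community does not perturb the qPCR noise stream.

What the generator does *not* model: PCR amplification bias, chimeras and
sequencing error, taxon-specific extraction efficiency, and operon-count
variation in the background community. Passing recovery tests therefore
demonstrate the pipeline's arithmetic and statistical correctness under
the stated sampling model, not robustness to those real-data artefacts.

`recovery_report` runs the full pipeline (curve fit → Ct quantification →
relative abundances → integration → spike regression) and scores it:
per-taxon relative error against the true `A_i`, coverage of 95%
normal-approximation multinomial intervals for read counts, and the
spike calibration slope/R². An `exact_counts` mode replaces the
multinomial draw with expected counts so that a noiseless configuration
recovers truth to floating-point accuracy — the end-to-end identity test.

## Numerical and design choices

- Counts are the primary data and must be integers; proportions are always
  derived. Minor-taxon pooling (<0.1% by default, strict inequality) pools
  a taxon only when it is below threshold in *every* sample of the table,
  so no taxon is split between its own label and "Minor" across a figure.
- Unclassified lineage segments truncate the lineage; aggregation at a
  rank pools everything unclassified there under one sentinel.
- V3 and V4 totals are never averaged: each region yields its own absolute
  table, and V4 is the sensible default (better classification reliability
  and total-quantity agreement).
- Regressions use closed-form normal equations (`Σxy/Σx²` through the
  origin); the test suite cross-checks them against statsmodels OLS, and
  clustering against a brute-force O(n³) agglomerative implementation.
- Test problem sizes (≤6 samples, ≤50 taxa, depths 10³–10⁷, ≤30
  replicates) keep the whole suite under a few seconds while leaving the
  statistical assertions well-powered.

## Known limitations

- The integration propagates no uncertainty: `A_i` inherits both
  multinomial noise (dominant for rare taxa) and qPCR noise (dominant for
  abundant ones), but the package reports point estimates; the synthetic
  generator is the tool for studying the resulting error distribution.
- Detection is bounded below by `L = (min detectable reads / depth) × T`;
  taxa below L are simply absent, not zero-inflated estimates.
- BIOM support is v1 (JSON) only; HDF5-based BIOM v2 files are not read.
- Tamhane's T2 p-values use the Šidák form; SPSS-style implementations
  differ in small details of the critical-value computation, so letter
  displays may differ marginally near α.
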