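# Methods

## Model and assumptions

`gbscov` treats GBS coverage as a windowed counting process. Reads start
at restriction-enzyme cut sites, so within a fixed genomic window the
number of read starts is approximately proportional to (i) the sample's
library size and (ii) the local density of usable, unmethylated cut sites
that map well against the reference. Large chromosomal modifications
change (ii) over megabase scales: donor segments introgressed from a
related species map poorly (fewer read starts), deletions remove cut
sites entirely, duplications double them, and methylation shifts silence
a fraction of them. The method makes no attempt to model read sequence;
it is purely a depth-ratio analysis, which is what makes it applicable to
the shallow, uneven coverage typical of GBS.

Assumptions worth stating explicitly:

- The positional coverage trend (high near telomeres, low near
  centromeres) is shared across samples, so it cancels in the per-window
  ratio against a reference profile built from the same collection.
- Library-size differences are purely multiplicative and are removed by
  the counts-per-million normalization.
- At 500 kb windows the per-window counts are large enough (hundreds of
  reads at typical GBS depth) for the log-ratio to be roughly Gaussian
  after smoothing; robustness of the median/MAD scoring covers the rest.
- At most a minority of samples carry any given modification, so the
  per-window median over the collection is a valid null reference.

## Pipeline stages and parameters

| parameter | default | role |
|---|---|---|
| window size *w* | 500,000 bp | grid resolution; smaller windows raise variance per window |
| min MAPQ | 20 (PHRED) | drops ambiguous mappings |
| min non-clipped bases | 30 | drops overclipped alignments; counted as read length minus soft+hard clips |
| min reads per sample | 100,000 | sample QC floor (strictly-less-than is discarded) |
| pseudocount ε | 1e6 / N | expected reads per window at 1M-read normalization; one genome-wide value |
| smoothing width *k* | 5 windows | centered rolling mean, per chromosome, truncated at ends |
| outlier probability | 0.9999 | two-sided threshold Φ⁻¹(0.9999) ≈ 3.7190 on the MAD z-score, computed at run time |
| MAD scale | 1.4826 | normal-consistency factor |
| min outliers per stretch | 3 | counted over flagged windows only |
| long-stretch minimum | 30 | conservative screen for large/low-coverage collections (≥ 15 Mb at 500 kb windows) |
| frequency threshold | 3% | "robust" windows flagged in at least this fraction of samples (inclusive boundary) |
| locus combined coverage | 10 reads | floor for the locus presence/absence analysis; presence is ≥ 1 read |

Design choices where the procedure was genuinely open:

- **Sidedness.** Outlier detection is two-sided on |z| by default (with a
  one-sided `upper` option): both decreased coverage (introgression,
  deletion) and increased coverage (duplication) are biologically
  expected, and in practice most detected outliers have negative
  denoised values.
- **Scoring scope.** The median and MAD are computed over the sample's
  genome-wide profile; stretch assembly is per chromosome and never
  crosses a chromosome boundary, and neither does the rolling mean.
- **"Overclipped".** Interpreted as fewer than 30 non-clipped query
  bases, counting soft and hard clips alike; the threshold is
  configurable.
- **Mates.** Both mates of a pair are counted independently when each
  passes the filter; a first-in-pair-only flag is provided.
- **Duplicates.** Not filtered (no duplicate filter is part of the
  counting rule); unmapped, secondary and supplementary records always
  are.
- **Even-sample median.** Mean of the two central order statistics. The
  query sample is included in its own median reference by default; a
  leave-one-out option exists.
- **Stretch minimum.** "At least 3 windows" counts flagged windows, not
  total span: `T F T` has 2 outliers and does not qualify at the default
  minimum. Bridged gap windows are inside the stretch but not counted.
- **Longest stretch ties.** Most outlier windows, then larger bp span,
  then chromosome order, then lowest start.
- **Direction tie.** A stretch whose mean denoised value is exactly zero
  is classified as decreased (the degenerate case essentially never
  occurs on real data).
- **Overlap reporting.** Against annotated regions both the fraction of
  the annotated interval covered and the Jaccard index are returned; the
  annotated-length fraction is the headline number, Jaccard the stricter
  symmetric measure.
- **Degenerate MAD.** A zero MAD (e.g. constant profile) yields zero
  flags plus a warning rather than an error, so one degenerate sample
  cannot abort a collection run.

## Synthetic data

The generator emulates what the detector must tolerate, at desk scale:

- **Baseline landscape**: per chromosome a smooth bowl
  exp(contrast · u²) in the normalized centromere distance u, minimal at
  the configured centromere (fraction 0.5 by default) and maximal at the
  telomeres; contrast 1.5 by default (≈ 4.5× telomere/centromere ratio),
  0 gives a flat genome. Weights are normalized genome-wide.
- **Study conditions**: 7 chromosomes × 100 Mb at 500 kb windows
  (1,400 windows — a deliberately scaled-down stand-in for a multi-Gb
  cereal genome), 30 samples, library sizes log-normal around 500,000
  passing reads (CV 0.3), matching the order of magnitude of typical
  genebank GBS runs.
- **Events**: factor-multiplied regional weights (deletion 0,
  introgression 0.1–0.5, duplication 1.5–2.0); partially covered windows
  scale by the covered fraction. Overlapping events of different kinds
  are rejected. Methylation shifts draw a Beta-distributed per-window
  retention factor (concentration 10, mean 1 − dropout), since
  methylation silences a variable subset of loci per window.
- **Noise**: independent Poisson counts per window (mean
  library size × weight); negative binomial opt-in for overdispersion
  stress tests.

The factor ranges for introgression events are an engineering choice: no
quantitative coverage-reduction factor is established for donor segments,
and the 0.3 default is consistent with roughly two-thirds of donor loci
lacking coverage in locus-level comparisons of parent, donor and
offspring. What passing simulation tests show is that the statistical
machinery recovers megabase-scale multiplicative coverage changes at
realistic depth and trend; they do not show robustness to features the
generator omits — GC/mappability structure, restriction-site clustering,
reference errors, partial-heterozygosity dosage, or batch effects between
sequencing runs.

## Numerical notes

- All profile math is double precision; nothing is rounded before outlier
  scoring.
- The outlier threshold is computed from the normal quantile at run time,
  never hard-coded.
- The rolling mean uses an exact cumulative-sum formulation; edge windows
  average over the available ≤ k values so output length equals input
  length.
- The frequency-summary boundary uses a 1e-12 tolerance so that e.g.
  3/100 lands in the 3% set despite binary floating point.
- Coordinates are 0-based half-open everywhere internally and in
  BED/TSV outputs; human-readable reports render Mb.
- Seeded simulation is reproducible bit-for-bit; pipeline outputs are
  byte-identical across reruns with the same inputs and configuration.

## Verification

The test suite checks exact conservation laws (counts sum to the passing
total; normalized counts to 1e6), worked log-ratio values and
antisymmetry, exhaustive equivalence of the stretch finder with a
brute-force interval enumerator on all 2¹⁴ flag vectors, statistical
calibration of the outlier caller on a 10⁶-window null profile (flagged
fraction 2×(1−Φ(3.719)) within 3 binomial SE), recovery of planted
introgression/duplication events in ≥ 18/20 seeded replicates at
Jaccard ≥ 0.7 with correct direction, ancestor-versus-median reference
concordance, a hand-computed alignment fixture through the real SAM/BAM
path, and locus presence/absence accounting at the combined-coverage
boundary. `scripts/acceptance.py` recomputes the same quantities from
scratch. Problem sizes (1,400-window genome, 20–30 samples, 20
replicates) were chosen so the full verification runs in seconds while
keeping per-window counts at realistic GBS depth.

## Known limitations

- Sensitivity falls for modifications much smaller than a few windows
  (≈ 1–2 Mb at the default grid) and for donors closely related to the
  reference.
- Regions absent from the reference assembly, inversions and balanced
  translocations are invisible to a depth-ratio method.
- The median reference breaks down if a modification is shared by ≳ 50%
  of the collection; the frequency summary is reported for exactly this
  reason.
- Direction classifies coverage change, not mechanism: decreased coverage
  cannot distinguish introgression from deletion from hypermethylation
  without the locus-level analysis or external evidence.
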