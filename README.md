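# gbscov

Detection of large chromosomal modifications — alien introgressions,
deletions, duplications, and methylation shifts — from genotyping-by-
sequencing (GBS) read-depth profiles.

GBS is a reduced-representation protocol: reads start at restriction-
enzyme cut sites, so a sample's per-region read-start density reflects
how well that region is represented in its genome. A segment introgressed
from a related species maps poorly against the crop reference and shows
*decreased* coverage; a duplication shows *increased* coverage; a
methylation change at a methylation-sensitive cut site silences loci
without any sequence change. `gbscov` screens whole collections (plant
genebanks, breeding panels, introgression-line libraries) for such
regions using nothing beyond the GBS data already produced for SNP
genotyping.

## Method

For each sample, high-quality read starts (primary alignments, MAPQ ≥ 20,
≥ 30 non-clipped bases) are counted in non-overlapping windows of
*w* = 500 kb. Counts are normalized to counts per million passing reads
(*c&#7522;*) and compared window-by-window against a reference profile *r&#7522;* —
either a known ancestor's normalized counts or the per-window median over
all samples:

    d_i = log2( (c_i + ε) / (r_i + ε) ),      ε = 1e6 / N

where *N* is the genome-wide window count, so ε is the expected number of
reads per window and dampens noise in sparsely covered windows. The log
ratio is smoothed per chromosome with a centered width-5 rolling mean,
giving the denoised profile *p*. Outlier windows are flagged with a
robust z-score,

    z_i = (p_i − median(p)) / (1.4826 · MAD(p)),    |z_i| > Φ⁻¹(0.9999) ≈ 3.719,

and assembled into stretches: runs of outlier windows that may bridge a
single non-outlier window but never two in a row, with at least 3 outlier
windows (≥ 30 for the conservative "long stretch" screen used on large,
lower-coverage collections). Each stretch is classified as increased or
decreased coverage by the sign of its mean *p*.

A companion locus-level analysis tabulates individual read-start
positions in a region of interest across samples (e.g. recurrent parent,
wild donor, offspring), keeps loci with a combined coverage of ≥ 10
reads, and partitions them by presence/absence (≥ 1 read) — separating
sequence-level from methylation-level differences.

## Worked example

Simulate a 30-sample collection on a 7 × 100 Mb genome in which sample
`S003` carries a 20 Mb introgression (coverage factor 0.3) on chr2H at
40–60 Mb, then run the full screen with the collection median as
reference:

```sh
cat > spec.yaml <<EOF
n_samples: 30
seed: 42
events:
  S003:
  - {chrom: chr2H, start: 40000000, end: 60000000, kind: introgression, factor: 0.3}
EOF
gbscov simulate --spec spec.yaml -o sim/
gbscov run --counts "sim/*.counts.tsv" --min-reads 1000 --long 30 -o out/
```

which prints

```
simulated 30 samples -> sim/
30 samples analyzed, 0 discarded; outputs in out/
```

and `out/long_stretches.tsv` contains exactly the planted carrier:

```
sample_id  total_passing  region          chrom  start     end       n_outliers  type
S003       417893         chr2H:39-61M    chr2H  39000000  61000000  44          Low
```

`S003`'s longest outlier stretch spans 39–61 Mb on chr2H — the planted
40–60 Mb region plus the one-to-two windows of smear the width-5 rolling
mean adds at each edge — with 44 outlier windows and type `Low`
(decreased coverage, as expected for an introgression). `out/` also holds
all stretches as BED6 (`stretches.bed`), per-window outlier frequencies
across the collection (`frequency.tsv`), the discarded-sample log, and a
YAML echo of the full configuration.

The same stages are available as library functions
(`gbscov.build_windows`, `normalize`, `build_reference`, `log_ratio`,
`denoise`, `call_outliers`, `find_stretches`, …) and as the subcommands
`count` (SAM/BAM → window counts), `profile`, `detect`, `summarize`,
`locus-venn`, `simulate`, and `run`.

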