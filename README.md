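# reelscreen

Tools for identifying **functional SNPs (fSNPs)** — noncoding variants that
alter regulatory-protein binding — from a cyclic EMSA-selection screen
(Reel-seq), together with the peptide-spectrum-count filter used to call
the proteins bound by those fSNPs in SNP-specific DNA competition pulldown
mass spectrometry (SDCP-MS).

GWAS associate whole linkage-disequilibrium blocks with disease; they
cannot say which variant in a block is functional. Reel-seq screens a
synthetic library of SNP-centred 31-bp oligos through repeated rounds of
gel-shift selection: oligos bound by nuclear-extract (NE) proteins shift
out of the unshifted gel band, the unshifted band is recovered and
re-amplified, and the cycle repeats. A variant whose two alleles bind a
protein unequally changes its allele ratio geometrically over cycles; a
non-functional variant does not. This package implements the computational
arm of that design for:

- **screen analysts**, turning barcoded FASTQ reads into per-SNP calls
  (candidate / putative / non-fSNP), and
- **method developers**, who need a forward simulator with known ground
  truth to benchmark the statistics.

## The model and statistics

For each sequence *i* in the pool, one selection cycle multiplies its
relative frequency by its survival probability and renormalizes
(PCR regeneration restores total material):

```
f_i  ←  f_i (1 − p_i) / Σ_j f_j (1 − p_j)
```

where `p_i` is the probability a molecule of sequence *i* is shifted out of
the unshifted band. Buffer-only (control) loss is allele-independent, so
within one SNP the control allele ratio is constant, while the NE-treated
(sample) risk/non-risk ratio after cycle *c* is `[(1−p_r)/(1−p_n)]^c`.
The screen runs 5 control + 5 sample replicate reactions through 10 cycles
and sequences cycles 1, 4, 7 and 10 (40 barcoded libraries).

Per SNP, the statistics are exactly the screen's two filters:

1. **t-test** — the raw risk/non-risk count ratio is computed per replicate
   at cycle 10; a two-tailed pooled-variance Student's *t*-test (df = 8)
   compares the five control ratios with the five sample ratios. No
   multiple-testing correction is applied by default.
2. **Slope** — at each sequenced cycle the *normalized ratio* is
   mean(sample ratios) ÷ mean(control ratios); *Slope* is the OLS slope of
   the normalized ratio against cycle number (1, 4, 7, 10).

Classification: **candidate** fSNP if *P* < 0.05 and |*Slope*| > 0.05,
**putative** fSNP if *P* < 0.05 but |*Slope*| ≤ 0.05, else **non-fSNP**.
Upstream, reads are assigned only on a perfect match (exact barcode, exact
primers, exact 31-mer) and a completeness QC removes any SNP lacking reads
for an allele in any of the 40 libraries.

The SDCP-MS filter (`reelscreen.sdcp`) triages a protein × (bait,
replicate) spectrum-count table: proteins with counts in *every* column are
nonspecific binders; evidence at a bait counts only if both duplicate
pulldowns are positive; the survivors are bait-specific binders classed by
how many baits they bound.

## Worked example

Simulate a 200-SNP screen end-to-end — selection, FASTQ emission, exact
re-counting, analysis — with one command:

```bash
reelscreen end2end --seed 7 --n-snps 200 --depth 20000 --out demo
```

```
INFO emitted 800000 reads
INFO round-trip identity verified at error rate 0
INFO classes: {'candidate': 3, 'putative': 13, 'non_fSNP': 166}
```

`demo/summary.json` reports 182 SNPs analyzed (18 removed by the
completeness QC at this modest depth) and the consecutive-replicate R²
values; `demo/results.tsv` holds one row per SNP allele pair:

```
snp_id      risk_allele  nonrisk_allele  p_value  ...  slope      classification
rs1000000   C            T               0.0871        -0.0434    non_fSNP
rs1000002   G            C               0.1872        -0.0144    non_fSNP
```

At the default 10% functional fraction, 20 of the 200 simulated SNPs are
true fSNPs; `demo/truth.tsv` records each SNP's per-allele shift
probabilities and expected slope sign so calls can be scored against
ground truth. The same stages are available separately
(`reelscreen simulate / count / analyze / sdcp`) and as library functions
(`simulate_screen`, `count_reads`, `run_screen`, `call_bindings`).

Filtering the packaged three-bait FGFR2-locus pulldown table:

```bash
reelscreen sdcp --counts src/reelscreen/data/fgfr2_sdcp_counts.tsv --out sdcp_out
# -> retained 19 of 19 proteins (8 bound one bait, 11 bound two)
```

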