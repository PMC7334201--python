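# Methods

## Selection model

The simulator treats one Reel-seq cycle as deterministic proportional
survival followed by renormalization. If `f` is the vector of relative
sequence frequencies in one reaction and `p` the per-sequence shift
probabilities, a cycle maps `f → f·(1−p) / Σ f·(1−p)`. This abstracts the
physics (band migration, partial shifts, gel recovery efficiency) into a
single per-sequence Bernoulli parameter and models PCR regeneration as
renormalization rather than molecule duplication: at fixed sequencing
depth only relative frequencies are observable, so an explicit
molecule-count bookkeeping would add state without adding observable
signal. Optional per-sequence lognormal jitter (`pcr_noise_sd`, default 0)
models uneven amplification.

Assumptions worth stating explicitly:

- **Allele-independent control loss.** Buffer-only shifting is even and
  random across sequences, so `p_control` is a scalar (default 0). The
  control allele ratio is then constant in expectation and the normalized
  ratio has the closed form `[(1−p_r)/(1−p_n)]^c`, which deterministic mode
  reproduces to machine precision and which anchors the oracle tests.
- **Independent replicate lineages.** Each of the 5 control and 5 sample
  reactions evolves from the uniform initial pool through all 10 cycles on
  its own, mirroring the physical design and inducing realistic
  between-replicate variance when `pcr_noise_sd > 0`.
- **Snapshot timing.** Sequenced counts are taken *after* the selection
  step of the named cycle (cycle 1 = after the first shift). The
  alternative (pre-selection) convention differs only by one factor of
  survival; the choice is fixed here so trajectories are well defined.
- **Sequencing** is a multinomial draw of `depth` reads per library
  (deterministic mode instead records `frequency × depth` as real numbers —
  an infinite-depth limit used by the oracle tests).

All randomness flows from one `numpy` generator seeded by
`SimulationConfig.seed`, consumed in a documented order (functional-SNP
assignment, then lineages: control replicates 1..5, sample replicates
1..5, cycles in order, one multinomial per snapshot), so a seed fixes the
whole screen byte-for-byte.

## Simulated study conditions and their defaults

| parameter | default | meaning |
|---|---|---|
| `replicates` | 5 | buffer controls and NE samples per cycle |
| `n_cycles`, `sequenced_cycles` | 10, (1,4,7,10) | selection rounds; sequenced snapshots |
| `depth` | 50 000 reads/library | the screen's per-library depth is unpublished; 50k gives ~10–50 reads per sequence at the simulated library sizes, enough for finite ratios yet cheap to simulate |
| `baseline_p` | 0.1 | nonspecific NE shift probability per cycle |
| `delta_p` | 0.3 | extra shift probability on one allele of a functional SNP; the affected allele (risk or non-risk) is drawn with equal probability, so expected slope signs vary |
| `fraction_functional` | 0.1 | fraction of SNPs that are true fSNPs |
| `pcr_noise_sd` | 0 | lognormal amplification jitter |

The generator emulates: allele-imbalanced selection, independent replicate
histories, fixed-depth multinomial sequencing, barcoded read structure,
and per-base substitution errors on FASTQ emission. It does **not**
emulate: oligo synthesis errors, PCR chimeras/indels, quality-score
structure, gel-recovery variation correlated across sequences, or real
effect-size distributions (effects are a point mass at `delta_p`). Passing
recovery tests therefore demonstrate correctness of the statistics under
the stated generative model, not performance on real screen data.

## Read counting

Reads are assigned only on exact matches: barcode (fixed-length,
prefix-free by construction), both constant primers, and the 31-mer
variable region, with reverse-complement reads accepted after
reorientation (flag-controlled). Discards are tallied per reason
(bad barcode / primer not found / variable-region mismatch) and
`assigned + discarded = total` per library. No error correction or fuzzy
matching is attempted; with per-base error rate *e* and read length *L*,
expected retention is `(1−e)^L`, which the tests verify by simulation.

The completeness QC retains a SNP iff every examined allele has
count ≥ `min_count` (default 1) in every one of the 40 libraries — the
strictest reading of "complete sequencing data", and the one that
guarantees every downstream ratio is finite without pseudocounts. The
threshold is exposed because the original rule is stated only
qualitatively.

## Screen statistics

Ratios are raw risk/non-risk counts (risk in the numerator; the slope's
sign depends on this orientation). Normalization divides the mean of the
five sample ratios by the mean of the five control ratios at each cycle
(not the mean of per-pair ratios — the closest reading of the procedure's
wording). The t-test is the classic pooled-variance Student's test
(Welch available by flag); zero pooled variance returns p = 1 for equal
means and a 0.0 underflow sentinel otherwise. The slope regresses against
actual cycle numbers (1, 4, 7, 10); regressing against rank (1..4) is
available (`slope_x="rank"`) and differs exactly by a factor 3, which
matters when comparing against the ±0.05 cutoff. Classification uses
strict inequalities at both cutoffs. Multi-allelic SNPs are analysed as
risk versus each non-risk allele separately and the SNP inherits its
strongest per-pair call (candidate > putative > non-fSNP).

Benjamini–Hochberg q-values are opt-in and never feed classification,
matching the screen's uncorrected design.

Two numerical properties of the slope statistic are worth knowing. First,
because the noise-free trajectory `r^c` is convex and saturates at zero,
|slope| is **not** monotone in effect size: it peaks near
`delta_p ≈ 0.2` over baseline 0.1 and shrinks again for stronger effects.
Second, very strong effects collide with the completeness QC: at
`delta_p = 0.3`, baseline 0.1 and 50k reads/library over 500 SNPs the
depleted allele's expected cycle-10 sample count is ≈0.9 reads, so most
true fSNPs lack a complete count set and are removed *before*
classification (the acceptance script reports recovery both end-to-end and
among QC-passing SNPs for this reason). In a real screen this trade-off is
resolved by sequencing depth; in the simulator it is a property of the
chosen conditions, not a defect of the statistics — among QC-passing
fSNPs, recovery is complete and every slope sign matches
`sign(p_n − p_r)`.

## SDCP-MS filtering

Filters run in the procedure's fixed order: (1) proteins positive in all
replicate columns of all baits are nonspecific (a protein reproducibly
bound at every bait is thus nonspecific by construction — with parallel
baits as mutual controls, ubiquitous binding is uninformative);
(2) within each bait, only duplicate-positive evidence counts; proteins
with no reproducible bait are irreproducible. Presence is count ≥ 1 by
default (`min_count` configurable; spectrum counts are integers and the
procedure names no threshold). Specificity classes (one/two/multi-bait)
are reported generically rather than hard-coding three baits.

The packaged `fgfr2_sdcp_counts.tsv` holds the spectrum counts of the 19
retained binders for baits rs7895676, rs2981578 and rs2981584. For the
two-bait proteins whose bait attribution is not stated alongside the
counts, pairs are placed in column order (TEAD1 and NFIB are placed on the
baits their binding was validated on); this placement does not affect the
filter tallies. TCERG1 carries duplicate-positive counts at two baits and
is classed `two_baits` by the rule.

## Design choices and limitations

- Flanks are per-SNP opaque 15-nt strings; no reference genome is ever
  consulted, and variable-region uniqueness across the library is enforced
  at load so perfect-match counting is unambiguous.
- Primer sequences are configuration (22 nt defaults giving the 75-bp
  unshifted construct); real primer sequences can be supplied in the
  library TSV header.
- The deterministic mode's real-valued counts are deliberately not
  integers; `emit_fastq` refuses them, since FASTQ emission is only
  meaningful for integer read multisets.
- Problem sizes in the test suite and acceptance script (2000 null SNPs
  for calibration, 500 SNPs for recovery, 10×10 oracle grid, 5×10⁵-read
  round trips) were chosen to exercise every pipeline stage at
  statistically meaningful scale while keeping a full run in seconds to
  minutes on one CPU.
- The pipeline analyses one screen at a time; meta-analysis across runs,
  LD-aware interpretation, and annotation-based prioritization are out of
  scope.
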