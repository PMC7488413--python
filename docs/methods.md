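# Methods

## The measurement model

A polyclonal editing experiment produces, for each targeted variant, a pair
of amplicon-sequencing samples: genomic DNA and cDNA from the same edited
culture. After classification, each sample yields counts
(n_ref, n_alt, n_nhej) of no-edit, HDR and NHEJ reads. The quantity of
interest is the allelic fold change

    aFC = log2( (n_alt/n_ref in cDNA) / (n_alt/n_ref in gDNA) ),

the log-ratio of the edited allele's abundance in mRNA relative to its
abundance in the genome of the same cell population. Because both materials
come from one culture, transfection efficiency, ploidy and HDR rate cancel;
what remains is the variant's cis-regulatory effect (0 = none). NHEJ reads
carry cut-site indels of unknown regulatory consequence and are excluded
from both numerator and denominator.

With the default `pseudocount=0`, a zero allele count raises an error
rather than returning an infinity; QC makes genuine zeros rare (≥ 0.4% HDR
of ≥ 1000 reads implies ≥ 4 alt reads in gDNA), and `pseudocount=0.5` is
the recommended setting whenever cDNA depletion may be near-total.

## Read classification

Reads are located within their amplicon reference by unit-cost infix
alignment (edlib), with exact-substring fast paths for clean unedited and
HDR reads. Whenever the unit-cost alignment reports an indel, the read is
re-aligned with affine gap penalties (match +2, mismatch −3, gap open −5,
extend −1, free end gaps): under unit costs a pair of clustered
substitutions ties with an insertion+deletion pair and can masquerade as an
NHEJ event; affine scoring makes substitutions strictly preferred, so only
genuine indels survive. Decision rules, in order:

1. alignment quality — aligned fraction < 0.5 or mismatch fraction > 0.1
   (mismatches at the variant base do not count: they are signal) →
   `DISCARD`; a failing read is retried as its reverse complement, so
   reverse-strand mates need no special handling;
2. ≥ 1 indel overlapping the edit window (cut site ± 20 bp) → `NHEJ`.
   The indel check deliberately precedes the allele check: a read carrying
   both the introduced allele and a cut-site indel cannot be used for
   allelic quantification;
3. otherwise the base(s) aligned to the variant position decide:
   alt → `HDR`, ref → `NO_EDIT`, anything else (third alleles, Ns, deleted
   variant base) → `DISCARD`. Third-allele reads are not counted as NHEJ —
   substitution errors at the variant base would otherwise inflate it.

Paired mates are classified independently and must agree; discordant pairs
are discarded (`mate conflict`) and a concordant pair counts once. Only
equal-length ref/alt alleles are supported: an HDR allele that is itself an
indel would be indistinguishable from NHEJ under this design.

## QC cascade

Per sample: coverage (classified reads; discards do not count) ≥ 1000, and
NHEJ rate ≤ 80% (higher values indicate alignment artifacts). Per variant,
on gDNA only: HDR rate ≤ 30% (a higher alternative-allele fraction means
the line was already heterozygous at the locus) and ≥ 0.4% (below which
replicate-to-replicate spread of aFC inflates sharply; the simulator
reproduces this relationship). All thresholds keep their stated boundary
sense: "fewer than 1000" and "less than 0.4%" are strict, so exactly 1000
reads or exactly 0.4% HDR pass. The coverage floor is applied to gDNA and
cDNA separately. A (variant, replicate) pair survives when both materials
pass and the gDNA passes the variant-level filters; a variant survives when
at least one replicate does — this maximises usable data, and the replicate
count is reported alongside every estimate.

## Effect estimation and significance

Per surviving replicate pair an aFC is computed; replicates are combined by
unweighted mean (treating replicates as paired observations), with
count-pooling available as an option (`combine="pool"`). The replicate sd
is reported when n ≥ 2.

Significance is assessed against an **empirical null**: the mean and sample
sd (n−1) of combined aFCs over the non-eQTL synonymous control variants.
Synthetic third-allele controls are excluded from the null — a subset shows
reproducible large effects, and their aFC variance is correspondingly much
larger than the non-eQTL controls'. For each variant,

    z = (aFC − null.mean) / null.sd,  p = 2·Φ(−|z|),  p_adj = min(1, m·p),

with the Bonferroni family m = number of non-control variants passing QC
(controls define the null and are not hypotheses; they receive z and p for
inspection but no adjusted p). Significance is p_adj < 0.05, two-sided —
depletion and enhancement are both of interest.

Treating the estimated null as known is the assay's standard procedure but
is slightly anti-conservative for small control sets: with ~30 controls the
statistic is t-like with ~29 df, and the realised family-wise false-positive
rate at Bonferroni-corrected α = 0.05 is ≈ 0.11 rather than 0.05 (measured
by simulation; the acceptance suite records this). `variant_z_test(...,
tail="t")` applies the finite-sample predictive correction (Student t with
n−1 df, scale √(1+1/n)) for users who want calibrated error control; the
default remains the normal tail for fidelity to the assay's published
procedure. A Shapiro-Wilk check on the control aFCs warns (advisory only)
when the normality assumption looks untenable.

Group-level contrasts are computed in-package: a two-sided Wilcoxon
rank-sum test (midranks for ties; exact enumeration of all C(n, n_a) rank
assignments when n ≤ 12, otherwise a tie-corrected,
continuity-corrected normal approximation) and a variance-ratio F test with
two-sided p = 2·min(P(F≤f), P(F≥f)). Both are cross-checked in the test
suite against brute-force enumeration and independent distribution
evaluations.

For comparison with population data, `afc_heterozygote` computes
per-individual aFC from allele-specific expression counts aggregated over
heterozygous gene-body sites, dropping individuals with ≤ 50 reads
(strict), and `AssayResults.direction_match` compares effect signs against
external (e.g. eQTL) estimates.

## NMD annotation and design utilities

The NMD distance d of a stop codon is measured in spliced-transcript bases
from the stop codon's **first base** to the last exon-exon junction
(positive = upstream; any stop in the last exon gives d ≤ 0). The
trigger/escape boundary defaults to d ≥ 55 — the upper end of the ~50-55 bp
range in which premature stops generally elicit NMD — and both the
threshold and the distance convention are explicit parameters, since the
measurement base (first vs last codon position) shifts d by 2 and matters
only within 2 bp of the boundary.

`tile_stop_codons` designs stop-gained SNVs spaced `spacing` (default
20 bp) apart in both directions from the 55-bp cutoff: trigger-side targets
at d = 55 + k·20 (including the boundary slot) and escape-side targets at
d = 55 − (k+1)·20. Each slot takes the nearest codon (within spacing/2,
measured at the codon's first base) that a single substitution turns into
TAA/TAG/TGA, alphabetical tie-break; slots with no such codon are reported
as unfillable rather than failing the design. HDR templates are the 50 bp
of reference context either side of the variant with the alternative allele
substituted (101 bp for a SNV). Synthetic-control alleles are the first
base in A<C<G<T order that differs from both the reference and the
stop-creating allele and creates no stop codon. Candidate-selection filters
(stop-gained ASE filters, eQTL fine-mapping filters, non-eQTL control
filter) implement their thresholds with the stated boundary senses
(inclusive "at least", strict ">").

Coordinates are 1-based inclusive in all I/O (VCF/GFF convention) and
0-based half-open internally.

## The simulator

`simulate_counts` draws one experiment from the generative model the
analysis assumes. The edited culture has class fractions (unedited
1−h−q, HDR h, NHEJ q). gDNA counts are multinomial at the requested depth.
cDNA expression weights are unedited·1, HDR·2^aFC, NHEJ·0.3 (frameshift
products are largely degraded; the value only shapes the discarded-class
fraction), renormalised, then mixed with a carryover fraction c of
entirely-unedited pre-editing mRNA — the reason harvests are taken ~9 days
post-transfection, and the mechanism `simulate_timecourse` tracks (with a
null variant, observed aFC ≈ log2 of the non-carryover fraction when the
edited fraction is small, returning to 0 as c → 0). Sequencing error flips
ref↔alt at the variant base at rate ε/3. All draws are reproducible from
the scenario seed.

`simulate_reads`/`simulate_fastq` are the read-level twin: molecules drawn
from the same class fractions, NHEJ molecules given a deletion or insertion
(equal odds, geometric size, default p = 0.4) at the cut site, per-base
substitution errors at ε, paired 150-bp reads (R2 reverse-complemented),
constant quality. Classifying the output recovers the generating class
fractions; this closes the loop between the simulator and the classifier.

`simulate_study` assembles a study-scale batch under realistic conditions:
30 non-eQTL controls (true aFC 0), 33 eQTL variants (|aFC| 0.3-1.5, mixed
signs), 6 NMD-triggering stop-gained variants (−2.5 to −0.5), and three
ClinVar-style disease stops at −1.39 / −1.02 / −0.17 (a strong trigger, a
moderate trigger, an NMD escaper). HDR rates are drawn log-uniformly over
0.1-30% — the range such assays exhibit — so a realistic fraction of
variants is lost to the 0.4% floor; depth is 85,000 (the design's median
coverage); two replicates per variant. On top of counting noise, each cDNA
replicate receives a technical perturbation of the allelic ratio
(sd 0.28 log2 units per replicate, i.e. ~0.20 on a 2-replicate mean),
chosen so the simulated control-variant aFC variance matches the ~0.038
such experiments show in practice; multinomial noise alone (~0.05 sd at
this depth) would understate the real replicate variability by a factor of
four and make trivially small effects look callable.

What the simulator does **not** model: PCR duplicates and jackpot
amplification, quality-score structure, off-target edits, large on-target
lesions, and locus-specific alignment pathologies. Passing tests therefore
demonstrate the pipeline's correctness under the stated generative model,
not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

The test and acceptance workloads use study-scale counts simulations
(72 variants × 2 materials × 2 replicates at 85k depth), 1000 simulated
null families for calibration, 200 seeds for parameter recovery, and
10,000 reads per class for classifier validation — sizes at which every
quantity of interest is estimated to well within its assertion tolerance.
Exact rank-sum enumeration is used up to n = 12 (C(12,6) = 924
assignments); beyond that the corrected normal approximation agrees with
enumeration to the accuracy the group tests require. Ties in stop-codon
tiling resolve to the smaller transcript coordinate and alphabetical
alternative allele, making designs deterministic.

## Known limitations

* The empirical-null z test inherits the calibration bias described above;
  use `tail="t"` when strict family-wise control matters.
* aFC is undefined for samples with zero allele counts unless a
  pseudocount is supplied; near-total cDNA depletion (strong NMD plus high
  carryover) therefore needs `pseudocount=0.5`.
* Classification assumes pre-trimmed reads and equal-length ref/alt
  alleles; mate merging is not attempted (concordance is required
  instead).
* The 55-bp rule is a heuristic; the package predicts, it does not decide,
  NMD.
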