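# Methods

`plasmafrac` models a specific liquid-biopsy experiment: plasma from cancer
patients is split into unfractionated cell-free DNA (cfDNA) and pooled
size-exclusion-chromatography (SEC) fractions — fractions 1–5 enriched in
small extracellular vesicles (sEV), fractions 7–11, 12–15 and 16–20
progressively EV-poor — and every sample is shallow-whole-genome sequenced
with paired-end reads. The package provides both the analysis of such data
and a synthetic-data generator that emulates its statistical structure, so
that every analysis stage can be exercised and validated without any
external dataset.

## Fragment model and read filters

A fragment is the sequencing insert reconstructed from a proper read pair:
the leftmost mate's 0-based start plus its positive template length (TLEN).
Reads are removed before analysis if they are unmapped, secondary,
supplementary, duplicate-flagged, have MAPQ < 5, or are not in a proper
pair; both mates must pass for the pair to yield a fragment. When a pair
fails several rules at once it is attributed to the first failing rule in
the fixed order *unmapped, secondary, supplementary, duplicate, low MAPQ,
improper pair*; the order affects only the bookkeeping, never the kept set.
Filter statistics satisfy `kept + dropped = total pairs`; records that do
not form pairs (secondary/supplementary alignments, orphan mates) are
counted separately.

## Synthetic cohorts

The generator is the study-conditions oracle: its defaults *are* the
conditions under which the package's claims are tested.

**Reference.** A small synthetic genome: three 8-Mb autosome-like contigs
(240 bins of 100 kb) plus a 16-kb mitochondrial-like contig (`chrM`), i.i.d.
bases, no N runs, no GC structure. Contig content is drawn from per-contig
child streams of the genome seed, so a contig's sequence does not depend on
which other contigs are present.

**Fragment lengths.** Each group has a mixture of components: a short
sub-nucleosomal component (normal, mode 145 bp, sd 15), a mono-nucleosomal
peak at 167 bp, a di-nucleosomal component (normal, 334 bp, sd 25) and — in
the sEV-rich fraction only — a long EV-associated component (normal,
1,500 bp, sd 300). Lengths are discretised and truncated at 20 bp. The
mono-nucleosomal peak uses a discretised *asymmetric Laplace* (left scale
6 bp, right scale 4 bp) rather than a normal: the observable of interest is
the modal histogram bin, and a symmetric normal centred on 167 leaves the
166 and 167 bp bins in a statistical near-tie (their expected counts differ
by a fraction of a standard error even at 2×10^5 fragments), whereas the
peaked family has a genuinely dominant modal bin — as real cfDNA size
profiles do. Component weights per group encode the study's qualitative
structure: EV-poor fractions carry more short-fragment weight (higher
P20_150), only fractions 1–5 carry long-fragment weight. The long-component
weight (default 0.12) is a free parameter, not a literature value.

**Placement and copy number.** Each fragment is mitochondrial with
probability `mtdna_prob` (defaults: 0.69% for plasma cfDNA and the EV-poor
fractions, 3.1% for the sEV-rich fraction — the cohort medians the analysis
is expected to recover). Autosomal fragments are placed with per-bp weight

    w(x) = TF · CN(x) + (1 − TF) · 2,

the two-population mixture of tumor-derived DNA (local copy number `CN(x)`
from the patient's aberration profile, capped at 3) and normal diploid DNA.
This is exactly the weight whose binned, depth-normalised log2 ratio the
estimator inverts. Two exceptions are placed copy-number neutrally:
mitochondrial fragments (no diploid CN semantics) and the *long* component
of the sEV-rich fraction, which emulates the observation that EV-associated
long DNA is poor in tumor signal and gives the in-silico size-selection
experiment its expected direction. Each patient's profile has one gain
(CN 3) and one loss (CN 1) segment, 1.5–2.5 Mb, on distinct contigs,
aligned to 100-kb boundaries; patient tumor fractions default to
Uniform(0.08, 0.40), reflecting a cohort selected for clearly detectable
tumor fraction.

**Fragment-end bias.** A 64-vector of trinucleotide weights biases where
fragments start and end, via rejection sampling on the reference
trinucleotide at *both* 5′ ends of the candidate placement. Acceptance uses
the product of the two normalised end weights; proposals are drawn in
adaptively sized vectorised batches with a budget of 10^5 proposals per
fragment before unconditional acceptance (an extreme bias concentrated on a
single trinucleotide accepts only ~1 proposal in 64², so a small cap would
silently destroy the bias). Defaults give C-starting trinucleotides extra
weight — stronger in unfractionated cfDNA (×1.8) than in SEC fractions
(×1.3) — so end composition separates cfDNA from the fractions but not the
fractions from one another.

**Reproducibility.** Every sample's seed is derived from the master seed by
a fixed rule (`SeedSequence([master, patient_index, group_index])`, folded
below 2^31), so any single sample can be regenerated independently.
Identical seeds give byte-identical FASTA, SAM and manifest files; manifest
paths are stored relative to the manifest so the determinism contract holds
across working directories. Sequencing noise is deliberately out of scope:
no base errors, no quality scores, no GC bias. `inject_noise` adds only the
two artefacts the filters must handle — duplicate-flagged pairs and
low-MAPQ pairs — in exact, deterministic proportions.

## Size analysis

Histograms cover 20–2,000 bp by default; lengths outside the window land in
under/overflow buckets that are excluded from the density but retained so
long DNA stays countable. The modal length is the smallest length achieving
the maximum count (ties break low). P20_150 is the proportion of fragments
between 20 and 150 bp, *both bounds inclusive*, with all passing fragments
in the denominator by default (in-window-only is available). Log2 ratios
between size densities use a symmetric pseudocount (default 10^-6), so
0/0-length bins give exactly 0 and swapping numerator and reference negates
the vector. The median distribution across samples takes the per-length
median of densities *then* renormalises; in-silico size selection filters
on the raw fragment stream, with the "long DNA" preset defined strictly as
length > 1,000 bp.

## Fragment-end composition

For each fragment the two 5′ ends contribute one trinucleotide each, read
from the reference at the mapped coordinates (never from read sequences, so
sequencing errors cannot enter): the plus-strand end is bases
`[start, start+3)`, the minus-strand end is the reverse complement of
`[end−3, end)`. Ends touching non-ACGT bases and fragments shorter than
3 bp are skipped and counted. Trinucleotides are ordered lexicographically
AAA…TTT in all I/O. Diversity is the Gini–Simpson index
`G = 1 − Σ_{i=1..64} P_i²`, which is 0 when one trinucleotide carries all
ends and 63/64 = 0.984375 at the uniform composition; no Lorenz-curve
variant is used.

## Mitochondrial DNA fraction

`mtDNA % = reads on the mitochondrial contig / aligned reads × 100`,
computed at the *read* level (two reads per proper pair) after the standard
filters, matching the convention of samtools-style read counting.
Mitochondrial contigs are matched case-insensitively against a configurable
name list (default `chrM`, `MT`). For proper pairs the fragment-level
proportion is identical; both conventions are available.

## Copy number and tumor fraction

Fragments are counted into fixed-width bins (default 100 kb; trailing
partial bins kept and flagged; mitochondrial contig excluded) by fragment
midpoint. A panel of ≥3 tumor-free samples provides per-bin medians of
depth-normalised counts; bins with zero median are masked and propagate as
missing (never imputed). The sample log2 ratio is
`log2((count / sample mean over unmasked bins) / panel reference)`, which
is invariant to scaling all counts. The default panel has 8 normals at
sample depth; real depth-normalisation panels are typically tens of
samples, and a larger panel only sharpens the reference.

Tumor fraction is estimated with a deliberately small, constrained model: a
three-state Gaussian hidden Markov model over bins with copy numbers
{1, 2, 3}, emission means tied to one parameter,

    mu_CN(TF) = log2((TF · CN + (1 − TF) · 2) / 2),

a single shared emission sd, self-transition probability 0.99 with
the off-diagonal mass split evenly, and a uniform initial distribution. The
log-likelihood is profiled over a TF grid — 0.005 steps on [0, 0.6] plus
the conventional high-purity restarts (non-tumor 0.95/0.99/0.995/0.999,
i.e. TF 0.05/0.01/0.005/0.001) — and the highest-likelihood solution wins,
ties breaking toward the smaller TF (parsimony). The state path is the
Viterbi path at the selected solution; at TF = 0 the states are by
definition all neutral.

The shared sd is held *common across the whole TF grid*: it is initialised
robustly (1.4826 × the median absolute deviation of the log2 ratios, which
is dominated by copy-neutral bins), the grid is profiled once, and the sd
is refined a single time from the forward–backward posteriors of the
provisional optimum before the final profile (floored at 10^-3 to survive
noiseless inputs). Letting every candidate TF refit its own sd is
tempting but wrong at low tumor fraction: a near-zero TF places three
barely separated state means inside the noise, and with a free per-TF sd
this acts as a scale mixture that fits the noise's tails better than a
single Gaussian, overruling genuine segment-level signal. Constraints mirror the analysis being emulated:
ploidy fixed at 2, maximum copy number 3, no subclonal states; there is no
GC or mappability correction because the generator is unbiased by design.
At least 50 usable bins are required, and zero-variance input is rejected
as degenerate.

Known bias: log2 ratios are normalised by the sample mean, so a copy-number
profile with unbalanced gains and losses shifts all bins by the log2 of the
mean factor; with the default profiles (roughly balanced 1.5–2.5 Mb gain
and loss on a 24-Mb genome) this shift is ≤ ~0.01 and the estimator
recovers simulated truth within ±0.05. No equivalence with any external
CNA caller is claimed — the validated property is recovery of simulated
truth.

## Group comparisons

Cohort metrics (tumor fraction, P20_150, Gini, mtDNA %, modal length) are
compared between groups with the two-sided paired Wilcoxon signed-rank
test, pairing by patient and dropping patients missing from either group.
Zero differences are dropped (classic Wilcoxon convention). Up to 25
informative pairs the null is exact: SciPy's exact distribution when the
absolute differences are tie-free, otherwise an exact sign-flip enumeration
via the shift-algorithm convolution over doubled average ranks. Above 25
pairs the normal approximation with continuity correction is used. The
reported statistic is the signed difference of positive and negative rank
sums, so swapping groups negates it. P values are unadjusted by default (a
Benjamini–Hochberg column is optional), and no multiplicity claim is made.

## Problem sizes and validation scope

The validation suite runs the generator at the study's sample scale —
200,000 fragments per sample, 16 patients, 240 bins — for the headline
checks (modal length 167 bp; cohort median mtDNA 0.69% and 3.1%; tumor
fraction within ±0.05 in ≥90% of 20 replicates at TF 0.05–0.4, null
estimates ≤0.03), and smaller cohorts (8–16 patients, 2,000–20,000
fragments) for directional and calibration properties (P20_150 ordering
across fractions, positive long-range size log2 ratio of the sEV-rich
fraction, lower tumor fraction in the >1,000 bp subset, ~5% type-I error of
the paired test under a null cohort, power of the mtDNA contrast).

What passing these tests shows — and does not. The generator reproduces the
*statistical skeleton* of the experiment: mixture modes and weights, group
differences, copy-number depth signal, end-motif bias. It does not model
GC-coverage coupling, mappability, sequencing error, real nucleosome
positioning (10-bp periodicity), or EV biology itself. Results on synthetic
cohorts therefore validate the pipeline's correctness and its ability to
recover known truth, not its field performance on clinical samples.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally, 1-based only inside SAM
  records.
- Duplicate injection flags whole pairs, mirroring coordinate-based
  duplicate marking.
- Empty size distributions (no passing fragments) are constructible but
  refuse to yield a mode or P20_150.
- `log2_ratios` guards zero sample counts in unmasked bins with a 10^-12
  floor inside the log.
- The signed-rank p value is clipped at 1 when the two-sided tails overlap
  at the distribution's centre.
- Bins, grids and manifests are plain pandas/NumPy objects; all tables are
  written as TSV with headers, FASTA/SAM through pyfaidx/pysam.
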