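# Methods

## Scope and data model

The package analyzes single-end histone-modification ChIP-seq in a
two-condition design. The unit of input is the *tag*: one aligned read
reduced to its 5′ genomic position and strand. Coordinates are 0-based
half-open (BED convention) everywhere. Four libraries make a study:
ChIP and matched input for each of a control and an exposed condition.
Upstream alignment is out of scope; tags arrive as 6-column BED.

## Fragment length and coverage

Sonicated chromatin inserts are measured on an analyzer trace; the
fragment length is the mode of the observed insert lengths minus a
120 bp adapter total (TruSeq-style chemistry), with mode ties broken to
the smaller value and non-positive results rejected. One fragment-length
parameter per library serves both coverage extension and the caller's
window default; the insert-size mode and the mean insert length are not
distinguished.

Coverage profiles extend each + tag at p over [p, p+F) and each − tag
with 5′ end at p over [p−F+1, p+1) — leftward extension for the minus
strand is the standard single-end convention. Extensions are clipped at
chromosome bounds rather than rejected, since edge tags are legitimate;
consequently the raw profile mass equals (tags × F) − clipped bases.
RPM scaling multiplies by 1e6/library-size and may be applied exactly
once.

## Enrichment calling

The caller is a windowed Poisson test against the scaled input:

- Windows of width `window` (default: fragment length, 200 bp) advance
  by `window // 2`.
- Expected ChIP count in a window:
  `λ = (max(input_count, input_rate × window) + pseudocount) × N_chip/N_input`
  with pseudocount 1. The floor at the genome-wide input rate exists
  because a shallow input fluctuates to zero tags in many windows; an
  unfloored local estimate understates λ several-fold there and floods
  the calls with high-scoring false windows. Taking the maximum of the
  local and global background estimates is the conventional guard in
  input-normalized callers. The floor can be disabled
  (`CallerParams.background_floor=False`).
- Window p-value: upper-tail Poisson P(X ≥ c; λ). All window p-values
  genome-wide form one Benjamini–Hochberg family; windows pass at
  fold ≥ `min_fold` (default 4, the conventional enrichment-over-input
  default) and adjusted p ≤ `fdr` (default 0.001).
- Passing windows separated by ≤ `merge_gap` (default: window) merge;
  each merged region is re-scored over its full span with the same λ
  construction. That fold-change-vs-input value is *the* region score
  used by every downstream stage. Region p/q are the minima over member
  windows. Output ordering is score-descending with (chrom, start) as
  the deterministic tie-break.

Exact reproduction of any particular caller's stitching internals is a
non-goal; the contract is the FDR target, the fold-change score, and
the calibration properties below (null FDR, sensitivity, monotonicity),
which the test suite measures by simulation. An empirical-FDR
cross-check is provided: ChIP tag positions are re-drawn uniformly
(counts and strands preserved) and the ratio of null to observed calls
estimates the realized FDR.

**Peak splitting.** Merged regions are split at valleys of the smoothed
ChIP profile (centered moving average with edge shrinkage, window
500 bp): an internal local minimum below `valley_fraction` (default
0.5) times the smaller flanking local maximum cuts the region at the
minimum. Sub-region spans partition the parent exactly and are
re-scored over their spans. Region counts are reported both before and
after splitting, since either could be quoted as "the" peak count.

## Gene association

Region-to-gene links come in three kinds: every gene whose body
overlaps the region (distance 0); the nearest non-overlapping TSS
within 100 kb; and any other TSS within 1.5× the nearest distance (and
within the cap). The TSS is strand-resolved: gene start on +, gene
end − 1 on −. A gene already linked by overlap is not re-linked through
the TSS rule — a region inside a gene body links once, as overlap.

Distances are unsigned. The region reference point is the midpoint by
default (configurable to nearest-edge or summit): the measuring point
is genuinely underdetermined by the rule set, and the midpoint is
symmetric and well-defined for every region. Distance ties for the
nearest TSS break by gene id for reproducibility.

The gene list for class enrichment ranks regions by score, keeps those
whose nearest gene (overlap counts as distance 0, measured to the TSS,
not the gene body) lies within 1 kb, truncates to the top 3,000, and
returns the de-duplicated symbols of their remaining ≤ 1 kb links in
rank order.

## Functional-class enrichment

Fold enrichment FE = (k/n)/(K/N) — percentage of query genes in a class
over percentage of background genes in it; FE is scale-invariant, and a
class absent from the background with query hits is an error (0/0
yields FE 0 by convention). Significance is the upper-tail
hypergeometric probability; the default EASE variant substitutes
max(k−1, 0) for k, so single-hit classes are never significant. Plain
Fisher is available (`mode="fisher"`) since published class tables do
not always state which variant produced them. Only classes with ≥ 1
query hit are tested, and only those enter the Benjamini–Hochberg
family — matching the convention of reporting represented terms only.
Background defaults to the full annotation universe and is
configurable. A class passes at FE ≥ 1.5 and adjusted p ≤ 0.05. Symbols
compare case-insensitively (uppercased) throughout, because gene lists
mix RIKEN-identifier and symbol capitalization; term clustering across
related classes is reduced to per-class rows.

## Condition comparison

Score vectors are summarized by exact order statistics (even-length
median = mean of the central pair) and binned into half-open,
zero-anchored histograms. The between-condition shift is tested with a
two-sided Mann–Whitney rank test — chosen as the distribution-free
default because fold-change scores are heavily right-skewed and no
distributional form is assumed — with the direction flag read off the
medians. The gene-set partition (unique-A / shared / unique-B) uppercases
and de-duplicates symbols and returns sorted lists; it is a true
partition for arbitrary inputs.

The packaged KRAB reference table preserves the published three-column
partition verbatim (54/14/36 symbols), including its internal
inconsistencies (ZFP867 appears in both the first-condition and shared
columns, ZFP788 in both unique columns); re-partitioning the column
unions therefore does not reproduce the printed columns, and the loader
says so.

## qPCR calculators

The standard curve is a least-squares line Ct = m·log10(q) + b from
≥ 3 dilution points; a non-negative slope is rejected (perfect doubling
chemistry gives m = −1/log10 2 ≈ −3.32). Percent-of-input inverts the
curve for the IP and input Cts and divides by the input aliquot
fraction; that fraction is a required parameter with no default, since
it is a property of the bench protocol that cannot be guessed. Relative
expression is 2^−ΔΔCt against an endogenous control gene; replicate Cts
are averaged arithmetically (the field convention) and flagged when
their range exceeds 0.5 cycles.

## Synthetic data generator

The generator emulates exactly the statistical structure the caller
assumes:

- background tag 5′ positions as a homogeneous Poisson process
  (default 0.02 tags/bp for ChIP and input alike — the depth of
  20–60 M-read mouse libraries; at substantially lower depth the
  detection limit of a 0.001-FDR caller sits at the fold range of
  interest and score estimates of marginal regions are
  selection-biased);
- planted enrichment regions (default 250, 1 kb wide, centered on
  distinct gene TSSs across 8 × 2 Mb chromosomes ≈ 15 peaks/Mb) whose
  ChIP rate inside the region is background × fold enrichment, with
  folds drawn log-normally (median 9, log-sd 0.5, clipped to
  [1.5, 100]) — a right-skewed score population with a long high tail;
- an exposed condition in which every surviving planted fold is
  multiplied by `depletion_factor` (default 0.6) and a
  `dropout_fraction` (default 0.5) of plants revert to background;
  input libraries are background-only and identical in law across
  conditions;
- strands equiprobable; annotation of `n_genes` genes laid out in
  non-overlapping slots with strand-aware TSSs, one generic functional
  class each, and a `krab_fraction` (default 0.1) additionally labeled
  as KRAB-box transcription factors.

One global seed drives fixed substreams (one per library, plus
annotation, planting, and dropout), so each library is byte-reproducible
independently of simulation order.

What the generator does **not** emulate: mappability and GC bias,
duplicate-read artifacts, chromatin-state–dependent background,
fragment-length variability, broad domains, or any class-biased
placement of enrichment (planted regions are assigned to genes
uniformly, so class fold enrichments are null by construction).
Passing tests therefore demonstrate the pipeline's statistical
correctness under its own model — calibration, sensitivity, and the
depletion contrast — not robustness to real-library artifacts, and the
class-enrichment stage is validated on separately constructed biased
gene lists rather than on the simulated study.

## Numerical choices and problem sizes

- Window p-values use the exact Poisson survival function; class tests
  the exact hypergeometric survival function (no normal approximations).
- BH adjustment delegates to the standard step-up implementation and is
  verified against a brute-force oracle in the tests.
- Degenerate inputs fail loudly: empty input library (fold change
  undefined), empty gene list, duplicate gene ids, p-values outside
  [0, 1], double RPM scaling, non-positive fragment length.
- The simulation-based checks use desk-scale problem sizes chosen to
  keep the full suite around a minute: 1 Mb genomes across 100 seeds
  for null calibration, 20 × 2 Mb planted genomes for sensitivity, and
  20 seeds of the default 16 Mb study for the two-condition contrast.
  The contrast's power analysis (Mann–Whitney p < 0.01 per seed)
  motivated the default plant count of 250, giving ≈ 90–110 called
  regions in the depleted arm.

## Known limitations

- The caller is single-end, fixed-window, and input-normalized only; no
  duplicate filtering, blacklist masking, broad-domain mode, or
  paired-end support.
- Scores of regions near the min-fold threshold are upward-biased by
  selection (only upward count fluctuations get called); at the default
  simulated depth this bias is small but it grows as depth falls.
- Isoform-level TSS handling is out of scope — one TSS per gene.
- Amplification-efficiency correction of qPCR (Pfaffl-style) is not
  implemented; the ΔΔCt method assumes near-perfect doubling.
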