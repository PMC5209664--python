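# Methods notes

This note documents the statistical procedures, the synthetic-data
model, the numerical choices, and the places where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design handled by the package

One variety of an epimutation accumulation line yields 16 WGBS samples:
generations G0, G10, G11 and G10R1 (G10 grown one further generation
well-watered), each with a drought-treated (D) and well-watered (W)
individual pair of sibling replicates.  All analyses run on the
*eligible-site universe*: cytosines covered ≥ 3-fold in every one of
the 16 samples.  Cytosines are strand-specific throughout; symmetric
CpG collapsing is deliberately not performed, matching the
strand-specific coverage accounting of the underlying data model.
Coordinates are 1-based inclusive externally (cytosine reports, GFF3)
and 0-based half-open only at the BED boundary.

## Methylation calling

The conversion error model has two components: the non-conversion rate
ε of unmethylated cytosines, estimated as the pooled methylated-read
fraction of an unmethylated lambda spike-in (calibration refuses to run
on < 100 spike-in reads), and a T-C sequencing error rate ε_TC taken as
configuration (default 0.001) since it cannot be estimated from the
spike-in alone.  They combine independently:
p_err = 1 − (1 − ε)(1 − ε_TC).

Per site, the p-value is the upper binomial tail
P(X ≥ m | n = coverage, p_err).  "False positive rate below 5%" is
operationalised as Benjamini–Hochberg FDR ≤ `fpr` (default 0.05) across
all callable sites of a sample; a raw per-site threshold mode
(`method="raw"`) exists for sensitivity analysis.  Sites under the
coverage floor (default 3) are *uncallable*, distinct from
unmethylated.

Regional methylation level is the **unweighted mean of per-site
levels** over covered sites, not the read-pooled ratio (the pooled mode
is available as an option); the two differ whenever coverage is uneven,
e.g. sites 9/1 and 0/4 give mean(0.9, 0) = 0.45 but pooled 9/14 ≈ 0.64.
Density (fraction of methylated cytosines) defaults to a
callable-cytosines denominator because counting uncallable sites in the
denominator makes density an artifact of depth; the strict all-cytosines
reading is a flag.

## Differential calling

**DMPs.**  For groups (g1, g2) of two replicates each, Fisher's exact
test is applied to the four cross-group replicate pairings; the
combined p is min(p₁..p₄) × 4 capped at 1 (Bonferroni over the four
dependent tests; a pooled-counts single-test mode is the alternative).
Candidates must have combined p < 0.01 and pass the replicate-DMP
filter: both within-group replicate-vs-replicate tests non-significant
at the same threshold.  FDR control is **genome-wide**: BH over the
combined p-values of *all* eligible sites, calls at q ≤ 0.05.  (BH over
only the pre-thresholded candidates was measured on the depth-30 spiked
simulation to be anti-conservative — empirical FDR ≈ 7% — while
genome-wide BH keeps it ≤ 1–3% at recall ≥ 0.99.)  Tests are two-sided
by default (one-sided behind a flag); direction comes from the pooled
level difference, and sites with exactly equal pooled levels are never
reported.  Fisher p-values come from `scipy.stats.fisher_exact` behind
an LRU cache with unique-table deduplication; the test suite verifies
them against an independent hypergeometric-tail enumeration for all
tables with small margins and random tables with margins ≤ 30.

**SMPs** use the binary status matrix: a site qualifies when both g1
replicates share one status, both g2 replicates the other, every
involved status is callable, and the site is not invariant across the
full 16-sample panel.  Orientation matches DMPs: "re-methylated" means
a gain in group 1 relative to group 2.

**DMRs.**  Windows of 200 bp tile each chromosome from position 1 in
50-bp steps; terminal partial windows are tested only if they contain
at least `min_dmps` cytosines.  Each window's pooled replicate counts
are compared by a two-sided Fisher test (pooling is the default for
windows; the per-pair combination used for DMPs is a documented open
alternative), BH-adjusted over all tested windows.  A window qualifies
at adjusted p < 0.01, level fold-change ≥ 1.5 (a zero level is replaced
by the pseudo-level 1/(pooled reads + 1); windows with both levels zero
are never candidates) and ≥ 7 DMPs **matching the window's direction**.
Same-direction qualifying windows with gaps ≤ 100 bp merge;
opposite-direction windows are never merged.  Merging is idempotent.
Reported boundaries default to the span of the outermost contributing
DMPs (`boundaries="trim"`), the convention of window-based DMR callers:
a raw window union systematically overhangs a short differential run by
up to window − span ≈ 200 bp, which would make region edges an artifact
of the grid; `boundaries="windows"` preserves the raw union.

## Dynamics

Locus identity across comparisons is exact (chrom, pos, strand) plus
direction for point events, and reciprocal overlap ≥ 50% plus direction
for DMRs (threshold configurable; greedy clustering against each
cluster's founding interval, deterministic in sorted comparison order).

*Recurrence*: a locus recurs when seen in ≥ 2 of K comparisons.  The
null expectation under uniform random placement with per-comparison
counts k_i over N eligible sites uses independent per-site hit
probabilities p_i = k_i/N:
E[fraction] = P(hit ≥ 2)/P(hit ≥ 1) with
P(hit ≥ 2) = 1 − Π(1−p_i) − Σ_i p_i Π_{j≠i}(1−p_j).
The permutation route draws k_i distinct loci per comparison (uniform
with collision redraw), 100 replicates by default, and averages the
per-replicate recurring fraction; both routes are cross-checked in the
tests and agree within Monte-Carlo error.

*Maintenance*: an induced (D0-vs-W0) event is maintained when its locus
and direction reappear in the advanced drought-vs-control comparisons —
by default in **any** of them (the "all" mode is provided; the phrasing
"maintained in G10, G11 and G10R1" is genuinely ambiguous and both are
reported).  *Transgenerational*: an accumulated (D10-vs-D0) event must
reappear in at least one drought-treated offspring comparison
(D11-vs-D0) **and** the well-watered recovery comparison (D10R1-vs-D0).
Report percentages are round-half-up to 2 decimals — the convention
that reproduces every printed worked-example percentage the acceptance
suite checks — and pooled rows are Σnum/Σden exactly.

A related printed figure could not be reproduced from its own inputs:
an average of "18,426 per generation in expectation" from a total of
312,695 accumulated events is consistent with no integer divisor near
the number of elapsed generations (312,695/11 ≈ 28,427; 312,695/17 ≈
18,394).  The package reports total/#generations and does not attempt
to match that figure.

*Clustering* is average-linkage agglomerative clustering (euclidean or
correlation distance) on the samples × loci level matrix, loci with any
undefined level dropped, samples pre-sorted lexicographically so ties
break deterministically; output is a Newick string whose root-to-leaf
path lengths equal the root merge height, plus the merge table.

## Synthetic methylome model

The generator's defaults are the study conditions: mean strand-specific
depth 13× (Poisson; a negative-binomial switch exists for overdispersed
libraries), non-conversion 0.005, optional over-conversion of true mC
(default 0), context mix CG/CHG/CHH = 0.22/0.17/0.61, TE fraction 0.35
of sites, per-context induction rate 0.004 (matching the observed
epimutation density of a few per thousand eligible sites), accumulated
rate 0.004, effect size 0.6, maintenance probability 0.7, hot-spot
fraction 1% with a 10× rate multiplier, and a 2,000-site lambda
spike-in.  Baseline levels are bimodal-high for CG, intermediate for
CHG, low for CHH, elevated in TEs for all contexts.  The reference
sequence is constructed to be exactly consistent with every site's
declared context and strand (verified by re-deriving contexts from the
emitted FASTA), with gene and TE intervals tiled deterministically and
emitted as GFF3.

Planted events come in two classes, because a single mechanism cannot
surface simultaneously in the treatment-contrast analyses (which need
D ≠ W within advanced generations) and in the generation-contrast
analyses and clustering (which need advanced samples of *both*
treatments to differ from G0):

- **Induced** events shift the D-sample truth of the inducing
  generation by ± effect size (hyper where baseline ≤ 0.5, hypo
  otherwise, so the shift has headroom; out-of-range shifts clamp and
  are flagged in the ledger).  Maintenance is a chain of Bernoulli
  draws along the lineage G0 → G10 → {G11, G10R1}: a lost event cannot
  reappear downstream, so the expected any-mode maintained fraction of
  G0-induced events equals the maintenance probability itself.
- **Accumulated** events fix along the line between G0 and G10 and are
  applied to both treatments of every descendant generation (persisting
  into G11/G10R1 by per-step draws), which is what separates the G0
  quartet from the advanced generations in clustering and feeds the
  accumulated/transgenerational analyses.

DMR-like events are contiguous runs of 8 sites within ≤ 200 bp.  Run
sites' baselines are clipped to leave the full effect achievable (a
regional event in a region of homogeneous methylation), and runs are
planted ≥ 1 kb apart so each is recoverable as its own region — two
runs closer than the merge gap legitimately merge into one called DMR,
which is correct caller behaviour but uninformative as a recovery
target.

Sibling replicates share identical truth and differ only through count
sampling; per-sample RNG streams are spawned deterministically from the
design seed, so identical (design, seed) gives byte-identical output.

What the generator does **not** emulate: read-level artifacts (mapping
bias, clonal duplicates, M-bias), sequence evolution or genetic
variation, spatially correlated methylation beyond the planted runs,
context-dependent coverage, and partial (cell-mixture) methylation
shifts — planted effects are step changes of a fixed size.  Passing the
recovery suites therefore demonstrates correctness of the calling and
dynamics machinery under the declared sampling model, not performance
on real libraries.

## Problem sizes used by the test and acceptance suites

The recovery suites run 2 chromosomes × 5,000 sites at 30× with ~2%
induction (≈ 220 planted point events and 10 planted runs per class), a
size at which per-event detection is near-saturated so that recall,
empirical FDR and maintenance-parameter recovery measure the callers
rather than sampling noise.  Error-control checks use 50,000-site null
and mixed genomes at 13×.  The random-recurrence computation runs at
the full published scale (858,301 placements over 86,672,538 sites, 100
permutation replicates) since it only involves integer sampling.  The
end-to-end pipeline fixture is 1 chromosome × 1,200 sites at 13×.

## Known limitations

- The Bonferroni-combined cross-pair DMP p-value is conservative; with
  more than two replicates per group a rank-based or GLM route would be
  preferable, but groups of two are structural here.
- DMR fold-change uses mean-of-site levels; read-pooled fold change can
  disagree at uneven coverage (both levels are reported).
- Interval matching across comparisons is greedy first-fit; pathological
  chains of half-overlapping DMRs can split clusters differently under
  permuted comparison order (comparisons are processed in sorted label
  order to keep results deterministic).
- The MSRE-qPCR helper implements only the 2^(−ΔΔCt) × 100 computation;
  values above 100% are reported with a warning rather than truncated.
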