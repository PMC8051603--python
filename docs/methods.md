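# Methods

`paleoploid` re-implements, as a tested library, the comparative-genomics
workflow used to characterise sequential paleopolyploidy in Apiaceae
genomes: collinear-block detection, synonymous-divergence (Ks) estimation
and peak decomposition, shared-event rate correction and WGD dating,
fractionation statistics on a reference-anchored homology table, subgenome
expression-bias classification, and an event algebra that replays
chromosome-evolution trajectories.  This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Collinearity

A candidate anchor set is the list of homologous gene pairs between two
chromosomes, expressed in gene-rank coordinates (order along the
chromosome, not base pairs).  Gene families — connected components of the
homolog-pair graph — larger than `max_family_size` (default 30 genes) are
removed first, since promiscuous families blur the dot plot.  A collinear
block is a chain of anchors strictly increasing in rank on both chromosomes
(or increasing on one and decreasing on the other, for an inverted
segment), with at most `max_gap` (default 50) intervening genes between
neighbouring anchors on either chromosome.  Chaining is an O(n²)
longest-chain dynamic programme per orientation; blocks are extracted
greedily by descending anchor count, removing each emitted block's anchors
before re-chaining, and accepted when they carry at least `min_anchors`
(default 5) anchors.  No statistical block-significance model is applied;
the anchor-count floor is the acceptance rule, as in the MCScanX family of
tools.  On small instances the top chain provably equals exhaustive
gap-constrained longest-chain search (checked against an independent
DAG-longest-path oracle in the tests).

## Ks estimation (NG86)

Coding sequences are aligned at the protein level (global alignment,
BLOSUM62) and mapped back to codons; gapped codon columns, codons with
ambiguous bases and terminal stops are removed, and internal stops are an
error.  The Nei–Gojobori (1986) counting estimator is then applied
directly:

* per codon, each of the nine possible single-nucleotide changes is
  classified synonymous or nonsynonymous against the standard genetic code;
  a change creating a stop codon counts as nonsynonymous.  This keeps
  S + N = 3 × codons exactly.
* observed differences are averaged over all minimal mutation pathways
  between the two codons; pathways passing through a stop are excluded and
  the rest reweighted (if every pathway hits a stop, all are used
  unweighted).
* proportions are Jukes–Cantor corrected, d = −(3/4)·ln(1 − (4/3)p);
  estimates with pS ≥ 3/4 are flagged saturated and carry no Ks.

Per-block Ks is the median over anchors with defined estimates (mean of the
central two for even counts).  Transition/transversion-weighted estimators
(YN00-class) are deliberately out of scope; NG86 is the specified estimator
and is implemented rather than wrapped.

## Ks peak decomposition

The Ks distribution is smoothed by a Gaussian kernel density estimate
(Silverman bandwidth by default, 512-point grid on [0, `ks_ceiling`],
ceiling default 2.5 — old-enough peaks in eudicots sit below this).  The
density is renormalised to unit mass on the grid so ceiling truncation does
not distort the curve.  A sum of k Gaussians is fitted to the *curve*
(not the raw values) by bounded nonlinear least squares with seeded
multi-start (5 starts, quantile-based initial means); the smallest k with
coefficient of determination R² ≥ 0.95 is accepted, otherwise the best fit
is returned flagged below-threshold.  Because the fit targets the KDE
curve, the published peak positions depend on the original smoothing
bandwidth, which is not known; bandwidth is therefore configurable and the
Silverman default is a documented divergence risk when comparing with
printed peak values.

## Rate correction and dating

Lineages sharing a polyploidy show that event at different Ks positions
when their synonymous clocks differ.  Correction step 1 computes
multiplicative factors f_s = μ_ref/μ_s from one shared event's peak means,
with the slowest genome as reference; step 2 re-corrects duplicates of a
younger clade-restricted event against a reference inside that clade, and
composes multiplicatively onto step 1.  Inter-species distributions are
scaled by the geometric mean of the two lineages' net factors — the
simplest scheme consistent with aligning distributions by peak position.
Relative rates are reported as (μ_s/μ_ref − 1) × 100 %.  Ages follow the
strict molecular clock T = Ks/(2r); the clock rate r (synonymous
substitutions per site per year) has no default because published plant
rates differ several-fold — the caller must choose one, and the package
does not claim to reproduce any particular published interval.

## Homology table and fractionation

The table lists every reference gene as a row and gives each compared
genome a declared number of homology columns (its expected collinear
multiplicity: 3 for a genome separated from a single-copy reference by a
triplication, 4 after two subsequent doublings, etc.).  Blocks are placed
whole — all anchors of one block occupy one column — by descending anchor
count into the first non-colliding column; overflow beyond the declared
multiplicity is dropped and logged.  Cells without a collinear partner hold
a dot.

From the table come: the loss rate (dot fraction over rows ×
multiplicity), per-gene homology depth (retained copies, 0..multiplicity),
the translocated fraction (best-hit target genes found in no column —
genes that left their ancestral location), and deletion run lengths.  A
run is a maximal stretch of consecutive dots strictly bordered by retained
genes on the same reference chromosome; runs touching a chromosome end are
excluded from the histogram and counted separately, since their length is
censored.  Run lengths are fitted with a geometric model
P(L = k) = (1 − p)·p^(k−1), k ≥ 1, whose extension parameter p (probability
a deletion run extends by one more gene) has the closed-form MLE
p̂ = 1 − 1/mean(L).  Both run-based and gene-based short-run summaries are
emitted because published singleton/pair fractions do not state which
denominator they use.

## Subgenomes and expression bias

For a genome with multiplicity 4, the four column tracks per reference
chromosome are labelled A1–A4 by descending retained-gene count (ties by
column index, deterministic).  Expression bias between duplicate copies is
classified per condition with the usual differential-expression cut-offs:
|log2 fold change| > 1 on mean FPKM (+1 pseudocount) *and* Welch's t-test
on log2(FPKM+1) replicate values surviving Benjamini–Hochberg adjustment at
α = 0.05; everything else is "no difference".  The test behind the
published higher/lower/no-difference split is not named in the source
procedure; Welch-on-logs with BH is the closest defensible analogue short
of a negative-binomial count model, which would require read counts the
pipeline does not consume.

## Karyotype event algebra

A karyotype is a set of chromosomes, each an ordered list of oriented
ancestral segments in gene-rank units.  Events: WGD/WGT replicate every
non-satellite chromosome with a/b(/c) suffixes; X (arm exchange) swaps the
distal parts of two chromosomes at their breakpoints; EJ (end-to-end
joining) concatenates two chromosomes; NCF (nested fusion) inserts one
chromosome into another at a breakpoint; Inv reverses a segment range;
satellite loss removes a satellite.  EJ and NCF each emit one
telomere-derived satellite (gene-free here), whose loss is what reduces
the chromosome number.  Segment content is a conserved multiset through
every event except satellite loss, and the replay engine asserts this.
Scripts in a one-event-per-line DSL are replayed deterministically with
snapshots at named checkpoints.

The packaged Apiales trajectory (`data/apiales_trajectory.txt`) is a
synthetic transcription: the published trajectory is drawn pictorially, so
the script was authored to satisfy every textual constraint (7 → 21 → 8 →
10 → 11 chromosomes at nodes E/H/P/Q/R; the stated fusion partners of P1;
the post-ω origin of Q2; the Q2a/Q2b crossovers) and is validated by
replay, not inferred.

Merge timing uses the parsimony rule on reference-chromosome
co-occurrence: with two successive duplications, an ancestral fusion seen
on 4 distinct descendant chromosomes predates both; on 2, it falls between
them; on 1, after the last.  The thresholds generalise to the running
product of any configured ploidy series.

## Synthetic data

The simulator pushes one ancestral genome (default 7 chromosomes × 60
genes × 150 codons) through a timeline of WGT/WGD, speciation, fusion and
inversion events (ages in Mya, oldest first) and emits exactly the formats
the readers consume, plus a truth record (true pairs with divergence event
and true dS, deletion runs, karyotypes, transposed genes, bias flags).

* **Sequences.**  Codons are drawn from the six amino-acid families whose
  third position is fully 4-fold degenerate and whose other positions admit
  no synonymous change (Ala, Gly, Pro, Thr, Val, Ser-TCN), giving exactly
  one synonymous site per codon.  Divergence accrues as Poisson-distributed
  synonymous substitutions per site — an exact 4-state Jukes–Cantor process
  that the NG86 correction inverts without bias, and by construction Ka = 0.
  This is a calibration substrate, not a general codon model: real
  sequences mix 2-fold and 4-fold sites and nonsynonymous change, so
  passing recovery tests here validates the estimator's counting and
  correction logic, not its behaviour under selection.
* **Rates.**  Each lineage carries a clock multiplier (clock rate default
  5 × 10⁻⁹ substitutions/site/year); a branch evolves at the rate of the
  lineage it belongs to.  The rate-correction scenario splits species
  immediately after the shared event so each species' whole-path rate
  equals its configured multiplier — the condition under which peak ratios
  recover the multipliers.
* **Fractionation.**  After each polyploidy, genes are deleted from the
  duplicated copies in runs of geometric length (extension parameter p,
  default 0.4) placed uniformly where they fit in live genes, until each
  copy reaches its retention target; the copy hit by each run is chosen
  uniformly (a bias knob exists but defaults off, matching the reported
  near-randomness of loss).  Realized run lengths therefore follow the
  drawn geometric law; in the *assembled table*, adjacent runs can merge,
  so end-to-end parameter recovery is demonstrated at light deletion,
  where merging is rare.
* **Transposition** relocates a configured fraction of surviving genes to
  uniform random positions.  **Spurious homolog pairs** (default 5% of true
  pairs) stress the chaining filter.  **Expression** gives duplicates a
  shared log-normal baseline (log2 mean 5, sd 2), optional ±4-fold bias on
  a configured fraction, and replicate noise (log2 sd 0.25) over 3
  conditions × 3 replicates.

Everything is driven by one `numpy` generator seeded from the config, so a
fixed config is byte-reproducible.

## Problem sizes

The validation suite runs genome-scale logic at desk scale: genomes of a
few hundred to a few thousand genes, 30,000-codon sequences for estimator
calibration, 1,000–2,000 draws for distribution fits.  Published
genome-wide figures (loss rates near 48–70%, extension parameters
0.26–0.63, dates in the tens of Mya) derive from full multi-gigabase
assemblies and are structural guides, not quantities this package claims
to reproduce at these sizes.

## Known limitations

* ColinearScan's block-significance statistics are not reproduced; block
  acceptance is the anchor-count floor.
* The rate-correction algebra is a peak-alignment scheme; it assumes peaks
  are well identified and rates constant per lineage.
* The geometric run model ignores run merging and censored end runs beyond
  excluding them; heavy fractionation biases p̂ upward.
* The karyotype DSL operates in gene-rank units on pictorially defined
  breakpoints; it validates trajectories rather than inferring them
  (automated search is out of scope).
* The expression model is FPKM-level, not count-level; dispersion
  behaviour of real RNA-seq is not emulated.
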