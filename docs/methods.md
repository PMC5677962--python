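# Methods

## Model and procedure

`delmap` localizes phenotype risk inside a contiguous deletion locus by
exploiting natural variation in deletion extent. The default domain is
distal chromosome 22q13 (chr22:42,000,000–51,304,566, hg19), where
terminal deletions of 45.8 kb–9.1 Mb cause Phelan-McDermid syndrome. The
underlying assumption is dosage: if haploinsufficiency of genes in a
sub-region drives a clinical feature, carriers whose deletion reaches
that sub-region should show the feature more often than carriers whose
deletion stops short of it.

For each binary feature, over the *mapping set* (array-QC-passing
patients carrying at least one deletion overlapping the locus;
duplication-only carriers excluded):

1. **Global prevalence** p̂ = k/n among informative carriers (feature
   status known). SE of the proportion = √(p̂(1−p̂)/n). Unknown status
   removes a patient from numerator and denominator alike.
2. **Window profile.** Windows [g, g+W) with W = 1.5 Mb anchored every
   s = 50 kb from the locus start; windows running past the locus end are
   truncated, not dropped, so telomeric breakpoints stay mappable. A
   carrier is assigned to a window iff its deletion's proximal breakpoint
   (minimum start among qualifying deletions) lies in the window.
   Windows with fewer than 3 informative carriers are emitted masked.
3. **Candidate region.** The literal min–max rule: from the start of the
   first to the end of the last unmasked window whose prevalence strictly
   exceeds the global prevalence. Gaps between passing windows are
   spanned. An alternative "anchor" mode spans only the passing anchors
   (plus one step), selectable per run.
4. **Enrichment.** 2×2 over informative carriers, rows = breakpoint
   in/out of the region (a "span" membership mode — deletion overlaps the
   region — is available; breakpoint membership is the default and is used
   consistently for windows, regional prevalence and the test). Two-sided
   Fisher exact p sums hypergeometric point probabilities ≤ the observed
   one (relative tolerance 1+1e-7). The headline odds ratio is the
   conditional MLE under Fisher's noncentral hypergeometric likelihood
   (solving E_ψ[X] = a), with the exact conditional CI from inverting the
   α/2 tails; boundary tables yield 0 or +∞ with the appropriate
   one-sided bound, degenerate margins yield p = 1 and an undefined OR.
5. **Sampling p-value.** Feature labels are permuted among informative
   carriers only (the missingness pattern and the number of present
   labels are preserved exactly — a permutation, not a resample). Each of
   the 1000 permutations re-derives the entire profile → region → 2×2
   chain; permutations producing no region contribute OR = 0. p = fraction
   of permutations with OR *strictly greater* than observed. Because +∞
   estimates would break strict comparison, permutation comparisons use
   the cross-product (sample) OR with Haldane–Anscombe +0.5 on all cells
   when any cell is zero, for the observed and permuted statistics alike.
   An optional (k+1)/(N+1) small-sample correction is off by default.
   No correction across features is applied (raw p-values, as is
   conventional for this exploratory design; the run metadata records it).

Candidate genes for a mapped region are all gene models overlapping it by
≥1 bp, flagged "contained" or "boundary", ranked by ascending DECIPHER HI
percentile, then descending pLI, missing annotations last.

### Randomness and reproducibility

One integer seed governs a run. Per-feature permutation streams are
sub-seeded from (seed, CRC32(feature name)), so the result for a feature
is independent of the order features are processed. Carriers are sorted
by patient id before any array is built, so permuting the input row order
changes nothing. Reports contain no timestamps; identical
seed + configuration reproduce every output byte.

## Burden analysis

The burden unit is the CNV: per QC-passing patient, the number of
distinct *additional* CNVs (any CNV overlapping the configured locus is
excluded as the defining rearrangement — non-locus CNVs on the same
chromosome still count) that overlap ≥1 exon of a panel gene. Intronic-
only overlap does not count; deletions and duplications both do. A
per-gene hit count is carried as a secondary column. Group comparison is
a two-sided Mann–Whitney U with normal approximation and tie correction
and *no* continuity correction, chosen so that identical count
distributions give p = 1 exactly; counts are small-n, heavily tied data
for which an exact rank test would also be defensible.

## Clustering

Complete-case patients × variables, binaries encoded 0/1 (sex M=0, F=1),
deletion size in Mb; every column z-standardized so the megabase-scale
size variable cannot dominate Euclidean distances; zero-variance columns
are dropped and recorded. Agglomeration is Ward's variance-minimizing
linkage in the Ward.D2 convention (scipy `linkage(method="ward")`; merge
heights are √(2|A||B|/(|A|+|B|)) · ‖c_A − c_B‖ and non-decreasing), cut
at k clusters (default 4), labels renumbered deterministically by first
appearance. The tree exports to Newick. Since the upstream tooling that
inspired this analysis did not document its preprocessing, no attempt is
made to reproduce any particular published dendrogram; correctness is
judged by recovery of well-separated synthetic prototypes (adjusted Rand
index) and by agreement of the merge sequence with a brute-force
variance-increase oracle.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any particular patient set:

- **Deletions are terminal**: interval [locus_end − size, locus_end).
  Sizes default to an exponential distribution truncated to
  [45.8 kb, 9.1 Mb] with scale = span/3 — right-skewed, because most
  terminal deletions at such loci are small, which makes breakpoint
  density (and hence window denominators) rise toward the telomere. A
  uniform option exists, as does an interstitial-deletion option for
  probing the start-vs-span membership distinction.
- **Planted risk.** A feature's risk segment defaults to
  chr22:45.0–47.0 Mb (2 Mb), placed so that roughly one carrier in five
  has a deletion reaching it — the in-region fraction real deletion-
  mapping cohorts of this size exhibit. A patient is a risk carrier iff
  its deletion *overlaps* the segment (the biological reading), while the
  mapping statistic works on breakpoints; this deliberate mismatch is
  exactly what the recovery tests exercise. Feature status is Bernoulli
  with penetrance p_in = 0.85 (carriers) / p_out = 0.30 (non-carriers),
  then masked to unknown completely at random at rate 0.10. Null
  scenarios set p_in = p_out.
- **Nuisance structure**: 8% duplication carriers (excluded from mapping
  by design), 3% mosaic flags (retained everywhere — flagged, never
  filtered), inheritance drawn 65/10/10/15% de novo/maternal/paternal/
  unknown, and a Poisson(1.0) count of additional CNVs per patient, each
  centred on a random exon of a simulated non-overlapping NP-gene panel
  (120 panel genes plus decoys, scattered over non-locus autosomes).
- Missingness is MCAR per feature; informative missingness is out of
  scope. Identical seeds give byte-identical bundles, including the
  emitted `truth.json` (segments, penetrances, per-patient flags).

What passing simulation tests do **not** show: robustness to genotyping
batch effects, informative missingness, phenotype correlation structure,
interstitial rearrangement mechanics (rings, translocations), or
population stratification — none of which the generator models.

## Numerical choices and problem sizes

- Coordinates are 0-based half-open internally (BED-native); the
  cohort-facing CNV dialect is 1-based inclusive with conversion only at
  the I/O boundary. Gene-symbol joins are exact and case-sensitive.
- Likelihood computations run in log space (`gammaln`, logsumexp);
  root-finding uses Brent's method on log-odds in [−40, 40], which covers
  every table the locus-scale 2×2s can produce.
- Strict ">" is used both for window passing and permutation counting; a
  rendered sampling p of 0 is reported as "<1/N".
- Test-suite problem sizes are chosen to exercise the statistics at full
  fidelity while keeping a laptop run short: Fisher machinery is checked
  against exhaustive enumeration for *all* tables with N ≤ 16 (p-values)
  and N ≤ 10 (cMLE + CI), plus 250 random tables up to N = 40; permutation
  exactness on cohorts of ≤ 8 carriers (complete enumeration); null
  calibration on 200 cohorts; recovery on 100; clustering prototypes on
  10 seeds.

## Known limitations

- **Left-boundary identifiability.** With terminal deletions, overlap
  with a risk segment depends only on the segment's distal edge, so every
  unmasked window proximal of that edge is all-carriers and exceeds the
  global prevalence: the recovered region's proximal boundary tracks the
  proximal edge of breakpoint support, not the planted segment's start.
  Localization claims should therefore be read as "risk attaches by this
  distal position", unless interstitial deletions inform the left edge.
- **Min–max fragility.** A single distal window passing by chance (≈10–20%
  per ~10-informative window at background prevalence 0.30, more for the
  narrow truncated windows near the telomere) stretches the literal
  min–max span toward the chromosome end, diluting the 2×2 and costing
  power. Under the default simulation conditions the planted segment is
  covered by the recovered region in ~100% of cohorts and the empirical
  null is calibrated (type-I ≈ 5%), but median boundary error
  exceeds one window width and only a minority of effect cohorts reach
  sampling p < 0.05. The anchor region mode and the fixed-region
  permutation mode trade faithfulness to the literal rule for robustness.
- The Fisher/permutation construction adjusts for no covariates; features
  are tested marginally, and the seven-feature family is reported without
  multiplicity correction.
- No liftover: real-data coordinates must already be hg19 (or at least
  internally consistent with the gene models supplied).
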