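# delmap

Genotype–phenotype mapping for contiguous deletion loci, built around the
22q13 deletion (Phelan-McDermid syndrome, PMS). Patients with terminal
22q13 deletions lose anywhere from tens of kilobases to >9 Mb of the
chromosome, and their clinical picture — absent speech, autism spectrum
traits, seizures, ophthalmic anomalies, reflux, heart and corpus-callosum
abnormalities — varies just as widely. `delmap` asks *which sub-region of
the deleted locus carries the risk for each feature*, and provides the
supporting analyses a cohort study of this kind needs: multiple-hit CNV
burden over a neuropsychiatric gene panel, exploratory patient clustering,
and a simulator that generates full synthetic cohorts with planted,
recoverable risk segments.

It is intended for statistical geneticists and bioinformaticians working
with cohort tables of binary clinical features plus per-patient CNV calls
(array-resolution, hg19 for real data).

## The method

For a feature *f* and the set of informative deletion carriers (patients
whose status for *f* is known — unknowns never enter any denominator):

- **Global prevalence** p̂ = k/n over all informative carriers, with
  SE = √(p̂(1−p̂)/n).
- **Window profile**: windows of 1.5 Mb slide every 50 kb along the locus
  (chr22:42,000,000–51,304,566 by default). A carrier belongs to a window
  iff the proximal breakpoint of its deletion lies in the window.
  Windows with fewer than 3 informative carriers are masked.
- **Candidate region**: the span from the first to the last window whose
  prevalence strictly exceeds the global prevalence (min–max rule).
- **Enrichment**: a 2×2 table (deletion start in/out of region × feature
  present/absent) tested with Fisher's exact machinery — two-sided exact
  p, conditional-MLE odds ratio with exact conditional 95% CI.
- **Sampling p-value**: feature labels are re-shuffled 1000× among the
  informative carriers, the whole derivation (profile → region → OR) is
  re-run per permutation, and p is the fraction of permutations whose
  Haldane-corrected sample OR strictly exceeds the observed one.
- **Candidate genes**: genes overlapping the region, ranked by DECIPHER
  haploinsufficiency (HI) percentile and pLI.

Burden analysis counts, per patient, the *additional* CNVs (everything
except the defining locus rearrangement) overlapping at least one exon of
a curated neuropsychiatric gene panel, and compares counts between
feature groups with a Mann–Whitney U test. Clustering is Ward.D2 on
z-standardized sex / binary features / deletion size (Mb).

## Worked example

Simulate a 70-patient cohort whose `absence_of_speech` risk is planted on
chr22:45.0–47.0 Mb (penetrance 0.85 inside, 0.30 outside, 10%
missingness), then map, test burden and cluster:

```
$ delmap simulate --seed 2 --out example/
$ delmap map --cohort example/cohort.tsv --cnv example/cnvs.tsv \
             --feature absence_of_speech --seed 2 --out example/out
absence_of_speech: region chr22:42000000-47500000 OR=7.88 [2.09-33.7] fisher_p=0.000725 sampling_p=0.046

$ delmap burden --cohort example/cohort.tsv --cnv example/cnvs.tsv \
                --genes example/genes.bed --np-list example/np_genes.txt \
                --feature absence_of_speech --out example/out
patients with >=1 panel CNV: 45 (1: 24, 2: 15, >=3: 6)
absence_of_speech: U=429 p=0.4316 mean(present)=0.864 mean(absent)=1.16

$ delmap cluster --cohort example/cohort.tsv --cnv example/cnvs.tsv \
                 --vars sex,absence_of_speech,deletion_size --k 4 --out example/out
clustered 64 complete-case patients into 4 clusters
```

Reading the output: the mapped region (42.0–47.5 Mb) covers the planted
45–47 Mb segment; carriers whose deletion starts inside it show the
feature at enriched odds (conditional-MLE OR 7.9, exact CI [2.1–33.7],
Fisher p 7×10⁻⁴), and only 4.6% of label reshuffles produced a larger
enrichment anywhere along the locus. The burden test finds no
association between feature status and the number of panel-hitting
additional CNVs (p 0.43), and the 4-cluster cut separates a large-deletion
cluster (mean 6.6 Mb, 92% without speech) from small-deletion clusters,
e.g.:

```
cluster  n   mean_deletion_mb  pct_absence_of_speech
1        23  1.94693           0
2        13  6.63923           92.3077
```

`delmap run-all --config run.yaml` executes every stage and writes a
report bundle (profiles, associations, candidate genes, burden tables,
cluster tree in Newick, `run_metadata.json`) that re-runs bit-identically
from the recorded seed. Real cohorts use the same two TSV dialects
(documented in the file headers: cohort table with 1/0/NA feature cells;
CNV table 1-based inclusive) plus BED12 gene models, an HI/pLI annotation
TSV and a one-symbol-per-line panel list.

## Layout

- `src/delmap/cohort.py` — domain types, table/BED12 I/O, analysis-set
  selection, cohort summaries, pooled screening prevalence
- `src/delmap/mapping.py` — window profiles, candidate regions, Fisher
  machinery, permutation engine, candidate genes
- `src/delmap/burden.py` — exonic panel-CNV burden and group comparison
- `src/delmap/clustering.py` — Ward clustering, summaries, Newick export
- `src/delmap/simulate.py` — synthetic cohorts with planted truth
- `src/delmap/pipeline.py`, `src/delmap/cli.py` — end-to-end runs and the
  `delmap` command
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions and known limitations
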