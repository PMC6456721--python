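# Methods

## Seed-site model

A canonical miRNA target site is defined by complementarity to the miRNA
seed (positions 2–7, 5′→3′). The four class patterns on the target strand
are derived as:

* `6mer` — reverse complement of miRNA positions 2–7;
* `7mer-m8` — reverse complement of positions 2–8;
* `7mer-1a` — the 6mer followed by a literal `A` (the adenosine opposite
  miRNA position 1 is recognised directly by Argonaute, so it is *not* the
  complement of position 1);
* `8mer` — the 7mer-m8 followed by a literal `A`.

Efficacy ordering is 8mer > 7mer-m8 > 7mer-1a > 6mer. Because all four
patterns share the 6mer core, every 7mer/8mer match nests weaker matches at
the same locus; the scanner therefore keys matches by the core position and
reports each locus once with its strongest requested class. Distinct loci
may overlap by up to 7 nt and are all reported. Coordinates are 1-based
inclusive on the supplied (sense) strand; the BED export alone uses 0-based
half-open convention. Sequences are uppercased and T mapped to U
internally, so DNA- and RNA-alphabet inputs give identical sites; `N`
matches nothing. "Canonical" scans cover {8mer, 7mer-m8, 7mer-1a}; a
permissive mode adds bare 6mers. No thermodynamic or context scoring, no
3′-supplementary pairing and no conservation computation is attempted —
conservation status is consumed as externally supplied gene-set files.

Duplicate FASTA ids have their counts merged under a warning, since the
gene symbol is the unit of all downstream analysis.

## Regulation classes and cutoffs

Log2 fold changes (mimic / control) are classified with strict
inequalities: decreased iff FC < −0.2, increased iff FC > +0.2, otherwise
unaltered; a value exactly at a threshold is unaltered. The ±0.2 default is
deliberately permissive — miRNA-induced repression is mostly mild — and is
configurable. Duplicate probes/protein groups per gene are collapsed before
classification; the default policy keeps the measurement of largest
|log2 FC| (how the original screens collapsed probes is not recoverable, so
the policy is explicit and configurable: extreme / mean / median). Gene
symbols are matched case-insensitively after trimming; no ortholog mapping
is performed.

## Enrichment statistics

For each regulation class the site-containing fraction is
(site genes in class) / (class size), with site genes restricted to the
measured universe (unmeasured site genes are dropped from numerator and
denominator, with a logged count). Independence is tested with Pearson's
chi-squared without Yates continuity correction (class sizes are in the
hundreds in the intended regime; the correction is available as a flag).
The default layout is 2×2 decreased-vs-rest — the minimal test of "site
genes are enriched among decreased genes" — with decreased-vs-increased and
the 2×3 three-class layout available. A three-class request with an empty
class raises rather than silently degenerating.

Cumulative-fraction curves evaluate, at every observed fold change x, the
fraction of the gene set with FC ≤ x (inclusive), against either the
complement of the set within the table (default) or an explicit control
set. The maximum vertical gap between the two step curves is the
two-sample KS D statistic; significance uses scipy's two-sided two-sample
KS test on the underlying fold-change samples. No multiple-testing
correction is applied anywhere: the pipeline tests one pre-specified miRNA.

## Candidate target calling

The transcriptome and proteome tables are inner-joined on gene symbol.
Candidates must satisfy a strict double decrease (both platforms below the
down threshold) and, by default, carry a canonical site (7mer-1a or
stronger; configurable). Ranking is by protein log2 FC ascending (the
proteome being the phenotype-proximal readout), ties broken by mRNA FC and
then gene id, so "rank 1" is the most repressed candidate and the ordering
is fully deterministic.

## miRNA array profiling

Global-mean normalization: within each sample,
ΔCt_i = Ct_i − mean(Ct over that sample's detected miRNAs), and relative
expression is 2^(−ΔCt). The mean is always taken over detected wells only,
which makes the transform exactly invariant to a per-sample additive shift
and fixes the geometric mean of detected relative expressions at 1.
Non-detects are flagged and, by default, imputed at the cycle ceiling
(40 cycles) before ΔCt so that miRNAs detected in only one group still
yield finite group statistics; an exclusion mode is available. Samples with
fewer than two detections are dropped with a warning. Group comparisons use
Welch's unequal-variance t-test on −ΔCt (the log2 scale): testing 2^(−ΔCt)
directly would let the exponential transform distort the test, while
reported group means are on the relative-expression scale for
interpretability. Two constant equal groups give p = 1 by convention. The
detection filter removes a miRNA only when its detection rate is below the
threshold in *both* groups: detected-mostly-in-one-group miRNAs are
findings, not artifacts, and the per-group rates are always reported.

## Synthetic data generator

The generator emulates the statistical structure of the study, not its
biochemistry, and its defaults are the study conditions used throughout the
tests:

* **UTRs** — i.i.d. uniform {A,C,G,U} backgrounds, lengths uniform in
  200–2000 nt, 1000 genes of which 100 are targets, each receiving one
  planted 7mer-m8 at a uniform random position. Chance pattern occurrences
  in the background are *recorded, not scrubbed* (scrubbing would distort
  background composition); the ground-truth site-gene set is the scan of
  the emitted sequences, so recovery metrics stay honest. Background hit
  rates follow the (1/4)^L per-position binomial, which the tests check.
* **Fold changes** — targets draw mRNA log2 FC ~ N(−0.5, 0.15²) and
  non-targets N(0, 0.15²); the protein value is
  p_g + ρ·s·(mRNA residual) + √(1−ρ²)·N(0, 0.15²) with target protein mean
  p_g = −0.35, correlation ρ = 0.8 and attenuation s = |−0.35/−0.5| = 0.7.
  Shifts sit just beyond the ±0.2 cutoff so that boundary bugs are visible;
  protein effects are attenuated relative to mRNA, as is typical of
  miRNA-mediated repression. ρ = 0.8 reflects the strong but imperfect
  mRNA–protein coupling of an overexpression screen; platform dropout
  defaults to 0 (full overlap) and is configurable to emulate partial
  screen overlap.
* **Prediction lists** — four "algorithms" each recover a true target with
  probability 0.6 and add each non-target with probability 0.1, emulating
  the poor inter-algorithm agreement of sequence-based predictors.
* **Ct matrix** — 96 miRNAs (a desk-scale array card) × two groups of 10
  samples; per-miRNA background means uniform in 22–32 cycles with noise
  σ = 0.5; one planted miRNA has its group-B values shifted by +3 cycles
  and its non-detects drawn with group probabilities (0, 0.6) — non-detects
  concentrate in the low-expression group, the detected-mostly-in-one-group
  pattern. Background non-detect probability is 0.02 per well. Because the
  planted miRNA's imputed non-detects inflate its group-B variance, its
  Welch p-value is strong but not extreme, and it ranks first among the 96
  in about 95% of runs — the recovery property the tests assert holds, with
  a thin margin by construction.

All randomness flows from a single `numpy.random.default_rng(seed)` stream
per run; identical configs produce byte-identical output files (fold
changes written at 12 significant digits, Cts at 3 decimals).

What passing these tests shows — and does not. The generator has uniform
base composition, no UTR length/GC realism, Gaussian noise and a single
effect size per platform; real screens have composition-biased chance-site
rates, heavy-tailed fold changes and heterogeneous effect sizes. Recovery
and calibration results on the generator therefore validate the *code
paths and statistics*, not expected performance on any real dataset.

## Numerical and design notes

* Problem sizes in the test and acceptance runs (1000 genes × ≤ 2000 nt,
  20–200 simulation replicates, 96-miRNA arrays) were chosen as the
  smallest sizes at which the asymptotic tests are well behaved and the
  binomial/CLT bounds in the property tests are tight.
* The chi-squared and Welch statistics delegate to scipy
  (`chi2_contingency`, `ttest_ind(equal_var=False)`, `ks_2samp`); the test
  suite independently re-derives them from the closed-form definitions.
* The scanner is validated exactly against a naive window-enumeration
  oracle with the same precedence rule over randomized miRNA/UTR pairs.
* Degenerate inputs fail loudly: empty joins, empty contingency rows,
  undersized KS/Welch groups, sub-8-nt miRNAs and invalid alphabets all
  raise with the offending item named.

## Limitations

* The mature miRNA sequence must be supplied by the user (e.g. from
  miRBase); only miR-324-5p is bundled as a constant.
* Site-containing gene sets can either be computed by the scanner from
  user-provided UTR FASTA or supplied as external files (e.g. TargetScan
  exports); the two need not agree, since external lists embed conservation
  filtering and database-version effects this package does not model.
* No upstream normalization (array quantile normalization, proteome ratio
  normalization) is performed: inputs are assumed to be
  already-normalized fold changes.
* Prediction-set intersections depend strongly on database versions;
  counts computed here from user-supplied lists will not reproduce any
  particular published union/intersection figure.
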