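# Methods

## The panel

The unit of analysis is a fixed 68-gene panel: 26 DNA damage checkpoint
factors (DDCFs) and 42 DNA damage repair factors (DDRFs).  Two DDCF
membership variants circulate for this panel and are both shipped as
bundled TSVs: the tabular list (`table2`, default) includes IL1A and splits
replication protein A into RPA1/RPA2/RPA3; the schematic list (`figure2`)
instead carries the CDC25A/CDC25C effectors and RFC1.  All quantitative
outputs (the risk denominator of 68, the organelle-stress tallies) use the
`table2` variant; the other is selectable and neither is asserted to be
"correct".  Symbol normalization is case-insensitive over official human
symbols, legacy aliases (Ku70 → XRCC6, XPB → ERCC3, NBS1 → NBN, ...) and
mouse homolog symbols; mouse homology is by symbol case convention only
(one-to-one), with no orthology database lookup.  RPA as a bare token maps
to RPA1.

## Expression profiling

EST counts are normalized per tissue cDNA library: `tpm = count /
library_total x 1e6`.  Calls are three-way: absent requires a count of
exactly zero (EST semantics — one observed tag means the gene is
expressed); high requires tpm strictly above the threshold, so ties go to
low.  The original threshold derivation is not published in reusable form,
so the default `auto` rule is a single global threshold, the mean TPM over
all nonzero panel-gene x tissue cells; an explicit TPM value can be passed
instead.  A global rule was chosen over per-gene or per-tissue rules
because the call language ("higher than the threshold") implies one
comparison level; the choice is configuration, not a claim about the
original computation.

H% for a tissue is the percentage of a panel subset called high; the
pyramid tiers partition H% into high variety (> 19), moderate (5–19,
both bounds inclusive) and low (< 5).  Ubiquitously expressed genes are
those not absent in any tissue.

## Modulation calling and the genomic-risk index

A contrast table carries one row per gene: fold change (disease/control,
positive) and optional p-value.  Defaults: up iff fc >= 2.0, down iff
fc <= 0.5 — boundaries inclusive, since reported calls include entries at
exactly 2.00 and 0.50 — with p <= 0.05 additionally required when a
p-value is present.  Rows without p-values are decided on fold change
alone (the bundled organelle-stress tables report none).  No
multiple-testing correction is applied by default; Benjamini–Hochberg per
contrast is available behind a flag.  Genes missing from a contrast count
as unchanged and stay in the denominator, which is fixed at the panel size
(68).

The genomic-risk index is `100 x (n_up + n_down) / 68`.  Risk groups are
assigned on the unrounded percentage: high >= 10, medium 5 to < 10, low
< 5.  The >= 10 boundary is required for internal consistency of the
source disease table (7-gene diseases at 10.29% sit in the high group while
6-gene diseases at 8.82% are medium); the narrative's low-group phrase
"> 5%" is treated as a typo for "< 5%".  Display percentages round half
away from zero (23.53 → 24, 26.47 → 26); cohort fractions and direction
percentages round the same way to one decimal.  One cohort cell in the
source table prints 18.8% for 5/27; the computed 18.5% is reported as
such, not patched.

## Overlap analysis

Venn regions are exclusive: each gene in the union is assigned to the
signature of all sets containing it, so region cardinalities sum to the
union size.  Exact enumeration covers up to six sets; beyond that only
pairwise intersections are reported.  "Mostly disease-specific" — a
qualitative phrase in the source — is operationalized as a strict majority
(> 50%) of the union lying in single-disease regions.  Up- and
down-regulated sets are analyzed separately by default.  The optional
figure for up to three sets is drawn with plain matplotlib circles.

## Methylation correlation

SAH is the hypomethylation index, SAM and SAM/SAH the hypermethylation
indices.  Correlation is Pearson only (the reported r²/p pairs are
consistent with the Pearson t transform); p is two-sided from
`t = r sqrt((n-2)/(1-r²))` with n−2 degrees of freedom, requiring n >= 3
and nonzero variance.  Significant correlations (p < 0.05) are tiered high
when r² > 0.7.  Grouping per gene: hypo if the SAH correlation is
significant; hyper if SAM or SAM/SAH is significant and SAH is not; non
otherwise.  SAH takes precedence when a gene is significant against both
index families; the precedence is explicit and the overlap is logged.
Per-tissue "DNA damage response potential" for regulator correlations
defaults to the tissue's H% over the combined 68-gene panel, with mean TPM
as the configurable alternative.  Scaling either variable affinely leaves
r² unchanged, so plots may use per-gene max-scaled expression without
affecting results.

## Synthetic data

Each generated artifact draws from its own stream seeded by (master seed,
CRC32 of the artifact name), so outputs are bit-reproducible and adding a
generator never perturbs existing fixtures.

* **EST tables** — counts are Poisson with mean `level x library_total /
  1e6`; library totals are uniform over 1e5–1e6 (typical tissue cDNA
  library sizes), planted high/low levels are 200/20 TPM (an order of
  magnitude apart, straddling the auto threshold).  Ten genes — the ones
  reported ubiquitous — are planted high everywhere; every other gene is
  forced absent in one to three tissues so that ubiquity is exactly
  recoverable, and is otherwise high with probability 0.3.  The default
  layout is 21 tissues x 68 genes.
* **Contrasts** — per gene, five log2-normal replicates per arm around a
  gene baseline (N(7,1)), case arm offset by the planted log2 fold change;
  defaults plant 10 up + 10 down genes at ±1.5 over noise sd 0.3.  The
  summary row is fold change of linear-scale arm means plus the two-sample
  t-test p on log2 values — a deliberately simple model of microarray
  ratio data, not a differential-expression method in its own right.
  Under the null the t-test's rejection rate is the calibrated quantity;
  the conjunctive fc-and-p call rule fires less often than the test alone,
  so the called fraction is bounded by, not equal to, alpha.
* **Methylation panels** — six tissues (heart, liver, lung, kidney,
  spleen, brain); SAM uniform 20–80, SAH uniform 5–30 (nmol/g scale).
  Planted hypo genes are linear in standardized SAH, hyper genes in SAM or
  the SAM/SAH ratio, slope magnitude 5 over unit Gaussian noise
  (signal-to-noise 5); defaults plant 5 hypo + 15 hyper among 68.

The `paper-shaped` preset regenerates the full study layout, with each of
the 39 contrasts planting exactly the modulated-gene count of the bundled
disease table (up/down split binomially).  The preset plants |log2fc| = 2
over noise sd 0.25 so that recovery of every planted call is essentially
certain and the regenerated report matches the planted manifest exactly at
any seed — the preset's defining contract.

### What passing tests do and do not show

The generators emulate the statistical *shape* of the inputs, not their
biology: no probe-level artifacts, batch effects, correlated genes, or
real tissue structure.  Recovery tests therefore validate the calling
arithmetic and thresholds, not performance on real microarray or EST data.
One known interaction: the SAM/SAH ratio is intrinsically anti-correlated
with SAH, so a gene planted on the ratio can legitimately reach
significance against SAH and be labeled hypo under the precedence rule;
together with the ~14% family-wise false-positive rate for non genes at
n = 6, this caps methylation class recovery around 80–90% and makes it the
noisiest of the three recovery rates across seeds.

## Numerical choices and problem sizes

Rounding is half-away-from-zero throughout (integers for risk display, one
decimal for fractions).  Degenerate correlation inputs (constant vectors)
raise rather than return NaN.  The test suite and the acceptance script
run on desk-scale sizes: 68 x 21 EST tables, 39 contrasts of 68 genes x 5
replicates, 6-tissue methylation panels, 1000-replicate Monte-Carlo
calibration checks and 1000 random collections for the Venn oracle.

## Known limitations

The original tissue-profile supplementary values derive from the retired
UniGene resource and are not reproducible here; the study's specific
r²/p pairs for methylation figures rest on unprinted SAM/SAH measurements
and are likewise out of reach.  Both are replaced by property and
planted-recovery tests on synthetic data.  Pathway annotation of overlap
regions is out of scope; regions report gene symbols only.
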