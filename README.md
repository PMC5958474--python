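# genorisk

Gene-panel genomic-risk profiling of DNA damage checkpoint and repair
factors.

Chronic inflammation releases reactive oxygen and nitrogen species that
damage DNA; if the damage is not repaired, genomic instability follows.  Two
gene families guard against this: **DNA damage checkpoint factors** (DDCFs —
26 sensors, mediators, transducers and effectors that arrest the cell cycle)
and **DNA damage repair factors** (DDRFs — 42 enzymes spanning direct
reversal, nucleotide and base excision repair, double-strand-break repair
and mismatch repair).  `genorisk` implements a database-mining-style
pipeline over this 68-gene panel for researchers studying how inflammatory
disorders, cancers and organelle stresses modulate the DNA damage response:

* **Tissue expression profiling** — EST (expressed sequence tag) counts are
  normalized to transcripts per million ESTs, `tpm = count / library_total x
  10^6`, and each gene x tissue cell is called highly expressed (`++`, tpm
  strictly above a global threshold), low (`+`) or absent (`-`, zero tags).
  Per tissue, `H% = 100 x #high / panel size` places tissues in a pyramid:
  high variety (H% > 19), moderate (5 <= H% <= 19), low (H% < 5).
* **Modulation calling and the genomic-risk index** — from a
  disease-vs-control fold-change table, a panel gene is up if `fc >= 2`,
  down if `fc <= 0.5` (each additionally requiring `p <= 0.05` when a
  p-value is present).  The genomic-risk index of a disease is
  `(Up + Down) / 68` as a percentage; diseases fall into high (>= 10%),
  medium (5 to < 10%) and low (< 5%) genomic-risk groups.
* **Overlap analysis** — exclusive Venn regions of modulated gene sets
  across diseases, disease-specific genes, and a "mostly disease-specific"
  flag (strict majority of the union in single-disease regions).
* **Methylation correlation** — per-gene cross-tissue expression is
  Pearson-correlated with tissue methylation indices (SAH, the
  hypomethylation index; SAM and SAM/SAH, hypermethylation indices), with
  p from `t = r sqrt((n-2)/(1-r^2))`; genes are grouped hypo- / hyper- /
  non-methylation-regulated, with an r² > 0.7 high-correlation tier.
* **Synthetic data** — seeded generators produce EST tables, case/control
  contrasts and methylation panels with planted ground truth, so the whole
  pipeline is testable offline, including a `paper-shaped` preset that
  mirrors the full study layout (21 tissues, 27 inflammation + 12 cancer
  contrasts, six-tissue methylation panel).

## Worked example

```sh
$ genorisk simulate --preset paper-shaped --seed 1 --out demo
wrote paper-shaped bundle (39 contrasts) to demo
$ genorisk risk --comparisons demo/comparisons --out demo/report.tsv
wrote risk report for 39 diseases to demo/report.tsv
$ head -6 demo/report.tsv
disease	class	n_up	n_down	n_total	percent	group
Coronary artery disease	inflammation	8	10	18	26	high
Acute coronary syndromes	inflammation	4	3	7	10	high
Hutchinson-Gilford progeria syndrome	inflammation	7	6	13	19	high
High glucose (25 mM)	inflammation	5	4	9	13	high
Type 2 diabetes	inflammation	1	6	7	10	high
```

Each report row is one disease contrast: the number of panel genes called
up and down, their sum, the genomic-risk index as an integer percentage
(18 of 68 genes -> 26%), and the risk group it implies.  The planted truth
for every contrast is in `demo/truth.json`; at any seed the recalled
counts, percentages and groups match it exactly.  The same bundle feeds the
expression profiler:

```sh
$ genorisk profile --counts demo/est_counts.tsv --totals demo/library_totals.tsv --out demo/prof
threshold 94.320 TPM; calls written to demo/prof.calls.tsv
```

which writes the `++/+/-` call matrix plus a JSON sidecar with the derived
threshold and each tissue's H% and pyramid tier.

From Python, the same objects compose directly:

```python
from genorisk import load_panel, call_modulation, assess_risk
from genorisk.datasets import load_organelle_stress_comparisons

panel = load_panel()                       # 26 DDCFs + 42 DDRFs
clpp = next(t for t in load_organelle_stress_comparisons()
            if t.geo_id == "GSE40207")     # mitochondrial stress contrast
calls = call_modulation(clpp, panel, species="mouse")
print(assess_risk(calls, panel).n_total)   # -> 16 modulated genes
```

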