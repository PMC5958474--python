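"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the statistical shape of the study's inputs:

* :func:`gen_est_table` — Poisson-sampled EST counts per gene x tissue with
  planted high / low / absent classes (tissue cDNA library totals drawn per
  tissue), so expression calling can be scored against known labels;
* :func:`gen_comparison` — case/control replicate arrays, log-normal with a
  planted log2 fold change per gene, summarized GEO2R-style as fold change +
  two-sample t-test p-value on log intensities;
* :func:`gen_methylation_panel` — per-tissue SAM/SAH concentrations and
  gene expression vectors that are linear in one methylation index (plus
  Gaussian noise) for planted hypo-/hyper-methylation-regulated genes.

Each artifact draws from its own pseudorandom stream derived from
(master seed, artifact name), so adding a generator never perturbs
previously generated fixtures.  The ``paper-shaped`` preset regenerates the
whole study layout: a 21-tissue x 68-gene EST table, 27 inflammation + 12
cancer contrasts whose planted modulated-gene counts equal the study's
disease table, and a six-tissue methylation panel with 5 hypo / 15 hyper /
48 non genes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .expression import ABSENT, HIGH, LOW, CallMatrix, ESTExpressionTable
from .methylation import (
    DEFAULT_TISSUES,
    HYPER,
    HYPO,
    NON,
    RATIO_INDEX,
    SAH_INDEX,
    SAM_INDEX,
    TissueMethylationTable,
    write_methylation_tsv,
)
from .modulation import (
    DOWN,
    UNCHANGED,
    UP,
    ComparisonTable,
    classify_risk,
    risk_percent,
    write_comparison_tsv,
)
from .panel import GenePanel, load_panel

__all__ = [
    "SimulationConfig",
    "gen_est_table",
    "gen_comparison",
    "gen_methylation_panel",
    "write_paper_shaped_bundle",
]

#: Panel genes the study found expressed in every human tissue; the EST
#: generator plants these as expressed everywhere by default.
UBIQUITOUS_GENES = (
    "PARP1",
    "XRCC6",
    "XRCC5",
    "PRKDC",
    "APEX1",
    "XPC",
    "ERCC3",
    "ERCC5",
    "HMGB1",
    "MLH1",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by the generators; the defaults are the study conditions.

    21 tissues matches the human tissue survey; library totals span the
    typical size range of tissue cDNA libraries; planted high/low expression
    sits at 200 / 20 transcripts per million ESTs (an order of magnitude
    apart, straddling the auto threshold); contrasts use 5 replicates per
    arm with log2 fold changes of +-1.5 over log-scale noise of 0.3 sd;
    methylation relations are planted at signal-to-noise 5.
    """

    seed: int = 0
    n_tissues: int = 21
    library_total_range: tuple[int, int] = (100_000, 1_000_000)
    tpm_high: float = 200.0
    tpm_low: float = 20.0
    planted_absent: Mapping[str, Sequence[str]] | None = None
    n_replicates: int = 5
    planted_log2fc: Mapping[str, float] | None = None
    log2fc_magnitude: float = 1.5
    noise_sd: float = 0.3
    methylation_slopes: Mapping[str, tuple[str, float]] | None = None
    methylation_snr: float = 5.0
    p_high: float = 0.3
    baseline_log2: float = 7.0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        lo, hi = self.library_total_range
        if not 0 < lo <= hi:
            raise ValueError("library_total_range must be positive and ordered")

    def rng(self, artifact: str) -> np.random.Generator:
        """Deterministic stream for one artifact: (master seed, name hash)."""
        return np.random.default_rng(
            [int(self.seed), zlib.crc32(artifact.encode()) & 0x7FFFFFFF]
        )


# -- EST expression --------------------------------------------------------

def gen_est_table(
    config: SimulationConfig,
    panel: GenePanel,
    ubiquitous: Sequence[str] | None = None,
) -> tuple[ESTExpressionTable, CallMatrix]:
    """Poisson EST counts with planted high/low/absent classes.

    Planted-ubiquitous genes (default: the ten the study reports) are high
    in every tissue; every other gene is forced absent in 1–3 random
    tissues (so ubiquity is exactly recoverable) and otherwise high with
    probability ``p_high``, else low.  counts[g, t] ~ Poisson(level x
    library_total[t] / 1e6).  Returns the table and the planted call matrix.
    """
    rng = config.rng("est")
    genes = list(panel.symbols)
    tissues = [f"tissue_{i + 1:02d}" for i in range(config.n_tissues)]
    ubiq = set(UBIQUITOUS_GENES if ubiquitous is None else ubiquitous) & set(genes)

    lo, hi = config.library_total_range
    totals = pd.Series(rng.integers(lo, hi + 1, size=len(tissues)), index=tissues)

    level = pd.DataFrame(0.0, index=genes, columns=tissues)
    truth = pd.DataFrame(ABSENT, index=genes, columns=tissues)
    for gene in genes:
        if gene in ubiq:
            absent_tissues: set[str] = set()
        else:
            k = int(rng.integers(1, 4))
            absent_tissues = set(rng.choice(tissues, size=k, replace=False))
        for tissue in tissues:
            if tissue in absent_tissues:
                continue
            is_high = rng.random() < config.p_high or gene in ubiq
            level.loc[gene, tissue] = config.tpm_high if is_high else config.tpm_low
    if config.planted_absent:
        for gene, forced in config.planted_absent.items():
            for tissue in forced:
                level.loc[gene, tissue] = 0.0
    truth[:] = np.where(
        level.values == 0,
        ABSENT,
        np.where(level.values >= config.tpm_high, HIGH, LOW),
    )

    lam = level.values * totals.values[None, :] / 1e6
    counts = pd.DataFrame(
        rng.poisson(lam), index=genes, columns=tissues, dtype=np.int64
    )
    table = ESTExpressionTable(counts=counts, library_totals=totals.astype(float))
    mid = (config.tpm_high + config.tpm_low) / 2
    truth_calls = CallMatrix(labels=truth, threshold_used=mid if mid > 0 else 1.0)
    return table, truth_calls


# -- case/control contrasts ------------------------------------------------

def gen_comparison(
    config: SimulationConfig,
    panel: GenePanel,
    disease_meta: Mapping[str, str] | None = None,
    n_up: int = 10,
    n_down: int = 10,
) -> tuple[ComparisonTable, pd.Series]:
    """Log-normal case/control contrast with planted log2 fold changes.

    Per gene, ``n_replicates`` log2 intensities are drawn per arm around a
    gene baseline, the case arm offset by the planted log2 fold change.
    The GEO2R-style summary row carries fold_change = mean(case) /
    mean(control) on the linear scale and the two-sample t-test p-value on
    log2 values.  Returns the table and the planted truth labels
    (up / down / unchanged; planted effects have |log2fc| >= 1).
    """
    meta = dict(disease_meta or {})
    disease = meta.get("disease", "synthetic disease")
    rng = config.rng(f"comparison:{disease}")
    genes = list(panel.symbols)

    if config.planted_log2fc is not None:
        lfc = pd.Series(0.0, index=genes)
        for gene, effect in config.planted_log2fc.items():
            lfc[gene] = effect
    else:
        chosen = rng.choice(genes, size=n_up + n_down, replace=False)
        lfc = pd.Series(0.0, index=genes)
        lfc[chosen[:n_up]] = config.log2fc_magnitude
        lfc[chosen[n_up:]] = -config.log2fc_magnitude

    base = config.baseline_log2 + rng.normal(0.0, 1.0, size=len(genes))
    n = config.n_replicates
    control_log = base[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    case_log = (
        base[:, None]
        + lfc.values[:, None]
        + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    )
    fc = np.power(2.0, case_log).mean(axis=1) / np.power(2.0, control_log).mean(axis=1)
    p = stats.ttest_ind(case_log, control_log, axis=1).pvalue

    rows = pd.DataFrame({"gene": genes, "fold_change": fc, "p_value": p})
    table = ComparisonTable(
        disease=disease,
        disease_class=meta.get("disease_class", "organelle_stress"),
        tissue=meta.get("tissue", "synthetic tissue"),
        geo_id=meta.get("geo_id", "SYN000"),
        rows=rows,
    )
    truth = pd.Series(
        np.where(lfc.values >= 1.0, UP, np.where(lfc.values <= -1.0, DOWN, UNCHANGED)),
        index=genes,
    )
    return table, truth


# -- methylation panel -----------------------------------------------------

def gen_methylation_panel(
    config: SimulationConfig,
    panel: GenePanel,
    n_hypo: int = 5,
    n_hyper: int = 15,
    tissues: Sequence[str] = DEFAULT_TISSUES,
) -> tuple[TissueMethylationTable, pd.DataFrame, pd.Series]:
    """Tissue SAM/SAH panel plus per-gene expression with planted classes.

    SAM and SAH are drawn uniformly in physiologic-looking ranges (nmol/g
    scale).  Planted hypo genes are linear in SAH, planted hyper genes in
    SAM or the SAM/SAH ratio, all with slope magnitude set by the
    signal-to-noise target over unit Gaussian noise; remaining genes are
    independent noise.  Returns (methylation table, genes x tissues
    expression, truth labels).
    """
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues")
    rng = config.rng("methylation")
    tissues = list(tissues)
    genes = list(panel.symbols)
    if n_hypo + n_hyper > len(genes):
        raise ValueError("more planted genes than panel members")

    sam = pd.Series(rng.uniform(20.0, 80.0, size=len(tissues)), index=tissues)
    sah = pd.Series(rng.uniform(5.0, 30.0, size=len(tissues)), index=tissues)
    meth = TissueMethylationTable(sam=sam, sah=sah)

    order = list(rng.permutation(genes))
    assignment: dict[str, tuple[str, float] | None] = {g: None for g in genes}
    for gene in order[:n_hypo]:
        assignment[gene] = (SAH_INDEX, config.methylation_snr)
    for gene in order[n_hypo : n_hypo + n_hyper]:
        idx = SAM_INDEX if rng.random() < 0.5 else RATIO_INDEX
        assignment[gene] = (idx, config.methylation_snr)
    if config.methylation_slopes:
        for gene, (idx, slope) in config.methylation_slopes.items():
            assignment[gene] = (idx, slope)

    expr = pd.DataFrame(index=genes, columns=tissues, dtype=float)
    truth = pd.Series(NON, index=genes, dtype=object)
    for gene in genes:
        intercept = rng.uniform(5.0, 10.0)
        noise = rng.normal(0.0, 1.0, size=len(tissues))
        planted = assignment[gene]
        if planted is None:
            expr.loc[gene] = intercept + noise
            continue
        idx_name, slope = planted
        z = meth.index_values(idx_name).values
        z = (z - z.mean()) / z.std(ddof=0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        expr.loc[gene] = intercept + sign * slope * z + noise
        truth[gene] = HYPO if idx_name == SAH_INDEX else HYPER
    return meth, expr, truth


# -- the paper-shaped preset -----------------------------------------------

def write_paper_shaped_bundle(
    seed: int, out_dir: str | Path, panel: GenePanel | None = None
) -> dict:
    """Write the full study-shaped fixture set and its truth manifest.

    Emits the EST table (counts + library totals), the 39 disease contrasts
    (planted modulated-gene counts equal the study's disease table; planted
    |log2fc| = 2 over noise sd 0.25 so recovery is essentially certain),
    the methylation panel, and ``truth.json`` recording all planted labels
    and the risk percentages/groups implied by the planted counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "comparisons").mkdir(exist_ok=True)
    if panel is None:
        panel = load_panel()

    config = SimulationConfig(seed=seed)
    manifest: dict = {"seed": int(seed), "diseases": {}}

    est, est_truth = gen_est_table(config, panel)
    counts = est.counts.copy()
    counts.index.name = "gene"
    counts.to_csv(out / "est_counts.tsv", sep="\t")
    totals = est.library_totals.rename("total_ests").astype(int)
    totals.index.name = "tissue"
    totals.to_csv(out / "library_totals.tsv", sep="\t")
    manifest["est_truth_labels"] = {
        t: est_truth.labels[t].to_dict() for t in est_truth.tissues
    }

    contrast_config = SimulationConfig(
        seed=seed, log2fc_magnitude=2.0, noise_sd=0.25
    )
    disease_counts = datasets.load_disease_gene_counts()
    rng = config.rng("paper-shaped-plan")
    for i, row in enumerate(disease_counts.itertuples(index=False), start=1):
        n_total = int(row.n_modulated)
        n_up = int(rng.binomial(n_total, 0.5)) if n_total else 0
        n_down = n_total - n_up
        meta = {
            "disease": row.disease,
            "disease_class": row.cohort,
            "tissue": "synthetic tissue",
            "geo_id": f"SYN{i:03d}",
        }
        table, truth = gen_comparison(
            contrast_config, panel, meta, n_up=n_up, n_down=n_down
        )
        fname = f"{i:02d}_{_slug(row.disease)}.tsv"
        write_comparison_tsv(table, out / "comparisons" / fname)
        raw, display = risk_percent(n_total, panel.size)
        manifest["diseases"][row.disease] = {
            "class": row.cohort,
            "file": fname,
            "n_up": n_up,
            "n_down": n_down,
            "n_total": n_total,
            "percent": display,
            "group": classify_risk(raw),
            "planted_up": sorted(truth.index[truth == UP]),
            "planted_down": sorted(truth.index[truth == DOWN]),
        }

    meth, expr, meth_truth = gen_methylation_panel(config, panel)
    write_methylation_tsv(meth, out / "methylation.tsv")
    expr.index.name = "gene"
    expr.to_csv(out / "methylation_expression.tsv", sep="\t")
    manifest["methylation_truth"] = meth_truth.to_dict()

    (out / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _slug(name: str) -> str:
    keep = [c.lower() if c.isalnum() else "_" for c in name]
    slug = "".join(keep).strip("_")
    while "__" in slug:
        slug = slug.replace("__", "_")
    return slug[:48]
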