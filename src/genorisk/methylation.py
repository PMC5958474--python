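"""Correlation of panel-gene expression with tissue methylation indices.

S-adenosylmethionine (SAM) is the universal methyl donor and serves as a
hypermethylation index; S-adenosylhomocysteine (SAH) inhibits
methyltransferases and serves as a hypomethylation index; the SAM/SAH ratio
is a second hypermethylation index.  A gene's cross-tissue expression vector
is correlated (Pearson) against each index; p-values come from the exact
t transform t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.

Genes are grouped by which index they track significantly:

* ``hypo``  — significant vs SAH (SAH takes precedence over SAM indices),
* ``hyper`` — significant vs SAM or SAM/SAH but not SAH,
* ``non``   — significant vs none.

Significant correlations are additionally tiered: high when r^2 > 0.7, low
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueMethylationTable",
    "CorrelationResult",
    "DegenerateInputError",
    "correlate",
    "classify_methylation_regulation",
    "methylation_group_summary",
    "regulator_correlation",
    "read_methylation_tsv",
]

logger = logging.getLogger(__name__)

HYPO, HYPER, NON = "hypo", "hyper", "non"
TIER_HIGH, TIER_LOW = "high", "low"
R2_TIER_CUT = 0.7

SAH_INDEX, SAM_INDEX, RATIO_INDEX = "SAH", "SAM", "SAM/SAH"
DEFAULT_TISSUES = ("heart", "liver", "lung", "kidney", "spleen", "brain")


class DegenerateInputError(ValueError):
    """Raised when a correlation input has zero variance."""


@dataclass(frozen=True)
class TissueMethylationTable:
    """Per-tissue SAM and SAH concentrations plus their ratio."""

    sam: pd.Series
    sah: pd.Series

    def __post_init__(self) -> None:
        if list(self.sam.index) != list(self.sah.index):
            raise ValueError("SAM and SAH must cover the same tissues")
        if len(self.sam) < 3:
            raise ValueError("need at least 3 tissues for correlation")
        if (self.sam <= 0).any() or (self.sah <= 0).any():
            raise ValueError("SAM and SAH concentrations must be positive")

    @property
    def tissues(self) -> list[str]:
        return list(self.sam.index)

    @property
    def ratio(self) -> pd.Series:
        return self.sam / self.sah

    def index_values(self, index: str) -> pd.Series:
        return {
            SAH_INDEX: self.sah,
            SAM_INDEX: self.sam,
            RATIO_INDEX: self.ratio,
        }[index]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one gene (or potential) against one index."""

    gene: str
    index: str
    n: int
    r: float
    r_squared: float
    p: float
    significant: bool
    tier: str | None  # high / low when significant, else None


def correlate(
    expression: Sequence[float] | pd.Series,
    index: Sequence[float] | pd.Series,
    alpha: float = 0.05,
    gene: str = "",
    index_name: str = "",
) -> CorrelationResult:
    """Pearson r / r^2 / two-sided p for paired per-tissue values.

    Requires n >= 3 and nonzero variance on both sides; raises
    :class:`DegenerateInputError` on a constant vector.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(index, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and index must pair the same tissues")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 tissues, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    p = float(p)
    significant = p < alpha
    r2 = r * r
    tier = None
    if significant:
        tier = TIER_HIGH if r2 > R2_TIER_CUT else TIER_LOW
    return CorrelationResult(
        gene=gene,
        index=index_name,
        n=n,
        r=r,
        r_squared=r2,
        p=p,
        significant=significant,
        tier=tier,
    )


def correlate_gene(
    gene: str,
    expression: pd.Series,
    methylation: TissueMethylationTable,
    alpha: float = 0.05,
) -> dict[str, CorrelationResult]:
    """Correlate one gene's cross-tissue expression against all three indices."""
    expr = expression.reindex(methylation.tissues)
    if expr.isna().any():
        raise ValueError(f"{gene}: expression missing for some tissues")
    return {
        idx: correlate(
            expr.values,
            methylation.index_values(idx).values,
            alpha=alpha,
            gene=gene,
            index_name=idx,
        )
        for idx in (SAH_INDEX, SAM_INDEX, RATIO_INDEX)
    }


def classify_methylation_regulation(
    results: Mapping[str, CorrelationResult], alpha: float = 0.05
) -> str:
    """hypo / hyper / non from the gene's three index correlations.

    SAH precedence: a gene significant vs both SAH and a SAM index is
    labeled hypo (and the overlap is logged).
    """
    missing = {SAH_INDEX, SAM_INDEX, RATIO_INDEX} - set(results)
    if missing:
        raise ValueError(f"missing index results: {sorted(missing)}")
    sah_sig = results[SAH_INDEX].p < alpha
    sam_sig = results[SAM_INDEX].p < alpha or results[RATIO_INDEX].p < alpha
    if sah_sig:
        if sam_sig:
            logger.info(
                "gene %r significant vs both SAH and SAM indices; labeling hypo",
                results[SAH_INDEX].gene,
            )
        return HYPO
    if sam_sig:
        return HYPER
    return NON


def methylation_group_summary(
    labels: Mapping[str, str] | pd.Series, panel_size: int | None = None
) -> pd.DataFrame:
    """Group counts and panel fractions (one-decimal percent) for
    hypo/hyper/non labels."""
    from .modulation import round_half_away

    series = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    n = panel_size if panel_size is not None else len(series)
    if n <= 0:
        raise ValueError("panel size must be positive")
    records = []
    for group in (HYPO, HYPER, NON):
        count = int((series == group).sum())
        records.append(
            {
                "group": group,
                "count": count,
                "panel_size": n,
                "percent": round_half_away(100.0 * count / n, 1),
            }
        )
    return pd.DataFrame.from_records(records).set_index("group")


def tissue_potential(
    calls, panel, method: str = "h_fraction", table=None
) -> pd.Series:
    """Per-tissue DNA-damage-response potential.

    Default: the tissue's H% over the combined panel (the fraction of the 68
    genes called highly expressed); ``method="mean_tpm"`` uses the mean TPM
    of panel genes instead (requires *table*).
    """
    from .expression import h_fraction

    if method == "h_fraction":
        return h_fraction(calls, list(panel.symbols))
    if method == "mean_tpm":
        if table is None:
            raise ValueError("mean_tpm potential needs the expression table")
        return table.tpm.loc[list(panel.symbols)].mean(axis=0)
    raise ValueError(f"unknown potential method {method!r}")


def regulator_correlation(
    tissue_potential: Sequence[float] | pd.Series,
    regulator_expression: Sequence[float] | pd.Series,
    alpha: float = 0.05,
    regulator: str = "",
) -> CorrelationResult:
    """Correlate per-tissue DNA-damage-response potential with a candidate
    regulator gene's expression; the r^2 > 0.7 tier is reported when
    significant."""
    return correlate(
        tissue_potential,
        regulator_expression,
        alpha=alpha,
        gene=regulator,
        index_name="regulator",
    )


def read_methylation_tsv(path: str | Path) -> TissueMethylationTable:
    """Read ``tissue<TAB>sam<TAB>sah``."""
    df = pd.read_csv(path, sep="\t", index_col="tissue")
    return TissueMethylationTable(sam=df["sam"], sah=df["sah"])


def write_methylation_tsv(table: TissueMethylationTable, path: str | Path) -> None:
    df = pd.DataFrame({"sam": table.sam, "sah": table.sah})
    df.index.name = "tissue"
    df.to_csv(path, sep="\t")


def write_correlation_report(
    rows: Sequence[CorrelationResult],
    labels: Mapping[str, str],
    path: str | Path,
) -> None:
    """Per-gene TSV: gene, index, n, r, r2, p, significant, tier, class."""
    df = pd.DataFrame.from_records(
        [
            {
                "gene": r.gene,
                "index": r.index,
                "n": r.n,
                "r": r.r,
                "r2": r.r_squared,
                "p": r.p,
                "significant": r.significant,
                "tier": r.tier if r.tier is not None else "NA",
                "class": labels.get(r.gene, "NA"),
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
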