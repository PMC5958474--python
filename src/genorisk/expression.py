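"""Tissue expression profiling from EST (expressed sequence tag) counts.

EST counts from tissue cDNA libraries proxy gene expression: the count of
tags for a gene divided by the library's total tag count, scaled to one
million, gives transcripts per million ESTs (TPM).  Each gene x tissue cell
is then called:

* ``absent`` (-)  — zero tags observed,
* ``high``   (++) — TPM strictly above the threshold,
* ``low``    (+)  — expressed but at or below the threshold.

Per tissue, H% is the percentage of a panel subset called high; tissues are
tiered into a pyramid by H%: high variety (> 19%), moderate variety
(5–19%, inclusive), low variety (< 5%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ESTExpressionTable",
    "CallMatrix",
    "normalize_est",
    "classify_expression",
    "auto_threshold",
    "h_fraction",
    "tier_tissue",
    "find_ubiquitous",
    "read_est_counts",
    "write_call_matrix",
]

HIGH, LOW, ABSENT = "high", "low", "absent"
CALL_NOTATION = {HIGH: "++", LOW: "+", ABSENT: "-"}
NOTATION_CALL = {v: k for k, v in CALL_NOTATION.items()}

TIER_HIGH, TIER_MODERATE, TIER_LOW = (
    "high_variety",
    "moderate_variety",
    "low_variety",
)


@dataclass(frozen=True)
class ESTExpressionTable:
    """Gene x tissue EST counts with per-tissue library totals and TPM.

    ``counts`` is a genes x tissues integer DataFrame; ``library_totals`` a
    per-tissue Series of total ESTs sequenced.  ``tpm`` is derived:
    ``counts / library_totals * 1e6``.
    """

    counts: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        totals = self.library_totals
        if (counts.values < 0).any():
            raise ValueError("EST counts must be nonnegative")
        if list(totals.index) != list(counts.columns):
            raise ValueError("library_totals index must match count columns")
        if (totals.values <= 0).any():
            raise ValueError("library totals must be positive")
        colsum = counts.sum(axis=0)
        if (colsum.values > totals.values).any():
            bad = colsum.index[(colsum.values > totals.values)].tolist()
            raise ValueError(f"counts exceed library totals in tissues {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tpm(self) -> pd.DataFrame:
        return self.counts / self.library_totals * 1e6


@dataclass(frozen=True)
class CallMatrix:
    """Gene x tissue labels in {high, low, absent} plus the threshold used."""

    labels: pd.DataFrame
    threshold_used: float

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels.values)) - {HIGH, LOW, ABSENT}
        if bad:
            raise ValueError(f"invalid call labels {sorted(bad)}")
        if not self.threshold_used > 0:
            raise ValueError("threshold_used must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.labels.columns)


def normalize_est(
    counts: pd.DataFrame, library_totals: pd.Series
) -> ESTExpressionTable:
    """Build an :class:`ESTExpressionTable` (TPM = count / total x 10^6)."""
    totals = pd.Series(library_totals, dtype=float).reindex(counts.columns)
    if totals.isna().any():
        missing = totals.index[totals.isna()].tolist()
        raise ValueError(f"missing library totals for tissues {missing}")
    return ESTExpressionTable(counts=counts.astype(np.int64), library_totals=totals)


def auto_threshold(table: ESTExpressionTable) -> float:
    """Default global call threshold: mean TPM over all nonzero cells."""
    tpm = table.tpm.values
    nonzero = tpm[tpm > 0]
    if nonzero.size == 0:
        raise ValueError("cannot derive a threshold: all counts are zero")
    return float(nonzero.mean())


def classify_expression(
    table: ESTExpressionTable, threshold: float | str = "auto"
) -> CallMatrix:
    """Call each gene x tissue cell high (++), low (+) or absent (-).

    ``absent`` iff the count is exactly zero; ``high`` iff TPM is strictly
    above the threshold (ties go to ``low``).  ``threshold="auto"`` uses
    :func:`auto_threshold`.
    """
    if threshold == "auto":
        thr = auto_threshold(table)
    else:
        thr = float(threshold)
        if not thr > 0:
            raise ValueError(f"threshold must be positive, got {thr}")
    tpm = table.tpm
    labels = pd.DataFrame(
        np.where(table.counts.values == 0, ABSENT, np.where(tpm.values > thr, HIGH, LOW)),
        index=tpm.index,
        columns=tpm.columns,
    )
    return CallMatrix(labels=labels, threshold_used=thr)


def h_fraction(calls: CallMatrix, panel_subset: Sequence[str]) -> pd.Series:
    """Per-tissue H%: percentage of *panel_subset* called high."""
    subset = list(panel_subset)
    if not subset:
        raise ValueError("panel_subset must be nonempty")
    missing = set(subset) - set(calls.genes)
    if missing:
        raise ValueError(f"genes not in call matrix: {sorted(missing)}")
    sub = calls.labels.loc[subset]
    return (sub == HIGH).sum(axis=0) / len(subset) * 100.0


def tier_tissue(h_percent: float) -> str:
    """Pyramid tier for one tissue's H%: >19 high, 5–19 moderate, <5 low."""
    if not 0.0 <= h_percent <= 100.0:
        raise ValueError(f"H% must be in [0, 100], got {h_percent}")
    if h_percent > 19.0:
        return TIER_HIGH
    if h_percent >= 5.0:
        return TIER_MODERATE
    return TIER_LOW


def find_ubiquitous(calls: CallMatrix, panel_subset: Sequence[str]) -> list[str]:
    """Genes of *panel_subset* expressed (high or low) in every tissue."""
    subset = list(panel_subset)
    if not subset:
        raise ValueError("panel_subset must be nonempty")
    sub = calls.labels.loc[subset]
    expressed_everywhere = (sub != ABSENT).all(axis=1)
    return [g for g in subset if expressed_everywhere[g]]


# -- TSV / JSON plumbing ----------------------------------------------------

def read_est_counts(
    counts_path: str | Path, totals_path: str | Path
) -> ESTExpressionTable:
    """Read a counts TSV (first column ``gene``) and a totals TSV
    (``tissue<TAB>total_ests``)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    totals = pd.read_csv(totals_path, sep="\t", index_col="tissue")["total_ests"]
    return normalize_est(counts, totals)


def write_call_matrix(
    calls: CallMatrix,
    tsv_path: str | Path,
    sidecar_path: str | Path | None = None,
    panel_subset: Sequence[str] | None = None,
) -> None:
    """Write calls as ++/+/- TSV plus a JSON sidecar with threshold, H%, tiers."""
    notated = calls.labels.replace(CALL_NOTATION)
    notated.index.name = "gene"
    notated.to_csv(tsv_path, sep="\t")
    if sidecar_path is not None:
        subset = list(panel_subset) if panel_subset is not None else calls.genes
        h = h_fraction(calls, subset)
        sidecar = {
            "threshold_used": calls.threshold_used,
            "h_percent": {t: float(h[t]) for t in calls.tissues},
            "tier": {t: tier_tissue(float(h[t])) for t in calls.tissues},
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_call_matrix(tsv_path: str | Path, threshold_used: float) -> CallMatrix:
    """Read a ++/+/- TSV back into a :class:`CallMatrix`."""
    notated = pd.read_csv(tsv_path, sep="\t", index_col="gene")
    return CallMatrix(labels=notated.replace(NOTATION_CALL), threshold_used=threshold_used)
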