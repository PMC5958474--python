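"""Modulation calling and the genomic-risk index.

A disease-vs-control contrast is summarized per gene as a fold change
(disease/control expression ratio) with an optional p-value.  A panel gene is
called ``up`` when fold change >= 2 (and p <= alpha when a p-value is
present), ``down`` when fold change <= 0.5 (same p condition), else
``unchanged``; genes absent from the contrast table count as unchanged and
stay in the denominator.

The genomic-risk index of a disease is (Up + Down) / 68 as a percentage; the
unrounded percentage places the disease in the high (>= 10%), medium
(5 to < 10%) or low (< 5%) genomic-risk group.  Display percentages round to
the nearest integer, ties away from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .panel import GenePanel, normalize_symbol

__all__ = [
    "ComparisonTable",
    "ModulationCalls",
    "RiskAssessment",
    "call_modulation",
    "count_modulated",
    "risk_percent",
    "classify_risk",
    "assess_risk",
    "direction_summary",
    "cohort_summary",
    "read_comparison_tsv",
    "write_comparison_tsv",
    "write_risk_report",
]

logger = logging.getLogger(__name__)

UP, DOWN, UNCHANGED = "up", "down", "unchanged"
HIGH_RISK, MEDIUM_RISK, LOW_RISK = "high", "medium", "low"
_RISK_ORDER = {LOW_RISK: 0, MEDIUM_RISK: 1, HIGH_RISK: 2}

DISEASE_CLASSES = frozenset(
    {
        "vascular",
        "autoimmune",
        "digestive",
        "metabolic",
        "aging",
        "cancer",
        "cytokine_stimulus",
        "oxidative_ko",
        "organelle_stress",
        "inflammation",
    }
)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (26.47 -> 26, 23.53 -> 24, 75.85 -> 75.9)."""
    scale = 10**ndigits
    scaled = x * scale
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / scale if ndigits else float(rounded)


@dataclass(frozen=True)
class ComparisonTable:
    """One disease-vs-control contrast: per-gene fold change and p-value."""

    disease: str
    disease_class: str
    tissue: str
    geo_id: str
    rows: pd.DataFrame  # columns: gene, fold_change, p_value (NaN = missing)

    def __post_init__(self) -> None:
        required = {"gene", "fold_change", "p_value"}
        if not required <= set(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(required)}")
        if (self.rows["fold_change"] <= 0).any():
            raise ValueError("fold changes must be positive ratios")
        if self.rows["gene"].duplicated().any():
            dup = self.rows.loc[self.rows["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene rows: {dup}")
        p = self.rows["p_value"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class ModulationCalls:
    """Per-panel-gene up/down/unchanged labels for one contrast."""

    disease: str
    disease_class: str
    labels: pd.Series  # index: panel symbols, values in {up, down, unchanged}
    up_fc: float = 2.0
    down_fc: float = 0.5
    alpha: float = 0.05

    def genes_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass(frozen=True)
class RiskAssessment:
    """Genomic-risk summary for one disease."""

    disease: str
    disease_class: str
    n_up: int
    n_down: int
    panel_size: int = 68
    n_total: int = field(init=False)
    risk_percent_raw: float = field(init=False)
    risk_percent_display: int = field(init=False)
    risk_group: str = field(init=False)

    def __post_init__(self) -> None:
        total = self.n_up + self.n_down
        raw, display = risk_percent(total, self.panel_size)
        object.__setattr__(self, "n_total", total)
        object.__setattr__(self, "risk_percent_raw", raw)
        object.__setattr__(self, "risk_percent_display", display)
        object.__setattr__(self, "risk_group", classify_risk(raw))


def call_modulation(
    table: ComparisonTable,
    panel: GenePanel,
    up_fc: float = 2.0,
    down_fc: float = 0.5,
    alpha: float = 0.05,
    species: str = "human",
    bh_correct: bool = False,
) -> ModulationCalls:
    """Label every panel gene up/down/unchanged from a contrast table.

    When a row carries a p-value the call additionally requires p <= *alpha*;
    rows with missing p are decided on fold change alone.  *bh_correct*
    applies Benjamini–Hochberg across the table's non-missing p-values before
    thresholding.  Unknown gene symbols are logged and ignored.
    """
    if not up_fc > 1 > down_fc > 0:
        raise ValueError("need up_fc > 1 > down_fc > 0")
    rows = table.rows.copy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = rows["p_value"].notna()
        if mask.any():
            rows.loc[mask, "p_value"] = multipletests(
                rows.loc[mask, "p_value"].values, method="fdr_bh"
            )[1]
    labels = pd.Series(UNCHANGED, index=list(panel.symbols), dtype=object)
    for gene, fc, p in rows[["gene", "fold_change", "p_value"]].itertuples(index=False):
        symbol = normalize_symbol(str(gene), panel, species=species)
        if symbol is None:
            logger.info("ignoring non-panel gene %r in %s", gene, table.disease)
            continue
        significant = pd.isna(p) or p <= alpha
        if fc >= up_fc and significant:
            labels[symbol] = UP
        elif fc <= down_fc and significant:
            labels[symbol] = DOWN
    return ModulationCalls(
        disease=table.disease,
        disease_class=table.disease_class,
        labels=labels,
        up_fc=up_fc,
        down_fc=down_fc,
        alpha=alpha,
    )


def count_modulated(
    calls: ModulationCalls, panel: GenePanel, category: str = "both"
) -> tuple[int, int]:
    """(n_up, n_down) restricted to a panel category (DDCF, DDRF or both)."""
    symbols = panel.category_symbols(category)
    sub = calls.labels.loc[list(symbols)]
    return int((sub == UP).sum()), int((sub == DOWN).sum())


def risk_percent(n_total: int, panel_size: int = 68) -> tuple[float, int]:
    """Genomic-risk index: (raw percentage, integer display percentage)."""
    if panel_size <= 0:
        raise ValueError("panel_size must be positive")
    if not 0 <= n_total <= panel_size:
        raise ValueError(f"n_total must be in [0, {panel_size}], got {n_total}")
    raw = 100.0 * n_total / panel_size
    return raw, int(round_half_away(raw))


def classify_risk(raw_percent: float) -> str:
    """high if raw >= 10, medium if 5 <= raw < 10, low if raw < 5."""
    if not 0.0 <= raw_percent <= 100.0:
        raise ValueError(f"risk percent must be in [0, 100], got {raw_percent}")
    if raw_percent >= 10.0:
        return HIGH_RISK
    if raw_percent >= 5.0:
        return MEDIUM_RISK
    return LOW_RISK


def assess_risk(
    calls: ModulationCalls, panel: GenePanel, panel_size: int | None = None
) -> RiskAssessment:
    """Fold one contrast's calls into a :class:`RiskAssessment`."""
    n_up, n_down = count_modulated(calls, panel, "both")
    return RiskAssessment(
        disease=calls.disease,
        disease_class=calls.disease_class,
        n_up=n_up,
        n_down=n_down,
        panel_size=panel_size if panel_size is not None else panel.size,
    )


def direction_summary(
    calls_list: Sequence[ModulationCalls],
    panel: GenePanel,
    category: str,
) -> tuple[int, int, float | None]:
    """Aggregate direction tendency across contrasts of one disease class.

    Returns (total_up, total_changes, percent_up rounded half-away to one
    decimal); percent is None when no gene changed.
    """
    if not calls_list:
        raise ValueError("calls_list must be nonempty")
    total_up = total_down = 0
    for calls in calls_list:
        n_up, n_down = count_modulated(calls, panel, category)
        total_up += n_up
        total_down += n_down
    total_changes = total_up + total_down
    if total_changes == 0:
        return 0, 0, None
    percent = round_half_away(100.0 * total_up / total_changes, 1)
    return total_up, total_changes, percent


def cohort_summary(
    assessments: Sequence[RiskAssessment],
    disease_class: str | None = None,
) -> pd.DataFrame:
    """Per-risk-group counts and cohort fractions (one-decimal percent).

    Optionally restrict to one disease class first.  Fractions use the
    cohort size after filtering; counts always sum to that size.
    """
    pool = [
        a
        for a in assessments
        if disease_class is None or a.disease_class == disease_class
    ]
    if not pool:
        raise ValueError("no assessments in cohort")
    n = len(pool)
    records = []
    for group in (HIGH_RISK, MEDIUM_RISK, LOW_RISK):
        count = sum(1 for a in pool if a.risk_group == group)
        records.append(
            {
                "risk_group": group,
                "count": count,
                "cohort_size": n,
                "percent": round_half_away(100.0 * count / n, 1),
            }
        )
    return pd.DataFrame.from_records(records).set_index("risk_group")


# -- TSV plumbing -----------------------------------------------------------

_META_KEYS = ("disease", "class", "tissue", "geo_id")


def read_comparison_tsv(path: str | Path) -> ComparisonTable:
    """Read a contrast TSV: ``#key=value`` header comments then
    ``gene<TAB>fold_change<TAB>p_value`` (p may be ``NA``)."""
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            data_lines.append(line)
    from io import StringIO

    rows = pd.read_csv(
        StringIO("\n".join(data_lines)), sep="\t", na_values=["NA"]
    )
    return ComparisonTable(
        disease=meta.get("disease", path.stem),
        disease_class=meta.get("class", "organelle_stress"),
        tissue=meta.get("tissue", ""),
        geo_id=meta.get("geo_id", ""),
        rows=rows,
    )


def write_comparison_tsv(table: ComparisonTable, path: str | Path) -> None:
    path = Path(path)
    header = "".join(
        f"# {key}={value}\n"
        for key, value in zip(
            _META_KEYS,
            (table.disease, table.disease_class, table.tissue, table.geo_id),
        )
    )
    body = table.rows.to_csv(sep="\t", index=False, na_rep="NA")
    path.write_text(header + body, encoding="utf-8")


def write_risk_report(
    assessments: Iterable[RiskAssessment], path: str | Path
) -> pd.DataFrame:
    """Write the per-disease risk table (TSV) and return it as a DataFrame."""
    df = pd.DataFrame.from_records(
        [
            {
                "disease": a.disease,
                "class": a.disease_class,
                "n_up": a.n_up,
                "n_down": a.n_down,
                "n_total": a.n_total,
                "percent": a.risk_percent_display,
                "group": a.risk_group,
            }
            for a in assessments
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
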