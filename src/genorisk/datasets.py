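"""Loaders for the bundled study tables.

Three small TSVs ship with the package:

* ``disease_gene_counts.tsv`` — the 39-disease table (27 inflammatory
  disorders, 12 cancers) with the number of up- plus down-regulated panel
  genes reported for each;
* ``organelle_stress_conditions.tsv`` / ``organelle_stress_foldchanges.tsv``
  — the ten organelle-stress knockout contrasts (GEO accession, stressed
  organelle, tissue, comparison) and every reported panel-gene fold change;
* ``methylation_groups.tsv`` — the panel genes reported as tracking a
  tissue methylation index (SAH, SAM or SAM/SAH), i.e. the hypo- and
  hyper-methylation-regulated groups.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .modulation import ComparisonTable
from .panel import GenePanel, normalize_symbol

__all__ = [
    "load_disease_gene_counts",
    "load_organelle_stress_comparisons",
    "load_methylation_groups",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("genorisk.data").joinpath(name)))


def load_disease_gene_counts() -> pd.DataFrame:
    """Disease, cohort (inflammation/cancer) and modulated-gene count."""
    return pd.read_csv(_data_path("disease_gene_counts.tsv"), sep="\t")


def load_organelle_stress_comparisons() -> list[ComparisonTable]:
    """The ten organelle-stress contrasts as :class:`ComparisonTable` rows.

    Fold changes are the reported values; no p-values were reported, so
    modulation calls on these tables are decided on fold change alone.
    """
    conditions = pd.read_csv(_data_path("organelle_stress_conditions.tsv"), sep="\t")
    fcs = pd.read_csv(_data_path("organelle_stress_foldchanges.tsv"), sep="\t")
    tables = []
    for row in conditions.itertuples(index=False):
        sub = fcs[fcs["geo_id"] == row.geo_id]
        rows = pd.DataFrame(
            {
                "gene": sub["gene"].tolist(),
                "fold_change": sub["fold_change"].astype(float).tolist(),
                "p_value": np.nan,
            },
            columns=["gene", "fold_change", "p_value"],
        )
        tables.append(
            ComparisonTable(
                disease=row.comparison,
                disease_class="organelle_stress",
                tissue=row.tissue,
                geo_id=row.geo_id,
                rows=rows,
            )
        )
    return tables


def load_methylation_groups(panel: GenePanel | None = None) -> pd.DataFrame:
    """Genes reported as methylation-regulated, with group and index.

    Symbols in the source table follow mouse case convention; when a panel
    is given they are normalized to official human symbols.
    """
    df = pd.read_csv(_data_path("methylation_groups.tsv"), sep="\t")
    if panel is not None:
        df = df.assign(
            gene=[
                normalize_symbol(tok, panel, species="mouse") for tok in df["gene"]
            ]
        )
        if df["gene"].isna().any():
            raise ValueError("methylation group table contains non-panel genes")
    return df
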