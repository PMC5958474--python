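"""Cross-disease overlap of modulated gene sets (Venn-region analysis).

Each disease contributes its set of modulated panel genes; every gene in the
union belongs to exactly one exclusive Venn region, identified by the
signature of diseases whose sets contain it.  Diseases whose modulated genes
fall mostly (strict majority of the union) into single-disease regions are
flagged "mostly disease-specific".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "GeneSetCollection",
    "venn_regions",
    "pairwise_intersections",
    "specific_genes",
    "write_region_table",
    "plot_venn",
]

MAX_EXACT_SETS = 6


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (disease -> modulated panel symbols) plus direction."""

    sets: Mapping[str, frozenset[str]]
    direction: str = "both"  # up, down or both

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down", "both"}:
            raise ValueError(f"invalid direction {self.direction!r}")
        object.__setattr__(
            self, "sets", {k: frozenset(v) for k, v in self.sets.items()}
        )

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.sets.values():
            out |= s
        return out


def venn_regions(
    collection: GeneSetCollection,
) -> dict[tuple[str, ...], list[str]]:
    """Exclusive Venn regions: signature of containing sets -> member genes.

    Every nonempty subset of set names appears as a key (members may be
    empty); each gene of the union lands in exactly one region, so region
    cardinalities sum to the union size.  Requires 1–6 sets; use
    :func:`pairwise_intersections` beyond that.
    """
    names = collection.names
    if not names:
        raise ValueError("collection must contain at least one set")
    if len(names) > MAX_EXACT_SETS:
        raise ValueError(
            f"exact region enumeration supports at most {MAX_EXACT_SETS} sets;"
            " use pairwise_intersections"
        )
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = []
    for gene in sorted(collection.union):
        signature = tuple(n for n in names if gene in collection.sets[n])
        regions[signature].append(gene)
    return regions


def pairwise_intersections(
    collection: GeneSetCollection,
) -> dict[tuple[str, str], int]:
    """|A ∩ B| for every unordered pair (fallback for > 6 sets)."""
    names = collection.names
    return {
        (a, b): len(collection.sets[a] & collection.sets[b])
        for a, b in combinations(names, 2)
    }


def specific_genes(
    collection: GeneSetCollection,
) -> tuple[dict[str, list[str]], bool]:
    """Genes unique to each disease, plus the "mostly specific" flag.

    The flag is True when singleton regions hold a strict majority
    (> 50%) of the union.
    """
    regions = venn_regions(collection)
    singles = {
        sig[0]: genes for sig, genes in regions.items() if len(sig) == 1
    }
    per_disease = {name: singles.get(name, []) for name in collection.names}
    n_specific = sum(len(g) for g in per_disease.values())
    union_size = len(collection.union)
    mostly = union_size > 0 and n_specific > union_size / 2
    return per_disease, mostly


def write_region_table(
    regions: Mapping[tuple[str, ...], Sequence[str]], path: str | Path
) -> None:
    """Region TSV: ``signature<TAB>count<TAB>genes`` (signature ``&``-joined)."""
    lines = ["signature\tcount\tgenes"]
    for sig, genes in regions.items():
        lines.append(f"{'&'.join(sig)}\t{len(genes)}\t{','.join(genes)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def plot_venn(collection: GeneSetCollection, path: str | Path) -> None:
    """Draw a 1–3 set Venn figure with region counts (matplotlib circles)."""
    names = collection.names
    if not 1 <= len(names) <= 3:
        raise ValueError("Venn figure supports 1–3 sets")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = venn_regions(collection)
    centers = {
        1: [(0.0, 0.0)],
        2: [(-0.5, 0.0), (0.5, 0.0)],
        3: [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.6)],
    }[len(names)]
    # mid-point of the contributing circles places each region label
    fig, ax = plt.subplots(figsize=(5, 5))
    for (x, y), name in zip(centers, names):
        ax.add_patch(plt.Circle((x, y), 1.0, alpha=0.3, label=name))
        ax.annotate(name, (x, y + 1.05), ha="center")
    for sig, genes in regions.items():
        idx = [names.index(n) for n in sig]
        cx = sum(centers[i][0] for i in idx) / len(idx)
        cy = sum(centers[i][1] for i in idx) / len(idx)
        ax.annotate(str(len(genes)), (cx, cy), ha="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
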