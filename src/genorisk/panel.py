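"""Registry of the 68-gene DNA damage checkpoint/repair panel.

The panel comprises 26 DNA damage checkpoint factors (DDCFs — the sensors,
mediators, transducers and effectors that arrest the cell cycle when DNA is
damaged) and 42 DNA damage repair factors (DDRFs — direct reversal, excision
repair, double-strand-break repair and mismatch repair enzymes).  Two DDCF
membership variants circulate in the literature for this panel: a tabular one
that includes IL1A and splits replication protein A into RPA1/RPA2/RPA3
(``table2``, the default, used by every quantitative analysis downstream), and
a schematic one that includes the CDC25A/CDC25C effectors and RFC instead
(``figure2``).  Both contain exactly 26 DDCFs.

Gene symbols are normalized case-insensitively against official human symbols,
legacy aliases (Ku70 -> XRCC6, XPB -> ERCC3, ...) and mouse homolog symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "GeneRecord",
    "GenePanel",
    "PanelIntegrityError",
    "AmbiguousSymbolError",
    "NOT_IN_PANEL",
    "load_panel",
    "normalize_symbol",
]

DDCF_SUBGROUPS = frozenset({"sensor", "mediator", "transducer", "effector"})
DDRF_SUBGROUPS = frozenset(
    {"DR", "NER", "BER", "DSBR-HR", "DSBR-NHEJ", "DSBR-MMEJ", "MMR", "shared"}
)

N_DDCF = 26
N_DDRF = 42
PANEL_SIZE = N_DDCF + N_DDRF

#: Sentinel returned by :func:`normalize_symbol` for tokens outside the panel.
NOT_IN_PANEL = None


class PanelIntegrityError(ValueError):
    """Raised when a panel file violates the 26 + 42 membership contract."""


class AmbiguousSymbolError(ValueError):
    """Raised when a token matches more than one panel record."""


@dataclass(frozen=True)
class GeneRecord:
    """One panel gene: official symbol, category, subgroup and synonyms."""

    symbol: str
    category: str  # "DDCF" or "DDRF"
    subgroup: str
    aliases: frozenset[str] = field(default_factory=frozenset)
    mouse_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be nonempty")
        if self.category == "DDCF":
            allowed = DDCF_SUBGROUPS
        elif self.category == "DDRF":
            allowed = DDRF_SUBGROUPS
        else:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subgroup not in allowed:
            raise ValueError(
                f"subgroup {self.subgroup!r} invalid for category {self.category}"
            )


@dataclass(frozen=True)
class GenePanel:
    """An ordered 26-DDCF + 42-DDRF gene panel."""

    name: str
    ddcf: tuple[GeneRecord, ...]
    ddrf: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        if len(self.ddcf) != N_DDCF:
            raise PanelIntegrityError(
                f"panel {self.name!r}: expected {N_DDCF} DDCFs, got {len(self.ddcf)}"
            )
        if len(self.ddrf) != N_DDRF:
            raise PanelIntegrityError(
                f"panel {self.name!r}: expected {N_DDRF} DDRFs, got {len(self.ddrf)}"
            )
        symbols = [r.symbol for r in self.records]
        if len(set(symbols)) != PANEL_SIZE:
            raise PanelIntegrityError(f"panel {self.name!r}: duplicate symbols")
        # aliases must not collide with any other record's symbol or aliases
        seen: dict[str, str] = {s.upper(): s for s in symbols}
        for rec in self.records:
            for alias in rec.aliases:
                key = alias.upper()
                owner = seen.get(key)
                if owner is not None and owner != rec.symbol:
                    raise PanelIntegrityError(
                        f"alias {alias!r} of {rec.symbol} collides with {owner}"
                    )
                seen.setdefault(key, rec.symbol)

    @property
    def records(self) -> tuple[GeneRecord, ...]:
        return self.ddcf + self.ddrf

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.records)

    @property
    def size(self) -> int:
        return len(self.records)

    def category_symbols(self, category: str) -> tuple[str, ...]:
        """Symbols of one category: ``"DDCF"``, ``"DDRF"`` or ``"both"``."""
        if category == "DDCF":
            return tuple(r.symbol for r in self.ddcf)
        if category == "DDRF":
            return tuple(r.symbol for r in self.ddrf)
        if category == "both":
            return self.symbols
        raise ValueError(f"unknown category {category!r}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)


def _bundled_path(variant: str) -> Path:
    fname = {"table2": "panel_table2.tsv", "figure2": "panel_figure2.tsv"}
    try:
        name = fname[variant]
    except KeyError:
        raise ValueError(f"unknown panel variant {variant!r}") from None
    return Path(str(resources.files("genorisk.data").joinpath(name)))


def load_panel(path: str | Path | None = None, variant: str = "table2") -> GenePanel:
    """Load a gene panel from a TSV definition file.

    Parameters
    ----------
    path
        Panel TSV with header ``symbol  category  subgroup  aliases
        mouse_symbol`` (aliases ``|``-separated, may be empty).  ``None``
        loads the bundled definition for *variant*.
    variant
        ``"table2"`` (default; includes IL1A and the RPA1/2/3 split) or
        ``"figure2"`` (includes CDC25A/CDC25C and RFC1).
    """
    if path is None:
        path = _bundled_path(variant)
    path = Path(path)
    required = ["symbol", "category", "subgroup", "aliases", "mouse_symbol"]
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != required:
            raise ValueError(
                f"{path}: expected columns {required}, found {header}"
            )
        ddcf: list[GeneRecord] = []
        ddrf: list[GeneRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(required):
                raise ValueError(
                    f"{path}:{lineno}: malformed row "
                    f"({len(fields)} fields, expected {len(required)})"
                )
            symbol, category, subgroup, aliases, mouse = fields
            try:
                rec = GeneRecord(
                    symbol=symbol.strip().upper(),
                    category=category.strip(),
                    subgroup=subgroup.strip(),
                    aliases=frozenset(
                        a.strip() for a in aliases.split("|") if a.strip()
                    ),
                    mouse_symbol=mouse.strip(),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            (ddcf if rec.category == "DDCF" else ddrf).append(rec)
    return GenePanel(name=f"{path.stem}", ddcf=tuple(ddcf), ddrf=tuple(ddrf))


def _match_token(token: str, rec: GeneRecord, species: str) -> bool:
    key = token.upper()
    if species == "human":
        candidates = {rec.symbol} | set(rec.aliases)
    elif species == "mouse":
        candidates = {rec.mouse_symbol} if rec.mouse_symbol else set()
        # mouse figures frequently reuse human aliases (e.g. Ku70)
        candidates |= set(rec.aliases) | {rec.symbol}
    else:
        raise ValueError(f"unknown species {species!r}")
    return key in {c.upper() for c in candidates}


def normalize_symbol(
    token: str, panel: GenePanel, species: str = "human"
) -> str | None:
    """Resolve a raw gene token to the official human symbol.

    Matching is case-insensitive against official symbols, ``|``-separated
    aliases, and mouse homolog symbols.  Returns :data:`NOT_IN_PANEL`
    (``None``) for tokens with no panel match; raises
    :class:`AmbiguousSymbolError` if a token matches two records.
    """
    if not token or not token.strip():
        raise ValueError("token must be nonempty")
    token = token.strip()
    hits = [rec for rec in panel.records if _match_token(token, rec, species)]
    if not hits:
        return NOT_IN_PANEL
    if len(hits) > 1:
        raise AmbiguousSymbolError(
            f"token {token!r} matches {[r.symbol for r in hits]}"
        )
    return hits[0].symbol


def normalize_many(
    tokens: Iterable[str], panel: GenePanel, species: str = "human"
) -> dict[str, str | None]:
    """Vector form of :func:`normalize_symbol`; keys are the input tokens."""
    return {t: normalize_symbol(t, panel, species) for t in tokens}
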