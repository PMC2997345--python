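"""Domain types, file readers/writers, symbol normalization and logging.

All downstream modules consume the types defined here.  Gene symbols are
normalized once, at read time, through :func:`normalize_symbol` so that set
arithmetic, enrichment overlaps and literature lookups all operate on a
single canonical namespace (trimmed, upper-case, alias-resolved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("raftomics")

PROTEIN_TABLE_COLUMNS = (
    "symbol",
    "accession",
    "peptides",
    "score",
    "confidence",
    "spectral_count",
    "replicate",
    "condition",
)


class ParseError(ValueError):
    """Malformed input file (carries the offending line number where known)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ProteinIdentification:
    """One protein's identification evidence in one animal/replicate.

    Attributes
    ----------
    symbol:
        Normalized gene symbol.
    accession:
        Database accession the search engine reported.
    peptide_count:
        Number of unambiguous (validated) peptides supporting the protein.
    id_score:
        Search-engine total identification score.
    confidence:
        Identification confidence in ``[0, 1]``.
    spectral_count:
        Number of MS/MS spectra assigned to the protein (label-free
        quantitation signal).
    replicate_id:
        Identifier of the animal/replicate the evidence came from.
    condition:
        Condition label (e.g. ``"control"`` or ``"case"``).
    """

    symbol: str
    accession: str
    peptide_count: int
    id_score: float
    confidence: float
    spectral_count: int
    replicate_id: str
    condition: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("symbol must be non-empty")
        if self.peptide_count < 0:
            raise ValueError(f"peptide_count must be >= 0, got {self.peptide_count}")
        if self.spectral_count < 0:
            raise ValueError(f"spectral_count must be >= 0, got {self.spectral_count}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.id_score < 0:
            raise ValueError(f"id_score must be >= 0, got {self.id_score}")


@dataclass
class ConditionDataset:
    """Consensus protein set for one condition.

    ``consensus_symbols`` holds the symbols that survived identification
    filtering and the replicate-consensus rule.  ``spectral_counts`` maps
    each consensus symbol to its spectral count summed across replicates
    (zero if counting was not performed).
    """

    condition: str
    replicates: list[str]
    consensus_symbols: set[str]
    spectral_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"condition {self.condition!r} has no replicates")


@dataclass(frozen=True)
class GeneSet:
    """A named pathway/functional group with member symbols."""

    name: str
    description: str
    members: frozenset[str]
    category: str = "uncategorized"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Gene sets plus the reference background (universe) they are tested against."""

    sets: list[GeneSet]
    universe: set[str]

    def __post_init__(self) -> None:
        stray = {m for gs in self.sets for m in gs.members} - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} gene-set members missing from universe "
                f"(e.g. {sorted(stray)[:5]})"
            )

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for gs in self.sets:
            seen.setdefault(gs.category)
        return list(seen)

    def extend_universe(self, symbols: Iterable[str]) -> None:
        """Grow the background to cover additional observed symbols."""
        self.universe |= set(symbols)


class AliasMap(dict):
    """Mapping from synonym/accession strings to official gene symbols.

    Keys and values are stored upper-case; lookup is idempotent on official
    symbols (an official symbol maps to itself).
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        super().__init__()
        for k, v in (mapping or {}).items():
            self[k.strip().upper()] = v.strip().upper()

    def resolve(self, symbol: str) -> str:
        return self.get(symbol, symbol)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Read a two-column TSV (synonym <tab> official symbol)."""
        mapping = {}
        for lineno, line in enumerate(_read_lines(path), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            mapping[parts[0]] = parts[1]
        return cls(mapping)


# ---------------------------------------------------------------------------
# symbol normalization


def normalize_symbol(raw: str, aliases: AliasMap | None = None) -> str:
    """Normalize a gene symbol: strip, upper-case, resolve aliases.

    Unknown symbols pass through unchanged (logged at DEBUG level), so the
    pipeline degrades gracefully when the alias map is incomplete.

    Raises
    ------
    ValueError
        If the input is empty or whitespace-only.
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError(f"cannot normalize empty symbol {raw!r}")
    if aliases is not None:
        resolved = aliases.resolve(sym)
        if resolved != sym:
            return resolved
        if sym not in aliases.values():
            logger.debug("symbol %s not in alias map; passing through", sym)
    return sym


# ---------------------------------------------------------------------------
# readers / writers


def _read_lines(path: str | Path) -> list[str]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return p.read_text().splitlines()


def read_gene_sets(
    path: str | Path,
    category_map: Mapping[str, str] | None = None,
    aliases: AliasMap | None = None,
    background: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member...).

    Member symbols are normalized and de-duplicated.  ``category_map``
    assigns each set a functional category (GMT itself has no category
    field); unmapped sets fall back to ``"uncategorized"``.  The universe
    defaults to the union of all members unless ``background`` is given.
    """
    lines = _read_lines(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                f"(name, description, members...), got {len(parts)}"
            )
        name, description = parts[0], parts[1]
        members = frozenset(normalize_symbol(m, aliases) for m in parts[2:] if m.strip())
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        category = (category_map or {}).get(name, "uncategorized")
        sets.append(GeneSet(name=name, description=description, members=members, category=category))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    if background is not None:
        universe = {normalize_symbol(s, aliases) for s in background}
    else:
        universe = set().union(*(gs.members for gs in sets))
    return GeneSetCollection(sets=sets, universe=universe)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (members sorted for reproducibility)."""
    with open(path, "w") as fh:
        for gs in collection.sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV sidecar: gene-set name <tab> category."""
    out = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        out[parts[0]] = parts[1]
    return out


def read_protein_table(
    path: str | Path, aliases: AliasMap | None = None
) -> list[ProteinIdentification]:
    """Read a protein identification TSV with a declared header.

    Required columns: ``symbol, accession, peptides, score, confidence,
    spectral_count, replicate, condition`` (``accession`` may be empty).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PROTEIN_TABLE_COLUMNS if c not in df.columns and c != "accession"]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "accession" not in df.columns:
        df["accession"] = ""
    records: list[ProteinIdentification] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            records.append(
                ProteinIdentification(
                    symbol=normalize_symbol(str(row["symbol"]), aliases),
                    accession=str(row["accession"]) if pd.notna(row["accession"]) else "",
                    peptide_count=int(row["peptides"]),
                    id_score=float(row["score"]),
                    confidence=float(row["confidence"]),
                    spectral_count=int(row["spectral_count"]),
                    replicate_id=str(row["replicate"]),
                    condition=str(row["condition"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_protein_table(records: Sequence[ProteinIdentification], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in records],
            "accession": [r.accession for r in records],
            "peptides": [r.peptide_count for r in records],
            "score": [r.id_score for r in records],
            "confidence": [r.confidence for r in records],
            "spectral_count": [r.spectral_count for r in records],
            "replicate": [r.replicate_id for r in records],
            "condition": [r.condition for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with a commented provenance header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# raftomics {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)
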