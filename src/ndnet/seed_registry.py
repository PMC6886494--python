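"""Curated gene sets and protein-accession bookkeeping.

The analyses in this package all start from a curated *seed* set of genes
linked to common neurodegenerative disorders (Alzheimer's and Parkinson's
disease, ALS, Huntington's disease, frontotemporal dementia).  A seed set is
a small list of gene symbols, optionally carrying UniProt-style protein
accessions, together with a *declared population size*: the number of genes
the curation claims, which may exceed the number of members that can actually
be enumerated.  All enrichment statistics use the declared size as the
population count K, while symbol-keyed operations (network induction,
detection summaries) use the enumerated members.

Accession housekeeping mirrors the routine step of replacing secondary or
obsolete UniProt identifiers with their current primary accession before
grouping records by protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "GeneRef",
    "GeneSet",
    "IdMap",
    "load_gene_set",
    "write_gene_set",
    "load_idmap",
    "resolve_accession",
]

#: UniProt-style primary accessions: uppercase alphanumeric, 6-10 characters.
ACCESSION_PATTERN = re.compile(r"^[A-Z0-9]{6,10}$")

Source = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class GeneRef:
    """A gene symbol with an optional protein accession and display label.

    Symbols are normalized to uppercase (HGNC style); mixed-case input is
    accepted.  ``accession`` must look like a UniProt accession when present.
    """

    symbol: str
    accession: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol or not str(self.symbol).strip():
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "symbol", str(self.symbol).strip().upper())
        if self.accession is not None:
            acc = str(self.accession).strip().upper()
            if not acc:
                object.__setattr__(self, "accession", None)
            elif not ACCESSION_PATTERN.match(acc):
                raise ValueError(f"malformed protein accession: {self.accession!r}")
            else:
                object.__setattr__(self, "accession", acc)


@dataclass(frozen=True)
class GeneSet:
    """A named, symbol-deduplicated collection of :class:`GeneRef`.

    ``declared_size`` is the population count K claimed for the set even when
    not every member is enumerable; it defaults to the member count and must
    not be smaller than it.
    """

    name: str
    members: tuple[GeneRef, ...]
    declared_size: int = field(default=0)

    def __post_init__(self) -> None:
        seen: dict[str, GeneRef] = {}
        for ref in self.members:
            seen.setdefault(ref.symbol, ref)
        object.__setattr__(self, "members", tuple(seen.values()))
        if self.declared_size == 0:
            object.__setattr__(self, "declared_size", len(self.members))
        if self.declared_size < len(self.members):
            raise ValueError(
                f"declared_size {self.declared_size} < enumerated members "
                f"{len(self.members)}"
            )

    def __len__(self) -> int:
        return len(self.members)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(ref.symbol for ref in self.members)

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(r.accession for r in self.members if r.accession)

    def __contains__(self, symbol: object) -> bool:
        return isinstance(symbol, str) and symbol.upper() in self.symbols


@dataclass(frozen=True)
class IdMap:
    """Mapping from obsolete/secondary accessions to current ones."""

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for old, new in self.entries.items():
            if not ACCESSION_PATTERN.match(new):
                raise ValueError(f"idmap target is not a valid accession: {new!r}")

    def resolve(self, accession: str, max_depth: int = 5) -> str:
        """Follow the mapping chain from ``accession`` to a current accession.

        Raises ``ValueError`` if more than ``max_depth`` hops are needed,
        which signals a cyclic or pathologically deep map.
        """
        current = accession
        for _ in range(max_depth + 1):
            nxt = self.entries.get(current)
            if nxt is None:
                return current
            current = nxt
        raise ValueError(
            f"accession mapping for {accession!r} exceeds depth {max_depth} "
            "(cyclic or over-deep idmap)"
        )


def _read_tsv(source: Source) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError("empty gene-set / idmap file") from exc
    if df.empty and len(df.columns) == 0:
        raise ValueError("empty gene-set / idmap file")
    return df


def load_gene_set(
    source: Source,
    name: str,
    declared_size: int | None = None,
) -> GeneSet:
    """Read a gene set from TSV with columns ``symbol`` [, ``accession``, ``label``].

    Lines starting with ``#`` are ignored.  Rows are deduplicated by symbol
    (first occurrence wins).  ``declared_size`` defaults to the member count.
    """
    df = _read_tsv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    if "symbol" not in df.columns:
        raise ValueError("gene-set file lacks required 'symbol' column")
    if df.empty:
        raise ValueError("gene-set file has a header but no rows")
    refs = []
    for row in df.itertuples(index=False):
        acc = getattr(row, "accession", None)
        label = getattr(row, "label", None)
        refs.append(
            GeneRef(
                symbol=row.symbol,
                accession=None if pd.isna(acc) else acc,
                label=None if pd.isna(label) else label,
            )
        )
    return GeneSet(name=name, members=tuple(refs), declared_size=declared_size or 0)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """Serialize a gene set back to the TSV dialect ``load_gene_set`` reads."""
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in gene_set.members],
            "accession": [r.accession for r in gene_set.members],
            "label": [r.label for r in gene_set.members],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_idmap(source: Source) -> IdMap:
    """Read an accession map from TSV columns ``old_accession``, ``new_accession``."""
    df = _read_tsv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("old_accession", "new_accession"):
        if col not in df.columns:
            raise ValueError(f"idmap file lacks required column {col!r}")
    entries = dict(zip(df["old_accession"].str.upper(), df["new_accession"].str.upper()))
    return IdMap(entries=entries)


def resolve_accession(ref: GeneRef, idmap: IdMap, max_depth: int = 5) -> GeneRef:
    """Replace an obsolete accession by its current mapping, if any.

    A ref without an accession, or whose accession is already current, is
    returned unchanged.  Resolution is a projection: applying it twice equals
    applying it once on acyclic maps.
    """
    if ref.accession is None:
        return ref
    resolved = idmap.resolve(ref.accession, max_depth=max_depth)
    if resolved == ref.accession:
        return ref
    return replace(ref, accession=resolved)
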