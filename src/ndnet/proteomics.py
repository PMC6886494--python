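"""Mass-spectrometry presence/absence matrices and expression filtering.

Shotgun proteomics surveys report, for each protein and dataset, only whether
the protein was identified.  Because mass spectrometry is an insensitive
technique, a detected protein can be taken as abundantly expressed; this
module therefore treats detection in at least one dataset of a cell-type
group (e.g. two independent B-lymphocyte surveys) as evidence of expression
in that cell type.

Proteins missing from a matrix are tri-state ``UNKNOWN`` rather than
not-detected: curated matrices only contain the rows that were reported.
Summaries count unknown as not detected, so a detected count over a declared
seed population of 48 reproduces the usual "34 of 48 (70%)"-style arithmetic
(percentages truncate toward zero).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .interactome import InteractionNetwork
from .seed_registry import GeneSet

__all__ = [
    "Detection",
    "DetectionMatrix",
    "DetectionSummary",
    "ExpressionFilterResult",
    "parse_detection_matrix",
    "is_detected",
    "summarize_detection",
    "filter_network_by_expression",
]

Source = Union[str, Path, IO[str]]

#: Cell vocabulary of curated detection tables, compared case-insensitively.
DEFAULT_TOKEN_MAP = {"detected": True, "0": False}


class Detection(enum.Enum):
    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    UNKNOWN = "unknown"


@dataclass
class DetectionMatrix:
    """Boolean protein × dataset detection table with named dataset groups."""

    values: pd.DataFrame  # bool, index = gene symbol, columns = dataset labels
    accessions: dict[str, str | None]
    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for group, datasets in self.groups.items():
            missing = set(datasets) - set(self.values.columns)
            if missing:
                raise ValueError(
                    f"group {group!r} references undeclared datasets {sorted(missing)}"
                )

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.values.columns)

    def detected_in_group(self, group: str) -> frozenset[str]:
        """Symbols detected in ≥1 dataset of ``group`` (union rule)."""
        if group not in self.groups:
            raise KeyError(f"undeclared dataset group {group!r}")
        cols = list(self.groups[group])
        return frozenset(self.values.index[self.values[cols].any(axis=1)])


def parse_detection_matrix(
    source: Source,
    group_config: Mapping[str, Sequence[str]],
    token_map: Mapping[str, bool] | None = None,
) -> DetectionMatrix:
    """Read a detection TSV: columns ``symbol``, ``accession``, then datasets.

    Cells must belong to the token vocabulary (default ``Detected``/``0``,
    case-insensitive); anything else raises with row/column context.
    """
    tokens = {k.lower(): v for k, v in (token_map or DEFAULT_TOKEN_MAP).items()}
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "symbol" not in df.columns:
        raise ValueError("detection table lacks required 'symbol' column")
    dataset_cols = [c for c in df.columns if c not in ("symbol", "accession")]
    if not dataset_cols:
        raise ValueError("detection table has no dataset columns")
    values = pd.DataFrame(index=df["symbol"].str.upper(), columns=dataset_cols, dtype=bool)
    for col in dataset_cols:
        parsed = []
        for sym, cell in zip(df["symbol"], df[col]):
            key = str(cell).strip().lower()
            if key not in tokens:
                raise ValueError(
                    f"unknown detection token {cell!r} at row {sym!r}, column {col!r}"
                )
            parsed.append(tokens[key])
        values[col] = parsed
    accs: dict[str, str | None] = {}
    if "accession" in df.columns:
        for sym, acc in zip(df["symbol"].str.upper(), df["accession"]):
            accs[sym] = None if pd.isna(acc) else str(acc)
    groups = {g: tuple(ds) for g, ds in group_config.items()}
    return DetectionMatrix(values=values, accessions=accs, groups=groups)


def is_detected(matrix: DetectionMatrix, protein: str, group: str) -> Detection:
    """Tri-state detection of ``protein`` in a dataset group (union rule)."""
    if group not in matrix.groups:
        raise KeyError(f"undeclared dataset group {group!r}")
    sym = protein.upper()
    if sym not in matrix.values.index:
        return Detection.UNKNOWN
    cols = list(matrix.groups[group])
    return (
        Detection.DETECTED
        if bool(matrix.values.loc[sym, cols].any())
        else Detection.NOT_DETECTED
    )


@dataclass(frozen=True)
class DetectionSummary:
    """Per-group seed detection counts and pairwise set relations.

    ``percents`` are integer percentages of ``declared_size`` truncated toward
    zero (34/48 → 70).  ``difference[(a, b)]`` counts seed proteins detected
    in group *a* but not *b*; ``subset[(a, b)]`` flags a ⊆ b.
    """

    declared_size: int
    counts: dict[str, int]
    percents: dict[str, int]
    detected: dict[str, frozenset[str]]
    difference: dict[tuple[str, str], int]
    subset: dict[tuple[str, str], bool]


def summarize_detection(
    matrix: DetectionMatrix,
    seed: GeneSet,
    groups: Sequence[str] | None = None,
) -> DetectionSummary:
    """Seed-set detection summary per group; unknown counts as not detected."""
    group_names = list(groups) if groups is not None else list(matrix.groups)
    detected: dict[str, frozenset[str]] = {}
    for g in group_names:
        detected[g] = matrix.detected_in_group(g) & seed.symbols
    counts = {g: len(s) for g, s in detected.items()}
    n = seed.declared_size
    percents = {g: int(100 * c / n) for g, c in counts.items()}
    difference = {}
    subset = {}
    for a in group_names:
        for b in group_names:
            if a == b:
                continue
            difference[(a, b)] = len(detected[a] - detected[b])
            subset[(a, b)] = detected[a] <= detected[b]
    return DetectionSummary(
        declared_size=n,
        counts=counts,
        percents=percents,
        detected=detected,
        difference=difference,
        subset=subset,
    )


@dataclass(frozen=True)
class ExpressionFilterResult:
    """Expression-filtered network plus the nodes removed and why."""

    network: InteractionNetwork
    dropped_not_detected: tuple[str, ...]
    dropped_unknown: tuple[str, ...]


def filter_network_by_expression(
    net: InteractionNetwork, matrix: DetectionMatrix, group: str
) -> ExpressionFilterResult:
    """Keep only network nodes detected in ``group``; report the rest.

    Nodes absent from the matrix (tri-state unknown) are dropped like
    not-detected ones but listed separately, since their status is missing
    evidence rather than negative evidence.
    """
    keep, not_det, unknown = [], [], []
    for node in sorted(net.nodes):
        status = is_detected(matrix, node, group)
        if status is Detection.DETECTED:
            keep.append(node)
        elif status is Detection.NOT_DETECTED:
            not_det.append(node)
        else:
            unknown.append(node)
    import networkx as nx

    sub = nx.Graph(net.graph.subgraph(keep))
    return ExpressionFilterResult(
        network=InteractionNetwork(graph=sub),
        dropped_not_detected=tuple(not_det),
        dropped_unknown=tuple(unknown),
    )
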