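"""MHC class II immunopeptidome filtering and restriction profiling.

Immune-epitope database exports mix assay types, hosts, MHC classes and cell
sources.  The pipeline here reproduces a three-step selection of *endogenous*
MHC class II ligands from unmanipulated human B-lineage cells:

1. keep human-host, human-antigen, MHC class II ligand assays;
2. keep only mass-spectrometry elution assays performed on B-lineage cells
   (including EBV-transformed B lymphoblastoid lines, the dominant source in
   practice) without immunization or stimulation protocols;
3. normalize parent-protein accessions so that redundant or obsolete IDs do
   not split one parent across several records.

Filtered records are grouped into *restriction profiles*: one parent protein
with the deduplicated set of MHC class II allele/serotype labels it was
eluted from.  Restriction labels are kept verbatim — serotype labels
("HLA-DR15"), allele pairs ("HLA-DRB1*15:01") and generic class labels
("HLA class II") are different statements, and silently conflating them
would fabricate allele-exclusivity claims.  An explicit allele group is used
for exclusivity queries instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .enrichment import EnrichmentParams, hypergeom_tail_p
from .seed_registry import GeneSet, IdMap

__all__ = [
    "EpitopeAssayRecord",
    "RestrictionProfile",
    "FilterCriteria",
    "FilterResult",
    "ParentSetEnrichment",
    "DR15_ALLELE_GROUP",
    "parse_assays",
    "filter_assays",
    "build_restriction_profiles",
    "exclusive_restriction",
    "parent_set_enrichment",
    "write_profiles",
]

Source = Union[str, Path, IO[str]]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Labels counted as "restricted by HLA-DRB1*15:01-encoded molecules".
#: DR15/DR51 pairs appear because DRB1*15:01 haplotypes co-express DRB5
#: (serologically DR51); the group is configurable per query.
DR15_ALLELE_GROUP = frozenset(
    {"HLA-DR15/DR51", "HLA-DRB1*15:01 (HLA-DR15)", "HLA-DR15"}
)

_MHC_II_TOKENS = {"ii", "class ii", "mhc class ii", "mhc-ii", "mhcii", "2"}
_MHC_I_TOKENS = {"i", "class i", "mhc class i", "mhc-i", "mhci", "1"}
_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n", ""}


@dataclass(frozen=True)
class EpitopeAssayRecord:
    """One ligand-assay row: an eluted peptide, its parent protein and context."""

    epitope_seq: str
    parent_accession: str
    parent_symbol: str | None
    mhc_class: str  # "I" | "II" | "unknown"
    restriction: str
    assay_method: str
    host: str
    antigen_organism: str
    cell_lineage: str
    immunized_or_stimulated: bool
    study_id: str


def _norm_mhc_class(token: object) -> str:
    key = str(token).strip().lower()
    if key in _MHC_II_TOKENS:
        return "II"
    if key in _MHC_I_TOKENS:
        return "I"
    return "unknown"


def parse_assays(source: Source) -> list[EpitopeAssayRecord]:
    """Parse an assay-export TSV into records (one per row).

    Required columns: ``epitope_seq``, ``parent_accession``, ``restriction``,
    ``assay_method``, ``host``, ``antigen_organism``, ``cell_lineage``,
    ``immunized``, ``study_id``; ``parent_symbol`` and ``mhc_class`` are
    optional (unknown class tokens normalize to ``"unknown"``).  Epitopes
    must be over the 20-letter amino-acid alphabet.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    required = [
        "epitope_seq",
        "parent_accession",
        "restriction",
        "assay_method",
        "host",
        "antigen_organism",
        "cell_lineage",
        "immunized",
        "study_id",
    ]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"assay table lacks required column {col!r}")
    records: list[EpitopeAssayRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        seq = str(row.epitope_seq).strip().upper()
        bad = set(seq) - AMINO_ACIDS
        if not seq or bad:
            raise ValueError(
                f"epitope {seq!r} at line {i} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        acc = str(row.parent_accession).strip().upper()
        if not acc:
            raise ValueError(f"missing parent_accession at line {i}")
        restriction = str(row.restriction).strip()
        if not restriction:
            raise ValueError(f"missing MHC restriction at line {i}")
        imm_key = str(row.immunized).strip().lower()
        if imm_key in _TRUE_TOKENS:
            immunized = True
        elif imm_key in _FALSE_TOKENS:
            immunized = False
        else:
            raise ValueError(f"unrecognized immunized flag {row.immunized!r} at line {i}")
        symbol = str(getattr(row, "parent_symbol", "")).strip().upper() or None
        records.append(
            EpitopeAssayRecord(
                epitope_seq=seq,
                parent_accession=acc,
                parent_symbol=symbol,
                mhc_class=_norm_mhc_class(getattr(row, "mhc_class", "")),
                restriction=restriction,
                assay_method=str(row.assay_method).strip(),
                host=str(row.host).strip(),
                antigen_organism=str(row.antigen_organism).strip(),
                cell_lineage=str(row.cell_lineage).strip(),
                immunized_or_stimulated=immunized,
                study_id=str(row.study_id).strip(),
            )
        )
    return records


@dataclass(frozen=True)
class FilterCriteria:
    """Vocabulary-based selection of endogenous B-cell MHC-II elution assays.

    The assay-method and lineage vocabularies are configuration, not claims:
    database exports are free-text, so the defaults cover the common spellings
    and callers extend them as their export requires.  All comparisons are
    case-insensitive.
    """

    ms_elution_methods: frozenset[str] = frozenset(
        {
            "cellular mhc/mass spectrometry",
            "secreted mhc/mass spectrometry",
            "mass spectrometry",
            "ms elution",
        }
    )
    b_lineages: frozenset[str] = frozenset(
        {
            "b lymphocyte",
            "b cell",
            "ebv-transformed b cell",
            "b lymphoblastoid line",
            "b lymphoblastoid cell line",
        }
    )
    human_tokens: frozenset[str] = frozenset({"homo sapiens", "human", "humans"})


@dataclass(frozen=True)
class FilterResult:
    """Kept records plus per-criterion drop counts (first failing criterion).

    Drop counts and the kept count always sum to the input count.
    """

    records: tuple[EpitopeAssayRecord, ...]
    n_input: int
    dropped: dict[str, int]

    @property
    def n_kept(self) -> int:
        return len(self.records)


_CRITERIA_ORDER = (
    "mhc_class",
    "assay_method",
    "host",
    "antigen_organism",
    "cell_lineage",
    "immunized_or_stimulated",
)


def filter_assays(
    records: Iterable[EpitopeAssayRecord],
    criteria: FilterCriteria | None = None,
) -> FilterResult:
    """Keep records satisfying *all* endogenous B-cell MHC-II criteria.

    A dropped record is charged to the first criterion it fails, in the fixed
    order class → method → host → antigen organism → lineage → immunization,
    so the drop counts are an additive decomposition of the losses.
    Order-preserving and idempotent.
    """
    crit = criteria or FilterCriteria()
    kept: list[EpitopeAssayRecord] = []
    dropped = {c: 0 for c in _CRITERIA_ORDER}

    def failing(rec: EpitopeAssayRecord) -> str | None:
        if rec.mhc_class != "II":
            return "mhc_class"
        if rec.assay_method.lower() not in crit.ms_elution_methods:
            return "assay_method"
        if rec.host.lower() not in crit.human_tokens:
            return "host"
        if rec.antigen_organism.lower() not in crit.human_tokens:
            return "antigen_organism"
        if rec.cell_lineage.lower() not in crit.b_lineages:
            return "cell_lineage"
        if rec.immunized_or_stimulated:
            return "immunized_or_stimulated"
        return None

    n = 0
    for rec in records:
        n += 1
        reason = failing(rec)
        if reason is None:
            kept.append(rec)
        else:
            dropped[reason] += 1
    return FilterResult(records=tuple(kept), n_input=n, dropped=dropped)


@dataclass(frozen=True)
class RestrictionProfile:
    """A parent protein and the MHC class II restrictions observed for it."""

    parent_symbol: str | None
    parent_accession: str
    restrictions: frozenset[str]
    n_supporting_records: int
    studies: frozenset[str]

    def __post_init__(self) -> None:
        if not self.restrictions:
            raise ValueError("restriction profile with empty restriction set")


def build_restriction_profiles(
    records: Iterable[EpitopeAssayRecord],
    idmap: IdMap | None = None,
    seed: GeneSet | None = None,
) -> list[RestrictionProfile]:
    """Group filtered records by (normalized) parent accession.

    Accessions are resolved through ``idmap`` first so records under an
    obsolete ID merge with their current parent.  If ``seed`` is given, only
    profiles whose symbol or accession belongs to the seed set are emitted.
    Profiles are sorted by descending restriction-set size then symbol (the
    most promiscuously presented parents first).
    """
    idmap = idmap or IdMap()
    grouped: dict[str, dict] = {}
    for rec in records:
        acc = idmap.resolve(rec.parent_accession)
        g = grouped.setdefault(
            acc, {"symbol": None, "restrictions": set(), "n": 0, "studies": set()}
        )
        if g["symbol"] is None and rec.parent_symbol:
            g["symbol"] = rec.parent_symbol
        g["restrictions"].add(rec.restriction)
        g["n"] += 1
        if rec.study_id:
            g["studies"].add(rec.study_id)
    profiles = [
        RestrictionProfile(
            parent_symbol=g["symbol"],
            parent_accession=acc,
            restrictions=frozenset(g["restrictions"]),
            n_supporting_records=g["n"],
            studies=frozenset(g["studies"]),
        )
        for acc, g in grouped.items()
    ]
    if seed is not None:
        profiles = [
            p
            for p in profiles
            if (p.parent_symbol and p.parent_symbol in seed.symbols)
            or p.parent_accession in seed.accessions
        ]
    return sorted(
        profiles,
        key=lambda p: (-len(p.restrictions), p.parent_symbol or "", p.parent_accession),
    )


def exclusive_restriction(
    profiles: Iterable[RestrictionProfile],
    allele_group: Iterable[str],
) -> list[RestrictionProfile]:
    """Parents whose *entire* restriction set lies within ``allele_group``.

    A parent seen with any label outside the group is not exclusive, even if
    it was also seen with group labels.
    """
    group = {a for a in allele_group}
    if not group:
        raise ValueError("empty allele group")
    out = [
        p
        for p in profiles
        if p.restrictions and p.restrictions <= group
    ]
    return sorted(out, key=lambda p: (p.parent_symbol or "", p.parent_accession))


@dataclass(frozen=True)
class ParentSetEnrichment:
    """Seed enrichment of a parent-protein list against a genome background."""

    n_parents: int
    k_seed: int
    share_percent: float  # 100·k/n, 2 dp
    ef: float  # (k/n)/(K/N), unrounded
    p_value: float
    K: int
    N: int


def parent_set_enrichment(
    parents: Sequence[RestrictionProfile],
    seed: GeneSet,
    params: EnrichmentParams | None = None,
) -> ParentSetEnrichment:
    """Test whether a parent-protein list is enriched in seed genes.

    Membership is matched by gene symbol.  The enrichment factor uses the
    seed population over the genome background (K/N) as its reference ratio
    and the one-sided hypergeometric tail as its p-value.
    """
    if not parents:
        raise ValueError("empty parent-protein list")
    params = params or EnrichmentParams(N=20000)
    n = len(parents)
    parent_symbols = {p.parent_symbol for p in parents if p.parent_symbol}
    k = len(parent_symbols & seed.symbols)
    share = round(100.0 * k / n, 2)
    ef = (k / n) / (params.K / params.N)
    p = hypergeom_tail_p(k, n, params.K, params.N)
    return ParentSetEnrichment(
        n_parents=n,
        k_seed=k,
        share_percent=share,
        ef=ef,
        p_value=p,
        K=params.K,
        N=params.N,
    )


def write_profiles(profiles: Sequence[RestrictionProfile], path: str | Path) -> None:
    """Export profiles as TSV: parent symbol/accession and ``|``-joined labels."""
    df = pd.DataFrame(
        {
            "parent_symbol": [p.parent_symbol for p in profiles],
            "parent_accession": [p.parent_accession for p in profiles],
            "restrictions": ["|".join(sorted(p.restrictions)) for p in profiles],
            "n_supporting_records": [p.n_supporting_records for p in profiles],
        }
    )
    df.to_csv(path, sep="\t", index=False)
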