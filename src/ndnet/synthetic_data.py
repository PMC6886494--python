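"""Seeded synthetic data emulating the three external evidence sources,
plus loaders for the packaged curated tables.

Live interaction, proteome-atlas and epitope databases change between
snapshots and cannot back a reproducible test suite, so every pipeline stage
can instead be exercised on synthetic tables that are pure functions of a
configuration and one integer seed:

* **interactome** — a planted-hub model: each configured hub is wired to an
  exact number of partners, an exact subset of which are seed genes, so
  hub-scan counts are deterministic ground truth; the remaining nodes form
  an Erdős–Rényi background whose seed-connectivity follows the null.
* **detection matrix** — per-group Bernoulli detection, optionally forcing a
  designated subset to be B-cell-only.
* **assay table** — MHC-II elution records whose parent list contains seed
  genes at ρ times the genome base rate K/N, the quantity the parent-set
  enrichment statistic estimates.

Sub-streams are derived by stable hashing of (seed, component name), so
adding a generator never shifts the output of an existing one.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .immunopeptidome import RestrictionProfile
from .proteomics import DetectionMatrix, parse_detection_matrix
from .seed_registry import GeneRef, GeneSet, load_gene_set

__all__ = [
    "SyntheticConfig",
    "generate_interactome",
    "generate_detection_matrix",
    "generate_assay_table",
    "synthetic_seed_gene_set",
    "load_profiles_table",
    "load_seed_gene_set",
    "load_table1_detection",
    "load_table2_hubs",
    "load_table4_profiles",
    "load_table5_hub_profiles",
    "DEFAULT_GROUPS",
]

#: Dataset grouping of the packaged detection table.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "B_cell": ("HPM_B", "blood_B"),
    "DC": ("blood_DC", "MoDC"),
}

DEFAULT_ALLELE_POOL = (
    "HLA class II",
    "HLA-DR",
    "HLA-DQ",
    "HLA-DR1",
    "HLA-DR3",
    "HLA-DQ7.5",
    "HLA-DQ2.5",
    "HLA-DQ2.2",
    "HLA-DR15/DR51",
    "HLA-DRB1*15:01 (HLA-DR15)",
    "HLA-DRB1*04:05 (HLA-DR4)",
    "HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic generators; one integer seed drives them all.

    Defaults mirror the study conditions of the curated analyses: a seed
    population of 48 over a genome of 20 000 coding genes, one planted hub
    with 500 partners of which 20 are seed genes, B-cell/DC detection
    probabilities equal to the observed seed detection rates (34/48, 20/48),
    and a 3523-gene parent list whose seed share is ρ·(48/20000) with
    ρ = 2.6, the unrounded enrichment observed for the curated parent list.
    """

    rng_seed: int = 0
    n_background_genes: int = 2000
    background_edge_prob: float = 0.002
    planted_hubs: tuple[tuple[str, int, int], ...] = (("HUB001", 500, 20),)
    seed_gene_count: int = 48
    detection_probs: Mapping[str, float] = field(
        default_factory=lambda: {"B_cell": 34 / 48, "DC": 20 / 48}
    )
    n_parents: int = 3523
    parent_seed_enrichment: float = 2.6
    immunized_fraction: float = 0.3
    allele_pool: tuple[str, ...] = DEFAULT_ALLELE_POOL
    seed_population: int = 48
    genome_size: int = 20000

    def __post_init__(self) -> None:
        for name, p in [
            ("background_edge_prob", self.background_edge_prob),
            ("immunized_fraction", self.immunized_fraction),
            *[(f"detection_probs[{g}]", p) for g, p in self.detection_probs.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for sym, n, k in self.planted_hubs:
            if not 0 <= k <= n:
                raise ValueError(f"planted hub {sym}: k_seed {k} > n_partners {n}")
        if self.parent_seed_enrichment < 0:
            raise ValueError("parent_seed_enrichment must be >= 0")

    def rng(self, component: str) -> np.random.Generator:
        """Independent, stable sub-stream for one generator component."""
        digest = hashlib.sha256(f"{self.rng_seed}:{component}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "big"))

    @property
    def seed_symbols(self) -> list[str]:
        return [f"ND{i:03d}" for i in range(1, self.seed_gene_count + 1)]

    @property
    def background_symbols(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_background_genes + 1)]


def synthetic_seed_gene_set(cfg: SyntheticConfig) -> GeneSet:
    """The synthetic seed gene set ND001..; accessions are synthesized."""
    members = tuple(
        GeneRef(symbol=s, accession=f"Q{i:05d}")
        for i, s in enumerate(cfg.seed_symbols, start=1)
    )
    return GeneSet(
        name="synthetic_nd_seed", members=members, declared_size=cfg.seed_population
    )


def generate_interactome(cfg: SyntheticConfig) -> tuple[pd.DataFrame, list[str]]:
    """Edge table (generic dialect) with planted hubs plus random background.

    Each planted hub (symbol, n, k) is wired to exactly k seed genes and
    n − k background genes, chosen without replacement.  Background edges are
    drawn independently with ``background_edge_prob`` among the non-hub nodes
    (seed and background genes alike), giving non-hub nodes null-level
    seed-connectivity.  No self-loops are emitted.  Returns the edge table
    and the seed-gene symbol list.
    """
    rng = cfg.rng("interactome")
    seed_syms = cfg.seed_symbols
    bg_syms = cfg.background_symbols
    edges: list[tuple[str, str]] = []
    for sym, n, k in cfg.planted_hubs:
        if k > len(seed_syms):
            raise ValueError(
                f"planted hub {sym} requires {k} seed partners but only "
                f"{len(seed_syms)} seed genes exist"
            )
        if n - k > len(bg_syms):
            raise ValueError(
                f"planted hub {sym} requires {n - k} background partners but "
                f"only {len(bg_syms)} background genes exist"
            )
        seed_part = rng.choice(len(seed_syms), size=k, replace=False)
        bg_part = rng.choice(len(bg_syms), size=n - k, replace=False)
        edges.extend((sym, seed_syms[i]) for i in sorted(seed_part))
        edges.extend((sym, bg_syms[i]) for i in sorted(bg_part))
    # Erdős–Rényi background over non-hub nodes.
    pool = seed_syms + bg_syms
    n_pool = len(pool)
    n_pairs = n_pool * (n_pool - 1) // 2
    if cfg.background_edge_prob > 0 and n_pairs > 0:
        m = int(rng.binomial(n_pairs, cfg.background_edge_prob))
        if m > 0:
            chosen = np.sort(rng.choice(n_pairs, size=m, replace=False))
            # decode linear pair index -> (i, j) with j < i; isqrt keeps it exact
            for idx in chosen:
                idx = int(idx)
                i = (1 + math.isqrt(1 + 8 * idx)) // 2
                j = idx - i * (i - 1) // 2
                edges.append((pool[i], pool[j]))
    df = pd.DataFrame(edges, columns=["symbol_a", "symbol_b"])
    df["evidence"] = "synthetic"
    return df, list(seed_syms)


def generate_detection_matrix(
    cfg: SyntheticConfig,
    proteins: Sequence[str],
    b_only: Iterable[str] = (),
) -> DetectionMatrix:
    """Per-group Bernoulli detection matrix over ``proteins``.

    Datasets are named after the groups (one dataset per group).  Proteins in
    ``b_only`` are forced detected in the ``B_cell`` group and undetected in
    every other group, regardless of the sampled values.
    """
    rng = cfg.rng("detection")
    groups = list(cfg.detection_probs)
    forced = {p.upper() for p in b_only}
    unknown_forced = forced - {p.upper() for p in proteins}
    if unknown_forced:
        raise ValueError(f"b_only proteins not in protein list: {sorted(unknown_forced)}")
    values = pd.DataFrame(index=[p.upper() for p in proteins], columns=groups, dtype=bool)
    for g in groups:
        values[g] = rng.random(len(proteins)) < cfg.detection_probs[g]
    for p in forced:
        for g in groups:
            values.loc[p, g] = g == "B_cell"
    return DetectionMatrix(
        values=values,
        accessions={},
        groups={g: (g,) for g in groups},
    )


def generate_assay_table(cfg: SyntheticConfig, seed: GeneSet) -> pd.DataFrame:
    """MHC-II elution assay table whose parents are seed genes at rate ρ·K/N.

    The number of seed parents is Binomial(n_parents, ρ·K/N) (capped at the
    number of enumerable seed members); the remainder are synthetic parents.
    Each parent receives 1–4 restriction labels from the allele pool, one
    record per label; ``immunized_fraction`` of records are flagged as
    immunization/stimulation experiments so the endogenous-ligand filter has
    something to drop.  All records carry MS-elution methods and B-lineage
    labels.
    """
    rng = cfg.rng("assays")
    p_seed = cfg.parent_seed_enrichment * cfg.seed_population / cfg.genome_size
    if p_seed > 1:
        raise ValueError(
            f"parent_seed_enrichment {cfg.parent_seed_enrichment} implies a "
            f"seed probability {p_seed:.3f} > 1"
        )
    members = list(seed.members)
    n_seed = min(int(rng.binomial(cfg.n_parents, p_seed)), len(members))
    picked = rng.choice(len(members), size=n_seed, replace=False)
    parents: list[tuple[str, str]] = []
    for i in sorted(picked):
        ref = members[i]
        parents.append((ref.symbol, ref.accession or f"Z{i + 1:05d}"))
    for i in range(1, cfg.n_parents - n_seed + 1):
        parents.append((f"PAR{i:05d}", f"P{i:05d}"))
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = []
    for symbol, accession in parents:
        n_restr = int(rng.integers(1, 5))
        labels = rng.choice(len(cfg.allele_pool), size=n_restr, replace=False)
        for lab in sorted(labels):
            peptide = "".join(rng.choice(aa, size=int(rng.integers(13, 18))))
            rows.append(
                {
                    "epitope_seq": peptide,
                    "parent_accession": accession,
                    "parent_symbol": symbol,
                    "mhc_class": "II",
                    "restriction": cfg.allele_pool[lab],
                    "assay_method": "cellular MHC/mass spectrometry",
                    "host": "Homo sapiens",
                    "antigen_organism": "Homo sapiens",
                    "cell_lineage": "EBV-transformed B cell",
                    "immunized": bool(rng.random() < cfg.immunized_fraction),
                    "study_id": f"STUDY{int(rng.integers(1, 20)):02d}",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged curated-table loaders


def _data_path(name: str):
    return resources.files("ndnet.data").joinpath(name)


def load_seed_gene_set() -> GeneSet:
    """The packaged neurodegeneration seed set: 38 members, population 48."""
    with resources.as_file(_data_path("seed_nd_genes.tsv")) as p:
        return load_gene_set(p, name="nd_seed", declared_size=48)


def load_table1_detection() -> DetectionMatrix:
    """Packaged B-cell/DC detection matrix (34 proteins × 4 datasets)."""
    with resources.as_file(_data_path("table1_detection.tsv")) as p:
        return parse_detection_matrix(p, group_config=DEFAULT_GROUPS)


def load_table2_hubs() -> pd.DataFrame:
    """Packaged hub-scan table: partner counts and reported statistics."""
    with resources.as_file(_data_path("table2_hubs.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_profiles_table(path) -> list[RestrictionProfile]:
    """Read a restriction-profile TSV (parent symbol/accession, ``|``-joined labels)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for row in df.itertuples(index=False):
        labels = frozenset(row.restrictions.split("|"))
        profiles.append(
            RestrictionProfile(
                parent_symbol=row.parent_symbol,
                parent_accession=row.parent_accession,
                restrictions=labels,
                n_supporting_records=len(labels),
                studies=frozenset(),
            )
        )
    return profiles


def load_table4_profiles() -> list[RestrictionProfile]:
    """Packaged seed-parent restriction profiles (23 parents)."""
    with resources.as_file(_data_path("table4_profiles.tsv")) as p:
        return load_profiles_table(p)


def load_table5_hub_profiles() -> list[RestrictionProfile]:
    """Packaged hub-parent restriction profiles (8 hubs)."""
    with resources.as_file(_data_path("table5_hub_profiles.tsv")) as p:
        return load_profiles_table(p)
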