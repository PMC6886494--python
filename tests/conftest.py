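"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import combinations

import pandas as pd
import pytest
from hypothesis import settings

from ndnet import immunopeptidome as imm
from ndnet import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seed_set():
    return sd.load_seed_gene_set()


@pytest.fixture(scope="session")
def table1_matrix():
    return sd.load_table1_detection()


@pytest.fixture(scope="session")
def table2_hubs():
    return sd.load_table2_hubs()


@pytest.fixture(scope="session")
def table4_profiles():
    return sd.load_table4_profiles()


@pytest.fixture(scope="session")
def table5_profiles():
    return sd.load_table5_hub_profiles()


def hypergeom_tail_by_enumeration(n: int, K: int, N: int) -> list[float]:
    """P(X >= k) for k = 0..min(n, K), by exhaustive enumeration of draws.

    Counts, over all C(N, n) equally likely draws of n items from a
    population whose first K items are successes, how many draws contain at
    least k successes.  Exact rational arithmetic via integer counts.
    """
    kmax = min(n, K)
    hist = [0] * (kmax + 1)
    for draw in combinations(range(N), n):
        hist[sum(1 for x in draw if x < K)] += 1
    total = math.comb(N, n)
    tails = []
    running = total
    for k in range(kmax + 1):
        tails.append(running / total)
        running -= hist[k]
    return tails


def records_from_frame(df: pd.DataFrame) -> list[imm.EpitopeAssayRecord]:
    """Build assay records straight from a generated table (no file round-trip)."""
    return [
        imm.EpitopeAssayRecord(
            epitope_seq=row.epitope_seq,
            parent_accession=row.parent_accession,
            parent_symbol=row.parent_symbol,
            mhc_class=row.mhc_class,
            restriction=row.restriction,
            assay_method=row.assay_method,
            host=row.host,
            antigen_organism=row.antigen_organism,
            cell_lineage=row.cell_lineage,
            immunized_or_stimulated=bool(row.immunized),
            study_id=row.study_id,
        )
        for row in df.itertuples(index=False)
    ]
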