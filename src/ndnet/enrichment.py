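"""Enrichment statistics: fixed-ratio enrichment factors and exact tests.

The central question throughout is whether a list of genes — the partner set
of a candidate hub protein, or a list of MHC ligand parent proteins — holds
more members of a small seed population than expected.  Two quantities are
reported:

* an **enrichment factor** ``(k/n) / r0``: the observed seed share among the
  n listed genes divided by a fixed reference ratio.  For interactome scans
  the reference ratio is 0.002, the seed population (48) over the number of
  protein-coding genes with retrievable interactors (23 098); for
  genome-background analyses it is K/N with N ≈ 20 000 coding genes.
* a one-sided exact p-value: the Fisher exact enrichment test, which for a
  2×2 table with fixed margins equals the hypergeometric upper tail
  P(X ≥ k) for X ~ Hypergeometric(N, K, n).

Families of tests are corrected with Bonferroni (the default here) or
Benjamini-Hochberg; both accept an explicit family size m so a correction
can span more tests than the list passed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .seed_registry import GeneSet

__all__ = [
    "EnrichmentParams",
    "HubResult",
    "TermResult",
    "BACKGROUND_INTERACTOME",
    "BACKGROUND_GENOME",
    "REFERENCE_RATIO",
    "enrichment_factor",
    "hypergeom_tail_p",
    "adjust_pvalues",
    "scan_candidate_hubs",
    "term_enrichment",
    "load_gmt",
    "write_hub_table",
]

#: Protein-coding genes with retrievable interactors in the interaction database.
BACKGROUND_INTERACTOME = 23098
#: Approximate number of human protein-coding genes.
BACKGROUND_GENOME = 20000
#: Fixed reference ratio for hub-partner enrichment factors (≈ 48 / 23098).
REFERENCE_RATIO = 0.002


@dataclass(frozen=True)
class EnrichmentParams:
    """Population sizes, reference ratio and correction for enrichment tests."""

    K: int = 48
    N: int = BACKGROUND_INTERACTOME
    r0: float = REFERENCE_RATIO
    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.r0 < 1:
            raise ValueError(f"reference ratio r0 must be in (0, 1), got {self.r0}")
        if not 0 < self.K <= self.N:
            raise ValueError(f"require 0 < K <= N, got K={self.K}, N={self.N}")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


def enrichment_factor(k: int, n: int, r0: float = REFERENCE_RATIO) -> float:
    """Observed ratio k/n over the reference ratio ``r0``, unrounded.

    Reporting layers round half-up to 2 decimals; all arithmetic here is
    exact so that ``enrichment_factor(k, n, r0) * r0 * n == k`` to machine
    precision.
    """
    if n <= 0:
        raise ValueError("list size n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if r0 <= 0:
        raise ValueError("reference ratio must be positive")
    return (k / n) / r0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal-style half-up rounding used for displayed enrichment factors."""
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


def hypergeom_tail_p(k: int, n: int, K: int, N: int, two_sided: bool = False) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n): one-sided enrichment p.

    Equals the one-sided (greater) Fisher exact p-value for the 2×2 table
    with margins (n, N−n) × (K, N−K).  ``two_sided=True`` instead sums all
    outcomes with probability ≤ the observed one (the usual two-sided Fisher
    convention); enrichment analyses use the one-sided default.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent population parameters n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0 and not two_sided:
        return 1.0
    if not two_sided:
        return float(hypergeom.sf(k - 1, N, K, n))
    pk = hypergeom.pmf(k, N, K, n)
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    return float(min(1.0, pmf[pmf <= pk * (1 + 1e-12)].sum()))


def adjust_pvalues(
    p: Sequence[float], method: str = "bonferroni", m: int | None = None
) -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m·p) elementwise.  ``bh``: Benjamini-Hochberg
    step-up, p_adj(i) = min_{j ≥ i} p_(j)·m/j in sorted order.  ``m``
    defaults to the list length and may be larger (a family wider than the
    reported list).
    """
    p = list(p)
    if not p:
        return []
    for x in p:
        if not 0 < x <= 1:
            raise ValueError(f"p-value outside (0, 1]: {x}")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than number of p-values {len(p)}")
    if method == "bonferroni":
        return [min(1.0, m * x) for x in p]
    if method != "bh":
        raise ValueError(f"unknown correction method {method!r}")
    order = np.argsort(p, kind="stable")
    adj = np.empty(len(p))
    running = 1.0
    for rank in range(len(p) - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return [float(min(1.0, x)) for x in adj]


@dataclass(frozen=True)
class HubResult:
    """A candidate hub: partner counts, enrichment factor and exact p-values."""

    symbol: str
    n_partners: int
    k_seed: int
    ef: float
    p_raw: float
    p_adj: float


def scan_candidate_hubs(
    partner_index: Mapping[str, Iterable[str]],
    seed: GeneSet,
    params: EnrichmentParams | None = None,
    min_seed_partners: int = 10,
    family_size: int | None = None,
) -> list[HubResult]:
    """Screen candidate hubs by seed-partner count and test each for enrichment.

    Candidates are entries of ``partner_index`` with *strictly more than*
    ``min_seed_partners`` seed partners.  Each candidate gets an enrichment
    factor against ``params.r0`` and a one-sided hypergeometric p-value with
    population (K, N); p-values are corrected across the candidate family
    (``family_size`` overrides the natural family = number of candidates).
    Results are sorted by adjusted p ascending, ties by enrichment factor
    descending then symbol.
    """
    params = params or EnrichmentParams()
    seed_symbols = seed.symbols
    candidates: list[tuple[str, int, int]] = []
    for hub, partners in partner_index.items():
        pset = {p.upper() for p in partners}
        if hub.upper() in pset:
            raise ValueError(
                f"hub {hub!r} appears in its own partner set; self-interactions "
                "must be excluded upstream"
            )
        k = len(pset & seed_symbols)
        if k > min_seed_partners:
            candidates.append((hub.upper(), len(pset), k))
    if not candidates:
        return []
    efs = [enrichment_factor(k, n, params.r0) for _, n, k in candidates]
    p_raw = [
        hypergeom_tail_p(k, n, params.K, params.N) for _, n, k in candidates
    ]
    p_adj = adjust_pvalues(p_raw, method=params.correction, m=family_size)
    results = [
        HubResult(symbol=s, n_partners=n, k_seed=k, ef=ef, p_raw=pr, p_adj=pa)
        for (s, n, k), ef, pr, pa in zip(candidates, efs, p_raw, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_adj, -r.ef, r.symbol))


@dataclass(frozen=True)
class TermResult:
    term: str
    overlap: int
    ef: float
    p_raw: float
    p_adj: float


def term_enrichment(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: int,
) -> list[TermResult]:
    """Generic term-over-representation test for a query gene list.

    For each term with gene set T: overlap with the query, enrichment factor
    (overlap/|query|) / (|T|/background), hypergeometric upper-tail p for
    drawing |query| genes from a background of ``background``, BH-adjusted
    across terms.  Results sorted by adjusted p, then term.
    """
    query_set = {q.upper() for q in query}
    if not query_set:
        raise ValueError("empty query gene list")
    if not annotation:
        raise ValueError("empty term annotation map")
    n = len(query_set)
    if background < n:
        raise ValueError("background smaller than query list")
    rows = []
    for term, genes in annotation.items():
        tset = {g.upper() for g in genes}
        if background < len(tset):
            raise ValueError(f"background smaller than term {term!r}")
        k = len(tset & query_set)
        ef = (k / n) / (len(tset) / background) if tset else 0.0
        p = hypergeom_tail_p(k, n, len(tset), background)
        rows.append((term, k, ef, p))
    p_adj = adjust_pvalues([r[3] for r in rows], method="bh")
    results = [
        TermResult(term=t, overlap=k, ef=ef, p_raw=p, p_adj=pa)
        for (t, k, ef, p), pa in zip(rows, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.term))


def load_gmt(source: Union[str, Path, IO[str]]) -> dict[str, set[str]]:
    """Read a GMT annotation file: term, description, then member symbols."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    annotation: dict[str, set[str]] = {}
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        annotation[parts[0]] = {g.upper() for g in parts[2:] if g}
    if not annotation:
        raise ValueError("empty GMT annotation file")
    return annotation


def write_hub_table(results: Sequence[HubResult], path: str | Path) -> None:
    """Export hub-scan results as TSV with displayed (2-dp) enrichment factors."""
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in results],
            "n_partners": [r.n_partners for r in results],
            "k_seed": [r.k_seed for r in results],
            "ef": [round_half_up(r.ef) for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
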