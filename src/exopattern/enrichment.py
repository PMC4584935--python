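"""Hypergeometric over-representation with BH FDR, plus a family contrast.

For a query gene set of size ``n`` drawn from a universe of ``N`` genes, a
term annotating ``K`` universe genes, and an observed overlap ``k``, the
enrichment p-value is the upper hypergeometric tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

adjusted across terms by Benjamini–Hochberg step-up.  The universe defaults
to all genes carrying any qualifying variant in the cohort (enrichment
conclusions are universe-sensitive, so callers can and should override it
when a better universe is known).  Terms annotating fewer than
``min_term_size`` universe genes are excluded by default.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .titv import Fisher2x2Result, fisher_exact_2x2

log = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (term, description, member genes...)."""
    terms: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"{path}: line {i}: need term, description, >=1 gene")
        terms[parts[0]] = [g for g in parts[2:] if g]
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            fh.write("\t".join([term, description, *terms[term]]) + "\n")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise EnrichmentError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_set(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Per-term over-representation of ``query`` against GMT annotations.

    Returns a DataFrame (term, k, K, n, N, p, q, significant) sorted by q
    then p.  Query genes outside the universe are dropped with a warning;
    term memberships are intersected with the universe.
    """
    universe_set = set(universe)
    if not universe_set:
        raise EnrichmentError("empty universe")
    query_set = set(query)
    if not query_set:
        raise EnrichmentError("empty query gene set")
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
        query_set &= universe_set
        if not query_set:
            raise EnrichmentError("no query genes remain inside the universe")

    N, n = len(universe_set), len(query_set)
    rows = []
    for term in sorted(annotations):
        members = set(annotations[term]) & universe_set
        K = len(members)
        if K < min_term_size:
            log.debug("term %s excluded (K=%d < %d)", term, K, min_term_size)
            continue
        k = len(members & query_set)
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_upper(k, K, n, N)}
        )
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "significant"])
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] < alpha
    return result.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)


def family_representation_test(
    family: Iterable[str],
    affected: Iterable[str],
    universe: Iterable[str],
    reference_family: Iterable[str],
) -> Fisher2x2Result:
    """Fisher contrast of affected-gene counts between two gene families.

    Rows: (affected, unaffected); columns: (family, reference family).  Both
    families must be disjoint subsets of the universe.
    """
    universe_set = set(universe)
    fam = set(family) & universe_set
    ref = set(reference_family) & universe_set
    if not fam or not ref:
        raise EnrichmentError("both families must be nonempty within the universe")
    if fam & ref:
        raise EnrichmentError("families must be disjoint")
    hit = set(affected)
    table = [
        [len(fam & hit), len(ref & hit)],
        [len(fam - hit), len(ref - hit)],
    ]
    return fisher_exact_2x2(table)
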