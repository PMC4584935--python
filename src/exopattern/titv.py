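"""Substitution-spectrum accounting and the novelty-stratified Ti/Tv test.

An elevated fraction of A<->G / C<->T transitions among novel SNVs relative
to cataloged SNVs is the editing signature this module quantifies: enzymatic
RNA/DNA editing (APOBEC/AID-type cytidine deamination) produces transition
excess, so novel substitutions arising from editing shift the two-class
transition/transversion balance.  The signal is tested with a two-sided
Fisher exact test on the (transitions, transversions) x (novel, known) 2x2
table.  Strand is ignored: alleles are counted as written, and the natural
Ti/Tv classes already pool the complementary substitution pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .variants import (
    AnnotatedVariant,
    VariantCatalog,
    VariantError,
    classify_novelty,
    NOVEL_AF_THRESHOLD,
)

#: display order used for substitution matrices
BASE_ORDER = ("A", "C", "T", "G")
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class TiTvError(ValueError):
    pass


@dataclass
class TiTvStratumResult:
    stratum: str
    transitions: int
    transversions: int

    @property
    def fraction(self) -> float:
        return self.transitions / (self.transitions + self.transversions)


@dataclass
class Fisher2x2Result:
    table: np.ndarray
    odds_ratio: float  # sample (cross-product) odds ratio
    p_two_sided: float
    odds_ratio_kind: str = "sample"


def substitution_matrix(snvs: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """4x4 ref x alt substitution counts (diagonal structurally zero)."""
    counts = pd.DataFrame(
        np.zeros((4, 4), dtype=int), index=list(BASE_ORDER), columns=list(BASE_ORDER)
    )
    counts.index.name = "ref"
    counts.columns.name = "alt"
    for v in snvs:
        if v.var_class != "SNV":
            raise TiTvError(f"non-SNV {v.key} in substitution spectrum")
        counts.loc[v.ref, v.alt] += 1
    return counts


def read_substitution_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df = df.loc[list(BASE_ORDER), list(BASE_ORDER)].astype(int)
    df.index.name, df.columns.name = "ref", "alt"
    return df


def load_example_substitution_matrix() -> pd.DataFrame:
    """Bundled substitution counts among shared somatic SNVs.

    Printed counts from a familial colorectal-adenocarcinoma exome study's
    inferred identical-by-state somatic SNVs (two tumors vs three related
    controls); used as a worked example and fixture.
    """
    ref = resources.files("exopattern").joinpath("data/ibs_somatic_substitutions.tsv")
    with resources.as_file(ref) as path:
        return read_substitution_matrix(path)


def transition_fraction(
    matrix: pd.DataFrame, stratum: str = "all"
) -> TiTvStratumResult:
    """Split a substitution matrix into transition and transversion counts."""
    ti = tv = 0
    for ref in BASE_ORDER:
        for alt in BASE_ORDER:
            if ref == alt:
                continue
            c = int(matrix.loc[ref, alt])
            if (ref, alt) in TRANSITIONS:
                ti += c
            else:
                tv += c
    if ti + tv == 0:
        raise TiTvError("empty spectrum")
    return TiTvStratumResult(stratum, ti, tv)


def fisher_exact_2x2(table) -> Fisher2x2Result:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided p sums hypergeometric point probabilities no larger than
    the observed table's.  A zero row or column margin carries no
    information: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise TiTvError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise TiTvError("table must hold non-negative integers")
        t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1")
        oddsr = np.nan
        p = 1.0
    else:
        oddsr, p = fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    sample_or = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return Fisher2x2Result(table=t, odds_ratio=float(sample_or),
                           p_two_sided=float(min(p, 1.0)))


def stratified_titv_test(
    callset,
    catalog: VariantCatalog,
    af_threshold: float = NOVEL_AF_THRESHOLD,
) -> tuple[TiTvStratumResult, TiTvStratumResult, Fisher2x2Result]:
    """Novel-vs-known transition-excess test for one callset.

    Returns the per-stratum Ti/Tv results (novel, known) and the Fisher test
    on the (transitions, transversions) x (novel, known) table.
    """
    strata: dict[str, list[AnnotatedVariant]] = {"novel": [], "known": []}
    for v in callset.snvs():
        strata[classify_novelty(v, catalog, af_threshold)].append(v)
    for name, variants in strata.items():
        if not variants:
            raise TiTvError(f"stratum {name!r} holds no SNVs")
    results = {
        name: transition_fraction(substitution_matrix(variants), stratum=name)
        for name, variants in strata.items()
    }
    table = np.array(
        [
            [results["novel"].transitions, results["known"].transitions],
            [results["novel"].transversions, results["known"].transversions],
        ]
    )
    return results["novel"], results["known"], fisher_exact_2x2(table)


def titv_table(novel: TiTvStratumResult, known: TiTvStratumResult,
               fisher: Fisher2x2Result) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "stratum": [novel.stratum, known.stratum],
            "transitions": [novel.transitions, known.transitions],
            "transversions": [novel.transversions, known.transversions],
            "fraction": [novel.fraction, known.fraction],
        }
    )
    df.attrs["fisher_p"] = fisher.p_two_sided
    return df
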