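"""Identity-by-state somatic variant inference by set logic.

Without germline sequencing of the tumor donors, shared somatic variants are
inferred indirectly: a variant is called IBS-somatic when it is present in
*both* tumor callsets, matches at least one entry of a positive somatic
catalog (cancer somatic calls from an external cohort), and is absent from
*every* related control callset (the controls act as germline references).

    result = (intersection of tumor keys) & catalog keys - (union of control keys)

Matching is by exact normalized (chrom, pos, ref, alt) key by default; a
position-only mode (``match="position"``) is available because external
somatic catalogs sometimes differ in allele representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .variants import SampleCallset, VariantCatalog, VariantError, VariantKey

log = logging.getLogger(__name__)


class IBSError(ValueError):
    pass


@dataclass
class IBSCallResult:
    variant_keys: frozenset[VariantKey]
    genes: frozenset[str]
    provenance: dict[VariantKey, list[VariantKey]]  # key -> matching catalog entries
    stages: dict[str, int]

    def to_frame(self, tumors: Sequence[SampleCallset]) -> pd.DataFrame:
        lookup = {}
        for t in tumors:
            for key in self.variant_keys:
                if key in t and key not in lookup:
                    lookup[key] = t.variants[key]
        rows = [
            {
                "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                "genes": ",".join(lookup[k].genes) if k in lookup else "",
            }
            for k in sorted(self.variant_keys)
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genes"])


def infer_ibs_somatic(
    tumors: Sequence[SampleCallset],
    controls: Sequence[SampleCallset],
    catalog: VariantCatalog,
    match: str = "exact",
) -> IBSCallResult:
    """Run the tumor-shared / catalog-matched / control-free filter."""
    if len(tumors) < 2:
        raise IBSError("need at least two tumor callsets")
    if len(controls) < 1:
        raise IBSError("need at least one control callset")
    if match not in ("exact", "position"):
        raise IBSError(f"unknown match mode {match!r}")
    if len(catalog) == 0:
        warnings.warn("positive somatic catalog is empty; result will be empty")

    shared = set.intersection(*(t.keys() for t in tumors))

    provenance: dict[VariantKey, list[VariantKey]] = {}
    if match == "exact":
        matched = {k for k in shared if k in catalog}
        provenance = {k: [k] for k in matched}
    else:
        by_pos: dict[tuple[str, int], list[VariantKey]] = {}
        for entry in catalog.keys():
            by_pos.setdefault((entry[0], entry[1]), []).append(entry)
        matched = set()
        for k in shared:
            hits = by_pos.get((k[0], k[1]))
            if hits:
                matched.add(k)
                provenance[k] = sorted(hits)

    control_keys = set().union(*(c.keys() for c in controls))
    final = matched - control_keys
    provenance = {k: provenance[k] for k in final}

    genes: set[str] = set()
    for t in tumors:
        for k in final:
            if k in t:
                genes.update(t.variants[k].genes)
    stages = {
        "tumor_shared": len(shared),
        "catalog_matched": len(matched),
        "after_controls": len(final),
        "genes": len(genes),
    }
    log.info("IBS stages: %s", stages)
    return IBSCallResult(
        variant_keys=frozenset(final), genes=frozenset(genes),
        provenance=provenance, stages=stages,
    )


def ibs_stage_report(result: IBSCallResult) -> pd.DataFrame:
    """Per-stage count table of the IBS filter."""
    order = ["tumor_shared", "catalog_matched", "after_controls", "genes"]
    return pd.DataFrame(
        {"stage": order, "count": [result.stages[s] for s in order]}
    )
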