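"""Synthetic five-sample family cohort generator with planted ground truth.

Emulates the study design the analysis modules assume: two tumor samples
(``P17``, ``P61``) and three related controls (``P39``, ``P26``, ``P84``)
drawn from a small two-branch pedigree.  Germline variants are gene-dropped
through the pedigree (each founder variant transmitted with probability 1/2
per meiosis) so related samples share identical-by-descent variants; tumors
additionally receive somatic SNVs and INDELs, a configurable fraction of
which is shared by both tumors (the identical-by-state signal the inference
stage recovers).

Planted structure, recorded in a :class:`TruthBundle`:

* shared somatic variant keys, partially mirrored into a positive somatic
  catalog (``catalog_overlap_prob``),
* an elevated transition fraction among novel SNV substitutions
  (``novel_transition_prob`` = 0.825 vs ``known_transition_prob`` = 0.68,
  the editing signature),
* a tumor INDEL burden excess (``indel_burden_multiplier``),
* gene-set terms enriched in tumor exonic-INDEL targets only,
* one high-degree hub gene in the interaction network, preferentially wired
  to genes carrying tumor nonsynonymous variants.

All randomness flows from the single ``seed``; with a fixed seed the written
bundle is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .variants import (
    AnnotatedVariant,
    SampleCallset,
    VariantCatalog,
    VariantError,
    VariantKey,
    write_vcf,
)

_TI_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = "ACGT"

# region label -> probability, per variant class; roughly exome-like
_SNV_REGIONS = {
    "exonic": 0.40, "intronic": 0.46, "UTR3": 0.045, "UTR5": 0.022,
    "splicing": 0.006, "upstream": 0.023, "downstream": 0.022,
    "intergenic": 0.022,
}
_INDEL_REGIONS = {
    "exonic": 0.055, "intronic": 0.75, "UTR3": 0.058, "UTR5": 0.016,
    "splicing": 0.004, "upstream": 0.05, "downstream": 0.045,
    "intergenic": 0.022,
}
_SNV_EXFUNC = {"nonsynonymous": 0.55, "synonymous": 0.40,
               "stopgain": 0.03, "stoploss": 0.02}
_INDEL_EXFUNC = {"frameshift": 0.60, "nonframeshift": 0.35, "unknown": 0.05}

DEFAULT_PHENOTYPES = {
    "P17": "tumor", "P61": "tumor", "P39": "control",
    "P26": "control", "P84": "control",
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Sizes default to roughly one tenth of the per-sample burdens an exome at
    ~100x coverage yields, which keeps a full simulated study under a couple
    of seconds without changing any of the planted contrasts (the paper-level
    absolute burdens are platform/coverage-dependent scale knobs).
    """

    n_genes: int = 1500
    n_terms: int = 50
    germline_per_sample: int = 6000
    indel_fraction: float = 0.25
    tumor_somatic_count: int = 600
    somatic_share_prob: float = 0.6
    catalog_overlap_prob: float = 0.8
    catalog_background: int = 500
    novel_transition_prob: float = 0.825
    known_transition_prob: float = 0.68
    indel_burden_multiplier: float = 2.0
    somatic_exonic_prob: float = 0.30
    common_variant_fraction: float = 0.5
    known_snv_prob: float = 0.80
    known_indel_prob: float = 0.30
    planted_terms: tuple[str, ...] = ("TERM_PLANTED_1", "TERM_PLANTED_2")
    planted_pool_size: int = 30
    planted_targeting: float = 0.6
    hub_gene: str = "HUB1"
    hub_query_prob: float = 0.4
    hub_background_prob: float = 0.02
    er_mean_degree: float = 6.0
    sample_phenotypes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.somatic_share_prob, self.catalog_overlap_prob,
                 self.novel_transition_prob, self.known_transition_prob,
                 self.somatic_exonic_prob, self.known_snv_prob,
                 self.known_indel_prob, self.planted_targeting,
                 self.hub_query_prob, self.hub_background_prob,
                 self.indel_fraction, self.common_variant_fraction)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if min(self.n_genes, self.n_terms, self.germline_per_sample,
               self.tumor_somatic_count) <= 0:
            raise ValueError("counts must be positive")
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.n_terms < len(self.planted_terms):
            raise ValueError("n_terms smaller than number of planted terms")
        phenos = sorted(self.sample_phenotypes.values())
        if phenos.count("tumor") != 2 or phenos.count("control") != 3:
            raise ValueError(
                "pedigree must map exactly 2 tumor and 3 control samples"
            )

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Reduced-size conditions used for repeated-simulation studies."""
        base = dict(
            n_genes=400, n_terms=40, germline_per_sample=1200,
            tumor_somatic_count=150, catalog_background=200, seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthBundle:
    """Ground truth recorded at generation time for recovery tests."""

    shared_somatic_keys: set[VariantKey]
    planted_terms: tuple[str, ...]
    hub_gene: str
    phenotypes: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "shared_somatic_keys": sorted(
                    list(k) for k in self.shared_somatic_keys
                ),
                "planted_terms": list(self.planted_terms),
                "hub_gene": self.hub_gene,
                "phenotypes": self.phenotypes,
            },
            indent=1,
        )


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: CohortConfig
    callsets: list[SampleCallset]
    known_catalog: VariantCatalog
    somatic_catalog: VariantCatalog
    annotations: dict[str, list[str]]
    universe: list[str]
    edges: list[tuple[str, str]]
    truth: TruthBundle
    somatic_keys: dict[str, set[VariantKey]] = field(default_factory=dict)

    def callset(self, sample_id: str) -> SampleCallset:
        return next(cs for cs in self.callsets if cs.sample_id == sample_id)

    @property
    def tumors(self) -> list[SampleCallset]:
        return [cs for cs in self.callsets if cs.phenotype == "tumor"]

    @property
    def controls(self) -> list[SampleCallset]:
        return [cs for cs in self.callsets if cs.phenotype == "control"]


def _choice(rng: np.random.Generator, dist: dict[str, float]) -> str:
    labels = list(dist)
    p = np.asarray([dist[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


class _VariantFactory:
    """Draws annotated variants with globally unique keys."""

    def __init__(self, config: CohortConfig, rng: np.random.Generator,
                 genes: list[str], planted_pool: list[str]):
        self.cfg = config
        self.rng = rng
        self.genes = genes
        self.planted_pool = planted_pool
        self.used: set[VariantKey] = set()
        self._rs = 0
        # deterministic gene -> (chrom, window start) layout
        self.layout = {
            g: (f"chr{(i % 22) + 1}", 1 + (i // 22) * 200_000)
            for i, g in enumerate(genes)
        }
        self.layout[config.hub_gene] = ("chr23", 1)  # hub never mutated

    def _position(self, gene: str) -> tuple[str, int]:
        chrom, start = self.layout[gene]
        return chrom, int(start + self.rng.integers(0, 100_000))

    def _snv_alleles(self, transition: bool) -> tuple[str, str]:
        ref = _BASES[self.rng.integers(4)]
        if transition:
            return ref, _TI_PARTNER[ref]
        return ref, _TV_PARTNERS[ref][self.rng.integers(2)]

    def _indel_alleles(self) -> tuple[str, str]:
        anchor = _BASES[self.rng.integers(4)]
        tail = "".join(_BASES[i] for i in self.rng.integers(0, 4, int(self.rng.integers(1, 6))))
        if self.rng.random() < 0.5:
            return anchor, anchor + tail  # insertion
        return anchor + tail, anchor  # deletion

    def draw(self, var_class: str, novel: bool, somatic: bool = False,
             known_catalog: Optional[VariantCatalog] = None,
             af_range: tuple[float, float] = (0.02, 0.5)) -> AnnotatedVariant:
        cfg = self.cfg
        if var_class == "SNV":
            p_ti = cfg.novel_transition_prob if novel else cfg.known_transition_prob
            ref, alt = self._snv_alleles(self.rng.random() < p_ti)
            regions = _SNV_REGIONS
        else:
            ref, alt = self._indel_alleles()
            regions = dict(_INDEL_REGIONS)
            if somatic:
                # tumor somatic INDELs hit coding sequence more often and
                # preferentially land in planted-term gene pools
                regions["exonic"] = cfg.somatic_exonic_prob
                regions["splicing"] = 0.01
                regions["intronic"] = 0.50
                regions["UTR3"], regions["UTR5"] = 0.08, 0.03
                regions["upstream"], regions["downstream"] = 0.04, 0.03
                regions["intergenic"] = 0.01
        region = _choice(self.rng, regions)
        if (somatic and var_class == "INDEL" and region in ("exonic", "splicing")
                and self.planted_pool and self.rng.random() < cfg.planted_targeting):
            gene = self.planted_pool[self.rng.integers(len(self.planted_pool))]
        else:
            gene = self.genes[self.rng.integers(len(self.genes))]
        for _ in range(1000):
            chrom, pos = self._position(gene)
            key = (chrom, pos, ref, alt)
            if key not in self.used:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a unique variant key")
        self.used.add(key)
        exfunc = None
        if region == "exonic":
            exfunc = _choice(
                self.rng, _SNV_EXFUNC if var_class == "SNV" else _INDEL_EXFUNC
            )
        elif region == "splicing":
            exfunc = "unknown"
        score = None
        if exfunc == "nonsynonymous":
            score = float(self.rng.beta(4, 2) if somatic else self.rng.beta(2, 3))
        known_id, af = None, None
        if not novel:
            self._rs += 1
            known_id = f"rs{self._rs:07d}"
            af = float(self.rng.uniform(*af_range))
            if known_catalog is not None:
                known_catalog.add(key, af)
        return AnnotatedVariant(
            chrom, pos, ref, alt, region=region, exonic_function=exfunc,
            genes=(gene,), known_id=known_id, pop_af=af,
            deleterious_score=score,
        )

    def fresh_key(self) -> VariantKey:
        """A key guaranteed not to belong to any generated variant."""
        while True:
            chrom = f"chr{self.rng.integers(1, 23)}"
            pos = int(self.rng.integers(1, 50_000_000))
            ref = _BASES[self.rng.integers(4)]
            alt = _TI_PARTNER[ref] if self.rng.random() < 0.7 else \
                _TV_PARTNERS[ref][self.rng.integers(2)]
            key = (chrom, pos, ref, alt)
            if key not in self.used:
                self.used.add(key)
                return key


def simulate_study(config: CohortConfig) -> StudyBundle:
    """Run the full generator: cohort, catalogs, annotations, and network."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    if config.hub_gene in genes:
        raise ValueError("hub gene collides with simulated gene symbols")

    # planted term pools: disjoint random gene subsets, fixed before the cohort
    n_pool = config.planted_pool_size * len(config.planted_terms)
    pool_genes = [genes[i] for i in rng.choice(config.n_genes, size=min(n_pool, config.n_genes), replace=False)]
    pools = {
        term: pool_genes[i * config.planted_pool_size:(i + 1) * config.planted_pool_size]
        for i, term in enumerate(config.planted_terms)
    }
    flat_pool = [g for term in config.planted_terms for g in pools[term]]

    factory = _VariantFactory(config, rng, genes, flat_pool)
    known_catalog = VariantCatalog()

    # ---- germline: shared common-variant pool + founder-private variants ---
    # real exomes share most of their variants through the population; the
    # common pool makes unrelated samples overlap (identity by state) while
    # founder-private variants carry the identity-by-descent signal
    n_common = round(config.germline_per_sample * config.common_variant_fraction * 2)
    common_pool = []
    for _ in range(n_common):
        is_indel = rng.random() < config.indel_fraction
        common_pool.append(
            factory.draw("INDEL" if is_indel else "SNV", novel=False,
                         known_catalog=known_catalog, af_range=(0.05, 0.95))
        )
    n_private = max(0, config.germline_per_sample - round(n_common * 0.5))

    def founder_pool() -> list[AnnotatedVariant]:
        carried = [v for v in common_pool if rng.random() < v.pop_af]
        out = []
        for _ in range(n_private):
            is_indel = rng.random() < config.indel_fraction
            var_class = "INDEL" if is_indel else "SNV"
            known_p = config.known_indel_prob if is_indel else config.known_snv_prob
            novel = rng.random() >= known_p
            out.append(factory.draw(var_class, novel, known_catalog=known_catalog))
        return carried + out

    founders = {name: founder_pool() for name in ("A1", "A2", "S1", "S2", "F84")}

    def drop(parent: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
        mask = rng.random(len(parent)) < 0.5
        return [v for v, m in zip(parent, mask) if m]

    def child(p: list[AnnotatedVariant], q: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
        seen: dict[VariantKey, AnnotatedVariant] = {}
        for v in drop(p) + drop(q):
            seen.setdefault(v.key, v)
        return list(seen.values())

    b1 = child(founders["A1"], founders["A2"])
    b2 = child(founders["A1"], founders["A2"])
    germline = {
        "P61": child(b1, founders["S1"]),
        "P39": child(b1, founders["S1"]),
        "P17": child(b2, founders["S2"]),
        "P26": child(b2, founders["S2"]),
        "P84": list(founders["F84"]),
    }

    # ---- tumor somatic variants -------------------------------------------
    n_shared_snv = round(config.tumor_somatic_count * config.somatic_share_prob)
    n_private_snv = config.tumor_somatic_count - n_shared_snv
    n_som_indel = round(
        config.germline_per_sample * config.indel_fraction
        * max(config.indel_burden_multiplier - 1.0, 0.0)
    )
    n_shared_indel = round(n_som_indel * config.somatic_share_prob)
    n_private_indel = n_som_indel - n_shared_indel

    shared_somatic = (
        [factory.draw("SNV", True, somatic=True) for _ in range(n_shared_snv)]
        + [factory.draw("INDEL", True, somatic=True) for _ in range(n_shared_indel)]
    )
    tumor_ids = sorted(s for s, ph in config.sample_phenotypes.items() if ph == "tumor")
    private_somatic = {
        t: [factory.draw("SNV", True, somatic=True) for _ in range(n_private_snv)]
        + [factory.draw("INDEL", True, somatic=True) for _ in range(n_private_indel)]
        for t in tumor_ids
    }

    callsets = []
    for sample_id in sorted(config.sample_phenotypes):
        phenotype = config.sample_phenotypes[sample_id]
        cs = SampleCallset(sample_id, phenotype)
        for v in germline[sample_id]:
            cs.add(v)
        if phenotype == "tumor":
            for v in shared_somatic + private_somatic[sample_id]:
                cs.add(v)
        callsets.append(cs)

    # ---- positive somatic catalog -----------------------------------------
    somatic_catalog = VariantCatalog()
    for v in shared_somatic:
        if rng.random() < config.catalog_overlap_prob:
            somatic_catalog.add(v.key)
    for t in tumor_ids:
        for v in private_somatic[t]:
            if rng.random() < config.catalog_overlap_prob:
                somatic_catalog.add(v.key)
    for _ in range(config.catalog_background):
        somatic_catalog.add(factory.fresh_key())

    # ---- term annotations ---------------------------------------------------
    annotations: dict[str, list[str]] = {}
    planted = set(config.planted_terms)
    for i in range(config.n_terms):
        term = f"TERM{i + 1:04d}"
        size = int(rng.integers(10, 80))
        members = sorted(
            genes[j] for j in rng.choice(config.n_genes, size=min(size, config.n_genes), replace=False)
        )
        annotations[term] = members
    for term in config.planted_terms:
        annotations[term] = sorted(pools[term])

    # ---- interaction network -----------------------------------------------
    tumor_nonsyn = sorted({
        g
        for t in tumor_ids
        for v in next(c for c in callsets if c.sample_id == t)
        if v.var_class == "SNV" and v.exonic_function == "nonsynonymous"
        for g in v.genes
    })
    edges = _simulate_edges(config, rng, genes, tumor_nonsyn)

    truth = TruthBundle(
        shared_somatic_keys={v.key for v in shared_somatic},
        planted_terms=config.planted_terms,
        hub_gene=config.hub_gene,
        phenotypes=dict(config.sample_phenotypes),
    )
    somatic_keys = {
        t: {v.key for v in shared_somatic} | {v.key for v in private_somatic[t]}
        for t in tumor_ids
    }
    return StudyBundle(
        config=config, callsets=callsets, known_catalog=known_catalog,
        somatic_catalog=somatic_catalog, annotations=annotations,
        universe=list(genes), edges=edges, truth=truth,
        somatic_keys=somatic_keys,
    )


def _simulate_edges(config: CohortConfig, rng: np.random.Generator,
                    genes: list[str], affected: list[str]) -> list[tuple[str, str]]:
    n = len(genes)
    m_background = round(config.er_mean_degree * n / 2)
    if m_background > n * (n - 1) // 2:
        raise ValueError("requested edge density exceeds simple-graph maximum")
    edges: set[tuple[str, str]] = set()
    affected_set = set(affected)
    hub = config.hub_gene
    for g in genes:
        p = config.hub_query_prob if g in affected_set else config.hub_background_prob
        if rng.random() < p:
            edges.add((hub, g) if hub < g else (g, hub))
    n_hub_edges = len(edges)
    while len(edges) < m_background + n_hub_edges:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = (genes[i], genes[j]) if genes[i] < genes[j] else (genes[j], genes[i])
        edges.add((a, b))
    return sorted(edges)


# ---------------------------------------------------------------------------
# spec-level wrappers
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig):
    """Return (callsets, {"known": ..., "somatic": ...}, truth)."""
    bundle = simulate_study(config)
    return (
        bundle.callsets,
        {"known": bundle.known_catalog, "somatic": bundle.somatic_catalog},
        bundle.truth,
    )


def simulate_interaction_network(config: CohortConfig) -> list[tuple[str, str]]:
    return simulate_study(config).edges


def simulate_annotations(config: CohortConfig) -> dict[str, list[str]]:
    return simulate_study(config).annotations


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write the full simulated study bundle as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cs in bundle.callsets:
        write_vcf(cs, outdir / f"{cs.sample_id}.vcf")
    bundle.known_catalog.write_tsv(outdir / "known_catalog.tsv")
    bundle.somatic_catalog.write_tsv(outdir / "somatic_catalog.tsv")
    with open(outdir / "annotations.gmt", "w") as fh:
        for term in sorted(bundle.annotations):
            fh.write("\t".join([term, "simulated"] + bundle.annotations[term]) + "\n")
    (outdir / "universe.txt").write_text("\n".join(bundle.universe) + "\n")
    with open(outdir / "ppi.tsv", "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in bundle.edges:
            fh.write(f"{a}\t{b}\n")
    (outdir / "truth.json").write_text(bundle.truth.to_json() + "\n")
    cfg = asdict(bundle.config)
    cfg["planted_terms"] = list(cfg["planted_terms"])
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
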