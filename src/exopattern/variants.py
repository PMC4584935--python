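"""Annotated variant containers, classification, and dialect I/O.

This module holds the normalized variant representation shared by every
downstream analysis: a variant is identified by its trim-normalized
``(chrom, pos, ref, alt)`` key, carries the annotation fields emitted by an
exome annotation pipeline (genomic region, exonic consequence, gene symbols,
known-variant identifier, population allele frequency, and a consensus
deleteriousness score in [0, 1]), and is classified as SNV or INDEL purely by
allele lengths.

Supported dialects
------------------
* minimal single-sample VCF 4.2 with INFO keys ``GENE``, ``REGION``,
  ``EXFUNC``, ``CONDEL``, ``KNOWN_ID``, ``AF`` (read via cyvcf2; written as
  plain text),
* an annotation-table TSV with columns ``chrom, start, end, ref, alt, region,
  exonic_function, gene, known_id, af, condel`` (1-based inclusive start),
* BED3+1 export/import (0-based half-open, name column ``ref>alt``),
* known-variant and somatic catalogs as key + optional-frequency TSVs.

No reference-genome left-alignment is performed: normalization trims shared
trailing then leading bases only, so the package needs no FASTA download.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

log = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

REGIONS = frozenset(
    {"exonic", "splicing", "intronic", "UTR3", "UTR5",
     "upstream", "downstream", "intergenic", "other"}
)
EXONIC_FUNCTIONS = frozenset(
    {"nonsynonymous", "synonymous", "stopgain", "stoploss",
     "frameshift", "nonframeshift", "unknown"}
)
PHENOTYPES = frozenset({"tumor", "control"})
_BASES = frozenset("ACGT")

#: default consensus-deleteriousness cutoff (published ConDel operating point)
DAMAGING_CUTOFF = 0.522
#: default population allele frequency below which a cataloged variant still
#: counts as novel ("novel or of low allele frequency")
NOVEL_AF_THRESHOLD = 0.01

# lenient mapping of annotation-tool region labels onto the canonical set
_REGION_ALIASES = {
    "exonic": "exonic", "splicing": "splicing", "intronic": "intronic",
    "intron": "intronic", "utr3": "UTR3", "3utr": "UTR3", "3'utr": "UTR3",
    "utr5": "UTR5", "5utr": "UTR5", "5'utr": "UTR5", "upstream": "upstream",
    "downstream": "downstream", "intergenic": "intergenic", "other": "other",
    "ncrna_exonic": "other", "ncrna_intronic": "other",
}
_EXFUNC_ALIASES = {
    "nonsynonymous": "nonsynonymous", "nonsynonymous snv": "nonsynonymous",
    "synonymous": "synonymous", "synonymous snv": "synonymous",
    "stopgain": "stopgain", "stoploss": "stoploss",
    "frameshift": "frameshift", "frameshift insertion": "frameshift",
    "frameshift deletion": "frameshift",
    "nonframeshift": "nonframeshift", "nonframeshift insertion": "nonframeshift",
    "nonframeshift deletion": "nonframeshift", "unknown": "unknown",
}


class VariantError(ValueError):
    """Raised for malformed variants or files."""


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Trim-normalize a variant to its minimal representation.

    Shared trailing bases are removed first, then shared leading bases with
    ``pos`` advanced accordingly; at least one base is always retained in each
    allele.  The operation is idempotent.

    Raises
    ------
    VariantError
        If an allele is empty or ref equals alt ("null variant").
    """
    if not ref or not alt:
        raise VariantError(f"empty allele at {chrom}:{pos}")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise VariantError(f"null variant at {chrom}:{pos} ({ref}>{alt})")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise VariantError(f"null variant at {chrom}:{pos} after trimming")
    return chrom, int(pos), ref, alt


@dataclass
class AnnotatedVariant:
    """One normalized, annotated variant call.

    ``var_class`` is derived from allele lengths: an SNV iff both alleles are
    single bases.  ``exonic_function`` is only meaningful (and only allowed)
    for exonic/splicing variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    region: str = "other"
    exonic_function: Optional[str] = None
    genes: tuple[str, ...] = ()
    known_id: Optional[str] = None
    pop_af: Optional[float] = None
    deleterious_score: Optional[float] = None
    sample_gt: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise VariantError(f"invalid alleles {self.ref}>{self.alt}")
        if self.var_class == "SNV" and not (
            self.ref in _BASES and self.alt in _BASES
        ):
            raise VariantError(f"non-ACGT SNV alleles {self.ref}>{self.alt}")
        if self.region not in REGIONS:
            raise VariantError(f"unknown region label {self.region!r}")
        if self.exonic_function is not None:
            if self.region not in ("exonic", "splicing"):
                raise VariantError(
                    "exonic_function only allowed for exonic/splicing variants"
                )
            if self.exonic_function not in EXONIC_FUNCTIONS:
                raise VariantError(
                    f"unknown exonic_function {self.exonic_function!r}"
                )
        self.genes = tuple(self.genes)

    @property
    def var_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_transition(self) -> bool:
        """True for A<->G / C<->T substitutions (SNVs only)."""
        if self.var_class != "SNV":
            raise VariantError("transition/transversion defined for SNVs only")
        return {self.ref, self.alt} in ({"A", "G"}, {"C", "T"})


@dataclass
class SampleCallset:
    """All variants called in one sample, keyed by normalized variant key."""

    sample_id: str
    phenotype: str
    variants: dict[VariantKey, AnnotatedVariant] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise VariantError(f"phenotype must be tumor/control, got {self.phenotype!r}")

    def add(self, variant: AnnotatedVariant) -> None:
        if variant.key in self.variants:
            raise VariantError(
                f"duplicate variant key {variant.key} in sample {self.sample_id}"
            )
        self.variants[variant.key] = variant

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[AnnotatedVariant]:
        return iter(self.variants.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def snvs(self) -> list[AnnotatedVariant]:
        return [v for v in self if v.var_class == "SNV"]

    def indels(self) -> list[AnnotatedVariant]:
        return [v for v in self if v.var_class == "INDEL"]


class VariantCatalog:
    """A set of known variant keys with optional population allele frequencies.

    Stands in for population catalogs (dbSNP/1000G-like) and for positive
    somatic catalogs alike; for the latter the frequency column is unused.
    """

    def __init__(self, entries: Optional[dict[VariantKey, Optional[float]]] = None):
        self._af: dict[VariantKey, Optional[float]] = dict(entries or {})

    def add(self, key: VariantKey, af: Optional[float] = None) -> None:
        self._af[key] = af

    def af(self, key: VariantKey) -> Optional[float]:
        return self._af.get(key)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._af

    def __len__(self) -> int:
        return len(self._af)

    def keys(self) -> set[VariantKey]:
        return set(self._af)

    def positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self._af}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "VariantCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(df.columns):
            raise VariantError(f"catalog {path} missing columns {required - set(df.columns)}")
        cat = cls()
        has_af = "af" in df.columns
        for row in df.itertuples(index=False):
            af = getattr(row, "af", None) if has_af else None
            if af is not None and pd.isna(af):
                af = None
            cat.add(normalize_variant(row.chrom, int(row.pos), row.ref, row.alt), af)
        return cat

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\taf\n")
            for (c, p, r, a) in sorted(self._af, key=_chrom_sort_key):
                af = self._af[(c, p, r, a)]
                fh.write(f"{c}\t{p}\t{r}\t{a}\t{'' if af is None else f'{af:.6g}'}\n")


def _chrom_sort_key(key: VariantKey):
    c, p, r, a = key
    stripped = c.removeprefix("chr")
    return (0, int(stripped)) if stripped.isdigit() else (1, stripped), p, r, a


def classify_novelty(
    variant: AnnotatedVariant,
    catalog: VariantCatalog,
    af_threshold: float = NOVEL_AF_THRESHOLD,
) -> str:
    """Return ``"novel"`` or ``"known"`` against a population catalog.

    A variant is novel iff its key is absent from the catalog, or present with
    a recorded allele frequency below ``af_threshold`` (low-frequency clause).
    A cataloged variant with unknown frequency counts as known.
    """
    if variant.key not in catalog:
        return "novel"
    af = catalog.af(variant.key)
    if af is None:
        af = variant.pop_af
    if af is not None and af < af_threshold:
        return "novel"
    return "known"


def classify_damaging(
    variant: AnnotatedVariant, cutoff: float = DAMAGING_CUTOFF
) -> bool:
    """True iff the deleteriousness score is present and >= ``cutoff``."""
    if not 0.0 <= cutoff <= 1.0:
        raise VariantError(f"damaging cutoff must be in [0,1], got {cutoff}")
    if variant.deleterious_score is None:
        log.debug("variant %s has no deleteriousness score; not damaging", variant.key)
        return False
    return variant.deleterious_score >= cutoff


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REGION_ORDER = ("Exonic", "Intronic", "UTR3", "UTR5", "Splicing")


def _map_region(label: str) -> str:
    canonical = _REGION_ALIASES.get(str(label).strip().lower())
    if canonical is None:
        warnings.warn(f"unknown region label {label!r}; recorded as 'other'")
        return "other"
    return canonical


def _map_exfunc(label: Optional[str]) -> Optional[str]:
    if label is None or (isinstance(label, float) and pd.isna(label)) or label == "":
        return None
    return _EXFUNC_ALIASES.get(str(label).strip().lower(), "unknown")


def read_annotated_variants(
    path: str | Path,
    dialect: str = "vcf",
    sample_id: Optional[str] = None,
    phenotype: str = "control",
) -> SampleCallset:
    """Read a per-sample annotated variant file into a :class:`SampleCallset`.

    Multi-allelic rows are split into one record per alternate allele; every
    record is trim-normalized.  ``dialect`` is ``"vcf"`` or ``"annovar_tsv"``.
    """
    path = Path(path)
    if dialect == "vcf":
        return _read_vcf(path, sample_id, phenotype)
    if dialect == "annovar_tsv":
        return _read_annovar_tsv(path, sample_id, phenotype)
    raise VariantError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path, sample_id: Optional[str], phenotype: str) -> SampleCallset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sid = sample_id or (vcf.samples[0] if vcf.samples else path.stem)
    callset = SampleCallset(sid, phenotype)
    n_rows = 0
    for i, rec in enumerate(vcf, start=1):
        n_rows += 1
        try:
            info = rec.INFO
            genes = tuple(g for g in str(info.get("GENE") or "").split(",") if g)
            region = _map_region(info.get("REGION") or "other")
            exfunc = _map_exfunc(info.get("EXFUNC"))
            if region not in ("exonic", "splicing"):
                exfunc = None
            condel = info.get("CONDEL")
            known_id = info.get("KNOWN_ID")
            af = info.get("AF")
            for alt in rec.ALT:
                chrom, pos, ref, a = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
                callset.add(
                    AnnotatedVariant(
                        chrom, pos, ref, a,
                        region=region, exonic_function=exfunc, genes=genes,
                        known_id=known_id,
                        pop_af=float(af) if af is not None else None,
                        deleterious_score=float(condel) if condel is not None else None,
                    )
                )
        except VariantError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise VariantError(f"{path}: malformed VCF record {i}: {exc}") from exc
    log.info("read %d records (%d variants after split) from %s",
             n_rows, len(callset), path)
    return callset


_TSV_COLUMNS = ["chrom", "start", "end", "ref", "alt", "region",
                "exonic_function", "gene", "known_id", "af", "condel"]


def _read_annovar_tsv(path: Path, sample_id: Optional[str], phenotype: str) -> SampleCallset:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "gene": str})
    except Exception as exc:
        raise VariantError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = set(_TSV_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise VariantError(f"{path}: missing required columns {sorted(missing)}")
    callset = SampleCallset(sample_id or path.stem, phenotype)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            region = _map_region(row.region)
            exfunc = _map_exfunc(getattr(row, "exonic_function", None))
            if region not in ("exonic", "splicing"):
                exfunc = None
            gene = getattr(row, "gene", None)
            genes = () if gene is None or pd.isna(gene) else tuple(
                g for g in str(gene).split(",") if g
            )
            known_id = getattr(row, "known_id", None)
            if known_id is not None and pd.isna(known_id):
                known_id = None
            af = getattr(row, "af", None)
            condel = getattr(row, "condel", None)
            for alt in str(row.alt).split(","):
                chrom, pos, ref, a = normalize_variant(
                    row.chrom, int(row.start), str(row.ref), alt
                )
                callset.add(
                    AnnotatedVariant(
                        chrom, pos, ref, a,
                        region=region, exonic_function=exfunc, genes=genes,
                        known_id=None if known_id is None else str(known_id),
                        pop_af=None if af is None or pd.isna(af) else float(af),
                        deleterious_score=None if condel is None or pd.isna(condel)
                        else float(condel),
                    )
                )
        except VariantError as exc:
            raise VariantError(f"{path}: line {i}: {exc}") from exc
    log.info("read %d variants from %s", len(callset), path)
    return callset


def write_vcf(callset: SampleCallset, path: str | Path) -> None:
    """Write a callset as a minimal single-sample VCF 4.2 text file."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=exopattern (phenotype={callset.phenotype})",
        '##INFO=<ID=GENE,Number=.,Type=String,Description="Gene symbols">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region class">',
        '##INFO=<ID=EXFUNC,Number=1,Type=String,Description="Exonic consequence">',
        '##INFO=<ID=CONDEL,Number=1,Type=Float,Description="Consensus deleteriousness score">',
        '##INFO=<ID=KNOWN_ID,Number=1,Type=String,Description="Known-variant identifier">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Population allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = sorted({v.chrom for v in callset},
                    key=lambda c: _chrom_sort_key((c, 0, "A", "C")))
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{callset.sample_id}")
    for v in sorted(callset, key=lambda v: _chrom_sort_key(v.key)):
        info = [f"REGION={v.region}"]
        if v.genes:
            info.append("GENE=" + ",".join(v.genes))
        if v.exonic_function:
            info.append(f"EXFUNC={v.exonic_function}")
        if v.deleterious_score is not None:
            info.append(f"CONDEL={v.deleterious_score:.4f}")
        if v.known_id:
            info.append(f"KNOWN_ID={v.known_id}")
        if v.pop_af is not None:
            info.append(f"AF={v.pop_af:.6g}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.known_id or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info) + "\tGT\t0/1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annovar_tsv(callset: SampleCallset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for v in sorted(callset, key=lambda v: _chrom_sort_key(v.key)):
            end = v.pos + len(v.ref) - 1
            fh.write("\t".join([
                v.chrom, str(v.pos), str(end), v.ref, v.alt, v.region,
                v.exonic_function or "", ",".join(v.genes), v.known_id or "",
                "" if v.pop_af is None else f"{v.pop_af:.6g}",
                "" if v.deleterious_score is None else f"{v.deleterious_score:.4f}",
            ]) + "\n")


def write_bed(callset: SampleCallset, path: str | Path) -> None:
    """Export variant intervals as BED3+1 (0-based half-open, name ``ref>alt``)."""
    if len(callset) == 0:
        raise VariantError("refusing to write BED for empty callset")
    with open(path, "w") as fh:
        for v in sorted(callset, key=lambda v: _chrom_sort_key(v.key)):
            start = v.pos - 1
            fh.write(f"{v.chrom}\t{start}\t{start + len(v.ref)}\t{v.ref}>{v.alt}\n")


def read_bed(path: str | Path) -> list[VariantKey]:
    """Read keys back from a BED3+1 file written by :func:`write_bed`."""
    keys: list[VariantKey] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4 or ">" not in parts[3]:
            raise VariantError(f"{path}: line {i}: not BED3+1 with ref>alt name")
        ref, alt = parts[3].split(">", 1)
        keys.append((parts[0], int(parts[1]) + 1, ref, alt))
    return keys


def summarize_callsets(
    callsets: Iterable[SampleCallset],
    catalog: VariantCatalog,
    cutoff: float = DAMAGING_CUTOFF,
    af_threshold: float = NOVEL_AF_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample x variant-class counts by region, novelty, and damage.

    Returns a DataFrame indexed by (sample, var_class) with columns
    All / Novel / Exonic / Intronic / UTR3 / UTR5 / Splicing / Damaging
    (Damaging counts score-passing nonsynonymous SNVs; 0 for INDEL rows).
    """
    callsets = list(callsets)
    if not callsets:
        raise VariantError("need at least one callset")
    rows = []
    for cs in callsets:
        for klass in ("SNV", "INDEL"):
            variants = [v for v in cs if v.var_class == klass]
            counts = {
                "All": len(variants),
                "Novel": sum(
                    classify_novelty(v, catalog, af_threshold) == "novel"
                    for v in variants
                ),
            }
            for col, region in zip(
                _REGION_ORDER, ("exonic", "intronic", "UTR3", "UTR5", "splicing")
            ):
                counts[col] = sum(v.region == region for v in variants)
            counts["Damaging"] = (
                sum(
                    v.exonic_function == "nonsynonymous" and classify_damaging(v, cutoff)
                    for v in variants
                )
                if klass == "SNV"
                else 0
            )
            rows.append({"sample": cs.sample_id, "var_class": klass, **counts})
    return pd.DataFrame(rows).set_index(["sample", "var_class"])
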