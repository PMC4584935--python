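"""Variant normalization, classification, dialect I/O, and summaries."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from exopattern.variants import (
    AnnotatedVariant,
    SampleCallset,
    VariantCatalog,
    VariantError,
    classify_damaging,
    classify_novelty,
    normalize_variant,
    read_annotated_variants,
    read_bed,
    summarize_callsets,
    write_annovar_tsv,
    write_bed,
    write_vcf,
)

from conftest import make_callset, make_variant

alleles = st.text(alphabet="ACGT", min_size=1, max_size=6)


@pytest.mark.parametrize(
    "given_var,expected",
    [
        (("chr1", 100, "CAG", "CG"), ("chr1", 100, "CA", "C")),
        (("chr1", 100, "C", "T"), ("chr1", 100, "C", "T")),
        (("chr2", 50, "GCC", "GTC"), ("chr2", 51, "C", "T")),
        (("chr1", 10, "ATA", "A"), ("chr1", 10, "ATA", "A")),
        (("chr1", 10, "AAC", "AC"), ("chr1", 10, "AA", "A")),
    ],
)
def test_normalize_trims_shared_bases(given_var, expected):
    assert normalize_variant(*given_var) == expected


def test_normalize_rejects_null_variant():
    with pytest.raises(VariantError, match="null variant"):
        normalize_variant("chr1", 1, "ACA", "ACA")


@given(ref=alleles, alt=alleles, pos=st.integers(1, 10**6))
@settings(max_examples=200, deadline=None)
def test_normalize_idempotent(ref, alt, pos):
    if ref == alt:
        return
    once = normalize_variant("chr1", pos, ref, alt)
    assert normalize_variant(*once) == once


def test_var_class_follows_allele_lengths():
    assert make_variant(ref="C", alt="T").var_class == "SNV"
    assert make_variant(ref="AT", alt="A").var_class == "INDEL"
    assert make_variant(ref="A", alt="AT").var_class == "INDEL"


def test_invariants_enforced():
    with pytest.raises(VariantError):
        make_variant(pos=0)
    with pytest.raises(VariantError):
        make_variant(region="intronic", exonic_function="nonsynonymous")
    with pytest.raises(VariantError):
        make_variant(ref="N", alt="T")


def test_novelty_rules():
    cat = VariantCatalog({("chr1", 100, "C", "T"): 0.30,
                          ("chr1", 200, "C", "T"): 0.005,
                          ("chr1", 300, "C", "T"): None})
    present = make_variant(pos=100)
    rare = make_variant(pos=200)
    no_af = make_variant(pos=300)
    absent = make_variant(pos=400)
    assert classify_novelty(present, cat) == "known"
    assert classify_novelty(rare, cat) == "novel"  # low-frequency clause
    assert classify_novelty(no_af, cat) == "known"  # unknown af counts known
    assert classify_novelty(absent, cat) == "novel"


def test_damaging_threshold_and_boundary():
    v = make_variant(region="exonic", exonic_function="nonsynonymous",
                     deleterious_score=0.9)
    assert classify_damaging(v)
    assert classify_damaging(make_variant(region="exonic",
                                          exonic_function="nonsynonymous",
                                          deleterious_score=0.522))
    assert not classify_damaging(make_variant())  # no score -> not damaging
    with pytest.raises(VariantError):
        classify_damaging(v, cutoff=1.5)


def _toy_vcf(path, rows):
    header = "\n".join([
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=.,Type=String,Description="g">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="r">',
        '##INFO=<ID=EXFUNC,Number=1,Type=String,Description="e">',
        '##INFO=<ID=CONDEL,Number=1,Type=Float,Description="c">',
        '##INFO=<ID=KNOWN_ID,Number=1,Type=String,Description="k">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="a">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
    ])
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_read_vcf_classifies_and_splits(tmp_path):
    vcf = tmp_path / "s1.vcf"
    _toy_vcf(vcf, [
        "chr1\t100\t.\tC\tT\t.\tPASS\tREGION=exonic;EXFUNC=nonsynonymous;GENE=GA\tGT\t0/1",
        "chr1\t200\t.\tAT\tA\t.\tPASS\tREGION=exonic;EXFUNC=frameshift;GENE=GB\tGT\t0/1",
        "chr1\t300\t.\tG\tA\t.\tPASS\tREGION=intronic\tGT\t0/1",
        "chr1\t400\t.\tC\tA,T\t.\tPASS\tREGION=intronic\tGT\t1/2",
    ])
    cs = read_annotated_variants(vcf, dialect="vcf")
    assert len(cs) == 5  # multi-allelic row split into two records
    classes = {(v.var_class, v.region) for v in cs}
    assert ("SNV", "exonic") in classes
    assert ("INDEL", "exonic") in classes
    assert ("SNV", "intronic") in classes
    alts_at_400 = {v.alt for v in cs if v.pos == 400}
    assert alts_at_400 == {"A", "T"}


def test_unknown_region_becomes_other_with_warning(tmp_path):
    vcf = tmp_path / "s1.vcf"
    _toy_vcf(vcf, ["chr1\t100\t.\tC\tT\t.\tPASS\tREGION=weird\tGT\t0/1"])
    with pytest.warns(UserWarning, match="unknown region"):
        cs = read_annotated_variants(vcf, dialect="vcf")
    assert next(iter(cs)).region == "other"


def test_vcf_round_trip_preserves_keys_and_classes(small_bundle, tmp_path):
    cs = small_bundle.callsets[0]
    path = tmp_path / "rt.vcf"
    write_vcf(cs, path)
    back = read_annotated_variants(path, dialect="vcf", phenotype=cs.phenotype)
    assert back.keys() == cs.keys()
    for key, v in back.variants.items():
        orig = cs.variants[key]
        assert (v.var_class, v.region, v.exonic_function, v.genes) == (
            orig.var_class, orig.region, orig.exonic_function, orig.genes
        )


def test_annovar_tsv_round_trip(small_bundle, tmp_path):
    cs = small_bundle.callsets[1]
    path = tmp_path / "rt.tsv"
    write_annovar_tsv(cs, path)
    back = read_annotated_variants(path, dialect="annovar_tsv",
                                   phenotype=cs.phenotype)
    assert back.keys() == cs.keys()


def test_malformed_tsv_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "chrom\tstart\tend\tref\talt\tregion\texonic_function\tgene\tknown_id\taf\tcondel\n"
        "chr1\t100\t100\tC\tT\texonic\tnonsynonymous\tGA\t\t\t\n"
        "chr1\t200\t200\tA\tA\tintronic\t\t\t\t\t\n"
    )
    with pytest.raises(VariantError, match="line 3"):
        read_annotated_variants(path, dialect="annovar_tsv")


def test_bed_coordinates_and_round_trip(tmp_path):
    cs = make_callset("S", "control", [
        make_variant(pos=100, ref="C", alt="T"),
        make_variant(pos=100, ref="CA", alt="C"),
    ])
    path = tmp_path / "out.bed"
    write_bed(cs, path)
    lines = path.read_text().splitlines()
    assert "chr1\t99\t100\tC>T" in lines
    assert "chr1\t99\t101\tCA>C" in lines
    assert set(read_bed(path)) == cs.keys()


def test_summarize_counts(toy_callsets):
    t1, *_ = toy_callsets
    t1_plus = make_callset("T1", "tumor", list(t1) + [
        make_variant(pos=9, ref="AT", alt="A", region="exonic",
                     exonic_function="frameshift"),
    ])
    table = summarize_callsets([t1_plus], VariantCatalog())
    snv = table.loc[("T1", "SNV")]
    indel = table.loc[("T1", "INDEL")]
    assert snv["All"] == 3 and snv["Exonic"] == 2
    assert indel["All"] == 1 and indel["Exonic"] == 1
    assert snv["Novel"] == 3  # empty catalog: everything novel
    empty = make_callset("E", "control", [])
    table = summarize_callsets([empty], VariantCatalog())
    assert (table.to_numpy() == 0).all()


def test_summary_region_counts_bounded_by_all(small_bundle):
    table = summarize_callsets(small_bundle.callsets, small_bundle.known_catalog)
    regions = table[["Exonic", "Intronic", "UTR3", "UTR5", "Splicing"]].sum(axis=1)
    assert (regions <= table["All"]).all()
    assert (table["Novel"] <= table["All"]).all()
    assert (table >= 0).all().all()
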