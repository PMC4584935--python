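"""Gene sets, affection matrices, distances, NMDS, and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from exopattern.ordination import (
    OrdinationError,
    binary_distance,
    build_affection_matrix,
    build_gene_set,
    hierarchical_cluster,
    isotonic_fit,
    nmds,
    set_intersections,
    stress1,
)

from conftest import make_callset, make_variant
from oracles import average_linkage_heights


# ---------------------------------------------------------------------- sets

def test_snv_set_excludes_synonymous():
    cs = make_callset("S", "tumor", [
        make_variant(pos=1, genes=("GENEX",), region="exonic",
                     exonic_function="synonymous"),
        make_variant(pos=2, genes=("GENEY",), region="exonic",
                     exonic_function="nonsynonymous"),
        make_variant(pos=3, genes=("GENEZ",), region="splicing",
                     exonic_function="unknown"),
    ])
    gs = build_gene_set(cs, "SNV")
    assert "GENEX" not in gs.genes
    assert gs.genes == {"GENEY", "GENEZ"}  # splice site qualifies as such


def test_indel_set_by_region_and_multi_gene():
    cs = make_callset("S", "tumor", [
        make_variant(pos=1, ref="AT", alt="A", genes=("GENEY",),
                     region="exonic", exonic_function="frameshift"),
        make_variant(pos=2, ref="A", alt="AC", genes=("G1", "G2"),
                     region="exonic", exonic_function="nonframeshift"),
        make_variant(pos=3, ref="A", alt="AC", genes=("G3",), region="intronic"),
    ])
    assert build_gene_set(cs, "INDEL").genes == {"GENEY", "G1", "G2"}


def test_affection_matrix_marks():
    sets = [
        build_gene_set(make_callset("S1", "tumor", [
            make_variant(pos=1, genes=("A",), region="exonic",
                         exonic_function="nonsynonymous"),
            make_variant(pos=2, genes=("B",), region="exonic",
                         exonic_function="stopgain")]), "SNV"),
        build_gene_set(make_callset("S2", "control", [
            make_variant(pos=3, genes=("B",), region="exonic",
                         exonic_function="nonsynonymous"),
            make_variant(pos=4, genes=("C",), region="exonic",
                         exonic_function="stoploss")]), "SNV"),
    ]
    m = build_affection_matrix(sets)
    assert list(m.columns) == ["A", "B", "C"]
    assert m.to_numpy().tolist() == [[1, 1, 0], [0, 1, 1]]


def test_affection_matrix_rejects_duplicates_and_warns_on_empty():
    a = build_gene_set(make_callset("S1", "tumor", []), "SNV")
    b = build_gene_set(make_callset("S1", "control", []), "SNV")
    with pytest.raises(OrdinationError, match="duplicate"):
        build_affection_matrix([a, b])
    c = build_gene_set(make_callset("S2", "control", [
        make_variant(pos=1, genes=("A",), region="exonic",
                     exonic_function="nonsynonymous")]), "SNV")
    with pytest.warns(UserWarning, match="empty gene set"):
        m = build_affection_matrix([a, c])
    assert m.loc["S1"].sum() == 0


# ----------------------------------------------------------------- distances

def test_binary_distances():
    m = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"],
                     columns=["x", "y", "z"])
    assert binary_distance(m, "jaccard").loc["a", "b"] == pytest.approx(2 / 3)
    assert binary_distance(m, "euclidean").loc["a", "b"] == pytest.approx(np.sqrt(2))
    same = pd.DataFrame([[1, 0], [1, 0]], index=["a", "b"], columns=["x", "y"])
    assert binary_distance(same).loc["a", "b"] == 0
    with pytest.raises(OrdinationError):
        binary_distance(m, "manhattan")


def test_both_empty_rows_have_zero_jaccard_distance():
    m = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=list("abc"),
                     columns=["x", "y"])
    d = binary_distance(m)
    assert d.loc["a", "b"] == 0


@given(st.lists(st.lists(st.integers(0, 1), min_size=6, max_size=6),
                min_size=3, max_size=3))
@settings(max_examples=100, deadline=None)
def test_jaccard_triangle_inequality(rows):
    m = pd.DataFrame(rows, index=list("abc"))
    d = binary_distance(m).to_numpy()
    for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


# ----------------------------------------------------------------- isotonic

def test_isotonic_fit_behaviour():
    order = np.arange(3)
    monotone = np.array([1.0, 2.0, 3.0])
    assert isotonic_fit(monotone, order).tolist() == [1, 2, 3]
    pooled = isotonic_fit(np.array([3.0, 1.0, 2.0]), order)
    assert pooled.tolist() == [2, 2, 2]


@given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=12))
@settings(max_examples=100, deadline=None)
def test_isotonic_fit_conserves_sum_and_is_monotone(values):
    d = np.asarray(values)
    order = np.arange(len(d))
    fit = isotonic_fit(d, order)
    assert np.isclose(fit.sum(), d.sum())
    assert (np.diff(fit[order]) >= -1e-9).all()


# ------------------------------------------------------------------- stress

def test_stress1_values():
    assert stress1([1.0, 2.0], [1.0, 2.0]) == 0
    assert stress1([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)
    assert stress1([1.0, 2.0], [1.5, 1.5]) == pytest.approx(0.3162277660)
    with pytest.raises(OrdinationError):
        stress1([0.0, 0.0], [1.0, 1.0])


# --------------------------------------------------------------------- NMDS

def test_nmds_recovers_collinear_points():
    D = squareform([1.0, 1.0, 2.0])  # points at 0, 1, -1 on a line
    res = nmds(D, k=1)
    assert res.stress <= 1e-6
    d = np.sort(pdist(res.configuration))
    assert d[1] / d[0] == pytest.approx(1.0, abs=1e-4)


def test_nmds_dimension_bound_and_symmetry_errors():
    D = squareform([1.0, 1.0, 2.0])
    with pytest.raises(OrdinationError, match="n-1"):
        nmds(D, k=3)
    with pytest.raises(OrdinationError, match="symmetric"):
        nmds(np.array([[0, 1.0], [2.0, 0]]), k=1)


def test_nmds_equal_distances_degenerate():
    D = np.ones((4, 4)) - np.eye(4)
    with pytest.warns(UserWarning, match="degenerate ties"):
        res = nmds(D, k=3)
    assert res.stress <= 1e-9


@pytest.mark.parametrize("seed", range(20))
def test_nmds_any_5x5_matrix_embeds_in_4_dims(seed):
    rng = np.random.default_rng(seed)
    D = squareform(rng.uniform(0.2, 1.0, size=10))
    res = nmds(D, k=4, seed=seed)
    assert res.stress <= 1e-6


def test_nmds_trace_non_increasing_and_matches_stress(small_bundle):
    from exopattern.ordination import build_gene_set as bgs
    sets = [bgs(cs, "INDEL") for cs in small_bundle.callsets]
    d = binary_distance(build_affection_matrix(sets))
    res = nmds(d, k=4, seed=0)
    trace = np.asarray(res.stress_trace)
    assert (np.diff(trace) <= 1e-12).all()
    assert res.stress == trace[-1]
    assert res.sample_ids == list(d.index)


def test_nmds_recovers_euclidean_configuration():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 2))
    D = squareform(pdist(X))
    res = nmds(D, k=2, seed=0)
    assert res.stress <= 1e-6
    rho, _ = spearmanr(pdist(X), pdist(res.configuration))
    assert rho == pytest.approx(1.0)


def test_nmds_matches_reference_implementation():
    """Final stress comparable to sklearn's non-metric MDS on random input."""
    sklearn = pytest.importorskip("sklearn.manifold")
    rng = np.random.default_rng(2)
    for _ in range(5):
        D = squareform(rng.uniform(0.2, 1.0, size=15))  # 6 points
        ours = nmds(D, k=2, seed=0).stress
        ref = sklearn.MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            normalized_stress=True, n_init=4, random_state=0, max_iter=500,
        )
        ref.fit(D)
        assert ours <= ref.stress_ + 0.02  # at least as good as reference


# --------------------------------------------------------------- clustering

def test_first_merge_is_closest_pair():
    D = pd.DataFrame(
        [[0, 1, 5], [1, 0, 5], [5, 5, 0]],
        index=list("ABC"), columns=list("ABC"), dtype=float,
    )
    res = hierarchical_cluster(D)
    left, right, height = res.merges[0]
    assert {tuple(sorted(left))[0], tuple(sorted(right))[0]} == {"A", "B"}
    assert height == 1
    assert res.newick.endswith(";")


def test_equal_distances_merge_lexicographically():
    D = pd.DataFrame(np.ones((3, 3)) - np.eye(3),
                     index=list("CBA"), columns=list("CBA"))
    res = hierarchical_cluster(D)
    assert res.heights == [1.0, 1.0]
    first_left, first_right, _ = res.merges[0]
    assert sorted(set(first_left) | set(first_right)) == ["A", "B"]


@pytest.mark.parametrize("seed", range(10))
def test_average_linkage_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    D = squareform(rng.uniform(0.1, 2.0, size=15))  # 6 samples
    ours = hierarchical_cluster(pd.DataFrame(D), linkage="average").heights
    assert np.allclose(sorted(ours), sorted(average_linkage_heights(D)))


def test_average_linkage_agrees_with_scipy():
    from scipy.cluster.hierarchy import linkage

    rng = np.random.default_rng(3)
    for _ in range(5):
        cond = rng.uniform(0.1, 2.0, size=15)
        ours = hierarchical_cluster(pd.DataFrame(squareform(cond))).heights
        ref = linkage(cond, method="average")[:, 2]
        assert np.allclose(sorted(ours), sorted(ref))


def test_newick_parses_and_preserves_leaves():
    dendropy = pytest.importorskip("dendropy")
    D = pd.DataFrame(squareform([0.3, 0.9, 1.0, 0.8, 0.7, 0.2]),
                     index=["P17", "P61", "P39", "P26"],
                     columns=["P17", "P61", "P39", "P26"])
    res = hierarchical_cluster(D)
    tree = dendropy.Tree.get(data=res.newick, schema="newick")
    assert {t.label for t in tree.taxon_namespace} == set(D.index)


# ------------------------------------------------------------ intersections

def test_set_intersections_counts():
    from exopattern.ordination import GeneSet

    a = GeneSet("S1", "SNV", "", frozenset("ABC"))
    b = GeneSet("S2", "SNV", "", frozenset("BCD"))
    counts = set_intersections([a, b])
    assert counts == {("S1",): 1, ("S1", "S2"): 2, ("S2",): 1}
    same = set_intersections([a, GeneSet("S2", "SNV", "", frozenset("ABC"))])
    assert same == {("S1", "S2"): 3}


@pytest.mark.parametrize("seed", range(5))
def test_set_intersections_partition_sums_to_union(seed):
    from exopattern.ordination import GeneSet

    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(40)]
    sets = [
        GeneSet(f"S{j}", "SNV", "",
                frozenset(g for g in genes if rng.random() < 0.4))
        for j in range(4)
    ]
    counts = set_intersections(sets)
    union = set().union(*(s.genes for s in sets))
    assert sum(counts.values()) == len(union)
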