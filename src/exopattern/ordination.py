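"""Gene-affection ordination: binary matrices, distances, NMDS, clustering.

The exploratory stage of the pipeline turns each sample's qualifying variants
into a gene set ("affected" genes), stacks the sets into a samples x genes
binary scoring matrix (1 = affected, 0 = spared), computes a binary distance
matrix, and ordinates it with non-metric multidimensional scaling (Kruskal
stress-1) plus agglomerative hierarchical clustering.

The NMDS implementation follows Kruskal's scheme: a classical-scaling
(Torgerson) initialization, then alternating isotonic regression of the
configuration distances against the dissimilarity rank order (primary tie
handling) and a Guttman-transform configuration update, tracking stress-1

    stress1 = sqrt( sum (d - dhat)^2 / sum d^2 )

until the stress change falls below ``tol``, stress is numerically zero, or
``max_iter`` is reached; the best of ``n_starts`` starts (classical init plus
seeded random perturbations) is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

#: exonic consequences that qualify an SNV for the gene-affection sets
SNV_QUALIFYING_FUNCTIONS = frozenset({"nonsynonymous", "stopgain", "stoploss"})
QUALIFYING_REGIONS = ("exonic", "splicing")


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """Genes affected by qualifying variants of one stratum in one sample."""

    sample_id: str
    stratum: str
    filter_spec: str
    genes: frozenset[str]


def build_gene_set(
    callset,
    stratum: str,
    regions: Sequence[str] = QUALIFYING_REGIONS,
    functions: Optional[Iterable[str]] = None,
) -> GeneSet:
    """Collect affected genes for one sample and stratum (``SNV``/``INDEL``).

    An SNV qualifies when it lies in a splice site, or is exonic with a
    consequence in ``functions`` (default: nonsynonymous/stopgain/stoploss;
    synonymous changes are excluded).  An INDEL qualifies by region alone.
    Every qualifying variant contributes all of its gene symbols.
    """
    if stratum not in ("SNV", "INDEL"):
        raise OrdinationError(f"stratum must be SNV or INDEL, got {stratum!r}")
    if functions is None and stratum == "SNV":
        functions = SNV_QUALIFYING_FUNCTIONS
    functions = None if functions is None else frozenset(functions)
    genes: set[str] = set()
    for v in callset:
        if v.var_class != stratum or v.region not in regions:
            continue
        if (
            functions is not None
            and v.region == "exonic"
            and v.exonic_function not in functions
        ):
            continue
        genes.update(v.genes)
    spec = f"region in {tuple(regions)}"
    if functions is not None:
        spec += f" and exonic function in {tuple(sorted(functions))}"
    return GeneSet(callset.sample_id, stratum, spec, frozenset(genes))


def build_affection_matrix(gene_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Binary samples x genes scoring matrix (1 = affected, 0 = spared)."""
    if len(gene_sets) < 2:
        raise OrdinationError("need at least two samples")
    ids = [gs.sample_id for gs in gene_sets]
    if len(set(ids)) != len(ids):
        raise OrdinationError("duplicate sample ids")
    strata = {gs.stratum for gs in gene_sets}
    if len(strata) != 1:
        raise OrdinationError(f"mixed strata {strata}")
    columns = sorted(set().union(*(gs.genes for gs in gene_sets)))
    data = np.zeros((len(gene_sets), len(columns)), dtype=np.int8)
    col_index = {g: j for j, g in enumerate(columns)}
    for i, gs in enumerate(gene_sets):
        if not gs.genes:
            warnings.warn(f"sample {gs.sample_id} has an empty gene set")
        for g in gs.genes:
            data[i, col_index[g]] = 1
    return pd.DataFrame(data, index=ids, columns=columns)


def binary_distance(matrix: pd.DataFrame, method: str = "jaccard") -> pd.DataFrame:
    """Pairwise distance between binary rows (``jaccard`` or ``euclidean``).

    Jaccard distance is 1 - |intersection| / |union| over the 1-columns, and
    defined as 0 when both rows are all-zero.
    """
    if method not in ("jaccard", "euclidean"):
        raise OrdinationError(f"unknown distance method {method!r}")
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise OrdinationError("affection matrix must be binary")
    metric_input = values.astype(bool) if method == "jaccard" else values.astype(float)
    d = squareform(pdist(metric_input, metric=method))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    configuration: np.ndarray  # (n, k)
    stress: float
    n_iter: int
    converged: bool
    stress_trace: list[float]
    sample_ids: Optional[list[str]] = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids or list(range(len(self.configuration)))
        return pd.DataFrame(
            self.configuration, index=idx,
            columns=[f"dim{i + 1}" for i in range(self.configuration.shape[1])],
        )


def stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (d - dhat)^2 / sum d^2)."""
    d = np.asarray(d, dtype=float)
    dhat = np.asarray(dhat, dtype=float)
    if d.shape != dhat.shape:
        raise OrdinationError("d and dhat must have equal length")
    denom = float(np.sum(d * d))
    if denom == 0.0:
        raise OrdinationError("all configuration distances are zero")
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def isotonic_fit(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of ``d`` taken in dissimilarity order.

    Returns disparities that are non-decreasing along ``order`` and preserve
    the mean of ``d`` within pooled blocks.
    """
    d = np.asarray(d, dtype=float)
    order = np.asarray(order, dtype=int)
    if d.shape != order.shape:
        raise OrdinationError("d and order must have equal length")
    fit = isotonic_regression(d[order]).x
    dhat = np.empty_like(d)
    dhat[order] = fit
    return dhat


def _classical_init(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering; top-k coordinates, negatives clipped."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def _validate_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise OrdinationError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise OrdinationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise OrdinationError("distance matrix must have a zero diagonal")
    if (D < 0).any():
        raise OrdinationError("distances must be non-negative")
    return D


def nmds(
    distance,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_starts: int = 4,
    seed: int = 0,
) -> NMDSResult:
    """Kruskal non-metric MDS of a dissimilarity matrix into ``k`` dimensions.

    ``k`` must satisfy 1 <= k <= n-1 (a configuration of n points needs at
    most n-1 dimensions).  Start 1 is the classical-scaling solution; further
    starts perturb it with seeded Gaussian noise.  The recorded stress trace
    is non-increasing: an iteration that would raise stress terminates the
    run on the previous configuration.
    """
    sample_ids = list(distance.index) if isinstance(distance, pd.DataFrame) else None
    D = _validate_distance(np.asarray(distance, dtype=float))
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise OrdinationError(
            f"k must satisfy 1 <= k <= n-1 = {n - 1} (got k={k})"
        )
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    if np.ptp(delta) == 0.0:
        warnings.warn("degenerate ties: all dissimilarities are equal")
    rng = np.random.default_rng(seed)
    x0 = _classical_init(D, k)
    scale = np.sqrt(np.mean(x0 ** 2)) or 1.0

    best: Optional[NMDSResult] = None
    for start in range(max(1, n_starts)):
        X = x0.copy() if start == 0 else x0 + rng.normal(0.0, 0.1 * scale, x0.shape)
        trace: list[float] = []
        converged = False
        X_prev = X
        for _ in range(max_iter):
            d = pdist(X)
            if np.all(d == 0.0):
                X = X + rng.normal(0.0, 1e-6, X.shape)
                d = pdist(X)
            order = np.lexsort((d, delta))  # primary approach to ties
            dhat = isotonic_fit(d, order)
            s = stress1(d, dhat)
            if trace and s > trace[-1] + 1e-15:
                X = X_prev  # keep the non-increasing configuration
                converged = True
                break
            trace.append(s)
            if s < 1e-12:
                converged = True
                break
            if len(trace) > 1 and trace[-2] - s < tol:
                converged = True
                break
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X_prev = X
            X = (B @ X) / n
            X = X - X.mean(axis=0)
        result = NMDSResult(
            configuration=X, stress=trace[-1], n_iter=len(trace),
            converged=converged, stress_trace=trace, sample_ids=sample_ids,
        )
        if best is None or result.stress < best.stress:
            best = result
    return best


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Agglomerative merge history plus a Newick rendering."""

    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]  # (left, right, height)
    newick: str

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def hierarchical_cluster(distance, linkage: str = "average") -> ClusterResult:
    """Naive agglomerative clustering of a distance matrix.

    Linkage distances are computed from the original pairwise dissimilarities
    (average = UPGMA mean over cross pairs, complete = max, single = min).
    Ties are broken toward the lexicographically smallest cluster pair, and
    the dendrogram is exported as Newick with branch lengths equal to height
    differences (leaves sit at height 0).
    """
    if linkage not in ("average", "complete", "single"):
        raise OrdinationError(f"unknown linkage {linkage!r}")
    labels = (
        list(distance.index)
        if isinstance(distance, pd.DataFrame)
        else [str(i) for i in range(np.asarray(distance).shape[0])]
    )
    D = _validate_distance(np.asarray(distance, dtype=float))
    n = D.shape[0]
    if n < 2:
        raise OrdinationError("need at least two samples to cluster")
    reduce = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]
    index = {label: i for i, label in enumerate(labels)}

    # cluster -> (member labels, current height, newick fragment)
    active: dict[frozenset, tuple[float, str]] = {
        frozenset([lab]): (0.0, lab) for lab in labels
    }
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(active) > 1:
        candidates = []
        clusters = sorted(active, key=lambda c: sorted(c))
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                dist = float(
                    reduce([D[index[x], index[y]] for x in a for y in b])
                )
                candidates.append((dist, sorted(a), sorted(b), a, b))
        dist, _, _, a, b = min(candidates, key=lambda t: (t[0], t[1], t[2]))
        ha, na = active.pop(a)
        hb, nb = active.pop(b)
        newick = f"({na}:{dist - ha:.6g},{nb}:{dist - hb:.6g})"
        active[a | b] = (dist, newick)
        merges.append((a, b, dist))
    (_, final_newick), = active.values()
    return ClusterResult(labels=labels, merges=merges, newick=final_newick + ";")


def set_intersections(gene_sets: Sequence[GeneSet]) -> dict[tuple[str, ...], int]:
    """Counts for every nonempty region of the Venn partition of 2-5 sets.

    Keys are sorted tuples of the sample ids a gene belongs to; values sum to
    the size of the union.
    """
    if not 2 <= len(gene_sets) <= 5:
        raise OrdinationError(
            "set_intersections supports 2-5 sets; use a tabular summary beyond"
        )
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*(gs.genes for gs in gene_sets))
    for gene in union:
        members = tuple(sorted(gs.sample_id for gs in gene_sets if gene in gs.genes))
        counts[members] = counts.get(members, 0) + 1
    return counts


def plot_affection_heatmap(matrix: pd.DataFrame, path) -> None:
    """Minimal PNG heatmap of a binary affection matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2 + 0.3 * len(matrix)))
    ax.imshow(matrix.to_numpy(), aspect="auto", cmap="Greys", interpolation="none")
    ax.set_yticks(range(len(matrix)), matrix.index)
    ax.set_xlabel(f"{matrix.shape[1]} genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
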