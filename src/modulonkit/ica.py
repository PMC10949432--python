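"""Robust independent component analysis of an expression compendium.

The centered gene x sample matrix X is decomposed as X ~ M.A, where M holds
robust gene-weight vectors (candidate iModulons) and A the per-sample
component activities. Robustness comes from running FastICA many times with
different initialisations, pooling all gene-weight vectors, clustering them
by the distance 1 - |Pearson r|, and keeping only clusters supported by at
least half of the restarts. Each surviving cluster is represented by its
centrotype (the member minimising summed within-cluster distance); A is then
recomputed as the least-squares projection of X onto the retained M, so the
X ~ M.A contract holds for the reported matrices.

Dimensionality is chosen by sweeping the requested component count and
keeping the largest dimension at which every robust component is a genuine
multi-gene component: past the intrinsic dimensionality, surplus components
degrade into single-gene or empty (noise-shaped) components, so the sweep
identifies the crossing point between under- and over-decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ._utils import spawn_seeds
from .imodulons import detect_single_gene_weights, threshold_gene_weights

__all__ = [
    "IcaDecomposition",
    "DimensionSweepStats",
    "OptimalDimension",
    "run_ica",
    "sweep_dimensions",
    "select_optimal_dimension",
]


@dataclass
class IcaDecomposition:
    """Robust M/A matrices plus per-component support metadata.

    Columns of ``M`` are unit L2 norm with the sign convention that the
    largest-magnitude gene weight is positive. ``cluster_sizes[i]`` is the
    number of restarts whose components populated component i's cluster.
    """

    M: pd.DataFrame  # genes x components
    A: pd.DataFrame  # components x samples
    n_restarts: int
    cluster_sizes: list[int]
    dimension: int
    seed: int

    @property
    def n_components(self) -> int:
        return self.M.shape[1]


@dataclass
class DimensionSweepStats:
    """Per-dimension robust / single-gene component counts."""

    table: pd.DataFrame  # index: dimension; columns: n_robust_components,
    #                      n_single_gene_components, n_non_single_gene

    def __post_init__(self) -> None:
        t = self.table
        if ((t["n_non_single_gene"]
             != t["n_robust_components"] - t["n_single_gene_components"]).any()):
            raise ValueError("inconsistent sweep statistics")


class OptimalDimension(int):
    """An int carrying whether the selection criterion was met exactly."""

    exact: bool

    def __new__(cls, value: int, exact: bool = True) -> "OptimalDimension":
        obj = super().__new__(cls, value)
        obj.exact = exact
        return obj


def _check_centered(X: pd.DataFrame, metadata: pd.DataFrame | None, tol: float = 1e-6) -> None:
    if metadata is None:
        return
    for project, group in metadata.groupby("project", sort=False):
        refs = [s for s in group.index[group["is_reference"].astype(bool)] if s in X.columns]
        if refs and np.abs(X[refs].mean(axis=1).to_numpy()).max() > tol:
            warnings.warn(
                f"project {project!r} reference mean is non-zero; X does not "
                "look centered on its reference conditions",
                stacklevel=3,
            )


def run_ica(
    X: pd.DataFrame,
    dimension: int,
    n_restarts: int = 100,
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
    min_support_frac: float = 0.5,
    cluster_eps: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> IcaDecomposition:
    """Robust ICA: repeated FastICA restarts + component clustering.

    Each restart runs FastICA (log-cosh contrast, SVD whitening) with a seed
    derived deterministically from ``seed``. All gene-weight vectors are
    pooled, normalised, and clustered with DBSCAN on the precomputed distance
    1 - |r| (``eps`` = ``cluster_eps``); clusters drawing on fewer than
    ``min_support_frac`` of the restarts are discarded. The centrotype of
    each cluster becomes a column of M, and A = pinv(M) @ X.
    """
    genes = list(X.index)
    samples = list(X.columns)
    if dimension > min(len(genes), len(samples)):
        raise ValueError(
            f"dimension {dimension} exceeds min(genes, samples) = "
            f"{min(len(genes), len(samples))}"
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    _check_centered(X, metadata)

    Xv = X.to_numpy()
    # Whiten by SVD without centering: genes are the observations, and the
    # top-`dimension` left singular vectors span the retained subspace, so
    # M.A (A = pinv(M) X) reconstructs X up to the discarded-subspace
    # residual exactly.
    U, _, _ = np.linalg.svd(Xv, full_matrices=False)
    Z = U[:, :dimension] * np.sqrt(Xv.shape[0])

    comps: list[np.ndarray] = []
    run_of: list[int] = []
    for run, s in enumerate(spawn_seeds(seed, n_restarts, "ica-restarts")):
        ica = FastICA(
            fun="logcosh",
            whiten=False,
            tol=tol,
            max_iter=max_iter,
            random_state=s,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            S = ica.fit_transform(Z)  # genes x dimension
        for k in range(S.shape[1]):
            v = S[:, k]
            norm = np.linalg.norm(v)
            if norm == 0:
                continue
            comps.append(v / norm)
            run_of.append(run)

    P = np.asarray(comps)
    corr = np.clip(np.abs(P @ P.T), 0.0, 1.0)  # unit vectors: r == dot product
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)

    min_support = int(np.ceil(min_support_frac * n_restarts))
    labels = DBSCAN(eps=cluster_eps, min_samples=min_support, metric="precomputed").fit(
        dist
    ).labels_

    columns: list[np.ndarray] = []
    cluster_sizes: list[int] = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        support = len({run_of[i] for i in idx})
        if support < min_support:
            continue
        centro = idx[np.argmin(dist[np.ix_(idx, idx)].sum(axis=1))]
        v = P[centro].copy()
        if v[np.argmax(np.abs(v))] < 0:  # sign convention
            v = -v
        columns.append(v)
        cluster_sizes.append(support)

    if not columns:
        # Degenerate (e.g. pure noise); fall back to empty decomposition.
        M = pd.DataFrame(np.zeros((len(genes), 0)), index=genes)
        A = pd.DataFrame(np.zeros((0, len(samples))), columns=samples)
        return IcaDecomposition(M, A, n_restarts, [], dimension, seed)

    Mv = np.column_stack(columns)
    Av = np.linalg.pinv(Mv) @ Xv
    names = [f"ic_{i}" for i in range(Mv.shape[1])]
    M = pd.DataFrame(Mv, index=genes, columns=names)
    A = pd.DataFrame(Av, index=names, columns=samples)
    return IcaDecomposition(M, A, n_restarts, cluster_sizes, dimension, seed)


def sweep_dimensions(
    X: pd.DataFrame,
    dims: list[int],
    n_restarts: int = 10,
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
) -> DimensionSweepStats:
    """Run :func:`run_ica` over a strictly increasing list of dimensions.

    For each dimension the robust component count and the number of those
    components that are single-gene-like (thresholded membership empty or
    dominated by one gene) are recorded. Failures at individual dimensions
    are recorded as NaN-free zero rows and the sweep continues.
    """
    if not dims:
        raise ValueError("dims must be non-empty")
    if any(b <= a for a, b in zip(dims, dims[1:])):
        raise ValueError("dims must be strictly increasing")
    rows = []
    for d in dims:
        try:
            dec = run_ica(X, d, n_restarts=n_restarts, seed=seed, metadata=metadata)
            n_robust = dec.n_components
            n_single = 0
            for c in dec.M.columns:
                weights = dec.M[c]
                try:
                    _, members = threshold_gene_weights(weights)
                except ValueError:
                    members = set()
                if detect_single_gene_weights(weights, members):
                    n_single += 1
        except ValueError as err:
            warnings.warn(f"dimension {d} failed: {err}", stacklevel=2)
            n_robust = n_single = 0
        rows.append(
            {
                "dimension": d,
                "n_robust_components": n_robust,
                "n_single_gene_components": n_single,
                "n_non_single_gene": n_robust - n_single,
            }
        )
    table = pd.DataFrame(rows).set_index("dimension")
    return DimensionSweepStats(table)


def select_optimal_dimension(stats: DimensionSweepStats) -> OptimalDimension:
    """Pick the decomposition dimensionality from sweep statistics.

    Candidate dimensions are those at which the number of non-single-gene
    components equals the robust component count — i.e. no component has yet
    collapsed into a single-gene/noise component. Among candidates, the
    dimension yielding the most non-single-gene components wins (ties break
    toward the smaller dimension): under-decomposed runs satisfy the
    equality trivially but produce fewer components, while over-decomposed
    runs either breach the equality or plateau. If no dimension satisfies
    the equality, the dimension minimising the shortfall is returned (ties
    toward the smaller dimension) and the result is flagged approximate.
    """
    t = stats.table
    if t.empty:
        raise ValueError("empty sweep statistics")
    informative = t[t["n_robust_components"] > 0]
    if informative.empty:
        raise ValueError("no dimension produced robust components")
    exact = informative[
        informative["n_non_single_gene"] == informative["n_robust_components"]
    ]
    if not exact.empty:
        best = exact["n_non_single_gene"].max()
        return OptimalDimension(
            int(exact.index[exact["n_non_single_gene"] == best].min()), exact=True
        )
    shortfall = informative["n_robust_components"] - informative["n_non_single_gene"]
    return OptimalDimension(int(shortfall.idxmin()), exact=False)
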