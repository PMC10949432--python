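"""iModulon extraction and characterisation.

An iModulon is a thresholded column of the ICA gene-weight matrix M: the set
of genes whose weight magnitude stands out from the near-Gaussian bulk of
the component. This module provides the thresholding procedure, the
explained-variance (sigma^2) computation, single-gene detection, activity
correlation/clustering, and differential iModulon activity (DIMA) between
condition groups with a replicate-fitted log-normal null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IModulon",
    "threshold_gene_weights",
    "explained_variance",
    "detect_single_gene",
    "detect_single_gene_weights",
    "correlate_and_cluster_imodulons",
    "differential_activity",
    "extract_imodulons",
]

CATEGORIES = {"regulatory", "functional", "single-gene", "uncharacterized"}


@dataclass
class IModulon:
    """A thresholded gene set derived from one robust ICA component."""

    name: str
    component_index: int
    gene_weights: pd.Series
    threshold: float
    member_genes: set[str]
    explained_variance: float | None = None
    category: str = "uncharacterized"
    enrichment: object | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def size(self) -> int:
        return len(self.member_genes)


def threshold_gene_weights(
    weights: pd.Series,
    method: str = "dagostino",
    dagostino_p: float = 1e-4,
    quantile_c: float = 3.0,
) -> tuple[float, set[str]]:
    """Separate a component's outlier genes from its Gaussian bulk.

    ``dagostino`` (default): iteratively strip the largest-|weight| gene
    until the remainder passes a D'Agostino K^2 normality test
    (p > ``dagostino_p``); the threshold is placed midway between the
    smallest stripped |weight| and the largest kept one, so membership
    (|weight| > threshold) is exactly the stripped set. ``quantile``:
    threshold = mean(|w|) + ``quantile_c`` * sd(|w|).

    Returns (threshold, member gene set); the member set is empty when the
    weights are already Gaussian (the caller should demote the component).
    """
    if len(weights) < 10:
        raise ValueError("need at least 10 genes to threshold a component")
    absw = weights.abs().to_numpy()
    if np.allclose(absw, absw[0]):
        raise ValueError("degenerate component: all weights identical")

    if method == "quantile":
        threshold = float(absw.mean() + quantile_c * absw.std())
        members = set(weights.index[np.abs(weights.to_numpy()) > threshold])
        return threshold, members
    if method != "dagostino":
        raise ValueError(f"unknown thresholding method {method!r}")

    order = np.argsort(absw)[::-1]  # largest |w| first
    w = weights.to_numpy()
    n = len(w)
    n_removed = 0
    # Keep at least 8 genes in the bulk so the normality test is defined.
    while n - n_removed > 8:
        remaining = w[order[n_removed:]]
        if stats.normaltest(remaining).pvalue > dagostino_p:
            break
        n_removed += 1
    if n_removed == 0:
        return float(absw.max()), set()
    smallest_removed = absw[order[n_removed - 1]]
    largest_kept = absw[order[n_removed:]].max() if n_removed < n else 0.0
    threshold = float((smallest_removed + largest_kept) / 2)
    members = set(weights.index[np.abs(w) > threshold])
    return threshold, members


def explained_variance(
    X: pd.DataFrame | np.ndarray,
    M: pd.DataFrame | np.ndarray,
    A: pd.DataFrame | np.ndarray,
    subset: list | None = None,
) -> float:
    """Fraction of compendium variance captured by a component subset.

    sigma^2(S) = 1 - ||X - M_S A_S||_F^2 / ||X||_F^2, with X the centered
    compendium. ``subset`` selects component columns of M (and rows of A);
    ``None`` uses all components. The empty subset gives 0.
    """
    Xv = np.asarray(X, dtype=float)
    Mv = np.asarray(M, dtype=float)
    Av = np.asarray(A, dtype=float)
    x_norm2 = float(np.sum(Xv**2))
    if x_norm2 == 0:
        raise ValueError("X has zero norm; explained variance undefined")
    if subset is not None:
        if isinstance(M, pd.DataFrame):
            idx = [M.columns.get_loc(c) if not isinstance(c, (int, np.integer)) else int(c)
                   for c in subset]
        else:
            idx = [int(c) for c in subset]
        Mv = Mv[:, idx]
        Av = Av[idx, :]
    if Mv.shape[1] == 0:
        return 0.0
    resid = Xv - Mv @ Av
    return 1.0 - float(np.sum(resid**2)) / x_norm2


def detect_single_gene_weights(weights: pd.Series, member_genes: set[str]) -> bool:
    """Single-gene test on raw weights + membership.

    True when the membership is a single gene, when thresholding left no
    members (a noise-shaped component with no outlier block), or when the
    top gene carries at least half of the column's total squared weight.
    """
    if len(member_genes) <= 1:
        return True
    w2 = weights.to_numpy() ** 2
    return bool(w2.max() >= 0.5 * w2.sum())


def detect_single_gene(imodulon: IModulon) -> bool:
    """True iff the iModulon is dominated by a single high-coefficient gene."""
    return detect_single_gene_weights(imodulon.gene_weights, imodulon.member_genes)


def extract_imodulons(
    M: pd.DataFrame,
    X: pd.DataFrame | None = None,
    A: pd.DataFrame | None = None,
    method: str = "dagostino",
) -> list[IModulon]:
    """Threshold every component of M into an iModulon.

    When X and A are supplied, each iModulon's singleton explained variance
    is computed; single-gene iModulons are categorised as such.
    """
    out = []
    for i, c in enumerate(M.columns):
        weights = M[c]
        try:
            threshold, members = threshold_gene_weights(weights, method=method)
        except ValueError:
            threshold, members = float(weights.abs().max()), set()
        ev = None
        if X is not None and A is not None:
            ev = explained_variance(X, M, A, subset=[c])
        im = IModulon(
            name=str(c),
            component_index=i,
            gene_weights=weights,
            threshold=threshold,
            member_genes=members,
            explained_variance=ev,
        )
        if detect_single_gene(im):
            im.category = "single-gene"
        out.append(im)
    return out


def correlate_and_cluster_imodulons(
    A: pd.DataFrame,
    linkage: str = "average",
    distance: str = "spearman",
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Cluster iModulons by the similarity of their activity profiles.

    Pairwise Spearman correlation of activity rows, hierarchical clustering
    (default average linkage) on 1 - r, and flat clusters cut at half the
    maximum merge height. Returns (correlation matrix, linkage matrix, flat
    cluster labels); per-cluster mean Spearman R is attached to the labels'
    ``.attrs['cluster_mean_r']``.
    """
    if A.shape[0] < 2:
        raise ValueError("need at least 2 components to cluster")
    sds = A.std(axis=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(f"constant activity row(s): {constant}; correlation undefined")
    if distance == "spearman":
        corr, _ = stats.spearmanr(A.to_numpy(), axis=1)
        corr = np.atleast_2d(corr)
    elif distance == "pearson":
        corr = np.corrcoef(A.to_numpy())
    else:
        raise ValueError(f"unknown distance {distance!r}")
    corr_df = pd.DataFrame(corr, index=A.index, columns=A.index)

    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    cut = Z[:, 2].max() / 2 if len(Z) else 0.0
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    flat = pd.Series(labels, index=A.index, name="cluster")

    means = {}
    for lab in np.unique(labels):
        members = flat.index[flat == lab]
        if len(members) < 2:
            means[int(lab)] = 1.0
            continue
        sub = corr_df.loc[members, members].to_numpy()
        means[int(lab)] = float(sub[np.triu_indices(len(members), k=1)].mean())
    flat.attrs["cluster_mean_r"] = means
    return corr_df, Z, flat


def fit_replicate_null(
    A: pd.DataFrame, replicate_pairs: list[tuple[str, str]]
) -> tuple[float, float]:
    """Fit a log-normal null to |activity differences| between replicates.

    Pools the absolute per-component activity differences across all
    biological replicate pairs and fits log-normal parameters (mean, sd of
    the log) by moment matching on the logs. Zero differences are dropped.
    """
    if not replicate_pairs:
        raise ValueError(
            "no replicate pairs available to fit the null; pass explicit "
            "null parameters instead"
        )
    diffs = []
    for a, b in replicate_pairs:
        diffs.append(np.abs(A[a].to_numpy() - A[b].to_numpy()))
    d = np.concatenate(diffs)
    d = d[d > 0]
    if d.size < 3:
        raise ValueError("too few non-zero replicate differences to fit a null")
    logs = np.log(d)
    return float(logs.mean()), float(logs.std(ddof=1))


def differential_activity(
    A: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    replicate_pairs: list[tuple[str, str]] | None = None,
    null_params: tuple[float, float] | None = None,
    alpha: float = 0.05,
    scale_null_to_groups: bool = True,
) -> pd.DataFrame:
    """Differential iModulon activity (DIMA) between two sample groups.

    delta = mean activity over ``group2`` minus mean over ``group1`` per
    component. Two-sided p-values come from a log-normal null on |delta|
    fitted to activity differences between biological replicate pairs
    (``replicate_pairs``), or from explicit ``null_params`` = (log-mean,
    log-sd). Significance is Benjamini-Hochberg FDR at ``alpha``.

    The replicate pairs measure single-sample scatter, but delta is a
    difference of group means of n1 and n2 samples, which scatters by the
    factor sqrt((1/n1 + 1/n2) / 2) relative to a single replicate pair.
    With ``scale_null_to_groups`` (default) the fitted log-mean is shifted
    by the log of that factor; disabling it leaves the raw pair null,
    which is conservative for multi-sample groups.
    """
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    if null_params is None:
        if not replicate_pairs:
            raise ValueError(
                "no replicate pairs for null fitting; pass null_params=(mu, sigma)"
            )
        null_params = fit_replicate_null(A, replicate_pairs)
    mu, sigma = null_params
    if scale_null_to_groups:
        mu += float(np.log(np.sqrt((1 / len(g1) + 1 / len(g2)) / 2)))

    delta = A[g2].mean(axis=1) - A[g1].mean(axis=1)
    absd = delta.abs().to_numpy()
    with np.errstate(divide="ignore"):
        p = stats.lognorm.sf(absd, s=sigma, scale=np.exp(mu))
    p = np.clip(p, 0.0, 1.0)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "component": A.index,
            "delta_activity": delta.to_numpy(),
            "p_value": p,
            "q_value": q,
            "significant": reject,
        }
    ).set_index("component")
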