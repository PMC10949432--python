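"""Regulon enrichment of iModulons against a draft TRN.

Each (iModulon, regulator) pair is tested for overlap with a one-sided
Fisher exact test (hypergeometric tail) over the gene universe of the
expression matrix; q-values are Benjamini-Hochberg across the whole pair
grid. Two recall metrics summarise agreement: iModulon recall = shared
genes / iModulon size, regulon recall = shared genes / regulon size; the
(regulon recall, iModulon recall) plane is cut into four quadrants —
well matched, regulon subset, regulon discovery, poorly matched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "compute_recalls",
    "enrich_regulons",
    "classify_quadrant",
    "trn_to_regulons",
]

QUADRANTS = {"well_matched", "regulon_subset", "regulon_discovery", "poorly_matched"}


@dataclass
class EnrichmentResult:
    imodulon: str
    regulator: str
    overlap: int
    p_value: float
    q_value: float
    imodulon_recall: float
    regulon_recall: float
    quadrant: str


def trn_to_regulons(trn: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse a (regulator, gene) table to regulator -> gene set.

    Duplicate pairs are rejected; row order is irrelevant.
    """
    if trn.duplicated(subset=["regulator", "gene"]).any():
        raise ValueError("duplicate (regulator, gene) pairs in TRN table")
    return {
        reg: set(sub["gene"]) for reg, sub in trn.groupby("regulator", sort=True)
    }


def compute_recalls(
    imodulon_genes: set[str], regulon_genes: set[str]
) -> tuple[float, float]:
    """iModulon recall = |shared| / |iModulon|; regulon recall = |shared| / |regulon|."""
    if not imodulon_genes or not regulon_genes:
        raise ValueError("both gene sets must be non-empty")
    shared = len(imodulon_genes & regulon_genes)
    return shared / len(imodulon_genes), shared / len(regulon_genes)


def classify_quadrant(
    imodulon_recall: float, regulon_recall: float, cut: float = 0.6
) -> str:
    """Quadrant of the (regulon recall, iModulon recall) plane.

    High/high = well matched; high iModulon recall only = regulon subset
    (the iModulon is a subset of a larger regulon); high regulon recall
    only = regulon discovery (the iModulon extends a known regulon); else
    poorly matched.
    """
    for name, v in (("imodulon_recall", imodulon_recall), ("regulon_recall", regulon_recall)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if imodulon_recall >= cut and regulon_recall >= cut:
        return "well_matched"
    if imodulon_recall >= cut:
        return "regulon_subset"
    if regulon_recall >= cut:
        return "regulon_discovery"
    return "poorly_matched"


def enrich_regulons(
    imodulons: dict[str, set[str]],
    trn: pd.DataFrame,
    background: set[str],
    alpha: float = 0.05,
    quadrant_cut: float = 0.6,
) -> pd.DataFrame:
    """Fisher-exact enrichment of every iModulon against every regulon.

    ``imodulons`` maps name -> member gene set; ``background`` is the gene
    universe (all genes in the expression matrix). Regulons are restricted
    to the background; regulators with no background genes are skipped with
    a warning. Returns one row per tested pair with p, BH q (across the
    full grid), both recalls, the quadrant, and whether the regulator is
    attached (best q per iModulon and q <= alpha).
    """
    regulons = trn_to_regulons(trn)
    rows = []
    N = len(background)
    for im_name, im_genes in imodulons.items():
        if not im_genes:
            continue
        im_in_bg = im_genes & background
        for reg, reg_genes in regulons.items():
            reg_in_bg = reg_genes & background
            if not reg_in_bg:
                warnings.warn(
                    f"regulator {reg!r} has no genes in the background; skipped",
                    stacklevel=2,
                )
                continue
            overlap = len(im_in_bg & reg_in_bg)
            # one-sided hypergeometric tail P(X >= overlap)
            p = float(
                stats.hypergeom.sf(overlap - 1, N, len(reg_in_bg), len(im_in_bg))
            )
            im_recall, reg_recall = compute_recalls(im_genes, reg_genes)
            rows.append(
                {
                    "imodulon": im_name,
                    "regulator": reg,
                    "overlap": overlap,
                    "imodulon_size": len(im_genes),
                    "regulon_size": len(reg_genes),
                    "p_value": min(p, 1.0),
                    "imodulon_recall": im_recall,
                    "regulon_recall": reg_recall,
                    "quadrant": classify_quadrant(im_recall, reg_recall, cut=quadrant_cut),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "imodulon", "regulator", "overlap", "imodulon_size", "regulon_size",
                "p_value", "q_value", "imodulon_recall", "regulon_recall",
                "quadrant", "attached",
            ]
        )
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
    table["q_value"] = q

    attached = []
    best = table.loc[table.groupby("imodulon")["q_value"].idxmin()]
    best_pairs = {
        (r.imodulon, r.regulator)
        for r in best.itertuples()
        if r.q_value <= alpha
    }
    for r in table.itertuples():
        attached.append((r.imodulon, r.regulator) in best_pairs)
    table["attached"] = attached
    return table.sort_values(["imodulon", "q_value"]).reset_index(drop=True)
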