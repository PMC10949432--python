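"""Compendium quality control: sample exclusion, replicate-correlation
filtering with group averaging, and reference-condition centering.

The QC pipeline applies three steps in a fixed order:

1. :func:`exclude_failing_samples` — drop samples with too few mapped reads,
   failed sequence-level QC, missing metadata, or no replicate partner.
2. :func:`replicate_correlation_filter` — within each (project, condition)
   replicate group, if ANY pairwise Pearson correlation falls below the
   threshold (default 0.80), the whole group is collapsed to its arithmetic
   mean profile.
3. :func:`center_to_reference` — subtract each project's reference-condition
   mean profile from every sample in that project.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionCompendium",
    "QcReport",
    "exclude_failing_samples",
    "replicate_correlation_filter",
    "center_to_reference",
    "hierarchical_outlier_report",
]

EXCLUSION_REASONS = {"low_reads", "fastqc_fail", "no_metadata", "no_replicate", "low_correlation"}

METADATA_COLUMNS = [
    "project",
    "condition",
    "replicate_index",
    "is_reference",
    "mapped_reads",
    "fastqc_pass",
]


@dataclass
class ExpressionCompendium:
    """A logTPM gene x sample matrix plus per-sample metadata.

    ``data`` holds genes as rows and samples as columns; ``metadata`` is
    indexed by sample id with columns project, condition, replicate_index,
    is_reference, mapped_reads, fastqc_pass. Identifiers must be unique and
    the two tables must describe the same sample set.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers in expression matrix")
        missing = set(self.data.columns) - set(self.metadata.index)
        extra = set(self.metadata.index) - set(self.data.columns)
        if missing or extra:
            raise ValueError(
                f"metadata/matrix sample mismatch: {len(missing)} samples lack "
                f"metadata, {len(extra)} metadata rows lack expression columns"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, samples: list[str]) -> "ExpressionCompendium":
        return ExpressionCompendium(
            data=self.data[samples], metadata=self.metadata.loc[samples]
        )


@dataclass
class QcReport:
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)  # (sample, reason)
    averaged_groups: list[dict] = field(default_factory=list)
    threshold_used: float | None = None

    def add_exclusion(self, sample: str, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        self.excluded_samples.append((sample, reason))

    def to_dict(self) -> dict:
        return {
            "excluded_samples": [
                {"sample": s, "reason": r} for s, r in self.excluded_samples
            ],
            "averaged_groups": self.averaged_groups,
            "threshold_used": self.threshold_used,
        }


def exclude_failing_samples(
    compendium: ExpressionCompendium,
    metadata: pd.DataFrame | None = None,
    min_reads: int = 500_000,
) -> tuple[ExpressionCompendium, QcReport]:
    """Drop samples failing read-depth, sequence-QC, or replication rules.

    A sample is excluded when its mapped-read count is below ``min_reads``
    (default 500,000 reads mapped to coding sequences), when it failed
    sequence-level QC, or when it has no metadata row. Samples whose
    (project, condition) group is left with fewer than two members are then
    dropped as replicate-less.
    """
    meta = compendium.metadata if metadata is None else metadata
    report = QcReport()
    surviving = []
    for s in compendium.sample_ids:
        if s not in meta.index or meta.loc[s].isna().any():
            report.add_exclusion(s, "no_metadata")
        elif int(meta.loc[s, "mapped_reads"]) < min_reads:
            report.add_exclusion(s, "low_reads")
        elif not bool(meta.loc[s, "fastqc_pass"]):
            report.add_exclusion(s, "fastqc_fail")
        else:
            surviving.append(s)

    kept = meta.loc[surviving]
    sizes = kept.groupby(["project", "condition"])["replicate_index"].transform("size")
    for s in surviving:
        if sizes.loc[s] < 2:
            report.add_exclusion(s, "no_replicate")
    singles = {s for s in surviving if sizes.loc[s] < 2}
    surviving = [s for s in surviving if s not in singles]

    if not surviving:
        raise ValueError("no samples survive exclusion filters")
    return compendium.subset(surviving), report


def _pairwise_pearson(block: np.ndarray, sample_ids: list[str]) -> list[tuple[str, str, float]]:
    sds = block.std(axis=0)
    for s, sd in zip(sample_ids, sds):
        if sd == 0:
            raise ValueError(f"sample {s!r} has zero variance; Pearson r undefined")
    corr = np.corrcoef(block, rowvar=False)
    return [
        (sample_ids[i], sample_ids[j], float(corr[i, j]))
        for i, j in itertools.combinations(range(len(sample_ids)), 2)
    ]


def replicate_correlation_filter(
    compendium: ExpressionCompendium,
    metadata: pd.DataFrame | None = None,
    threshold: float = 0.80,
) -> tuple[ExpressionCompendium, QcReport]:
    """Collapse internally inconsistent replicate groups to their mean.

    For each (project, condition) group, all pairwise Pearson correlations
    between member columns are computed on the logTPM values. If any pair
    falls below ``threshold``, the entire group is replaced by a single
    column equal to the unweighted arithmetic mean of its members (sample id
    ``{project}.{condition}_avg``); otherwise the group passes unchanged.
    """
    meta = (compendium.metadata if metadata is None else metadata).copy()
    report = QcReport(threshold_used=threshold)

    new_cols: dict[str, np.ndarray] = {}
    new_meta_rows: dict[str, dict] = {}
    for (project, condition), group in meta.groupby(["project", "condition"], sort=False):
        members = [s for s in compendium.sample_ids if s in group.index]
        block = compendium.data[members].to_numpy()
        pairs = _pairwise_pearson(block, members)
        if any(r < threshold for _, _, r in pairs):
            avg_id = f"{project}.{condition}_avg"
            new_cols[avg_id] = block.mean(axis=1)
            row = group.iloc[0].to_dict()
            row["replicate_index"] = 1
            new_meta_rows[avg_id] = row
            report.averaged_groups.append(
                {
                    "project": project,
                    "condition": condition,
                    "members": members,
                    "pairwise_r": [
                        {"a": a, "b": b, "r": r} for a, b, r in pairs
                    ],
                    "averaged_as": avg_id,
                }
            )
            for s in members:
                report.add_exclusion(s, "low_correlation")
        else:
            for s in members:
                new_cols[s] = compendium.data[s].to_numpy()
                new_meta_rows[s] = meta.loc[s].to_dict()

    data = pd.DataFrame(new_cols, index=compendium.data.index)
    new_meta = pd.DataFrame.from_dict(new_meta_rows, orient="index")
    new_meta.index.name = "sample_id"
    return ExpressionCompendium(data=data, metadata=new_meta), report


def center_to_reference(
    compendium: ExpressionCompendium, metadata: pd.DataFrame | None = None
) -> ExpressionCompendium:
    """Center each project on its reference condition.

    For every sample of project *p*, the gene-wise mean profile of *p*'s
    reference-condition samples is subtracted, so each reference group's mean
    becomes the zero vector. Raises if a project lacks a reference condition.
    """
    meta = compendium.metadata if metadata is None else metadata
    data = compendium.data.copy()
    for project, group in meta.groupby("project", sort=False):
        ref_samples = group.index[group["is_reference"].astype(bool)]
        if len(ref_samples) == 0:
            raise ValueError(f"project {project!r} has no reference condition")
        ref_profile = compendium.data[list(ref_samples)].mean(axis=1)
        data[list(group.index)] = data[list(group.index)].sub(ref_profile, axis=0)
    return ExpressionCompendium(data=data, metadata=meta.copy())


def hierarchical_outlier_report(
    compendium: ExpressionCompendium, cut_height: float = 0.3
) -> dict:
    """Advisory outlier scan via correlation-linkage hierarchical clustering.

    Samples are clustered by average linkage on 1 - Pearson r; singleton
    clusters at ``cut_height`` are flagged as atypical expression profiles.
    This is a report only — no sample is ever excluded automatically, since
    no principled cut criterion exists without manual review.
    """
    corr = np.corrcoef(compendium.data.to_numpy(), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    counts = pd.Series(labels).value_counts()
    flagged = [
        s for s, lab in zip(compendium.sample_ids, labels) if counts[lab] == 1
    ]
    return {
        "linkage": Z,
        "cluster_labels": dict(zip(compendium.sample_ids, labels.tolist())),
        "flagged_samples": flagged,
        "cut_height": cut_height,
    }
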