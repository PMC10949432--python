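"""End-to-end pipeline driver: QC -> ICA -> iModulons -> enrichment ->
operons -> motif scan -> regulon classifier.

The driver is deliberately thin: every stage is an ordinary library call,
and failure of an optional stage (TRN enrichment, operon/motif/classifier
arm) is logged without aborting the core ICA path. A manifest records the
master seed, a configuration hash, and the defaults in effect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as mio
from .classifier import evaluate_cv
from .enrichment import enrich_regulons
from .ica import run_ica, select_optimal_dimension, sweep_dimensions
from .imodulons import explained_variance, extract_imodulons
from .motifs import build_pssm, score_operon_promoters
from .operons import cluster_operons
from .qc import (
    center_to_reference,
    exclude_failing_samples,
    replicate_correlation_filter,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serialisable to/from YAML or JSON."""

    expression: str
    metadata: str
    outdir: str
    seed: int
    trn: str | None = None
    gff3: str | None = None
    promoters: str | None = None
    sites: str | None = None
    qc_min_reads: int = 500_000
    qc_threshold: float = 0.80
    ica_dimension: int | None = None
    ica_sweep: list[int] = field(default_factory=list)
    ica_restarts: int = 100
    threshold_method: str = "dagostino"
    enrichment_alpha: float = 0.05
    quadrant_cut: float = 0.6
    operon_gap: int = 500
    pssm_pseudocount: float = 0.5
    pssm_background: str = "promoters"  # promoters | sites
    classifier_labels: str | None = None
    l1_ratio: float = 0.5
    k_neighbors: int = 5
    folds: int = 5

    def __post_init__(self) -> None:
        for name in ("expression", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns a manifest of outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "seed": config.seed,
        "config_hash": chash,
        "outputs": {},
        "stages": {},
        "decisions": {
            "qc_order": "exclude -> correlation filter -> center",
            "averaging": "unweighted arithmetic mean over logTPM",
            "threshold_method": config.threshold_method,
            "quadrant_cut": config.quadrant_cut,
            "operon_gap_bp": config.operon_gap,
            "pssm_pseudocount": config.pssm_pseudocount,
        },
    }

    def _save(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    # --- QC ---------------------------------------------------------------
    compendium = mio.read_compendium(config.expression, config.metadata)
    compendium, excl_report = exclude_failing_samples(
        compendium, min_reads=config.qc_min_reads
    )
    compendium, corr_report = replicate_correlation_filter(
        compendium, threshold=config.qc_threshold
    )
    compendium = center_to_reference(compendium)
    qc_path = outdir / "qc_report.json"
    mio.write_json_report(
        {"exclusions": excl_report.to_dict(), "correlation": corr_report.to_dict()},
        qc_path, seed=config.seed, config_hash=chash,
    )
    mio.write_expression_tsv(compendium.data, outdir / "X_filtered.tsv")
    _save("qc_report", qc_path)
    _save("X_filtered", outdir / "X_filtered.tsv")
    manifest["stages"]["qc"] = "ok"

    # --- ICA --------------------------------------------------------------
    dim = config.ica_dimension
    if config.ica_sweep:
        stats = sweep_dimensions(
            compendium.data, config.ica_sweep, n_restarts=config.ica_restarts,
            seed=config.seed, metadata=compendium.metadata,
        )
        stats.table.to_csv(outdir / "dimension_sweep.tsv", sep="\t")
        _save("dimension_sweep", outdir / "dimension_sweep.tsv")
        dim = int(select_optimal_dimension(stats))
        manifest["stages"]["sweep"] = {"selected_dimension": dim}
    if dim is None:
        raise ValueError("config must set ica_dimension or ica_sweep")
    dec = run_ica(
        compendium.data, dim, n_restarts=config.ica_restarts, seed=config.seed,
        metadata=compendium.metadata,
    )
    dec.M.to_csv(outdir / "M.tsv", sep="\t")
    dec.A.to_csv(outdir / "A.tsv", sep="\t")
    _save("M", outdir / "M.tsv")
    _save("A", outdir / "A.tsv")
    manifest["stages"]["ica"] = {
        "dimension": dim, "n_robust_components": dec.n_components,
        "total_explained_variance": explained_variance(
            compendium.data, dec.M, dec.A
        ) if dec.n_components else 0.0,
    }

    # --- iModulons --------------------------------------------------------
    imods = extract_imodulons(
        dec.M, X=compendium.data, A=dec.A, method=config.threshold_method
    )
    imod_table = pd.DataFrame(
        [
            {
                "name": im.name, "threshold": im.threshold, "n_genes": im.size,
                "explained_variance": im.explained_variance,
                "category": im.category,
                "genes": ";".join(sorted(im.member_genes)),
            }
            for im in imods
        ]
    )
    imod_table.to_csv(outdir / "imodulons.tsv", sep="\t", index=False)
    mio.write_json_report(
        {"imodulons": imod_table.to_dict(orient="records")},
        outdir / "imodulons.json", seed=config.seed, config_hash=chash,
    )
    _save("imodulons", outdir / "imodulons.json")
    manifest["stages"]["imodulons"] = {"n": len(imods)}

    # --- enrichment (optional) -------------------------------------------
    if config.trn and Path(config.trn).exists():
        trn = mio.read_trn_tsv(config.trn)
        table = enrich_regulons(
            {im.name: im.member_genes for im in imods if im.member_genes},
            trn, background=set(compendium.gene_ids),
            alpha=config.enrichment_alpha, quadrant_cut=config.quadrant_cut,
        )
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        _save("enrichment", outdir / "enrichment.tsv")
        manifest["stages"]["enrichment"] = {"n_pairs": len(table)}
    else:
        log.warning("TRN table missing; enrichment stage skipped")
        manifest["stages"]["enrichment"] = "skipped"

    # --- bitome arm: operons, motif scan, classifier (optional) ----------
    operon_map = None
    if config.gff3 and Path(config.gff3).exists():
        try:
            genes = mio.read_gff3_genes(config.gff3)
            operon_map = cluster_operons(genes, gap_threshold=config.operon_gap)
            operon_map.to_frame(genes).to_csv(
                outdir / "operons.tsv", sep="\t", index=False
            )
            _save("operons", outdir / "operons.tsv")
            manifest["stages"]["operons"] = {"n_operons": operon_map.n_operons}
        except Exception as err:  # optional stage must not abort the core path
            log.warning("operon stage failed: %s", err)
            manifest["stages"]["operons"] = f"failed: {err}"

    score_table = None
    if operon_map is not None and config.promoters and config.sites:
        try:
            promoters = mio.read_fasta(config.promoters)
            sites = list(mio.read_fasta(config.sites).values())
            background = (
                list(promoters.values())
                if config.pssm_background == "promoters" else sites
            )
            pssm = build_pssm(sites, background, pseudocount=config.pssm_pseudocount)
            score_table = score_operon_promoters(operon_map, promoters, pssm)
            score_table.to_csv(outdir / "motif_scores.tsv", sep="\t", index=False)
            _save("motif_scores", outdir / "motif_scores.tsv")
            manifest["stages"]["motif_scan"] = {"n_operons_scored": int(score_table["has_promoter"].sum())}
        except Exception as err:
            log.warning("motif stage failed: %s", err)
            manifest["stages"]["motif_scan"] = f"failed: {err}"

    if score_table is not None and config.classifier_labels and Path(config.classifier_labels).exists():
        try:
            labels = pd.read_csv(
                config.classifier_labels, sep="\t", index_col=0
            ).iloc[:, 0]
            gene_scores = score_table.attrs["gene_scores"].set_index("gene_id")
            report = evaluate_cv(
                gene_scores[["best_score"]], labels, operon_map,
                k=config.folds, l1_ratio=config.l1_ratio,
                k_neighbors=config.k_neighbors, seed=config.seed,
            )
            mio.write_json_report(
                report.to_dict(), outdir / "classifier_report.json",
                seed=config.seed, config_hash=chash,
            )
            _save("classifier_report", outdir / "classifier_report.json")
            manifest["stages"]["classifier"] = {"mean_auc": report.mean_auc}
        except Exception as err:
            log.warning("classifier stage failed: %s", err)
            manifest["stages"]["classifier"] = f"failed: {err}"

    mio.write_json_report(manifest, outdir / "manifest.json", seed=config.seed,
                          config_hash=chash)
    _save("manifest", outdir / "manifest.json")
    return manifest
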