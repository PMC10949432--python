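"""File formats: expression/metadata/TRN TSV, GFF3, FASTA, JSON reports.

All tabular files are tab-separated with headers. Round-trip fidelity is
part of the contract: writing then reading preserves identifiers exactly
and values to better than 1e-12.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .operons import GeneRecord
from .qc import ExpressionCompendium, METADATA_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_metadata_tsv", "write_metadata_tsv",
    "read_trn_tsv", "write_trn_tsv",
    "read_gff3_genes", "write_gff3_genes",
    "read_fasta", "write_fasta",
    "write_json_report", "read_compendium",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    # pandas silently renames duplicate column labels, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise ValueError(f"{path}: duplicate sample identifiers")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {missing}")
    meta["is_reference"] = meta["is_reference"].astype(bool)
    meta["fastqc_pass"] = meta["fastqc_pass"].astype(bool)
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_compendium(expression_path: str | Path, metadata_path: str | Path) -> ExpressionCompendium:
    return ExpressionCompendium(
        data=read_expression_tsv(expression_path),
        metadata=read_metadata_tsv(metadata_path),
    )


def read_trn_tsv(path: str | Path) -> pd.DataFrame:
    trn = pd.read_csv(path, sep="\t")
    for col in ("regulator", "gene"):
        if col not in trn.columns:
            raise ValueError(f"{path}: TRN table needs a {col!r} column")
    return trn[["regulator", "gene"]]


def write_trn_tsv(trn: pd.DataFrame, path: str | Path) -> None:
    trn[["regulator", "gene"]].to_csv(path, sep="\t", index=False)


def read_gff3_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneRecord]:
    """Read gene records from a GFF3 file (type ``gene`` by default).

    Every feature must carry an ``ID`` (or ``locus_tag``) attribute; a
    missing identifier is reported with its line number.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            gid = feat.attributes.get("ID", feat.attributes.get("locus_tag", [None]))[0]
            if gid is None:
                raise ValueError(
                    f"{path}: {ftype} at {feat.seqid}:{feat.start}-{feat.end} "
                    "lacks an ID attribute"
                )
            records.append(
                GeneRecord(
                    gene_id=gid, accession=feat.seqid,
                    start=feat.start, end=feat.end, strand=feat.strand,
                )
            )
    if not records:
        raise ValueError(f"{path}: no features of type {feature_types} found")
    return records


def write_gff3_genes(genes: list[GeneRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(genes, pd.DataFrame):
        from .operons import genes_from_dataframe

        genes = genes_from_dataframe(genes)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.accession}\tmodulonkit\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into id -> sequence; lowercase bases are uppercased."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if s != s.upper():
            log.info("FASTA %s: sequence %s uppercased on read", path, rec.id)
        seqs[rec.id] = s.upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_json_report(obj: dict, path: str | Path, seed: int | None = None,
                      config_hash: str | None = None) -> None:
    payload = dict(obj)
    if seed is not None or config_hash is not None:
        payload["_provenance"] = {"seed": seed, "config_hash": config_hash}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
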