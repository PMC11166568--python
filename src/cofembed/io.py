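"""Readers, writers and run artifacts.

File formats are the plain-text lingua franca of the field: Matrix Market
bundles with TSV id sidecars for cell-by-feature matrices, BED for peaks,
TSV (or GTF) for gene annotation, FASTA for peak sequences, JASPAR-style
text for position weight matrices. ``save_artifacts`` writes a run's
outputs atomically with a content-hash manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomicAnnotation
from .matrix import CellFeatureMatrix

__all__ = [
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "read_fasta",
    "write_fasta",
    "read_jaspar_pwms",
    "load_dataset",
    "save_artifacts",
]


# ---------------------------------------------------------------------------
# matrix bundles
# ---------------------------------------------------------------------------


def write_mtx_bundle(m: CellFeatureMatrix, outdir) -> None:
    """Write matrix.mtx (cells x features) + barcodes.tsv + features.tsv.

    A meta.json sidecar records the layer, the feature kind and any
    preprocessing parameters stored on the matrix (e.g. discretization
    boundaries), so a round trip reproduces the object exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), m.values)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.feature_ids).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    meta = {"layer": m.layer, "feature_kind": m.feature_kind, "meta": _jsonable(m.meta)}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def read_mtx_bundle(indir) -> CellFeatureMatrix:
    """Read a matrix bundle written by :func:`write_mtx_bundle`."""
    indir = Path(indir)
    values = scipy.io.mmread(str(indir / "matrix.mtx"))
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None, dtype=str)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None, dtype=str)[0]
    values = sp.csr_matrix(values)
    if values.shape[0] != len(barcodes):
        raise ValueError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix has {values.shape[0]}"
        )
    if values.shape[1] != len(features):
        raise ValueError(
            f"features.tsv has {len(features)} rows but matrix has {values.shape[1]} columns"
        )
    meta_path = indir / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CellFeatureMatrix(
        values=values,
        cell_ids=barcodes.to_numpy(dtype=object),
        feature_ids=features.to_numpy(dtype=object),
        feature_kind=meta.get("feature_kind", "gene"),
        layer=meta.get("layer", "raw"),
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# genomic intervals and annotation
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> DataFrame(peak_id, chrom, start, end)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected at least 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
            rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    if df["peak_id"].duplicated().any():
        dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise ValueError(f"{path}: duplicate peak id {dup!r}")
    return df


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation from a 5-column TSV or a GTF file.

    The TSV form has a header ``gene_id chrom start end strand``; in the
    GTF form, lines with feature type ``gene`` are used and ``gene_id`` is
    taken from the attribute column. Coordinates are returned 0-based
    half-open (GTF input is converted).
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        recs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{ln}: expected 9 GTF columns")
                if parts[2] != "gene":
                    continue
                attrs = dict(
                    (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                    for kv in parts[8].rstrip(";").split(";")
                    if kv.strip()
                )
                if "gene_id" not in attrs:
                    raise ValueError(f"{path}:{ln}: gene line without gene_id")
                recs.append(
                    (attrs["gene_id"], parts[0], int(parts[3]) - 1, int(parts[4]), parts[6])
                )
        df = pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand"])
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        missing = {"gene_id", "chrom", "start", "end", "strand"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# sequences and motifs
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict:
    """FASTA -> ordered dict of id -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar_pwms(path) -> dict:
    """JASPAR-format motifs -> dict of motif id -> 4 x L count matrix."""
    out = {}
    with open(path) as fh:
        for motif in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
            name = motif.matrix_id or motif.name
            out[name] = counts
    return out


def load_dataset(path, kind: str):
    """Dispatch loader: kind in {matrix, bed, genes, fasta, pwms, graph}."""
    from .graph import MultiRelationGraph

    loaders = {
        "matrix": read_mtx_bundle,
        "bed": read_bed,
        "genes": read_gene_annotation,
        "fasta": read_fasta,
        "pwms": read_jaspar_pwms,
        "graph": MultiRelationGraph.load,
    }
    if kind not in loaders:
        raise ValueError(f"unknown dataset kind {kind!r}; expected one of {sorted(loaders)}")
    return loaders[kind](path)


def annotation_from_files(gene_path, peak_path) -> GenomicAnnotation:
    return GenomicAnnotation(genes=read_gene_annotation(gene_path), peaks=read_bed(peak_path))


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def save_artifacts(
    outdir,
    model=None,
    graph=None,
    tables: dict | None = None,
    reports: dict | None = None,
    config=None,
) -> dict:
    """Write run outputs and a manifest of every file with content hashes.

    Text artifacts are written via temp-then-rename so a crash cannot leave
    a truncated file under its final name. Returns the manifest dict (also
    written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is not None:
        model.save(outdir / "model")
    if graph is not None:
        graph.save(outdir / "graph")
    for name, table in (tables or {}).items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t")
    for name, report in (reports or {}).items():
        text = report.to_json() if hasattr(report, "to_json") else json.dumps(_jsonable(report), indent=1)
        _atomic_write_text(outdir / f"{name}.json", text)
    if config is not None:
        payload = config.to_dict() if hasattr(config, "to_dict") else _jsonable(vars(config))
        _atomic_write_text(outdir / "run_config.json", json.dumps(payload, indent=1))
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": [
            {"path": str(p.relative_to(outdir)), "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in files
        ]
    }
    _atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=1))
    return manifest
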