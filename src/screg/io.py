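"""Readers and writers: 10x-style Matrix Market triplets, TSV sidecars, JSON.

Matrix Market files follow the 10x convention (genes as rows, 1-based
coordinate indices) with features.tsv / barcodes.tsv sidecars.  All writers
emit deterministic column order, row sort and float formatting so re-runs with
the same seed are byte-identical; readers tolerate CRLF and trailing newlines.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io
import anndata as ad

from .synthetic import GroundTruth
from .metacell import MetacellMatrix

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Malformed or inconsistent on-disk dataset."""


def _read_lines(path: Path) -> list:
    return path.read_text().replace("\r\n", "\n").rstrip("\n").split("\n")


def write_10x_mtx(adata: ad.AnnData, outdir) -> None:
    """Write matrix.mtx (genes x cells, integer), features.tsv, barcodes.tsv
    and cell_metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo().astype(np.int64),
                     field="integer")
    feats = pd.DataFrame({
        "id": adata.var_names, "name": adata.var_names,
        "type": "Gene Expression"})
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", header=False,
                                      index=False)
    meta = adata.obs.reset_index().rename(columns={"index": "barcode"})
    meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)


def read_10x_mtx(indir) -> ad.AnnData:
    """Read a 10x-style triplet directory into a cells x genes AnnData.

    The Matrix Market file stores genes as rows with 1-based indices; 1,1 maps
    to gene 0 / cell 0 internally.  Dimension mismatches against the sidecars
    and truncated entry lists raise :class:`FormatError` with counts / line
    numbers.  Duplicate feature ids are disambiguated with numeric suffixes.
    """
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    for p in (mtx_path, indir / "features.tsv", indir / "barcodes.tsv"):
        if not p.exists():
            raise FormatError(f"missing required file {p}")

    lines = _read_lines(mtx_path)
    body = [(i + 1, ln) for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith("%")]
    if not body:
        raise FormatError(f"{mtx_path}: no header line found")
    try:
        n_genes, n_cells, nnz = map(int, body[0][1].split())
    except ValueError as e:
        raise FormatError(f"{mtx_path}: bad size header at line {body[0][0]}") from e
    entries = body[1:]
    if len(entries) != nnz:
        lineno = entries[-1][0] if entries else body[0][0]
        raise FormatError(
            f"{mtx_path}: header promises {nnz} entries but {len(entries)} found "
            f"(last entry at line {lineno})")
    try:
        M = scipy.io.mmread(str(mtx_path)).tocsr()
    except Exception as e:
        for lineno, ln in entries:
            parts = ln.split()
            if len(parts) < 3:
                raise FormatError(f"{mtx_path}: malformed entry at line {lineno}") from e
        raise FormatError(f"{mtx_path}: {e}") from e

    feat_lines = _read_lines(indir / "features.tsv")
    barcodes = _read_lines(indir / "barcodes.tsv")
    if len(feat_lines) != n_genes or len(barcodes) != n_cells:
        raise FormatError(
            f"{indir}: matrix is {n_genes} genes x {n_cells} cells but sidecars "
            f"have {len(feat_lines)} features and {len(barcodes)} barcodes")
    genes = [ln.split("\t")[0] for ln in feat_lines]
    if len(set(genes)) != len(genes):
        seen: dict = {}
        fixed = []
        for g in genes:
            if g in seen:
                seen[g] += 1
                fixed.append(f"{g}.{seen[g]}")
            else:
                seen[g] = 0
                fixed.append(g)
        warnings.warn(f"{len(genes) - len(seen)} duplicate feature ids suffixed")
        genes = fixed

    adata = ad.AnnData(
        X=M.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
        adata.obs = adata.obs.join(meta)
    return adata


def write_dataset(adata: ad.AnnData, gt: GroundTruth | None, outdir) -> None:
    """Counts plus ground truth, marker sets and regulator-class sidecars."""
    outdir = Path(outdir)
    write_10x_mtx(adata, outdir)
    if gt is not None:
        (outdir / "ground_truth.json").write_text(gt.to_json() + "\n")
        (outdir / "marker_sets.json").write_text(
            json.dumps(gt.type_markers, indent=1, sort_keys=True) + "\n")
        rows = [(g, cls) for cls, members in sorted(gt.regulator_classes.items())
                for g in sorted(members)]
        pd.DataFrame(rows, columns=["gene", "class"]).to_csv(
            outdir / "regulators.tsv", sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def read_regulator_classes(path) -> dict:
    """Regulator class lists from a (gene, class) TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "class"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'gene' and 'class'")
    return {cls: sorted(g["gene"]) for cls, g in df.groupby("class")}


def write_metacells(mc: MetacellMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    M = sp.coo_matrix(np.asarray(mc.matrix).T)  # genes x metacells
    scipy.io.mmwrite(str(outdir / "metacells.mtx"), M, field="real",
                     precision=6)
    pd.Series(mc.genes).to_csv(outdir / "features.tsv", header=False, index=False)
    names = [f"MC{i + 1:04d}" for i in range(mc.n_metacells)]
    pd.Series(names).to_csv(outdir / "barcodes.tsv", header=False, index=False)
    with open(outdir / "members.tsv", "w") as fh:
        fh.write("metacell\tmembers\n")
        for name, mem in zip(names, mc.members):
            fh.write(f"{name}\t{','.join(mem)}\n")
    (outdir / "meta.json").write_text(json.dumps(
        {"condition": mc.condition, "is_cpm": mc.is_cpm}) + "\n")


def read_metacells(indir) -> MetacellMatrix:
    indir = Path(indir)
    M = scipy.io.mmread(str(indir / "metacells.mtx")).toarray().T
    genes = _read_lines(indir / "features.tsv")
    members = []
    for ln in _read_lines(indir / "members.tsv")[1:]:
        members.append(ln.split("\t")[1].split(","))
    meta = json.loads((indir / "meta.json").read_text())
    return MetacellMatrix(matrix=M, genes=genes, members=members,
                          condition=meta["condition"], is_cpm=meta["is_cpm"])


def write_regulons(regulons, path) -> None:
    payload = {
        r.regulator: [
            {"gene": t, "mode": float(m), "weight": float(w)}
            for t, m, w in zip(r.targets, r.modes, r.weights)]
        for r in regulons}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_regulons(path) -> list:
    from .network import Regulon
    payload = json.loads(Path(path).read_text())
    out = []
    for reg in sorted(payload):
        targets = payload[reg]
        out.append(Regulon(
            regulator=reg,
            targets=[t["gene"] for t in targets],
            modes=np.array([t["mode"] for t in targets]),
            weights=np.array([t["weight"] for t in targets])))
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT,
              lineterminator="\n")
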