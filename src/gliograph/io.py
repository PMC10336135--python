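"""Plain-text readers/writers for the pipeline's on-disk formats.

Expression goes to Matrix Market (MTX) plus ``genes.csv``/``spots.csv``
sidecars; label maps are long-format CSV (x, y, label); survival tables,
ground truth, scores and feature tables are CSV; configs are YAML.
"""

from __future__ import annotations

import pathlib

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .graph import CellularMap


def write_expression_mtx(adata: ad.AnnData, outdir) -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(outdir / "matrix.mtx", X, field="integer")
    genes = adata.var.reset_index(names="gene")
    genes.to_csv(outdir / "genes.csv", index=False)
    spots = adata.obs.reset_index(names="spot_id")
    spots.to_csv(outdir / "spots.csv", index=False)


def read_expression_mtx(indir) -> ad.AnnData:
    indir = pathlib.Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.csv").set_index("gene")
    genes.index = genes.index.astype(str)
    spots = pd.read_csv(indir / "spots.csv").set_index("spot_id")
    spots.index = spots.index.astype(str)
    return ad.AnnData(X=X, obs=spots, var=genes)


def write_label_map(cmap: CellularMap, path) -> None:
    cmap.to_frame().to_csv(path, index=False)


def read_label_map(path, sample_id: str = "sample") -> CellularMap:
    return CellularMap.from_frame(pd.read_csv(path), sample_id=sample_id)


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_module_defs(path) -> dict:
    """Module definitions CSV with columns (module, gene)."""
    df = pd.read_csv(path)
    return {m: g["gene"].tolist() for m, g in df.groupby("module")}


def write_module_defs(defs: dict, path) -> None:
    rows = [(m, g) for m in sorted(defs) for g in defs[m]]
    pd.DataFrame(rows, columns=["module", "gene"]).to_csv(path, index=False)
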