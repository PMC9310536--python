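"""Readers and writers binding the pipeline stages together.

Stacks travel as multi-page TIFF plus a JSON sidecar with acquisition
metadata; cohorts add a metadata CSV (one row per stack).  Expression goes
as an MTX triplet with gene/barcode TSVs plus a cell-metadata CSV, or as a
dense CSV.  Gene sets use the GMT format (set name, description, member
genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from mitosig.synthetic.images import ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_cohort",
    "read_cohort",
    "write_expression",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "write_json",
]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a ``.json`` metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))
    meta = stack.meta()
    if stack.beta_schedule is not None:
        meta["beta_schedule"] = [float(b) for b in stack.beta_schedule]
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; metadata from sidecar when present."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    data = np.asarray(data, dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    schedule = meta.pop("beta_schedule", None)
    meta.pop("n_slices", None)
    return ImageStack(
        data=data,
        pixel_size=float(meta.pop("pixel_size", 100.0 / 512.0)),
        z_step=float(meta.pop("z_step", 5.0)),
        stack_id=meta.pop("stack_id", path.stem),
        patient=meta.pop("patient", "P0"),
        site=meta.pop("site", "S0"),
        condition=meta.pop("condition", "nonlesional"),
        timepoint=meta.pop("timepoint", "baseline"),
        beta_schedule=np.asarray(schedule) if schedule is not None else None,
    )


def write_cohort(stacks: Iterable[ImageStack], outdir: str | Path) -> Path:
    """Write a collection of stacks plus a ``stacks.csv`` manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack in stacks:
        fname = f"{stack.stack_id}.tif"
        write_stack(stack, outdir / fname)
        row = stack.meta()
        row["file"] = fname
        rows.append(row)
    manifest = outdir / "stacks.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(indir: str | Path) -> list[ImageStack]:
    """Read every stack listed in a cohort directory's manifest."""
    indir = Path(indir)
    manifest = indir / "stacks.csv"
    if manifest.exists():
        files = pd.read_csv(manifest)["file"].tolist()
    else:
        files = sorted(p.name for p in indir.glob("*.tif"))
    if not files:
        raise FileNotFoundError(f"no stacks found in {indir}")
    return [read_stack(indir / f) for f in files]


def write_expression(adata, outdir: str | Path) -> Path:
    """Write counts as MTX triplet + genes/barcodes TSV + cell metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.csr_matrix(X) if not sparse.issparse(X) else X
    spio.mmwrite(outdir / "matrix.mtx", mat.T.astype(int))  # genes x cells
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(outdir / "cell_meta.csv")
    if "gene_sets" in adata.uns:
        write_gmt(adata.uns["gene_sets"], outdir / "gene_sets.gmt")
    return outdir


def read_expression(indir: str | Path):
    """Read an MTX-triplet expression directory back into AnnData."""
    import anndata as ad

    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    meta_path = indir / "cell_meta.csv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, index_col=0)
        obs = obs.loc[barcodes]
    adata = ad.AnnData(
        X=np.asarray(mat.todense(), dtype=np.int32),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    gmt = indir / "gene_sets.gmt"
    if gmt.exists():
        adata.uns["gene_sets"] = read_gmt(gmt)
    return adata


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, f"{name} gene set"] + list(genes))
        for name, genes in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path
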