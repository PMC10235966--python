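"""Readers and writers for the plain-text interchange formats.

CSV schemas:
  trajectories  follicle_id, stage, t_min, volume_um3, cell_count
  force curves  map_id, point_i, point_j, z_nm, force_pN
  cell records  cell_id, stage, factin_au, yap_ratio
  recoil        t_s, L_um

Count matrices travel as MatrixMarket (.mtx) with genes.tsv / barcodes.tsv /
populations.tsv sidecars; sequences as FASTA via Biopython; gene sets as
plain-text lists or single-line GMT.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .actin import GeneSet
from .afm import ForceCurve, ForceMap
from .errors import ValidationError
from .mechano import CellMechRecord
from .recoil import RecoilTrace
from .volume import VolumeTrajectory


# ---------------------------------------------------------------- volumes

def write_trajectories(trajs: list[VolumeTrajectory], path) -> None:
    rows = []
    for t in trajs:
        for i in range(t.times.size):
            rows.append(
                (t.follicle_id, t.stage, t.times[i], t.volumes[i], t.cell_count)
            )
    pd.DataFrame(
        rows, columns=["follicle_id", "stage", "t_min", "volume_um3", "cell_count"]
    ).to_csv(path, index=False)


def read_trajectories(path) -> list[VolumeTrajectory]:
    df = pd.read_csv(path)
    out = []
    for (fid, stage), g in df.groupby(["follicle_id", "stage"], sort=False):
        g = g.sort_values("t_min")
        cc = g["cell_count"].iloc[0]
        out.append(
            VolumeTrajectory(
                str(fid),
                str(stage),
                g["t_min"].to_numpy(),
                g["volume_um3"].to_numpy(),
                None if pd.isna(cc) else int(cc),
            )
        )
    return out


# ---------------------------------------------------------------- force maps

def write_force_map(fmap: ForceMap, path, map_id: str = "map0") -> None:
    rows = []
    for idx, curve in enumerate(fmap.curves):
        i, j = divmod(idx, fmap.grid)
        for k in range(curve.z_nm.size):
            rows.append((map_id, i, j, curve.z_nm[k], curve.force_pn[k]))
    pd.DataFrame(rows, columns=["map_id", "point_i", "point_j", "z_nm", "force_pN"]).to_csv(
        path, index=False
    )


def read_force_curves(path) -> dict[tuple[int, int], ForceCurve]:
    df = pd.read_csv(path)
    out = {}
    for (i, j), g in df.groupby(["point_i", "point_j"], sort=True):
        g = g.sort_values("z_nm")
        out[(int(i), int(j))] = ForceCurve(g["z_nm"].to_numpy(), g["force_pN"].to_numpy())
    return out


def read_force_map(path, region: str = "unknown", region_size_um: float = 15.0) -> ForceMap:
    curves_by_pos = read_force_curves(path)
    grid = int(round(np.sqrt(len(curves_by_pos))))
    if grid * grid != len(curves_by_pos):
        raise ValidationError("force map file does not contain a square grid of points")
    curves = [curves_by_pos[divmod(k, grid)] for k in range(grid * grid)]
    return ForceMap(region, grid, region_size_um, curves)


# ---------------------------------------------------------------- cell records

def write_cell_records(records: list[CellMechRecord], path) -> None:
    pd.DataFrame(
        [(r.cell_id, r.stage, r.factin_au, r.yap_ratio) for r in records],
        columns=["cell_id", "stage", "factin_au", "yap_ratio"],
    ).to_csv(path, index=False)


def read_cell_records(path) -> list[CellMechRecord]:
    df = pd.read_csv(path)
    return [
        CellMechRecord(str(r.cell_id), str(r.stage), float(r.factin_au), float(r.yap_ratio))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- recoil

def write_recoil(trace: RecoilTrace, path) -> None:
    pd.DataFrame({"t_s": trace.t_s, "L_um": trace.l_um}).to_csv(path, index=False)


def read_recoil(path) -> RecoilTrace:
    df = pd.read_csv(path)
    return RecoilTrace(df["t_s"].to_numpy(), df["L_um"].to_numpy())


# ---------------------------------------------------------------- expression

def write_expression(adata, out_dir) -> None:
    """matrix.mtx (genes x cells) + genes.tsv / barcodes.tsv / populations.tsv."""
    from scipy import io as spio
    from scipy import sparse

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # MatrixMarket convention for scRNA matrices is genes x cells
    mat = sparse.csc_matrix(adata.X.T)
    spio.mmwrite(out_dir / "matrix.mtx", mat)
    pd.Series(adata.var_names).to_csv(out_dir / "genes.tsv", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out_dir / "barcodes.tsv", index=False, header=False)
    adata.obs["population"].to_csv(
        out_dir / "populations.tsv", sep="\t", header=["population"]
    )


def read_expression(in_dir):
    import anndata as ad
    from scipy import io as spio
    from scipy import sparse

    in_dir = Path(in_dir)
    mat = spio.mmread(in_dir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(in_dir / "genes.tsv", header=None)[0].tolist()
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", header=None)[0].tolist()
    obs = pd.DataFrame(index=barcodes)
    pop_path = in_dir / "populations.tsv"
    if pop_path.exists():
        pops = pd.read_csv(pop_path, sep="\t", index_col=0)
        obs["population"] = pops["population"].reindex(barcodes)
    return ad.AnnData(X=sparse.csr_matrix(mat), obs=obs, var=pd.DataFrame(index=genes))


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Plain-text list (one gene per line) or GMT (first matching line)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValidationError(f"empty gene set file {path}")
    lines = text.splitlines()
    if "\t" in lines[0] and len(lines[0].split("\t")) > 2:  # GMT: name, desc, genes...
        fields = lines[0].split("\t")
        return GeneSet(fields[0], tuple(g for g in fields[2:] if g))
    return GeneSet(name or path.stem, tuple(l.strip() for l in lines if l.strip()))


# ---------------------------------------------------------------- FASTA

def write_fasta(records, path) -> None:
    """records: iterable of (name, sequence)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        os.fspath(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio.SeqIO import parse

    return [(rec.id, str(rec.seq)) for rec in parse(os.fspath(path), "fasta")]
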