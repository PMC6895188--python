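"""Readers and writers for the package's plain-text exchange formats.

Schemas (all 0-based landmark indices, µm units, right-handed axes):

* landmarks CSV: ``specimen,species,landmark_id,x,y,z``
* modes CSV: ``species,mode``
* volumes CSV: ``species,brain_mm3,cerebellum_mm3[,mode]``
* depths CSV: ``species,cell_id,dist_gcl_um,ml_thickness_um``
* expression TSV: genes x species, first column ``gene``
* GO TSV: ``gene,go_id,term``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cell_scatter import CellDepthTable
from .expression import ExpressionMatrix
from .morphometry import LandmarkSet, ShapeSpace
from .trees import PhyloTree
from .volumetrics import VolumeTable

__all__ = [
    "read_landmarks", "write_landmarks", "read_modes", "read_volumes",
    "read_depths", "read_expression", "read_go", "read_tree",
    "read_ply_vertices", "write_shape_space",
]


def read_tree(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(str(path))


def read_landmarks(path: str | Path,
                   subsets: dict[str, list[int]] | None = None) -> LandmarkSet:
    """Read the long-format landmark CSV into a LandmarkSet."""
    df = pd.read_csv(path)
    need = {"specimen", "species", "landmark_id", "x", "y", "z"}
    if not need <= set(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(need)}")
    specimens = list(dict.fromkeys(df["specimen"]))
    k = df["landmark_id"].nunique()
    coords = np.empty((len(specimens), k, 3))
    species = []
    for i, spec in enumerate(specimens):
        sub = df[df["specimen"] == spec].sort_values("landmark_id")
        if len(sub) != k or not (sub["landmark_id"].to_numpy()
                                 == np.arange(k)).all():
            raise ValueError(
                f"specimen {spec!r}: landmark ids must be 0..{k - 1}")
        coords[i] = sub[["x", "y", "z"]].to_numpy()
        species.append(sub["species"].iloc[0])
    subs = ({k_: np.asarray(v, dtype=int) for k_, v in subsets.items()}
            if subsets else {})
    return LandmarkSet(coords, specimens, species, subs)


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    rows = []
    for i, (spec, sp) in enumerate(zip(lm.specimens, lm.species)):
        for j in range(lm.n_landmarks):
            rows.append((spec, sp, j, *lm.coords[i, j]))
    pd.DataFrame(rows, columns=["specimen", "species", "landmark_id",
                                "x", "y", "z"]).to_csv(path, index=False)


def read_modes(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["species"].astype(str), df["mode"].astype(str)))


def read_volumes(path: str | Path,
                 modes: dict[str, str] | None = None) -> VolumeTable:
    return VolumeTable.from_dataframe(pd.read_csv(path), modes)


def read_depths(path: str | Path) -> CellDepthTable:
    return CellDepthTable.from_dataframe(pd.read_csv(path))


def read_expression(path: str | Path,
                    modes: dict[str, str] | None = None) -> ExpressionMatrix:
    return ExpressionMatrix.from_tsv(str(path), modes)


def read_go(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "go_id"}
    if not need <= set(df.columns):
        raise ValueError("GO TSV must have columns gene, go_id[, term]")
    if "term" not in df.columns:
        df["term"] = df["go_id"]
    return df[["gene", "go_id", "term"]]


def read_ply_vertices(path: str | Path) -> np.ndarray:
    """Vertices of a PLY surface mesh (faces are ignored)."""
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float)


def write_shape_space(space: ShapeSpace, path: str | Path) -> None:
    """Scores plus percent variance per axis as a TSV."""
    cols = {f"PC{j + 1}": space.scores[:, j]
            for j in range(space.scores.shape[1])}
    df = pd.DataFrame({"specimen": space.specimens, **cols})
    with open(path, "w") as fh:
        pct = "\t".join(f"{v:.6f}" for v in space.percent_variance)
        fh.write(f"# percent_variance\t{pct}\n")
        df.to_csv(fh, sep="\t", index=False)
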