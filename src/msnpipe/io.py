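"""File formats: TSV tables and matrices, GMT gene sets, mesh text.

All tables are tab-separated with a header row and an id column; floats are
written at full repr precision so that write-then-read round-trips exactly.
The mesh format is line-oriented: ``v x y z`` per vertex, ``f i j k`` per
face (0-based vertex indices), and ``l label`` per vertex in vertex order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .modularity import ModulePartition
from .parcellation import LabeledMesh


class ParseError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.path, self.lineno = str(path), lineno


# -- tables and matrices -----------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    # round_trip: the default C float parser can be 1 ulp off, which would
    # break the write-then-read exactness contract
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def write_feature_table(ft: pd.DataFrame, path) -> None:
    write_table(ft, path)


def read_feature_table(path, subject_id: str | None = None) -> pd.DataFrame:
    ft = read_table(path)
    ft.attrs["subject_id"] = subject_id or Path(path).stem
    return ft


def write_matrix(m: pd.DataFrame, path) -> None:
    write_table(m, path)


def read_matrix(path) -> pd.DataFrame:
    m = read_table(path)
    m.columns = m.index if len(m.columns) == len(m.index) else m.columns
    return m


# -- partitions --------------------------------------------------------------

def write_partition(part: ModulePartition, path_json, path_tsv=None) -> None:
    payload = {
        "assignment": part.assignment,
        "gamma": part.gamma,
        "modularity_Q": part.modularity_Q,
        "seed": part.seed,
    }
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=1)
    if path_tsv is not None:
        pd.Series(part.assignment, name="module").rename_axis("region_id").to_csv(
            path_tsv, sep="\t"
        )


def read_partition(path_json) -> ModulePartition:
    with open(path_json) as fh:
        payload = json.load(fh)
    return ModulePartition(
        payload["assignment"], payload["gamma"], payload["modularity_Q"], payload["seed"]
    )


# -- GMT gene sets -----------------------------------------------------------

def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], tuple(parts[2:])
            if len(set(genes)) != len(genes):
                raise ParseError(path, lineno, f"duplicate gene id in set {name!r}")
            sets.append(GeneSet(name, genes, desc))
    return sets


# -- meshes ------------------------------------------------------------------

def write_mesh(mesh: LabeledMesh, path) -> None:
    with open(path, "w") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for i, j, k in mesh.faces:
            fh.write(f"f {i} {j} {k}\n")
        for lab in mesh.parent_label:
            fh.write(f"l {lab}\n")


def read_mesh(path) -> LabeledMesh:
    verts, faces, labels = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            tag, rest = parts[0], parts[1:]
            try:
                if tag == "v":
                    if len(rest) != 3:
                        raise ValueError("vertex needs 3 coordinates")
                    verts.append([float(v) for v in rest])
                elif tag == "f":
                    if len(rest) != 3:
                        raise ValueError("face needs 3 vertex indices")
                    faces.append([int(v) for v in rest])
                elif tag == "l":
                    if len(rest) != 1:
                        raise ValueError("label line needs exactly one label")
                    labels.append(rest[0])
                else:
                    raise ValueError(f"unknown record type {tag!r}")
            except ValueError as err:
                raise ParseError(path, lineno, str(err)) from None
    verts = np.array(verts)
    faces = np.array(faces, dtype=int) if faces else np.empty((0, 3), dtype=int)
    if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
        raise ParseError(path, 0, "face references a vertex index out of range")
    if len(labels) != len(verts):
        raise ParseError(path, 0, f"{len(labels)} labels for {len(verts)} vertices")
    return LabeledMesh(verts, faces, np.array(labels))


# -- misc --------------------------------------------------------------------

def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (set, frozenset)):
        return sorted(v)
    raise TypeError(f"not JSON-serializable: {type(v)}")
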