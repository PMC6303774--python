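"""Readers and writers for the plain-text interchange formats.

Trees travel as Newick (one per line), incidence and environment tables as
CSV, section assignments as CSV rows of ``species, anchor1, anchor2, ...``,
and configs as YAML.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import dendropy
import pandas as pd
import yaml

from .config import SimulationConfig
from .grid_assembly import CommunityMatrix
from .tree_augmentation import SectionAssignment, TreeSet

PathLike = Union[str, Path]


def read_tree_set(path: PathLike) -> TreeSet:
    """Read a Newick tree list (one tree per line; shared taxon namespace)."""
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    if not tl:
        raise ValueError(f"no trees found in {path}")
    return TreeSet(trees=list(tl), provenance={"source": str(path)})


def write_tree_set(trees: TreeSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True))


def write_tree(tree: dendropy.Tree, path: PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_assignments(path: PathLike) -> SectionAssignment:
    """CSV rows: species, anchor1, anchor2, ... (ragged rows allowed)."""
    constraints = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            row = [c.strip() for c in row if c.strip()]
            if not row:
                continue
            constraints[row[0]] = tuple(row[1:])
    return SectionAssignment(constraints=constraints)


def write_assignments(assignments: SectionAssignment, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for sp, anchors in assignments.constraints.items():
            writer.writerow([sp, *anchors])


def read_community(incidence_path: PathLike, cells_path: PathLike) -> CommunityMatrix:
    inc = pd.read_csv(incidence_path, index_col="cell_id")
    cells = pd.read_csv(cells_path, index_col="cell_id")
    return CommunityMatrix(incidence=inc.astype("int8"), cells=cells.loc[inc.index])


def write_community(cm: CommunityMatrix, incidence_path: PathLike, cells_path: PathLike) -> None:
    cm.incidence.to_csv(incidence_path)
    cm.cells.to_csv(cells_path)


def read_environment(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_environment(env: pd.DataFrame, path: PathLike) -> None:
    env.to_csv(path, index=False)


def read_simulation_config(path: PathLike) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig(**data)


def write_simulation_config(config: SimulationConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
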