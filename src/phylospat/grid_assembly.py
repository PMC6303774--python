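"""Occurrence records to a filtered cells x species presence/absence matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["CommunityMatrix", "EmptyResultError", "build_matrix", "filter_cells"]


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell."""


@dataclass
class CommunityMatrix:
    """Cells x species binary incidence with per-cell coordinates and areas.

    ``incidence`` is indexed by cell_id with one 0/1 column per species;
    ``cells`` is indexed identically with columns x, y (km) and area (km^2).
    """

    incidence: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.incidence.index.equals(self.cells.index):
            raise ValueError("incidence and cell metadata indices differ")
        vals = self.incidence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence values must be 0/1")

    @property
    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=1).rename("SR")

    @property
    def species(self) -> list:
        return list(self.incidence.columns)

    @property
    def n_cells(self) -> int:
        return len(self.incidence)

    def total_presences(self) -> int:
        return int(self.incidence.to_numpy().sum())


def build_matrix(
    records: pd.DataFrame,
    cell_size: float,
    origin: Optional[Tuple[float, float]] = None,
) -> CommunityMatrix:
    """Bin point occurrence records into square grid cells.

    Records need columns ``species``, ``x``, ``y`` (projected km). Binning is
    half-open, [x0 + i*s, x0 + (i+1)*s), with the origin at the lower-left
    corner of the data bounding box unless given — a record exactly on an
    interior boundary falls in the higher-index cell. Duplicate records
    collapse to a single presence.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if len(records) == 0:
        warnings.warn("empty record list: returning empty matrix", stacklevel=2)
        empty = pd.DataFrame(index=pd.Index([], name="cell_id"))
        meta = pd.DataFrame(columns=["x", "y", "area"], index=empty.index)
        return CommunityMatrix(incidence=empty, cells=meta)
    xy = records[["x", "y"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("record coordinates must be finite")
    if (records["species"].astype(str).str.len() == 0).any():
        raise ValueError("species ids must be non-empty")
    x0, y0 = origin if origin is not None else (xy[:, 0].min(), xy[:, 1].min())
    ix = np.floor((xy[:, 0] - x0) / cell_size).astype(int)
    iy = np.floor((xy[:, 1] - y0) / cell_size).astype(int)
    df = pd.DataFrame({"species": records["species"].astype(str), "ix": ix, "iy": iy})
    df["cell_id"] = [f"g{a}_{b}" for a, b in zip(df.ix, df.iy)]
    incidence = (
        pd.crosstab(df["cell_id"], df["species"]).clip(upper=1).astype(np.int8)
    )
    centers = df.drop_duplicates("cell_id").set_index("cell_id")
    cells = pd.DataFrame(
        {
            "x": x0 + (centers["ix"] + 0.5) * cell_size,
            "y": y0 + (centers["iy"] + 0.5) * cell_size,
            "area": cell_size**2,
        }
    ).loc[incidence.index]
    incidence.columns.name = None
    return CommunityMatrix(incidence=incidence, cells=cells)


def filter_cells(
    matrix: CommunityMatrix, min_species: int = 3, min_area: float = 5000.0
) -> CommunityMatrix:
    """Drop low-coverage border cells and species-poor cells.

    The area threshold (default 5,000 km^2, i.e. half of a 100-km cell) is
    applied first, then the richness threshold (default 3 species, the floor
    below which assemblage phylogenetic structure is not informative).
    Species left with no presences are removed from the species list. The
    operation is idempotent and never increases total presences.
    """
    if min_species < 0:
        raise ValueError("min_species must be >= 0")
    keep = matrix.cells["area"] >= min_area
    inc = matrix.incidence.loc[keep]
    inc = inc.loc[inc.sum(axis=1) >= min_species]
    if len(inc) == 0:
        raise EmptyResultError(
            f"no cells satisfy area >= {min_area} and richness >= {min_species}"
        )
    inc = inc.loc[:, inc.sum(axis=0) > 0]
    return CommunityMatrix(incidence=inc, cells=matrix.cells.loc[inc.index])
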