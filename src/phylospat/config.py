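"""Configuration objects shared across the analysis chain."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np


def derive_seed(master: int, *path: int) -> np.random.SeedSequence:
    """Deterministically derive a child seed sequence from a master seed.

    Every stochastic stage draws its generator from ``(master, *path)`` so a
    single master seed fans out to reproducible, independent streams (e.g.
    ``(seed, cell_index, tree_index)`` for per-cell, per-tree NRI nulls).
    """
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(p) for p in path))


def rng_for(master: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *path))


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the synthetic data generator.

    The defaults emulate the structure of a continental-scale survey of a
    woody plant family: ~145 species on a dated tree tens of millions of
    years deep, a 20 x 20 lattice of 100-km cells, smooth climate and soil
    surfaces with a strong negative pH-MAP cross-correlation (-0.813), and
    occupancy driven by a phylogenetically conserved soil-pH niche so that
    richness declines toward high-pH cells.

    Parameters
    ----------
    n_species:
        Number of extant tips on the simulated tree (>= 4).
    birth_rate:
        Per-lineage speciation rate of the Yule process, 1/My. The default
        0.1 yields crown ages of roughly 40-60 My for ~145 tips.
    grid_rows, grid_cols:
        Lattice dimensions; the grid must have at least 9 cells.
    cell_size:
        Cell edge length in km (cells are squares of area cell_size**2).
    env_range:
        Range (in cells) of the exponential spatial covariance of each
        environment field; larger values give smoother surfaces.
    target_corr_pH_MAP:
        Cross-correlation imposed between the pH and MAP fields, in (-1, 0].
    niche_sigma2:
        Brownian-motion rate of pH-optimum evolution (pH units squared per My).
    niche_breadth:
        Gaussian niche tolerance width in pH units (> 0).
    baseline_occupancy:
        Occupancy probability at the niche optimum, in (0, 1).
    pH_effect:
        Signed additive shift of occupancy per standard deviation of cell pH;
        negative values depress richness in high-pH cells.
    seed:
        Master seed; all stages derive child streams from it.
    """

    n_species: int = 145
    birth_rate: float = 0.1
    grid_rows: int = 20
    grid_cols: int = 20
    cell_size: float = 100.0
    env_range: float = 5.0
    target_corr_pH_MAP: float = -0.813
    niche_sigma2: float = 0.01
    niche_breadth: float = 1.0
    baseline_occupancy: float = 0.35
    pH_effect: float = -0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError(f"n_species must be >= 4, got {self.n_species}")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.grid_rows * self.grid_cols < 9:
            raise ValueError("grid must have at least 9 cells")
        if not abs(self.target_corr_pH_MAP) < 1:
            raise ValueError(
                "target_corr_pH_MAP must lie strictly inside (-1, 1); "
                f"{self.target_corr_pH_MAP} is unreachable by field mixing"
            )
        if not self.niche_breadth > 0:
            raise ValueError("niche_breadth must be positive")
        if not 0 < self.baseline_occupancy < 1:
            raise ValueError("baseline_occupancy must lie in (0, 1)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.env_range < 0:
            raise ValueError("env_range must be non-negative")
        if self.niche_sigma2 < 0:
            raise ValueError("niche_sigma2 must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NullModelSpec:
    """Null model for the NRI permutation test.

    ``label_shuffle`` draws richness-matched assemblages uniformly without
    replacement from the full species pool of the distance matrix, which is
    equivalent to shuffling tip labels at fixed assemblage size.
    """

    null_type: str = "label_shuffle"
    n_randomizations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.null_type != "label_shuffle":
            raise ValueError(f"unknown null type: {self.null_type!r}")


@dataclass
class AnalysisConfig:
    """Settings of the full pipeline run.

    Variable groups keep MAP and pH apart (their pairwise correlation is far
    beyond the |r| > 0.7 collinearity rule), richness and MAP are natural-log
    transformed, and every predictor is z-scored before model fitting so
    coefficients are directly comparable.
    """

    dataset: str = "family"
    cell_size: float = 100.0
    min_species: int = 3
    min_area: float = 5000.0
    weights_scheme: str = "queen"
    row_standardize: bool = True
    n_trees: int = 1000
    null: NullModelSpec = field(default_factory=NullModelSpec)
    n_distance_classes: int = 12
    n_moran_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    outdir: Optional[str] = None

    # Group 1 = {MINT, MAP}, Group 2 = {MINT, pH}; never mixed (collinearity).
    group1: tuple = ("MINT", "logMAP")
    group2: tuple = ("MINT", "pH")

    def __post_init__(self) -> None:
        if self.min_species < 0:
            raise ValueError("min_species must be >= 0")
        for g in (self.group1, self.group2):
            if "logMAP" in g and "pH" in g or "MAP" in g and "pH" in g:
                raise ValueError("a variable group must not mix MAP and pH")
        if self.weights_scheme not in ("queen", "rook"):
            raise ValueError("weights_scheme must be 'queen' or 'rook'")
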