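"""Orchestration of the full diversity-pattern analysis.

The pipeline filters the gridded community, averages NRI over the tree set,
assembles the per-cell analysis table (log-transformed richness and MAP,
z-scored predictors), and then runs three families of spatially explicit
models: richness ~ environment, richness ~ NRI (+ NRI^2), and NRI ~
environment, each over two collinearity-safe variable groups (MINT+MAP and
MINT+pH) and as both SAR and OLS fits. The final stage maps the best
richness~NRI model onto the competing explanations of richness gradients:

- significant negative linear NRI term  -> time-for-speciation (rich
  assemblages of distantly related species, long occupancy);
- significant positive linear NRI term  -> diversification-rate (rich
  assemblages of close relatives, rapid in-situ speciation);
- significant positive quadratic term   -> U-shaped / mixed signal;
- nothing significant                    -> cancellation or no signal.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .grid_assembly import CommunityMatrix, filter_cells
from .phylo_structure import mean_nri
from .spatial_stats import (
    ModelSelectionTable,
    all_subsets,
    build_weights,
    pearson_dutilleul,
    significance_stars,
)
from .tree_augmentation import TreeSet

__all__ = ["run_pipeline", "classify_relationship", "model_table_frame"]

logger = logging.getLogger(__name__)

CORR_VARIABLES = ("MINT", "MAP", "pH", "NRI", "SR")


def _zscore(v: pd.Series) -> pd.Series:
    return (v - v.mean()) / v.std(ddof=1)


def classify_relationship(
    best_fit,
    alpha: float = 0.05,
    linear_term: str = "NRI",
    quad_term: str = "NRI2",
) -> Tuple[str, str]:
    """Map the best richness~NRI model onto a hypothesis label.

    Returns ``(relationship_class, hypothesis_label)`` derived solely from
    the signs and significance of the best model's terms.
    """
    params, pvals = best_fit.params, best_fit.pvalues
    quad_sig = quad_term in params and pvals[quad_term] < alpha
    lin_sig = linear_term in params and pvals[linear_term] < alpha
    if quad_sig and params[quad_term] > 0:
        return "U-shaped", "mixed/complex"
    if lin_sig and params[linear_term] < 0:
        return "negative-linear", "time-for-speciation"
    if lin_sig and params[linear_term] > 0:
        return "positive-linear", "diversification-rate"
    return "none", "cancellation-or-none"


def _check_consistency(
    community: CommunityMatrix, env: pd.DataFrame, trees: TreeSet
) -> None:
    env_cells = set(env["cell_id"])
    missing_cells = sorted(set(community.incidence.index) - env_cells)
    if missing_cells:
        raise ValueError(f"cells missing from environment table: {missing_cells[:5]}")
    tree_tips = trees.tip_labels(0)
    missing_sp = sorted(set(community.species) - set(tree_tips))
    if missing_sp:
        raise ValueError(f"species missing from trees: {missing_sp[:5]}")


def _analysis_table(
    community: CommunityMatrix, env: pd.DataFrame, nri_table: pd.DataFrame
) -> pd.DataFrame:
    env_idx = env.set_index("cell_id").loc[community.incidence.index]
    tab = pd.DataFrame(
        {
            "x": env_idx["x"],
            "y": env_idx["y"],
            "SR": community.richness,
            "MINT": env_idx["MINT"],
            "MAP": env_idx["MAP"],
            "pH": env_idx["pH"],
            "NRI": nri_table["nri"],
        }
    )
    if (tab["MAP"] <= 0).any():
        raise ValueError("MAP must be positive for the log transform")
    if (tab["SR"] <= 0).any():
        raise ValueError("SR must be positive for the log transform")
    tab["logSR"] = np.log(tab["SR"])
    tab["logMAP"] = np.log(tab["MAP"])
    for v in ("MINT", "logMAP", "pH", "NRI"):
        z = _zscore(tab[v])
        tab[f"z{v}"] = z
        tab[f"z{v}2"] = z**2
    return tab


def _selection_pair(
    response: np.ndarray,
    tab: pd.DataFrame,
    terms: Tuple[str, ...],
    w,
    moran_n_perm: int,
    moran_seed: int,
) -> Dict[str, ModelSelectionTable]:
    """SAR and OLS all-subsets selections for one response/term group."""
    design = pd.DataFrame(index=tab.index)
    marginality = []
    for t in terms:
        design[t] = tab[f"z{t}"]
        design[f"{t}2"] = tab[f"z{t}2"]
        marginality.append((f"{t}2", t))
    out = {}
    for kind in ("sar", "ols"):
        out[kind] = all_subsets(
            response,
            design,
            marginality=marginality,
            model_kind=kind,
            w=w,
            moran_n_perm=moran_n_perm,
            moran_seed=moran_seed,
        )
    return out


def model_table_frame(selection: ModelSelectionTable, alpha: float = 0.05) -> pd.DataFrame:
    """Tidy per-term summary of a model selection, in the layout of the
    multimodel-inference tables: best-model coefficient with significance
    stars, per-term Akaike weight (importance), and the best model's fit
    statistics repeated on the first row."""
    best = selection.best
    rows = []
    for i, term in enumerate(selection.importance.index):
        in_best = term in best.terms
        coef = best.params[term] if in_best else np.nan
        p = best.pvalues[term] if in_best else np.nan
        rows.append(
            {
                "term": term,
                "coefficient": coef,
                "significance": significance_stars(p) if in_best else "",
                "importance": selection.importance[term],
            }
        )
    frame = pd.DataFrame(rows)
    frame["best_aicc"] = [best.aicc] + [np.nan] * (len(frame) - 1)
    if selection.kind == "sar":
        frame["pseudo_r2"] = [best.pseudo_r2] + [np.nan] * (len(frame) - 1)
        frame["lambda"] = [best.lam] + [np.nan] * (len(frame) - 1)
        if best.residual_moran is not None:
            frame["residual_moran_I"] = [best.residual_moran.statistic] + [np.nan] * (
                len(frame) - 1
            )
            frame["residual_moran_p"] = [best.residual_moran.p_value] + [np.nan] * (
                len(frame) - 1
            )
    else:
        frame["r2"] = [best.r2] + [np.nan] * (len(frame) - 1)
    return frame


def _correlation_tables(
    tab: pd.DataFrame, n_classes: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    coords = tab[["x", "y"]].to_numpy(float)
    k = len(CORR_VARIABLES)
    r = pd.DataFrame(np.eye(k), index=CORR_VARIABLES, columns=CORR_VARIABLES)
    p = pd.DataFrame(np.zeros((k, k)), index=CORR_VARIABLES, columns=CORR_VARIABLES)
    for i, a in enumerate(CORR_VARIABLES):
        for j in range(i + 1, k):
            b = CORR_VARIABLES[j]
            res = pearson_dutilleul(tab[a], tab[b], coords, n_distance_classes=n_classes)
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p_value
    return r, p


def run_pipeline(
    community: CommunityMatrix,
    env: pd.DataFrame,
    trees: TreeSet,
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Run the full analysis and return a result bundle.

    The bundle maps output names to DataFrames / dicts:
    ``analysis_table``, ``corr_r``, ``corr_p``, ``sr_env_group1``,
    ``sr_env_group2``, ``sr_nri``, ``nri_env_group1``, ``nri_env_group2``
    (each of the model keys holding {'sar': ..., 'ols': ...} selections),
    ``interpretation`` and ``seed_manifest``. If ``config.outdir`` is set the
    tables are also written as CSV/JSON.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    _check_consistency(community, env, trees)

    filtered = filter_cells(community, config.min_species, config.min_area)
    logger.info("filtered to %d cells, %d species", filtered.n_cells, len(filtered.species))

    nri_table = mean_nri(filtered, trees, config.null)
    logger.info("NRI stage done (%.1fs)", time.perf_counter() - t0)

    tab = _analysis_table(filtered, env, nri_table)
    corr_r, corr_p = _correlation_tables(tab, config.n_distance_classes)

    w = build_weights(
        filtered.cells, scheme=config.weights_scheme, row_standardize=config.row_standardize
    )
    moran_seed = config.seed + 7919

    selections = {}
    logsr = tab["logSR"].to_numpy()
    nri_resp = tab["NRI"].to_numpy()
    groups = {"group1": config.group1, "group2": config.group2}
    for gname, gterms in groups.items():
        selections[f"sr_env_{gname}"] = _selection_pair(
            logsr, tab, gterms, w, config.n_moran_perm, moran_seed
        )
        selections[f"nri_env_{gname}"] = _selection_pair(
            nri_resp, tab, gterms, w, config.n_moran_perm, moran_seed
        )
    selections["sr_nri"] = _selection_pair(
        logsr, tab, ("NRI",), w, config.n_moran_perm, moran_seed
    )

    rel_class, hypothesis = classify_relationship(
        selections["sr_nri"]["sar"].best, alpha=config.alpha
    )
    best = selections["sr_nri"]["sar"].best
    interpretation = {
        "dataset": config.dataset,
        "relationship_class": rel_class,
        "hypothesis": hypothesis,
        "alpha": config.alpha,
        "supporting_coefficients": {
            t: {"coefficient": float(best.params[t]), "p": float(best.pvalues[t])}
            for t in best.terms
        },
    }
    manifest = {
        "master_seed": config.seed,
        "null_seed": config.null.seed,
        "null_randomizations": config.null.n_randomizations,
        "moran_seed": moran_seed,
        "n_trees": len(trees),
        "weights_scheme": config.weights_scheme,
        "n_cells": filtered.n_cells,
        "n_species": len(filtered.species),
    }

    bundle = {
        "analysis_table": tab,
        "nri_table": nri_table,
        "corr_r": corr_r,
        "corr_p": corr_p,
        **selections,
        "interpretation": interpretation,
        "seed_manifest": manifest,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    logger.info("pipeline done (%.1fs)", time.perf_counter() - t0)
    return bundle


def _write_bundle(bundle: dict, config: AnalysisConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["analysis_table"].to_csv(out / "analysis_table.csv")
    bundle["nri_table"].to_csv(out / "nri_table.csv")
    bundle["corr_r"].to_csv(out / "corr_table_r.csv")
    bundle["corr_p"].to_csv(out / "corr_table_p.csv")
    for key in ("sr_env_group1", "sr_env_group2", "sr_nri", "nri_env_group1", "nri_env_group2"):
        for kind, sel in bundle[key].items():
            model_table_frame(sel, config.alpha).to_csv(
                out / f"{key}_{kind}.csv", index=False
            )
    with open(out / "interpretation.json", "w") as fh:
        json.dump(bundle["interpretation"], fh, indent=2)
    with open(out / "seed_manifest.json", "w") as fh:
        json.dump(bundle["seed_manifest"], fh, indent=2)
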