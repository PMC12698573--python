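"""Vegetation indices at fixed wavelength anchors and the screening procedure.

Seven candidate indices are computed from canopy reflectance at nearest-grid
anchor wavelengths.  Screening proceeds in three stages: random-forest
importance ranking, forward stepwise retention by cross-validated RMSE, and
correlation pruning of redundant (highly positively correlated) pairs.
Strongly negatively correlated pairs are retained by default on the grounds
that they capture different physiological characteristics; an orthodox
absolute-correlation mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score

from hypyield.errors import ConfigurationError, DataError
from hypyield.hsi_io import wavelength_to_channel


@dataclass(frozen=True)
class IndexDefinition:
    """One spectral index: its anchor wavelengths (nm) and soil factor L."""

    name: str
    anchors: dict
    soil_factor_L: float = 0.0


# Anchor wavelengths follow the canopy red-edge/NIR conventions of the
# low-green-vegetation setting; SAVI/MSAVI use L = 1 accordingly.
INDEX_DEFINITIONS = {
    "NDVI": IndexDefinition("NDVI", {"NIR": 801, "RED": 682}),
    "ReCI": IndexDefinition("ReCI", {"NIR": 801, "RED": 701}),
    "NDRE": IndexDefinition("NDRE", {"NIR": 801, "RED_EDGE": 720}),
    "GNDVI": IndexDefinition("GNDVI", {"NIR": 801, "GREEN": 561}),
    "SAVI": IndexDefinition("SAVI", {"NIR": 820, "RED": 680}, soil_factor_L=1.0),
    "SIPI": IndexDefinition("SIPI", {"NIR": 820, "BLUE": 462, "RED": 712}),
    "MSAVI": IndexDefinition("MSAVI", {"NIR": 801, "RED": 682}),
}

INDEX_NAMES = tuple(INDEX_DEFINITIONS)


def compute_index(
    spectrum: np.ndarray, definition: IndexDefinition | str, grid: np.ndarray
) -> float | np.ndarray:
    """Evaluate one index on a spectrum (or a stack of spectra).

    Anchors resolve to the nearest grid channel.  Vectorised over leading
    dimensions: a (n, bands) stack returns n values.
    """
    if isinstance(definition, str):
        definition = INDEX_DEFINITIONS[definition]
    spectrum = np.asarray(spectrum, dtype=float)
    rho = {
        role: spectrum[..., wavelength_to_channel(grid, nm)]
        for role, nm in definition.anchors.items()
    }
    name = definition.name
    if name == "NDVI" or name == "NDRE" or name == "GNDVI":
        other = rho.get("RED", rho.get("RED_EDGE", rho.get("GREEN")))
        denom = rho["NIR"] + other
        _check_denominator(name, denom)
        return (rho["NIR"] - other) / denom
    if name == "ReCI":
        _check_denominator(name, rho["RED"])
        return rho["NIR"] / rho["RED"] - 1.0
    if name == "SAVI":
        L = definition.soil_factor_L
        denom = rho["NIR"] + rho["RED"] + L
        _check_denominator(name, denom)
        return (rho["NIR"] - rho["RED"]) / denom * (1.0 + L)
    if name == "SIPI":
        denom = rho["NIR"] - rho["RED"]
        _check_denominator(name, denom)
        return (rho["NIR"] - rho["BLUE"]) / denom
    if name == "MSAVI":
        nir, red = rho["NIR"], rho["RED"]
        disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - red)
        if np.any(disc < 0):
            raise DataError("MSAVI discriminant negative")
        return 0.5 * (2.0 * nir + 1.0 - np.sqrt(disc))
    raise ConfigurationError(f"unknown index {name!r}")


def _check_denominator(name: str, denom) -> None:
    if np.any(np.asarray(denom) == 0):
        raise DataError(f"{name} undefined: zero denominator")


def compute_index_table(spectra: np.ndarray, grid: np.ndarray) -> pd.DataFrame:
    """All seven indices for a (samples, bands) reflectance matrix."""
    return pd.DataFrame(
        {name: compute_index(spectra, name, grid) for name in INDEX_NAMES}
    )


# ---------------------------------------------------------------------------
# Screening


@dataclass
class IndexScreenResult:
    importances: dict
    stepwise_kept: list
    correlation_matrix: pd.DataFrame
    final_set: list
    dropped: dict = field(default_factory=dict)  # name -> reason

    def to_dict(self) -> dict:
        return {
            "importances": {k: float(v) for k, v in self.importances.items()},
            "stepwise_kept": list(self.stepwise_kept),
            "correlation_matrix": self.correlation_matrix.round(6).to_dict(),
            "final_set": list(self.final_set),
            "dropped": dict(self.dropped),
        }


def rank_importance(
    index_table: pd.DataFrame, y: np.ndarray, n_trees: int = 500, seed: int = 0
) -> dict:
    """Impurity-based random-forest importances, normalised and sorted descending."""
    if index_table.shape[1] < 2:
        raise ConfigurationError("need at least 2 indices to rank")
    if index_table.shape[0] < 10:
        raise ConfigurationError("need at least 10 samples to rank")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise DataError("constant yield: importances undefined")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(index_table.to_numpy(), y)
    imp = rf.feature_importances_
    imp = imp / imp.sum()
    order = np.argsort(imp)[::-1]
    return {index_table.columns[i]: float(imp[i]) for i in order}


def stepwise_select(
    index_table: pd.DataFrame,
    y: np.ndarray,
    importances: dict | None = None,
    tol: float = 1e-4,
    n_trees: int = 200,
    folds: int = 5,
    seed: int = 0,
) -> list:
    """Forward stepwise retention in descending-importance order.

    A candidate is kept when adding it lowers the k-fold CV RMSE of the
    incremental random-forest model by more than ``tol``; the scan stops
    after two consecutive failures.  A single-column table is kept as is.
    """
    y = np.asarray(y, dtype=float)
    if index_table.shape[1] == 1:
        return list(index_table.columns)
    if importances is None:
        importances = rank_importance(index_table, y, seed=seed)
    order = list(importances)

    def cv_rmse(cols: list) -> float:
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = cross_val_score(
            rf, index_table[cols].to_numpy(), y,
            scoring="neg_root_mean_squared_error", cv=cv,
        )
        return -float(scores.mean())

    kept: list = []
    best = np.inf
    failures = 0
    for name in order:
        candidate = kept + [name]
        score = cv_rmse(candidate)
        if best - score > tol:
            kept = candidate
            best = score
            failures = 0
        else:
            failures += 1
            if failures >= 2:
                break
    return kept


def correlation_prune(
    index_table: pd.DataFrame,
    kept: list,
    importances: dict,
    threshold_pos: float = 0.90,
    use_abs: bool = False,
) -> tuple[list, pd.DataFrame, dict]:
    """Drop the lower-importance member of each highly correlated pair.

    The Pearson matrix is computed over *all* columns of ``index_table``;
    pruning acts within ``kept``.  By default only positive correlations
    ``r >= threshold_pos`` trigger a drop — strongly anti-correlated pairs
    are treated as complementary and retained; set ``use_abs`` for the
    sign-agnostic |r| rule.

    Returns ``(final_names, correlation_matrix, dropped_reasons)``.
    """
    corr = index_table.corr(method="pearson")
    final = list(kept)
    dropped: dict = {}
    pairs = []
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            r = float(corr.loc[a, b])
            stat = abs(r) if use_abs else r
            if stat >= threshold_pos:
                pairs.append((stat, a, b, r))
    for _, a, b, r in sorted(pairs, reverse=True):
        if a not in final or b not in final:
            continue
        loser = a if importances.get(a, 0.0) < importances.get(b, 0.0) else b
        winner = b if loser == a else a
        final.remove(loser)
        dropped[loser] = f"r={r:.2f} with {winner}"
    return final, corr, dropped


def screen_indices(
    index_table: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 500,
    threshold_pos: float = 0.90,
    use_abs: bool = False,
    seed: int = 0,
) -> IndexScreenResult:
    """Full three-stage screen: importance ranking, stepwise, correlation prune.

    The correlation stage considers all seven candidate indices (not just
    the stepwise survivors), since anti-correlated index families excluded
    by the stepwise scan can still carry complementary physiological
    signal; the stepwise list is reported alongside for inspection.
    """
    importances = rank_importance(index_table, y, n_trees=n_trees, seed=seed)
    kept = stepwise_select(index_table, y, importances=importances, seed=seed)
    final, corr, dropped = correlation_prune(
        index_table, list(index_table.columns), importances,
        threshold_pos=threshold_pos, use_abs=use_abs,
    )
    return IndexScreenResult(
        importances=importances,
        stepwise_kept=kept,
        correlation_matrix=corr,
        final_set=final,
        dropped=dropped,
    )
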