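"""Experiment orchestration: pretreatment comparison, input-set grammar, model sweep.

Input-set codes name the feature blocks fed to a model: ``A1`` is the full
pretreated band set, ``A2`` the four screened vegetation indices, ``A3``-``A8``
the band subsets chosen by PSO, PSAMA, SPA, PCA, LASSO and CARS, and ``B``
the four ROI-pixel-set summary features.  A code is ``base + optional A2 +
optional B`` (e.g. ``A4A2B``); the sweep enumerates the 30 standard codes
crossed with the seven model kinds (210 runs).

Everything downstream of the split consumes training (and validation) rows
only: pretreatment statistics, index screening, band selection and tuning
never see the test split.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hypyield import band_selection, indices as indices_mod, models as models_mod
from hypyield.containers import SampleTable
from hypyield.errors import ConfigurationError
from hypyield.preprocessing import PretreatmentSpec
from hypyield.synthetic import SceneConfig

log = logging.getLogger(__name__)

BASES = tuple(f"A{i}" for i in range(1, 9))
BASE_TO_SELECTOR = {
    "A3": "pso", "A4": "psama", "A5": "spa", "A6": "pca", "A7": "lasso", "A8": "cars",
}
_CODE_RE = re.compile(r"^(A[1-8])(A2)?(B)?$")


def standard_codes() -> list[str]:
    """The 30 standard input-set codes: base x {-, B, A2, A2B} (A2 only x {-, B})."""
    codes = []
    for base in BASES:
        suffixes = ["", "B"] if base == "A2" else ["", "B", "A2", "A2B"]
        codes.extend(base + s for s in suffixes)
    return codes


def parse_code(code: str) -> tuple[str, bool, bool]:
    """Split a code into (base, has_A2, has_B); rejects A2 combined with itself."""
    m = _CODE_RE.match(code)
    if not m:
        raise ConfigurationError(f"invalid input-set code {code!r}")
    base, a2, b = m.group(1), bool(m.group(2)), bool(m.group(3))
    if base == "A2" and a2:
        raise ConfigurationError("A2 cannot combine with itself")
    return base, a2, b


def build_input_set(
    code: str,
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    subsets: dict,
    index_table: pd.DataFrame,
    screened_indices: list,
    rop: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the feature matrix for one code, with column provenance.

    Block order is base, then the screened indices (A2), then the ROP
    features (B).  ``subsets`` maps base codes A3-A8 to
    :class:`~hypyield.band_selection.BandSubset` objects.
    """
    base, has_a2, has_b = parse_code(code)
    blocks: list[np.ndarray] = []
    provenance: list[str] = []
    if base == "A1":
        blocks.append(np.asarray(spectra, dtype=float))
        provenance.extend(f"band:{wl:.1f}nm" for wl in wavelengths)
    elif base == "A2":
        blocks.append(index_table[screened_indices].to_numpy(dtype=float))
        provenance.extend(f"index:{n}" for n in screened_indices)
    else:
        subset = subsets[base]
        idx = subset.channel_indices
        blocks.append(np.asarray(spectra, dtype=float)[:, idx])
        provenance.extend(f"band:{wavelengths[i]:.1f}nm" for i in idx)
    if has_a2:
        blocks.append(index_table[screened_indices].to_numpy(dtype=float))
        provenance.extend(f"index:{n}" for n in screened_indices)
    if has_b:
        if rop is None:
            raise ConfigurationError(f"code {code!r} needs ROP features")
        blocks.append(np.asarray(rop, dtype=float))
        provenance.extend(f"rop:{n}" for n in ("pixel_count", "dispersion", "brightness", "heterogeneity"))
    return np.column_stack(blocks), provenance


# ---------------------------------------------------------------------------
# Pretreatment comparison


def compare_pretreatments(
    table: SampleTable,
    methods: tuple[str, ...] = ("msc", "snv", "sg", "fd", "ss"),
    model: str = "plsr",
    seed: int = 0,
    folds: int = 5,
    include_raw: bool = True,
) -> pd.DataFrame:
    """Fit a tuned model on raw + each pretreated spectrum set; rank by Rp2.

    Pretreatment state fits on the calibration (training) rows only.
    Returns one row per method with calibration and prediction metrics,
    sorted by decreasing prediction R^2.
    """
    if len(methods) < 2:
        raise ConfigurationError("need at least 2 pretreatment methods to compare")
    if table.split is None:
        table = models_mod.split_dataset(table, models_mod.SplitSpec(seed=seed))
    candidates = (["raw"] if include_raw else []) + list(methods)
    rows = []
    tr_mask = table.split == "train"
    for method in candidates:
        spec = PretreatmentSpec(method=method).fit(table.spectra[tr_mask])
        X = spec.apply(table.spectra, table.wavelengths)
        ym = models_mod.YieldModel(
            X, table.y, table.split, kind=model, training_seed=seed,
        )
        res = ym.fit(tune=True, folds=folds)
        rows.append({
            "method": method,
            "Rc2": res.Rc2, "RMSEc": res.RMSEc,
            "Rp2": res.Rp2, "RMSEp": res.RMSEp,
            "hyperparameters": str(res.fitted.spec.hyperparameters),
        })
    df = pd.DataFrame(rows).sort_values("Rp2", ascending=False, kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything a sweep needs, fully seeded and serialisable."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    pretreatment: str = "snv"
    split_seed: int = 0
    selection_seed: int = 0
    training_seed: int = 0
    folds: int = 5
    tune: bool = True
    selector_k: dict = field(default_factory=dict)      # method -> k_bands
    swarm_particles: int = 30
    swarm_iters: int = 100
    cars_runs: int = 50
    nn_options: dict = field(default_factory=dict)      # recurrent schedule
    codes: list | None = None                           # None -> all 30
    model_kinds: list | None = None                     # None -> all 7
    output_dir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.md5(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def reduced_protocol(seed: int = 0) -> RunConfig:
    """Desk-scale sweep profile: 50 samples, 64 bands, light recurrent training.

    The statistical structure (trait-linked spectra, 70/15/15 split, full
    30-code x 7-model enumeration) is unchanged; only problem sizes and
    training schedules shrink so a full sweep runs in minutes on one CPU.
    """
    return RunConfig(
        scene=SceneConfig(n_samples=50, n_bands=64, roi_pixels=25, seed=seed),
        split_seed=seed,
        selection_seed=seed,
        training_seed=seed,
        folds=3,
        tune=False,
        selector_k={"pso": 6, "psama": 8, "spa": 6, "pca": 8, "lasso": 8},
        swarm_particles=8,
        swarm_iters=10,
        cars_runs=15,
        nn_options={"max_epochs": 8, "hidden_size": 8, "patience": 4},
    )


# ---------------------------------------------------------------------------
# Sweep


def prepare_features(
    table: SampleTable, config: RunConfig, rop: np.ndarray | None = None
) -> dict:
    """Shared stage outputs feeding every grid run.

    Splits the table, fits the pretreatment on the training rows, screens
    the vegetation indices on training rows, and runs every band selector
    on the pretreated training spectra.
    """
    if table.split is None:
        table = models_mod.split_dataset(table, models_mod.SplitSpec(seed=config.split_seed))
    tr = table.split == "train"

    spec = PretreatmentSpec(method=config.pretreatment).fit(table.spectra[tr])
    X_pre = spec.apply(table.spectra, table.wavelengths)
    wl_pre = spec.output_wavelengths(table.wavelengths)

    # vegetation indices are computed from reflectance; screening sees train rows only
    index_table = indices_mod.compute_index_table(table.spectra, table.wavelengths)
    screen = indices_mod.screen_indices(
        index_table.loc[tr].reset_index(drop=True), table.y[tr], seed=config.selection_seed
    )

    subsets = {}
    for base, method in BASE_TO_SELECTOR.items():
        k = config.selector_k.get(method)
        kwargs = {}
        if method in ("pso", "psama"):
            cfg = band_selection.SwarmConfig(
                n_particles=config.swarm_particles,
                max_iter=config.swarm_iters,
                k_bands=k or (10 if method == "pso" else 20),
                seed=config.selection_seed,
            )
            fn = band_selection.pso_select if method == "pso" else band_selection.psama_select
            subset = fn(X_pre[tr], table.y[tr], cfg, folds=config.folds)
        elif method == "cars":
            subset = band_selection.cars_select(
                X_pre[tr], table.y[tr], n_runs=config.cars_runs,
                folds=config.folds, seed=config.selection_seed,
            )
        else:
            subset = band_selection.select(
                method, X_pre[tr], table.y[tr], k_bands=k,
                seed=config.selection_seed, **kwargs,
            )
        subset.wavelengths_nm = [float(wl_pre[i]) for i in subset.channel_indices]
        subsets[base] = subset

    return {
        "table": table,
        "pretreatment": spec,
        "X_pre": X_pre,
        "wl_pre": wl_pre,
        "index_table": index_table,
        "screen": screen,
        "subsets": subsets,
        "rop": rop,
    }


def run_grid(
    table: SampleTable,
    config: RunConfig,
    rop: np.ndarray | None = None,
    features: dict | None = None,
) -> pd.DataFrame:
    """Enumerate input-set codes x model kinds; one evaluated row per run.

    Failed runs are recorded with status "failed" and the sweep continues.
    The result table is sorted by decreasing prediction R^2 and, when
    ``config.output_dir`` is set, written as ``results.csv`` with a
    JSON-lines run log alongside.
    """
    feats = features or prepare_features(table, config, rop=rop)
    table = feats["table"]
    codes = config.codes or standard_codes()
    kinds = config.model_kinds or list(models_mod.MODEL_KINDS)
    if feats["rop"] is None:
        codes = [c for c in codes if not parse_code(c)[2]]

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log_rows = []
    rows = []
    cfg_hash = config.config_hash()
    for code in codes:
        try:
            X, provenance = build_input_set(
                code, feats["X_pre"], feats["wl_pre"], feats["subsets"],
                feats["index_table"], feats["screen"].final_set, feats["rop"],
            )
        except Exception as exc:  # noqa: BLE001 - recorded, sweep continues
            for kind in kinds:
                rows.append(_failed_row(code, kind, exc))
            continue
        for kind in kinds:
            t0 = time.perf_counter()
            try:
                ym = models_mod.YieldModel(
                    X, table.y, table.split, kind=kind,
                    input_code=code, training_seed=config.training_seed,
                    nn_options=config.nn_options or None,
                )
                res = ym.fit(tune=config.tune, folds=config.folds)
                row = res.report.to_row()
                row["status"] = "ok"
                row["n_features"] = X.shape[1]
                rows.append(row)
            except Exception as exc:  # noqa: BLE001
                rows.append(_failed_row(code, kind, exc))
            log_rows.append({
                "code": code, "model": kind, "config_hash": cfg_hash,
                "seed": config.training_seed,
                "wall_time_s": round(time.perf_counter() - t0, 4),
            })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["Rp2", "input_code", "model"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    if out_dir:
        df.to_csv(out_dir / "results.csv", index=False)
        with open(out_dir / "runs.jsonl", "w") as fh:
            for entry in log_rows:
                fh.write(json.dumps(entry) + "\n")
    return df


def _failed_row(code: str, kind: str, exc: Exception) -> dict:
    log.warning("run %s/%s failed: %s", code, kind, exc)
    return {
        "input_code": code, "model": kind,
        "Rc2": np.nan, "RMSEc": np.nan, "Rp2": np.nan, "RMSEp": np.nan,
        "hyperparameters": "", "status": f"failed: {type(exc).__name__}",
        "n_features": np.nan,
    }


# ---------------------------------------------------------------------------
# Hyperparameter heatmap


def hyperparameter_heatmap(
    surface: pd.DataFrame,
    x: str = "learning_rate",
    y: str = "hidden_layer_size",
    value: str = "cv_rmse",
    out_csv: str | Path | None = None,
    out_png: str | Path | None = None,
    minimize: bool = True,
) -> tuple[pd.DataFrame, tuple]:
    """Pivot a grid-search score surface to a 2-D table and annotate the best cell.

    Returns ``(pivot, (best_x, best_y))``.  Raises if the surface is not a
    full rectangle over the two axes.
    """
    for col in (x, y, value):
        if col not in surface.columns:
            raise ConfigurationError(f"surface lacks column {col!r}")
    pivot = surface.pivot_table(index=y, columns=x, values=value, aggfunc="first")
    if pivot.isna().any().any() or len(surface) != pivot.size:
        raise ConfigurationError("score surface is not rectangular")
    arr = pivot.to_numpy()
    flat = int(np.argmin(arr) if minimize else np.argmax(arr))
    iy, ix = np.unravel_index(flat, arr.shape)
    best = (pivot.columns[ix], pivot.index[iy])
    if out_csv:
        pivot.to_csv(out_csv)
    if out_png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 + pivot.shape[1], 1.0 + pivot.shape[0] * 0.6))
        im = ax.imshow(arr, cmap="Reds_r" if minimize else "Reds", aspect="auto")
        ax.set_xticks(range(pivot.shape[1]), [str(c) for c in pivot.columns])
        ax.set_yticks(range(pivot.shape[0]), [str(i) for i in pivot.index])
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        ax.plot(ix, iy, "k*", markersize=14)
        for (r, c), val in np.ndenumerate(arr):
            ax.text(c, r, f"{val:.3g}", ha="center", va="center", fontsize=8)
        fig.colorbar(im, ax=ax, label=value)
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return pivot, best
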