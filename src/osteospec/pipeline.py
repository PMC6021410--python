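"""Pipeline orchestration: simulate -> preprocess -> fit per window ->
morphometry -> statistics -> report, with fixed on-disk contracts.

The central product is the window-comparison table: for every optical
window and every morphometric parameter, the chosen number of PLS
components, cross-validated R^2, RMSECV and RMSEC (both percent of the
reference range), with the best window per parameter flagged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .datasets import SpectralDataset
from .groupstats import classify_mankin, compare_classes, compare_locations
from .morphometry import morphometry_report
from .pls import kfold_cv
from .preprocess import PreprocessConfig, check_uniform_grid, extract_window, msc_correct, sg_derivative
from .synthetic import MORPH_PARAMS, CohortConfig, generate_cohort

__all__ = [
    "RunConfig",
    "run_window_comparison",
    "run_group_statistics",
    "run_morphometry",
    "render_report",
    "run_all",
]

log = logging.getLogger("osteospec")

PARAM_LABELS = {
    "sb_th_mm": "Sb.Th (mm)",
    "tb_th_mm": "Tb.Th (mm)",
    "bvtv_fraction": "BV/TV",
    "smi": "SMI",
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv_folds: int = 10
    ncomp_grid: tuple[int, ...] = tuple(range(1, 16))
    selection_tolerance: float = 0.05
    per_fold_preprocessing: bool = True
    cv_seed: int = 0
    with_volumes: bool = False
    max_morphometry_volumes: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.get("cohort", {}))
        prep = PreprocessConfig(**raw.get("preprocess", {}))
        keys = {
            f.name
            for f in dataclasses.fields(cls)
            if f.name not in ("cohort", "preprocess")
        }
        extra = {k: v for k, v in raw.items() if k in keys}
        unknown = set(raw) - keys - {"cohort", "preprocess"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(cohort=cohort, preprocess=prep, **extra)
        if isinstance(cfg.ncomp_grid, list):
            cfg.ncomp_grid = tuple(cfg.ncomp_grid)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["window_defs"] = [
            {"name": w.name, "lo_nm": w.lo_nm, "hi_nm": w.hi_nm}
            for w in self.cohort.window_defs
        ]
        return d


def make_fold_preprocessor(config: PreprocessConfig, grid_step: float):
    """Build a per-training-fold preprocessing closure for cross-validation.

    The MSC reference is the training-fold mean spectrum, so held-out
    spectra never influence their own correction (leakage-safe).
    """

    def prep(X_train):
        ref = X_train.mean(axis=0) if config.apply_msc else None
        def apply(X):
            if ref is not None:
                X, _, _ = msc_correct(X, reference=ref)
            if config.derivative_order > 0:
                X = sg_derivative(X, config, grid_step)
            return X
        return apply(X_train), apply

    return prep


def run_window_comparison(
    ds: SpectralDataset,
    truth: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Cross-validated PLS1 metrics for every window x parameter pair.

    Returns a tidy DataFrame with one row per (window, parameter):
    chosen component count, cv-R^2 (%), RMSECV (%), RMSEC (%), the R^2
    method chosen by the normality gate, and a best-window flag.
    """
    rows = []
    for window in config.cohort.window_defs:
        sub = extract_window(ds, window)
        step = check_uniform_grid(sub.wavelengths)
        X_raw = sub.absorbance
        prep = make_fold_preprocessor(config.preprocess, step)
        for param in MORPH_PARAMS:
            y = truth[param].to_numpy(dtype=float)
            if config.per_fold_preprocessing:
                cv = kfold_cv(
                    X_raw, y,
                    k=config.cv_folds,
                    ncomp_grid=config.ncomp_grid,
                    seed=config.cv_seed,
                    selection_tolerance=config.selection_tolerance,
                    preprocessor=prep,
                )
            else:
                X_once, _ = prep(X_raw)
                cv = kfold_cv(
                    X_once, y,
                    k=config.cv_folds,
                    ncomp_grid=config.ncomp_grid,
                    seed=config.cv_seed,
                    selection_tolerance=config.selection_tolerance,
                )
            rows.append(
                {
                    "window": window.name,
                    "parameter": param,
                    "n_components": cv.chosen_ncomp,
                    "cv_r2_pct": cv.chosen_cv_r2,
                    "rmsecv_pct": cv.chosen_rmsecv,
                    "rmsec_pct": cv.chosen_rmsec,
                    "r2_method": cv.r2_method,
                }
            )
            log.info(
                "window %s param %s: N=%d cv-R2=%.1f%% RMSECV=%.1f%%",
                window.name, param, cv.chosen_ncomp, cv.chosen_cv_r2, cv.chosen_rmsecv,
            )
    results = pd.DataFrame(rows)
    best = results.loc[results.groupby("parameter")["cv_r2_pct"].idxmax()]
    results["best_window"] = False
    results.loc[best.index, "best_window"] = True
    return results


def cv_predictions_for(
    ds: SpectralDataset,
    truth: pd.DataFrame,
    config: RunConfig,
    window_name: str,
    param: str,
):
    """Cross-validated predictions for one window/parameter (for plots)."""
    window = next(w for w in config.cohort.window_defs if w.name == window_name)
    sub = extract_window(ds, window)
    step = check_uniform_grid(sub.wavelengths)
    prep = make_fold_preprocessor(config.preprocess, step)
    y = truth[param].to_numpy(dtype=float)
    cv = kfold_cv(
        sub.absorbance, y,
        k=config.cv_folds,
        ncomp_grid=config.ncomp_grid,
        seed=config.cv_seed,
        selection_tolerance=config.selection_tolerance,
        preprocessor=prep if config.per_fold_preprocessing else None,
    )
    return y, cv


def run_group_statistics(truth: pd.DataFrame) -> dict:
    """Location and Mankin-class statistics for all four parameters."""
    out: dict = {"locations": {}, "classes": {}, "class_counts": {}}
    labels = classify_mankin(truth["mankin"].to_numpy())
    counts = pd.Series(labels).value_counts().to_dict()
    out["class_counts"] = {k: int(v) for k, v in counts.items()}
    for param in MORPH_PARAMS:
        loc = compare_locations(truth, param)
        out["locations"][param] = {
            "omnibus_test": loc.omnibus_test,
            "omnibus_p": loc.omnibus_p,
            "pairwise_test": loc.pairwise_test,
            "pairwise_p": {
                f"{a}|{b}": float(loc.pairwise_p.loc[a, b])
                for a in loc.pairwise_p.index
                for b in loc.pairwise_p.columns
                if a < b
            },
            "all_normal": loc.all_normal,
        }
        cls = compare_classes(truth, param)
        out["classes"][param] = {
            "test": cls.test,
            "p": cls.p_value,
            "summaries": {
                c: {
                    "n": int(cls.summaries.loc[c, "n"]),
                    "mean": float(cls.summaries.loc[c, "mean"]),
                    "ci_lo": float(cls.summaries.loc[c, "ci_lo"]),
                    "ci_hi": float(cls.summaries.loc[c, "ci_hi"]),
                }
                for c in cls.summaries.index
            },
        }
    return out


def run_morphometry(volumes, truth: pd.DataFrame, voi_mm, max_volumes=None) -> pd.DataFrame:
    """Morphometric parameters measured from the generated volumes."""
    rows = []
    for (_, t), vol in zip(truth.iterrows(), volumes):
        if max_volumes is not None and len(rows) >= max_volumes:
            break
        try:
            res = morphometry_report(vol, voi_mm)
        except ValueError as exc:
            raise RuntimeError(
                f"morphometry failed for sample {t['sample_id']}: {exc}"
            ) from exc
        rows.append({"sample_id": t["sample_id"], **res.as_dict()})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def render_report(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    ds: SpectralDataset,
    config: RunConfig,
    out_dir,
) -> list[Path]:
    """Scatter + residual panels per parameter (best window) and box plots
    by location and Mankin class.  All numbers come from the result
    objects; nothing is recomputed inside the plotting code paths."""
    if results.empty:
        raise ValueError("empty results: nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    png_meta = {"Software": None}

    from .pls import residual_percent  # local import to keep plotting thin

    for param in MORPH_PARAMS:
        sub = results[results["parameter"] == param]
        best_row = sub[sub["best_window"]].iloc[0]
        y, cv = cv_predictions_for(ds, truth, config, best_row["window"], param)
        yhat = cv.chosen_cv_predictions
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(y, yhat, s=18, c="tab:blue", edgecolors="k", linewidths=0.3)
        lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
        ax1.plot(lims, lims, "k--", lw=0.8)
        ax1.set_xlabel(f"measured {PARAM_LABELS[param]}")
        ax1.set_ylabel(f"predicted {PARAM_LABELS[param]}")
        ax1.set_title(
            f"{best_row['window']}: N={best_row['n_components']}, "
            f"R$^2$={best_row['cv_r2_pct']:.1f}%"
        )
        res_pct = residual_percent(y, yhat)
        ax2.bar(np.arange(res_pct.size), res_pct, color="tab:gray")
        ax2.axhline(0, color="k", lw=0.8)
        ax2.set_xlabel("sample")
        ax2.set_ylabel("residual (% of range)")
        fig.tight_layout()
        p = out_dir / f"prediction_{param}.png"
        fig.savefig(p, dpi=120, metadata=png_meta)
        plt.close(fig)
        written.append(p)

    # box plots by location and by Mankin class
    fig, axes = plt.subplots(2, 4, figsize=(14, 7))
    labels = classify_mankin(truth["mankin"].to_numpy())
    for j, param in enumerate(MORPH_PARAMS):
        ax = axes[0, j]
        data = [truth.loc[truth["location"] == g, param] for g in sorted(truth["location"].unique())]
        ax.boxplot(data, tick_labels=sorted(truth["location"].unique()))
        ax.set_title(PARAM_LABELS[param])
        ax = axes[1, j]
        data = [truth.loc[labels == c, param] for c in ("Class1", "Class2")]
        ax.boxplot(data, tick_labels=["Class1", "Class2"])
        ax.set_xlabel("Mankin class")
    fig.tight_layout()
    p = out_dir / "group_boxplots.png"
    fig.savefig(p, dpi=120, metadata=png_meta)
    plt.close(fig)
    written.append(p)
    return written


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig, out_dir, make_figures: bool = True) -> dict:
    """Execute every stage and write the standard output contract:
    spectra/metadata/truth CSVs, results.csv, morphometry.csv (if volumes),
    stats.json, run_manifest.json and figures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("simulating cohort (n=%d, seed=%d)", config.cohort.n_samples, config.cohort.seed)
    ds, volumes, truth = generate_cohort(
        config.cohort, out_dir=out_dir, with_volumes=config.with_volumes
    )

    results = run_window_comparison(ds, truth, config)
    results.to_csv(out_dir / "results.csv", index=False, float_format="%.6f")

    stats_payload = run_group_statistics(truth)
    (out_dir / "stats.json").write_text(json.dumps(stats_payload, indent=2, sort_keys=True))

    if volumes is not None:
        morpho = run_morphometry(
            volumes, truth, config.cohort.voi_mm, config.max_morphometry_volumes
        )
        morpho.to_csv(out_dir / "morphometry.csv", index=False, float_format="%.6f")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed,
        "n_samples": int(config.cohort.n_samples),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))

    if make_figures:
        render_report(results, truth, ds, config, out_dir / "figures")

    return {"results": results, "stats": stats_payload, "truth": truth}
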