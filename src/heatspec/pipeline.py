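"""Stage-wise study orchestration.

Runs, per growth stage: preprocessing (smoothing + FDR), trilateral
extraction, correlation spectra, top-10 and SPA band selection,
two-band index optimisation, feature-set assembly and the full
model x indicator x group x feature-set grid of fits; then compares
stages (red-edge shifts, amplitude/area orderings, per-indicator
percent change eta, best-feature tallies).

All randomness flows from one run seed; per-cell seeds are derived
deterministically from (stage, group, indicator) names so that a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as prep
from . import regression_models as rm
from . import synthetic_data as synth
from . import trilateral_features as tf
from . import vegetation_indices as vi
from .errors import ConfigError, EmptyFeatureSetError
from .spectra_io import SampleTable

logger = logging.getLogger(__name__)

GROUPS = ("CK", "T")

DEFAULT_STAGE_INDICATORS: dict[str, tuple[str, ...]] = {
    "branching": ("SPAD", "gsw", "qP"),
    "budding": ("SPAD", "A", "qN"),
    "flowering": ("SPAD", "gsw", "qP"),
}

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Full-pipeline configuration; every stated default is overridable."""

    simulation: synth.SimulationConfig = field(
        default_factory=synth.SimulationConfig)
    sg_window: int = 11
    sg_polyorder: int = 2
    derivative_method: str = "central"
    stride: int = 1
    spa_n_max: int = 10
    spa_stride: int = 5
    top_k: int = 10
    tp_threshold: float = 0.6
    cv_folds: int = 5
    test_fraction: float = 0.25
    models: Sequence[str] = rm.MODEL_KINDS
    feature_sets: Sequence[str] = rm.FEATURE_SETS
    index_kinds: Sequence[str] = vi.INDEX_KINDS
    indicators: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_INDICATORS))
    windows: tf.EdgeWindows = field(default_factory=tf.EdgeWindows)
    paper_mode: bool = False  # fit selectors on all data (comparability mode)

    def __post_init__(self):
        for m in self.models:
            if m not in rm.MODEL_KINDS:
                raise ConfigError(f"unknown model {m!r}")
        for f in self.feature_sets:
            if f not in rm.FEATURE_SETS:
                raise ConfigError(f"unknown feature set {f!r}")
        if self.stride < 1 or self.spa_stride < 1:
            raise ConfigError("strides must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "simulation": synth.config_to_dict(self.simulation),
            "windows": {f: list(getattr(self.windows, f))
                        for f in ("red_edge", "blue_edge", "yellow_edge",
                                  "green_peak", "red_valley")},
            "indicators": {k: list(v) for k, v in self.indicators.items()},
            "models": list(self.models),
            "feature_sets": list(self.feature_sets),
            "index_kinds": list(self.index_kinds),
        }
        for key in ("sg_window", "sg_polyorder", "derivative_method", "stride",
                    "spa_n_max", "spa_stride", "top_k", "tp_threshold",
                    "cv_folds", "test_fraction", "paper_mode"):
            d[key] = getattr(self, key)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        if "simulation" in kwargs:
            kwargs["simulation"] = synth.config_from_dict(kwargs["simulation"])
        if "windows" in kwargs:
            kwargs["windows"] = tf.EdgeWindows(
                **{k: tuple(v) for k, v in kwargs["windows"].items()})
        if "indicators" in kwargs:
            kwargs["indicators"] = {
                k: tuple(v) for k, v in kwargs["indicators"].items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StageReport:
    """All per-stage result tables (analogues of the study's tables)."""

    stage: str
    corr_tables: pd.DataFrame
    spa_tables: pd.DataFrame
    index_tables: pd.DataFrame
    model_tables: pd.DataFrame
    best_features: pd.DataFrame
    red_edge: pd.DataFrame
    eta: pd.DataFrame


def derive_seed(base_seed: int, *names) -> int:
    """Stable per-cell seed below 2^31 from a base seed and labels."""
    tag = "|".join(str(n) for n in names)
    return (int(base_seed) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


def preprocess_table(table: SampleTable, config: RunConfig):
    """Smooth and differentiate a stage table.

    Returns (wavelengths, smoothed reflectance, FDR) with the stride
    applied after smoothing/differentiation so FDR stays per nm.
    """
    wl = table.wavelengths
    X = table.spectra.to_numpy(dtype=float)
    step = float(wl[1] - wl[0])
    Xs = prep.smooth_matrix(X, config.sg_window, config.sg_polyorder)
    Xd = prep.derivative_matrix(Xs, step, method=config.derivative_method,
                                window=config.sg_window,
                                polyorder=config.sg_polyorder)
    s = config.stride
    return wl[::s], Xs[:, ::s], Xd[:, ::s]


def _eta_table(table: SampleTable, stage: str) -> pd.DataFrame:
    """Per-date and stage-mean percent change (T vs CK) per indicator."""
    rows = []
    meta = table.metadata
    phys = table.physiology
    indicators = list(phys.columns)
    dates = sorted(meta["date"].unique())
    for ind in indicators:
        stage_means = {}
        for g in GROUPS:
            stage_means[g] = phys.loc[meta["group"] == g, ind].mean()
        for date in dates:
            sel = meta["date"] == date
            v = {g: phys.loc[sel & (meta["group"] == g), ind].mean()
                 for g in GROUPS}
            rows.append({
                "stage": stage, "indicator": ind, "date": date,
                "eta_pct": rm.amplitude_of_variation(v["T"], v["CK"]),
            })
        rows.append({
            "stage": stage, "indicator": ind, "date": "stage_mean",
            "eta_pct": rm.amplitude_of_variation(stage_means["T"],
                                                 stage_means["CK"]),
        })
    return pd.DataFrame(rows)


def run_stage_analysis(table: SampleTable, config: RunConfig, stage: str,
                       seed: int = 0) -> StageReport:
    """Execute the full analysis for one stage's SampleTable."""
    wl, Xs, Xd = preprocess_table(table, config)
    meta = table.metadata
    trilat = tf.extract_table(wl, Xs, Xd, table.sample_ids, config.windows)

    red_edge_rows = []
    for g in GROUPS:
        gmask = (meta["group"] == g).to_numpy()
        sub = trilat.loc[gmask]
        red_edge_rows.append({
            "stage": stage, "group": g,
            "lambda_r_nm": sub["lambda_r"].mean(),
            "Dr": sub["Dr"].mean(),
            "SDr": sub["SDr"].mean(),
        })
    red_edge = pd.DataFrame(red_edge_rows)
    eta = _eta_table(table, stage)

    corr_rows, spa_rows, index_rows, model_rows = [], [], [], []
    indicators = config.indicators.get(stage, ("SPAD",))
    for indicator in indicators:
        if indicator not in table.physiology.columns:
            logger.warning("stage %s: indicator %s missing; skipped",
                           stage, indicator)
            continue
        for group in GROUPS:
            gmask = np.flatnonzero((meta["group"] == group).to_numpy())
            y = table.physiology[indicator].to_numpy(dtype=float)[gmask]
            ctx = rm.FeatureContext(wl, Xs[gmask], Xd[gmask],
                                    trilat.iloc[gmask])
            cell_seed = derive_seed(seed, stage, group, indicator)
            train, test = rm.split_train_test(len(gmask),
                                              config.test_fraction, cell_seed)
            fit_idx = np.arange(len(gmask)) if config.paper_mode else train
            selectors = rm.fit_selectors(
                ctx.take(fit_idx), y[fit_idx],
                tp_threshold=config.tp_threshold, top_k=config.top_k,
                spa_n_max=config.spa_n_max, spa_stride=config.spa_stride,
                cv_folds=config.cv_folds, seed=cell_seed,
            )
            corr_rows.append({
                "stage": stage, "indicator": indicator, "group": group,
                "kind": "original",
                "top_bands_nm": " ".join(f"{b:g}" for b in selectors.os1_bands),
            })
            corr_rows.append({
                "stage": stage, "indicator": indicator, "group": group,
                "kind": "first_derivative",
                "top_bands_nm": " ".join(f"{b:g}" for b in selectors.fds1_bands),
            })
            for kind_name, res in (("original", selectors.os2),
                                   ("first_derivative", selectors.fds2)):
                bands = selectors.spa_wavelengths[list(res.selected)]
                spa_rows.append({
                    "stage": stage, "indicator": indicator, "group": group,
                    "kind": kind_name,
                    "bands_nm": " ".join(f"{b:g}" for b in bands),
                    "k0_nm": f"{selectors.spa_wavelengths[res.k0]:g}",
                    "n_selected": res.n_selected,
                    "rmsecv": res.rmsecv,
                })
            for ikind in config.index_kinds:
                X_for = ctx.X_fd if ikind in vi.DERIVATIVE_KINDS else ctx.X_orig
                pair = vi.optimize_band_pair(
                    X_for[fit_idx], wl, y[fit_idx], ikind)
                index_rows.append({
                    "stage": stage, "indicator": indicator, "group": group,
                    "index_kind": ikind,
                    "lambda1_nm": pair.lambda1, "lambda2_nm": pair.lambda2,
                    "r": pair.r, "n": pair.n,
                })
            ctx_train, ctx_test = ctx.take(train), ctx.take(test)
            for fset in config.feature_sets:
                try:
                    F_train = rm.build_features(ctx_train, selectors, fset)
                    F_test = rm.build_features(ctx_test, selectors, fset)
                except EmptyFeatureSetError as exc:
                    logger.warning("stage %s %s/%s: feature set %s skipped: %s",
                                   stage, group, indicator, fset, exc)
                    continue
                for model in config.models:
                    rep = rm.evaluate(
                        model, F_train, y[train], F_test, y[test],
                        indicator=indicator, group=group, stage=stage,
                        feature_set=fset, seed=cell_seed,
                    )
                    model_rows.append(rep.as_dict())

    model_tables = pd.DataFrame(model_rows)
    best_rows = []
    if not model_tables.empty:
        for (model, indicator, group), sub in model_tables.groupby(
                ["model", "indicator", "group"], sort=True):
            best = sub.loc[sub["r2_test"].idxmax()]
            best_rows.append({
                "stage": stage, "model": model, "indicator": indicator,
                "group": group, "feature_set": best["feature_set"],
                "r2_train": best["r2_train"], "rmse_train": best["rmse_train"],
                "r2_test": best["r2_test"], "rmse_test": best["rmse_test"],
            })
    return StageReport(
        stage=stage,
        corr_tables=pd.DataFrame(corr_rows),
        spa_tables=pd.DataFrame(spa_rows),
        index_tables=pd.DataFrame(index_rows),
        model_tables=model_tables,
        best_features=pd.DataFrame(best_rows),
        red_edge=red_edge,
        eta=eta,
    )


@dataclass
class GroupComparison:
    """Cross-stage summaries derived from per-stage reports."""

    red_edge_shift: pd.DataFrame
    stage_order: pd.DataFrame
    eta_stage: pd.DataFrame
    best_feature_tally: pd.DataFrame


def compare_groups(reports: Sequence[StageReport]) -> GroupComparison:
    """Cross-stage CK vs T comparison; needs at least two stages."""
    if len(reports) < 2:
        raise ConfigError("compare_groups needs reports for >= 2 stages")
    shift_rows = []
    for rep in reports:
        re = rep.red_edge.set_index("group")
        shift = float(re.loc["T", "lambda_r_nm"] - re.loc["CK", "lambda_r_nm"])
        label = "red shift" if shift > 0 else ("blue shift" if shift < 0
                                               else "none")
        shift_rows.append({
            "stage": rep.stage,
            "lambda_r_CK_nm": float(re.loc["CK", "lambda_r_nm"]),
            "lambda_r_T_nm": float(re.loc["T", "lambda_r_nm"]),
            "shift_nm": shift, "label": label,
        })
    order_rows = []
    for group in GROUPS:
        for quantity in ("Dr", "SDr"):
            vals = {rep.stage: float(
                rep.red_edge.set_index("group").loc[group, quantity])
                for rep in reports}
            ordering = " > ".join(sorted(vals, key=vals.get, reverse=True))
            order_rows.append({"group": group, "quantity": quantity,
                               "ordering": ordering})
    eta_rows = []
    for rep in reports:
        sub = rep.eta[rep.eta["date"] == "stage_mean"]
        for _, row in sub.iterrows():
            eta_rows.append({"stage": rep.stage, "indicator": row["indicator"],
                             "eta_pct": row["eta_pct"]})
    tally = {}
    for rep in reports:
        if rep.best_features.empty:
            continue
        for fset, count in rep.best_features["feature_set"].value_counts().items():
            tally[fset] = tally.get(fset, 0) + int(count)
    tally_df = pd.DataFrame(
        sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature_set", "count"],
    )
    return GroupComparison(
        red_edge_shift=pd.DataFrame(shift_rows),
        stage_order=pd.DataFrame(order_rows),
        eta_stage=pd.DataFrame(eta_rows),
        best_feature_tally=tally_df,
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def run_full(config: RunConfig, out_dir=None, seed: int | None = None):
    """Simulate, analyse every stage, compare, and (optionally) write CSVs.

    Returns (stage reports, comparison).  ``seed`` overrides the
    simulation seed and seeds every downstream selector and model.
    """
    if seed is not None:
        sim = synth.config_from_dict(
            {**synth.config_to_dict(config.simulation), "seed": seed})
        config = RunConfig(**{**config.__dict__, "simulation": sim})
    run_seed = config.simulation.seed
    tables = synth.simulate_experiment(config.simulation)
    reports = []
    for stage, table in zip(config.simulation.stages, tables):
        logger.info("analysing stage %s (n=%d)", stage, len(table))
        reports.append(run_stage_analysis(table, config, stage, seed=run_seed))
    comparison = compare_groups(reports) if len(reports) >= 2 else None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        for rep in reports:
            for name in ("corr_tables", "spa_tables", "index_tables",
                         "model_tables", "best_features", "red_edge", "eta"):
                _write_csv(getattr(rep, name), out / f"{rep.stage}_{name}.csv")
        if comparison is not None:
            for name in ("red_edge_shift", "stage_order", "eta_stage",
                         "best_feature_tally"):
                _write_csv(getattr(comparison, name), out / f"summary_{name}.csv")
    return reports, comparison
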